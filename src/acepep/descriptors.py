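"""Amino-acid descriptor tables and peptide encoding.

Peptides are turned into residue-by-feature numeric matrices by looking each
residue up in one or more *descriptor sets* — published tables that assign
every natural amino acid a fixed-length vector of physicochemical properties
(z-scales, VHSE, FASGAI, ST-scales, ...).  Several sets can be concatenated
column-wise into a :class:`DescriptorCombination`, the encoding strategy used
throughout this package: the classifier, the grouped feature-elimination
search and the masking-based importance analysis all operate on these
combined encodings.

Tables are packaged as CSV files (header = feature names, 20 rows keyed by
one-letter residue code) together with a ``registry.json`` manifest and are
loaded with :func:`load_descriptor_registry`.  Each feature additionally
carries a *pattern tag* — one of ``geometrical``, ``electronic``,
``hydrophobic``, ``steric`` or ``composition`` — used to aggregate feature
importances into five physicochemical patterns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RESIDUES",
    "PATTERNS",
    "DescriptorSet",
    "DescriptorCombination",
    "EncodedPeptide",
    "DescriptorError",
    "EncodingError",
    "load_descriptor_registry",
    "standard_combinations",
    "encode",
    "encode_many",
    "mask_features",
]

#: The twenty natural residues, in the fixed column order used everywhere.
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: The five physicochemical pattern labels features may be tagged with.
PATTERNS = ("geometrical", "electronic", "hydrophobic", "steric", "composition")

#: Label of the optimal six-set, 37-feature combination shipped with the package.
OPTIMAL_COMBINATION = "VVSFZL37"

#: Label of the full all-sets combination.
FULL_COMBINATION = "CodeSet22"

_OPTIMAL_MEMBERS = ("VSW", "VHSE", "ST-scales", "FASGAI", "Z-scales", "Lin")


class DescriptorError(ValueError):
    """Raised when a descriptor table fails validation at load time."""


class EncodingError(ValueError):
    """Raised when a sequence cannot be encoded (bad residue, too short)."""


@dataclass(frozen=True)
class DescriptorSet:
    """One named residue → vector table.

    Parameters
    ----------
    name:
        Short identifier, unique within a registry (e.g. ``"Z-scales"``).
    table:
        Mapping from each of the 20 one-letter residue codes to a
        ``float64`` vector of length ``n_features``.
    feature_names:
        Unique names for the columns.
    pattern_tags:
        Per-feature physicochemical pattern label (one of :data:`PATTERNS`).
    source:
        Free-text provenance of the numeric values.
    synthetic:
        True when the numbers are a constructed stand-in rather than a
        published table.
    """

    name: str
    table: Mapping[str, np.ndarray]
    feature_names: tuple[str, ...]
    pattern_tags: tuple[str, ...]
    source: str = ""
    synthetic: bool = False

    def __post_init__(self) -> None:
        if set(self.table) != set(RESIDUES):
            missing = sorted(set(RESIDUES) - set(self.table))
            raise DescriptorError(
                f"descriptor set {self.name!r}: table must cover the 20 natural "
                f"residues (missing: {missing})"
            )
        n = self.n_features
        for res, vec in self.table.items():
            if len(vec) != n:
                raise DescriptorError(
                    f"descriptor set {self.name!r}: vector for {res} has length "
                    f"{len(vec)}, expected {n}"
                )
        if len(set(self.feature_names)) != n:
            raise DescriptorError(
                f"descriptor set {self.name!r}: feature names are not unique"
            )
        if len(self.pattern_tags) != n:
            raise DescriptorError(
                f"descriptor set {self.name!r}: {len(self.pattern_tags)} pattern "
                f"tags for {n} features"
            )
        bad = set(self.pattern_tags) - set(PATTERNS)
        if bad:
            raise DescriptorError(
                f"descriptor set {self.name!r}: unknown pattern tags {sorted(bad)}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def as_matrix(self) -> np.ndarray:
        """20 × n_features matrix in :data:`RESIDUES` row order."""
        return np.stack([self.table[r] for r in RESIDUES])


@dataclass(frozen=True)
class DescriptorCombination:
    """An ordered concatenation of descriptor sets.

    ``total_features`` is always the sum of the members' widths; feature
    columns appear in member order, each member's columns in its own order.
    """

    member_sets: tuple[str, ...]
    member_features: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if len(set(self.member_sets)) != len(self.member_sets):
            raise DescriptorError(
                f"combination {self.label!r}: member set names must be unique"
            )
        if len(self.member_features) != len(self.member_sets):
            raise DescriptorError(
                f"combination {self.label!r}: member_features length mismatch"
            )

    @property
    def total_features(self) -> int:
        return int(sum(self.member_features))

    def without(self, member: str) -> "DescriptorCombination":
        """A new combination with one member removed (for Leave-Group-Out)."""
        if member not in self.member_sets:
            raise DescriptorError(f"{member!r} is not a member of {self.label!r}")
        keep = [(s, n) for s, n in zip(self.member_sets, self.member_features) if s != member]
        names = tuple(s for s, _ in keep)
        return DescriptorCombination(
            member_sets=names,
            member_features=tuple(n for _, n in keep),
            label="+".join(names),
        )


@dataclass
class EncodedPeptide:
    """Residue-by-feature matrix for one peptide.

    ``matrix`` has one row per residue and one column per combined feature;
    ``mask`` flags real rows (all ``True`` here — padding is introduced only
    transiently inside batched model code and never leaks back out).
    """

    matrix: np.ndarray
    mask: np.ndarray
    sequence: str

    def copy(self) -> "EncodedPeptide":
        return EncodedPeptide(self.matrix.copy(), self.mask.copy(), self.sequence)


class DescriptorRegistry:
    """Named collection of :class:`DescriptorSet` with combination helpers."""

    def __init__(self, sets: Iterable[DescriptorSet]):
        self._sets: dict[str, DescriptorSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise DescriptorError(f"duplicate descriptor set name {s.name!r}")
            self._sets[s.name] = s

    def __getitem__(self, name: str) -> DescriptorSet:
        try:
            return self._sets[name]
        except KeyError:
            raise KeyError(
                f"unknown descriptor set {name!r}; available: {sorted(self._sets)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def combination(
        self, members: Sequence[str], label: str | None = None
    ) -> DescriptorCombination:
        """Build a combination of registered sets, validating membership."""
        feats = tuple(self[m].n_features for m in members)
        return DescriptorCombination(
            member_sets=tuple(members),
            member_features=feats,
            label=label or "+".join(members),
        )

    def single(self, name: str) -> DescriptorCombination:
        return self.combination([name], label=name)

    def combination_feature_names(self, combo: DescriptorCombination) -> list[str]:
        names: list[str] = []
        for m in combo.member_sets:
            s = self[m]
            names.extend(f"{m}:{f}" for f in s.feature_names)
        return names

    def combination_pattern_tags(self, combo: DescriptorCombination) -> list[str]:
        tags: list[str] = []
        for m in combo.member_sets:
            tags.extend(self[m].pattern_tags)
        return tags


def _load_one(desc_dir: Path, entry: dict) -> DescriptorSet:
    path = desc_dir / entry["file"]
    if not path.exists():
        raise DescriptorError(f"descriptor file missing: {path}")
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        if header[0] != "residue":
            raise DescriptorError(f"{path}: first column must be 'residue'")
        feature_names = tuple(header[1:])
        table: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            cells = line.strip().split(",")
            if len(cells) != len(feature_names) + 1:
                raise DescriptorError(
                    f"{path}:{lineno}: expected {len(feature_names) + 1} columns, "
                    f"got {len(cells)}"
                )
            res = cells[0]
            if res in table:
                raise DescriptorError(f"{path}:{lineno}: duplicate residue row {res!r}")
            table[res] = np.array([float(c) for c in cells[1:]])
    try:
        return DescriptorSet(
            name=entry["name"],
            table=table,
            feature_names=feature_names,
            pattern_tags=tuple(entry["pattern_tags"]),
            source=entry.get("source", ""),
            synthetic=bool(entry.get("synthetic", False)),
        )
    except DescriptorError as err:
        raise DescriptorError(f"{path}: {err}") from err


def load_descriptor_registry(data_dir: str | Path | None = None) -> DescriptorRegistry:
    """Load the packaged (or an external) descriptor registry.

    Parameters
    ----------
    data_dir:
        Directory containing ``registry.json`` and the CSV tables it names.
        Defaults to the data files shipped with the package.
    """
    if data_dir is None:
        data_dir = Path(str(resources.files("acepep").joinpath("data")))
    data_dir = Path(data_dir)
    manifest_path = data_dir / "registry.json"
    if not manifest_path.exists():
        raise DescriptorError(f"registry manifest missing: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    return DescriptorRegistry(_load_one(data_dir, entry) for entry in manifest)


def standard_combinations(registry: DescriptorRegistry) -> dict[str, DescriptorCombination]:
    """The two named combinations shipped with the package.

    ``CodeSet22`` concatenates every registered set; ``VVSFZL37`` is the
    compact six-set optimum (VSW + VHSE + ST-scales + FASGAI + Z-scales +
    Lin's scales, 37 features) that the grouped elimination search converges
    to on the reference benchmark.
    """
    out = {FULL_COMBINATION: registry.combination(registry.names, label=FULL_COMBINATION)}
    if all(m in registry for m in _OPTIMAL_MEMBERS):
        out[OPTIMAL_COMBINATION] = registry.combination(
            _OPTIMAL_MEMBERS, label=OPTIMAL_COMBINATION
        )
    return out


def validate_sequence(seq: str) -> str:
    """Upper-case and validate a peptide sequence against the 20-letter alphabet."""
    s = seq.upper()
    for i, ch in enumerate(s):
        if ch not in RESIDUES:
            raise EncodingError(
                f"unknown residue {ch!r} at position {i + 1} in sequence {seq!r}"
            )
    return s


def encode(
    seq: str,
    combo: DescriptorCombination,
    registry: DescriptorRegistry,
    *,
    min_length: int = 2,
) -> EncodedPeptide:
    """Encode one peptide under a descriptor combination.

    Row *i* of the result is the concatenation, in member order, of each
    member set's vector for residue *i*.  Sequences are upper-cased first;
    any character outside the 20-residue alphabet is a hard error naming the
    offending position.
    """
    s = validate_sequence(seq)
    if len(s) < min_length:
        raise EncodingError(
            f"sequence {seq!r} is shorter than the minimum length {min_length}"
        )
    blocks = []
    for m in combo.member_sets:
        tab = registry[m].table
        blocks.append(np.stack([tab[ch] for ch in s]))
    matrix = np.concatenate(blocks, axis=1) if blocks else np.zeros((len(s), 0))
    return EncodedPeptide(
        matrix=matrix, mask=np.ones(len(s), dtype=bool), sequence=s
    )


def encode_many(
    seqs: Iterable[str],
    combo: DescriptorCombination,
    registry: DescriptorRegistry,
) -> list[EncodedPeptide]:
    return [encode(s, combo, registry) for s in seqs]


def mask_features(enc: EncodedPeptide, feature_indices: Iterable[int]) -> EncodedPeptide:
    """Zero the named feature columns at every position (masking probe).

    Returns a copy; the input is never modified.  Zeroing is idempotent and
    order-independent, which is what makes grouped masking well defined.
    """
    idx = sorted(set(int(i) for i in feature_indices))
    n_cols = enc.matrix.shape[1]
    for i in idx:
        if i < 0 or i >= n_cols:
            raise IndexError(f"feature index {i} out of range for {n_cols} columns")
    out = enc.copy()
    if idx:
        out.matrix[:, idx] = 0.0
    return out
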