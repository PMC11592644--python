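"""Labeled peptide datasets: construction, filtering, splitting and IO.

The benchmark-building convention implemented here: experimentally measured
inhibitory peptides with IC50 below a potency threshold (default 1000 µM)
form the positive class; an equal number of random peptides — lengths drawn
from the positives' empirical length distribution, residues uniform — form
the negative class, after removing any candidate that aligns to a positive
with more than 90 % identity.  Both classes are then split 7:3 into a
training benchmark and an independent test set.

Sequence identity is computed from an optimal global (Needleman–Wunsch)
alignment as matched positions divided by the shorter sequence's length.
At peptide lengths (2–19 residues) exact alignment is cheap, so no heuristic
clustering is needed.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .descriptors import RESIDUES, EncodingError, validate_sequence

__all__ = [
    "PeptideRecord",
    "LabeledDataset",
    "DatasetError",
    "filter_positives",
    "generate_negatives",
    "pairwise_identity",
    "similarity_filter",
    "split_dataset",
    "build_benchmark",
    "read_dataset",
    "write_dataset",
]

logger = logging.getLogger(__name__)

Label = Literal["positive", "negative", "unknown"]


class DatasetError(ValueError):
    """Raised for malformed dataset files or invalid construction requests."""


@dataclass
class PeptideRecord:
    """One peptide with optional activity annotation.

    ``ic50_uM`` is the concentration (µM) at which the peptide inhibits 50 %
    of ACE activity; lower values mean stronger inhibitors.
    """

    id: str
    sequence: str
    label: Label = "unknown"
    ic50_uM: float | None = None
    source: str = ""
    split: str | None = None  # "train" / "test" once assigned

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        if self.ic50_uM is not None and self.ic50_uM <= 0:
            raise DatasetError(f"record {self.id!r}: IC50 must be positive (µM)")


@dataclass
class LabeledDataset:
    """A list of :class:`PeptideRecord` plus construction provenance."""

    records: list[PeptideRecord]
    construction_params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(r.label for r in self.records))

    def subset(self, split: str) -> "LabeledDataset":
        return LabeledDataset(
            [r for r in self.records if r.split == split],
            dict(self.construction_params, subset=split),
        )

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        """0/1 array (1 = positive); raises if any record is unlabeled."""
        out = []
        for r in self.records:
            if r.label == "unknown":
                raise DatasetError(f"record {r.id!r} has no class label")
            out.append(1 if r.label == "positive" else 0)
        return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# construction

def filter_positives(
    records: Iterable[PeptideRecord], ic50_threshold_uM: float = 1000.0
) -> list[PeptideRecord]:
    """Select positives by potency and drop duplicate/conflicting sequences.

    A sequence is kept when its IC50 is strictly below the threshold.  A
    sequence reported with IC50 values on *both* sides of the threshold is
    treated as experimentally inconsistent and dropped entirely; duplicate
    reports on the same side keep one representative (the first seen).
    """
    below: dict[str, PeptideRecord] = {}
    above: set[str] = set()
    for r in records:
        if r.ic50_uM is None:
            continue
        if r.ic50_uM < ic50_threshold_uM:
            below.setdefault(r.sequence, r)
        else:
            above.add(r.sequence)
    kept = []
    for seq, r in below.items():
        if seq in above:
            logger.info("dropping %s: IC50 reports on both sides of threshold", seq)
            continue
        kept.append(
            PeptideRecord(r.id, seq, "positive", r.ic50_uM, r.source)
        )
    return kept


def empirical_length_distribution(sequences: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, probabilities) of the observed length histogram."""
    if not sequences:
        raise DatasetError("cannot take a length distribution from no sequences")
    counts = Counter(len(s) for s in sequences)
    lengths = np.array(sorted(counts))
    probs = np.array([counts[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    return lengths, probs


def generate_negatives(
    n: int,
    length_distribution: tuple[np.ndarray, np.ndarray] | Sequence[str],
    rng_seed: int = 0,
) -> list[str]:
    """Random peptides with lengths matched to the positive class.

    Lengths are drawn from the empirical length distribution of the positive
    sequences (pass either the ``(lengths, probs)`` pair or the sequences
    themselves); residues are uniform over the 20-letter alphabet.
    Reproducible for a fixed seed.
    """
    if n < 1:
        raise DatasetError("n must be >= 1")
    if not isinstance(length_distribution, tuple):
        length_distribution = empirical_length_distribution(length_distribution)
    lengths, probs = length_distribution
    rng = np.random.default_rng(rng_seed)
    drawn = rng.choice(lengths, size=n, p=probs)
    alphabet = np.array(list(RESIDUES))
    return ["".join(rng.choice(alphabet, size=int(L))) for L in drawn]


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    return a


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / length of the shorter sequence."""
    aligner = aligner or _aligner()
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def similarity_filter(
    candidates: Sequence[str],
    references: Sequence[str],
    identity_cutoff: float = 0.9,
) -> list[str]:
    """Remove candidates >cutoff identical to any reference sequence.

    Deterministic and order-preserving.  With no references all candidates
    survive.
    """
    if not 0 < identity_cutoff <= 1:
        raise DatasetError("identity cutoff must be in (0, 1]")
    aligner = _aligner()
    ref_set = set(references)
    survivors = []
    for cand in candidates:
        if cand in ref_set:  # identity 1.0, skip alignment
            continue
        if any(pairwise_identity(cand, r, aligner) > identity_cutoff for r in references):
            continue
        survivors.append(cand)
    return survivors


def split_dataset(ds: LabeledDataset, ratio: float = 0.7, rng_seed: int = 0) -> LabeledDataset:
    """Assign a stratified train/test split, per class, at the given ratio.

    Each class is split independently with ``train = round(ratio * n)``.
    With 1043 peptides per class and a 7:3 ratio this yields 730 training and
    313 test peptides per class.
    """
    if not 0 < ratio < 1:
        raise DatasetError(f"split ratio must be in (0, 1), got {ratio}")
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(ds.records):
        by_class.setdefault(r.label, []).append(i)
    if len(by_class) < 2:
        raise DatasetError("both classes must be present to split")
    rng = np.random.default_rng(rng_seed)
    for label, idx in by_class.items():
        if len(idx) < 2:
            raise DatasetError(f"class {label!r} has fewer than 2 members")
        n_train = int(round(ratio * len(idx)))
        if n_train in (0, len(idx)):
            raise DatasetError(
                f"ratio {ratio} leaves an empty partition for class {label!r}"
            )
        order = rng.permutation(len(idx))
        for k, j in enumerate(order):
            ds.records[idx[j]].split = "train" if k < n_train else "test"
    ds.construction_params.update(split_ratio=ratio, split_seed=rng_seed)
    return ds


def build_benchmark(
    positives: Iterable[PeptideRecord],
    *,
    ic50_threshold_uM: float = 1000.0,
    identity_cutoff: float = 0.9,
    split_ratio: float = 0.7,
    rng_seed: int = 0,
) -> LabeledDataset:
    """Full benchmark construction pipeline.

    Filters positives by potency, generates an equal number of random
    negatives with matched lengths, removes negatives with >cutoff identity
    to any positive (topping up until the classes balance), and assigns the
    stratified 7:3 split.
    """
    pos = filter_positives(positives, ic50_threshold_uM)
    if not pos:
        raise DatasetError("no positive records survive the IC50 filter")
    pos_seqs = [r.sequence for r in pos]
    length_dist = empirical_length_distribution(pos_seqs)
    need = len(pos)
    negatives: list[str] = []
    seen = set(pos_seqs)
    round_seed = rng_seed
    while len(negatives) < need:
        batch = generate_negatives(need - len(negatives), length_dist, round_seed)
        batch = [s for s in batch if s not in seen]
        for s in similarity_filter(batch, pos_seqs, identity_cutoff):
            if s not in seen:
                negatives.append(s)
                seen.add(s)
        round_seed += 1
    records = list(pos) + [
        PeptideRecord(f"neg{i + 1}", s, "negative", None, "random")
        for i, s in enumerate(negatives)
    ]
    ds = LabeledDataset(
        records,
        {
            "ic50_threshold_uM": ic50_threshold_uM,
            "identity_cutoff": identity_cutoff,
            "split_ratio": split_ratio,
            "seed": rng_seed,
        },
    )
    return split_dataset(ds, split_ratio, rng_seed)


# ---------------------------------------------------------------------------
# IO

_COLUMNS = ["id", "sequence", "label", "ic50_uM", "source", "split"]


def write_dataset(ds: LabeledDataset, path: str | Path, format: str = "tsv") -> None:
    """Write a dataset as TSV (all fields) or FASTA (fields in headers).

    A JSON sidecar ``<path>.params.json`` records the construction
    parameters for provenance.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            [
                {
                    "id": r.id,
                    "sequence": r.sequence,
                    "label": r.label,
                    "ic50_uM": r.ic50_uM,
                    "source": r.source,
                    "split": r.split,
                }
                for r in ds.records
            ],
            columns=_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "fasta":
        recs = []
        for r in ds.records:
            desc = f"label={r.label}"
            if r.ic50_uM is not None:
                desc += f" ic50_uM={r.ic50_uM:g}"
            if r.split:
                desc += f" split={r.split}"
            recs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
        SeqIO.write(recs, str(path), "fasta")
    else:
        raise DatasetError(f"unknown dataset format {format!r}")
    if ds.construction_params:
        Path(f"{path}.params.json").write_text(
            json.dumps(ds.construction_params, indent=1)
        )


def read_dataset(path: str | Path, format: str = "tsv") -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset` (round-trip stable)."""
    path = Path(path)
    records: list[PeptideRecord] = []
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"id": str})
        except pd.errors.EmptyDataError:
            logger.warning("empty dataset file: %s", path)
            return LabeledDataset([])
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            try:
                ic50 = None if pd.isna(row.ic50_uM) else float(row.ic50_uM)
                rec = PeptideRecord(
                    id=str(row.id),
                    sequence=str(row.sequence),
                    label=str(row.label),
                    ic50_uM=ic50,
                    source="" if pd.isna(row.source) else str(row.source),
                    split=None if pd.isna(row.split) else str(row.split),
                )
            except (AttributeError, ValueError, EncodingError) as err:
                raise DatasetError(f"{path}:{lineno}: {err}") from err
            records.append(rec)
    elif format == "fasta":
        seen: set[str] = set()
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise DatasetError(f"{path}: duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            fields = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            records.append(
                PeptideRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    label=fields.get("label", "unknown"),
                    ic50_uM=float(fields["ic50_uM"]) if "ic50_uM" in fields else None,
                    split=fields.get("split"),
                )
            )
        if not records:
            logger.warning("empty dataset file: %s", path)
    else:
        raise DatasetError(f"unknown dataset format {format!r}")
    params_path = Path(f"{path}.params.json")
    params = json.loads(params_path.read_text()) if params_path.exists() else {}
    return LabeledDataset(records, params)
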