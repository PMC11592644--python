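"""Synthetic peptide and protein generators.

Three generators make the whole toolkit testable without any database
download:

* :func:`generate_labeled_set` emits a balanced two-class peptide set whose
  positive class mimics the sequence statistics of experimentally validated
  ACE-inhibitory peptides: short oligopeptides (2–10 residues, mostly tri-
  to octapeptides), enriched in hydrophobic (Pro, Leu, Val, Gly, Ala) and
  aromatic (Tyr) residues, with C-termini biased toward Pro/Phe/Arg/Lys/Tyr
  and N-termini toward Leu/Val/Ala/Gly/Ile.  Negatives are uniform random
  peptides with the same length distribution.  All biases are parameters,
  so null (zero-bias) and extreme regimes are equally available.

* :func:`generate_planted_rule_set` labels uniform random peptides through
  a known logistic rule on one descriptor feature (the peptide-mean of a
  chosen column), providing ground truth for importance-recovery and
  selection-recovery tests.

* :func:`generate_proteins_with_embedded_peptides` builds random proteins
  that release chosen peptides exactly under complete digestion with a
  given enzyme, with a manifest of embedding coordinates — an end-to-end
  oracle for the digestion + screening pipeline.

Every generator is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datasets import LabeledDataset, PeptideRecord
from .descriptors import RESIDUES, DescriptorRegistry
from .digestion import ENZYMES, CleavageRule, digest

__all__ = [
    "GeneratorSpec",
    "FIG_LENGTH_WEIGHTS",
    "generate_labeled_set",
    "generate_planted_rule_set",
    "generate_proteins_with_embedded_peptides",
]

#: Default length distribution: oligopeptides of 2–10 residues with most
#: mass on tri- to octapeptides.
FIG_LENGTH_WEIGHTS: dict[int, float] = {
    2: 0.06, 3: 0.18, 4: 0.14, 5: 0.18, 6: 0.12, 7: 0.10, 8: 0.10, 9: 0.06, 10: 0.06,
}


@dataclass
class GeneratorSpec:
    """Parameters of the biased-composition generator.

    A bias of ``b`` multiplies the sampling weight of each enriched residue
    by ``(1 + b)`` before renormalisation; ``b = 0`` reduces every
    distribution to uniform (the null regime).
    """

    n_per_class: int = 500
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(FIG_LENGTH_WEIGHTS)
    )
    enriched_residues: str = "PLVGAY"
    composition_bias: float = 1.5
    cterm_residues: str = "PFRKY"
    cterm_bias: float = 2.0
    nterm_residues: str = "LVAGI"
    nterm_bias: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if min(self.length_weights) < 2:
            raise ValueError("peptide lengths must be >= 2")
        for b in (self.composition_bias, self.cterm_bias, self.nterm_bias):
            if b < 0:
                raise ValueError("biases must be >= 0")


def _biased_probs(enriched: str, bias: float) -> np.ndarray:
    w = np.ones(len(RESIDUES))
    for r in enriched:
        w[RESIDUES.index(r)] *= 1.0 + bias
    return w / w.sum()


def _length_sampler(weights: Mapping[int, float]):
    lengths = np.array(sorted(weights))
    p = np.array([weights[l] for l in lengths], dtype=float)
    if p.sum() <= 0:
        raise ValueError("length weights must have positive mass")
    return lengths, p / p.sum()


def generate_labeled_set(spec: GeneratorSpec) -> LabeledDataset:
    """Balanced positive-like / negative-like peptide dataset."""
    rng = np.random.default_rng(spec.seed)
    lengths, lp = _length_sampler(spec.length_weights)
    alphabet = np.array(list(RESIDUES))
    p_comp = _biased_probs(spec.enriched_residues, spec.composition_bias)
    p_cterm = _biased_probs(spec.cterm_residues, spec.cterm_bias)
    p_nterm = _biased_probs(spec.nterm_residues, spec.nterm_bias)

    records: list[PeptideRecord] = []
    for i in range(spec.n_per_class):
        L = int(rng.choice(lengths, p=lp))
        chars = [str(rng.choice(alphabet, p=p_nterm))]
        chars += [str(c) for c in rng.choice(alphabet, size=max(L - 2, 0), p=p_comp)]
        chars.append(str(rng.choice(alphabet, p=p_cterm)))
        records.append(PeptideRecord(f"pos{i + 1}", "".join(chars), "positive"))
    for i in range(spec.n_per_class):
        L = int(rng.choice(lengths, p=lp))
        seq = "".join(rng.choice(alphabet, size=L))
        records.append(PeptideRecord(f"neg{i + 1}", seq, "negative"))
    return LabeledDataset(
        records,
        {
            "generator": "biased_composition",
            "n_per_class": spec.n_per_class,
            "composition_bias": spec.composition_bias,
            "cterm_bias": spec.cterm_bias,
            "nterm_bias": spec.nterm_bias,
            "seed": spec.seed,
        },
    )


def generate_planted_rule_set(
    n: int,
    registry: DescriptorRegistry,
    set_name: str = "Z-scales",
    feature_index: int = 0,
    effect: float = 6.0,
    noise_sd: float = 0.25,
    length_weights: Mapping[int, float] | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Uniform random peptides labelled by a known single-feature rule.

    For each peptide the chosen descriptor feature is averaged over its
    residues, standardised across the generated batch, perturbed with
    Gaussian noise, and passed through a logistic of slope ``effect``;
    the label is a Bernoulli draw of that probability.  ``effect = 0``
    yields chance-level labels; a large effect yields a nearly separable
    set.  The ground-truth rule is stored in ``construction_params``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    dset = registry[set_name]
    if not 0 <= feature_index < dset.n_features:
        raise ValueError(
            f"feature index {feature_index} out of range for {set_name!r} "
            f"({dset.n_features} features)"
        )
    rng = np.random.default_rng(seed)
    lengths, lp = _length_sampler(length_weights or FIG_LENGTH_WEIGHTS)
    alphabet = np.array(list(RESIDUES))
    feature = np.array([dset.table[r][feature_index] for r in RESIDUES])
    seqs = []
    x = np.empty(n)
    for i in range(n):
        L = int(rng.choice(lengths, p=lp))
        idx = rng.integers(0, 20, size=L)
        seqs.append("".join(alphabet[idx]))
        x[i] = feature[idx].mean()
    z = (x - x.mean()) / (x.std() or 1.0)
    logits = effect * z + rng.normal(0.0, noise_sd, size=n)
    p = 1.0 / (1.0 + np.exp(-logits))
    labels = rng.random(n) < p
    if labels.all() or not labels.any():  # degenerate draw: force both classes
        labels[int(np.argmin(p))] = False
        labels[int(np.argmax(p))] = True
    records = [
        PeptideRecord(f"pep{i + 1}", s, "positive" if lab else "negative")
        for i, (s, lab) in enumerate(zip(seqs, labels))
    ]
    return LabeledDataset(
        records,
        {
            "generator": "planted_rule",
            "set": set_name,
            "feature_index": feature_index,
            "feature_name": dset.feature_names[feature_index],
            "effect": effect,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


# residues that can never create a cleavage site inside the random
# background, per packaged enzyme
_SAFE_BACKGROUND = {
    "trypsin": "ACDEGHINQSTW",
    "chymotrypsin": "ACDEGHIKNQST",
    "papain": "CDEGHNQST",
    "proteinase_k": "CDGHKNPQRS",
    "pepsin": "ACDEGHIKNQST",
    "thermolysin": "CDGHKNPQRSTWY",
}

# flank inserted immediately before each embedded peptide so a cleavage
# site forms at its N-terminal boundary
_FLANK = {
    "trypsin": "K",
    "chymotrypsin": "F",
    "papain": "AK",
    "proteinase_k": "A",
    "pepsin": "AF",
    "thermolysin": "",
}


def generate_proteins_with_embedded_peptides(
    positives: Sequence[str],
    n_proteins: int,
    protein_length: int = 80,
    enzyme: str = "trypsin",
    rng_seed: int = 0,
) -> tuple[list[tuple[str, str]], dict]:
    """Random proteins that release chosen peptides on complete digestion.

    Each protein carries one embedded peptide at its C-terminus, preceded
    by an enzyme-appropriate flank, inside a background that contains no
    cleavage sites; complete digestion with that enzyme therefore releases
    the peptide exactly.  Peptides that cannot be released intact (because
    they contain an internal site for the enzyme, or block the flanking
    cut) are rejected and listed in the manifest.

    Returns ``(proteins, manifest)`` where proteins is a list of
    ``(id, sequence)`` and the manifest records 1-based embedding
    coordinates plus any rejections.
    """
    if enzyme not in ENZYMES:
        raise KeyError(f"unknown enzyme {enzyme!r}; available: {sorted(ENZYMES)}")
    rule: CleavageRule = ENZYMES[enzyme]
    rng = np.random.default_rng(rng_seed)
    bg = np.array(list(_SAFE_BACKGROUND[enzyme]))
    flank = _FLANK[enzyme]

    proteins: list[tuple[str, str]] = []
    embedded: list[dict] = []
    rejected: list[dict] = []
    queue = list(positives)
    for k in range(n_proteins):
        pid = f"prot{k + 1}"
        pep = queue[k % len(queue)] if queue else None
        placed = False
        if pep is not None:
            for _attempt in range(20):
                n_bg = max(protein_length - len(pep) - len(flank), 5)
                body = "".join(rng.choice(bg, size=n_bg))
                seq = body + flank + pep
                frags = digest(seq, rule, pid).sequences()
                if frags[-1] == pep and seq.count(pep) == 1:
                    proteins.append((pid, seq))
                    start = len(seq) - len(pep) + 1
                    embedded.append(
                        {"protein_id": pid, "peptide": pep, "start": start, "end": len(seq)}
                    )
                    placed = True
                    break
            if not placed:
                rejected.append(
                    {
                        "protein_id": pid,
                        "peptide": pep,
                        "reason": "peptide not released intact by the enzyme rule",
                    }
                )
        if not placed:
            seq = "".join(rng.choice(bg, size=protein_length))
            proteins.append((pid, seq))
    manifest = {
        "enzyme": enzyme,
        "rng_seed": rng_seed,
        "embedded": embedded,
        "rejected": rejected,
    }
    return proteins, manifest
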