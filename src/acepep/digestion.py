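"""Virtual proteolysis and proteome screening.

Protein sequences are cut in silico with rule-based protease specificities
and the resulting 2–19-residue fragments are scored with a trained
classifier to nominate candidate ACE-inhibitory peptides.  Digestion is
*complete*: hydrolysis is assumed to proceed under optimal conditions
(ideal pH and temperature, maximum enzyme activity), so every position that
satisfies an enzyme's site rule is cleaved and no missed cleavages remain
by default.

Each :class:`CleavageRule` is a pure predicate over a local sequence window
around the candidate scissile bond (positions P4–P1 on the N-terminal side,
P1'–P4' on the C-terminal side).  The six packaged enzymes use simplified
specificities in the style of the ExPASy PeptideCutter rule tables; each
rule documents its source and can be replaced or extended without touching
the digestion engine.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import RESIDUES, validate_sequence

__all__ = [
    "CleavageRule",
    "Fragment",
    "DigestResult",
    "ENZYMES",
    "digest",
    "multi_digest",
    "screen",
    "profile_sequences",
]

logger = logging.getLogger(__name__)

# Site predicate: cleave(sequence, i) — True when the bond between residue i
# and residue i+1 (0-based) is hydrolysed.  Must read only a local window.
SitePredicate = Callable[[str, int], bool]


@dataclass(frozen=True)
class CleavageRule:
    """A protease's cleavage specificity as a pure local-window predicate."""

    enzyme: str
    ec_number: str
    source: str
    predicate: SitePredicate

    def cleaves(self, seq: str, i: int) -> bool:
        if not 0 <= i < len(seq) - 1:
            return False
        return self.predicate(seq, i)


def _trypsin(seq: str, i: int) -> bool:
    # C-terminal to K/R, blocked by proline at P1'
    return seq[i] in "KR" and seq[i + 1] != "P"


def _chymotrypsin(seq: str, i: int) -> bool:
    # high-specificity rule: C-terminal to F/Y/W, blocked by proline at P1'
    return seq[i] in "FYW" and seq[i + 1] != "P"


def _pepsin_ph13(seq: str, i: int) -> bool:
    # preferential cleavage around F/L at pH 1.3; proline at P1 or P1' blocks
    if seq[i] == "P" or seq[i + 1] == "P":
        return False
    return seq[i] in "FL" or seq[i + 1] in "FL"


def _pepsin_ph2(seq: str, i: int) -> bool:
    # broader specificity above pH 2: aromatic residues join the F/L set
    if seq[i] == "P" or seq[i + 1] == "P":
        return False
    return seq[i] in "FLWY" or seq[i + 1] in "FLWY"


def _thermolysin(seq: str, i: int) -> bool:
    # N-terminal side of bulky hydrophobics; acidic P1 blocks
    return seq[i + 1] in "AFILMV" and seq[i] not in "DE"


def _papain(seq: str, i: int) -> bool:
    # C-terminal to R/K with a hydrophobic residue at P2; proline at P1' blocks
    if seq[i] not in "KR" or seq[i + 1] == "P":
        return False
    return i >= 1 and seq[i - 1] in "AVLIFWY"


def _proteinase_k(seq: str, i: int) -> bool:
    # broad specificity: C-terminal to aliphatic and aromatic residues
    return seq[i] in "AEFILTVWY"


_PC = "simplified from the ExPASy PeptideCutter specificity tables"

ENZYMES: dict[str, CleavageRule] = {
    "trypsin": CleavageRule("trypsin", "EC 3.4.21.4", _PC, _trypsin),
    "chymotrypsin": CleavageRule("chymotrypsin", "EC 3.4.21.1", _PC, _chymotrypsin),
    "pepsin": CleavageRule("pepsin (pH 1.3)", "EC 3.4.23.1", _PC, _pepsin_ph13),
    "pepsin_ph2": CleavageRule("pepsin (pH > 2)", "EC 3.4.23.1", _PC, _pepsin_ph2),
    "thermolysin": CleavageRule("thermolysin", "EC 3.4.24.27", _PC, _thermolysin),
    "papain": CleavageRule("papain", "EC 3.4.22.2", _PC, _papain),
    "proteinase_k": CleavageRule("proteinase K", "EC 3.4.21.64", _PC, _proteinase_k),
}

#: The six-enzyme panel used for proteome screening.
DEFAULT_PANEL = (
    "chymotrypsin",
    "papain",
    "proteinase_k",
    "thermolysin",
    "pepsin",
    "trypsin",
)


@dataclass(frozen=True)
class Fragment:
    """One digestion product with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int


@dataclass
class DigestResult:
    protein_id: str
    enzyme: str
    fragments: list[Fragment]

    def sequences(self) -> list[str]:
        return [f.sequence for f in self.fragments]


def digest(
    protein: str,
    rule: CleavageRule,
    protein_id: str = "protein",
    missed_cleavages: int = 0,
) -> DigestResult:
    """Completely digest one protein with one enzyme.

    Every bond satisfying the rule is cut; fragments are contiguous,
    non-overlapping and concatenate back to the parent.  With
    ``missed_cleavages > 0``, products spanning up to that many uncut sites
    are appended after the complete-digestion fragments.
    """
    seq = validate_sequence(protein)
    if not seq:
        raise ValueError("protein sequence is empty")
    cuts = [i + 1 for i in range(len(seq) - 1) if rule.cleaves(seq, i)]
    bounds = [0, *cuts, len(seq)]
    fragments = [
        Fragment(seq[a:b], a + 1, b) for a, b in zip(bounds[:-1], bounds[1:])
    ]
    if missed_cleavages > 0:
        complete = list(fragments)
        for span in range(1, missed_cleavages + 1):
            for j in range(len(complete) - span):
                a = complete[j].start
                b = complete[j + span].end
                fragments.append(Fragment(seq[a - 1 : b], a, b))
    return DigestResult(protein_id, rule.enzyme, fragments)


def multi_digest(
    proteins: Mapping[str, str] | Sequence[tuple[str, str]],
    enzymes: Sequence[str | CleavageRule] = DEFAULT_PANEL,
    length_range: tuple[int, int] = (2, 19),
    missed_cleavages: int = 0,
) -> pd.DataFrame:
    """Pooled digestion of many proteins with many enzymes.

    Each protein is digested with each enzyme separately and the in-range
    fragments are pooled, deduplicated by sequence.  Returns a DataFrame
    with one row per (sequence, protein, enzyme, start, end) provenance
    entry; unique peptides are ``df["sequence"].unique()``.
    """
    items = list(proteins.items()) if isinstance(proteins, Mapping) else list(proteins)
    if not items:
        raise ValueError("no proteins to digest")
    rules = [e if isinstance(e, CleavageRule) else ENZYMES[e] for e in enzymes]
    if not rules:
        raise ValueError("no enzymes given")
    lo, hi = length_range
    rows = []
    for pid, seq in items:
        for rule in rules:
            res = digest(seq, rule, pid, missed_cleavages)
            for fr in res.fragments:
                if lo <= len(fr.sequence) <= hi:
                    rows.append(
                        {
                            "sequence": fr.sequence,
                            "protein": pid,
                            "enzyme": rule.enzyme,
                            "start": fr.start,
                            "end": fr.end,
                        }
                    )
    df = pd.DataFrame(rows, columns=["sequence", "protein", "enzyme", "start", "end"])
    return df.drop_duplicates().reset_index(drop=True)


def screen(
    pool: pd.DataFrame | Sequence[str],
    model,
    registry,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score a peptide pool with a trained classifier and keep candidates.

    Candidates are pool members with positive-class probability strictly
    above the threshold, sorted by descending probability.  Peptides the
    model cannot encode are skipped with a log entry.
    """
    from .model import predict  # local import to avoid a cycle

    if isinstance(pool, pd.DataFrame):
        peptides = list(pd.unique(pool["sequence"]))
    else:
        peptides = list(dict.fromkeys(pool))
    probs, errors = predict(model, peptides, registry)
    for i, msg in errors.items():
        logger.warning("skipping unencodable fragment %r: %s", peptides[i], msg)
    ok = ~np.isnan(probs)
    df = pd.DataFrame({"sequence": np.array(peptides)[ok], "probability": probs[ok]})
    df = df[df["probability"] > threshold]
    return (
        df.sort_values(["probability", "sequence"], ascending=[False, True])
        .reset_index(drop=True)
    )


def profile_sequences(peptides: Sequence[str]) -> dict:
    """Sequence-feature profile of a peptide set.

    Returns the length histogram, overall residue composition frequencies,
    and N-/C-terminal residue frequencies — the summaries used to compare
    predicted candidate pools against experimentally validated peptides.
    """
    peptides = [validate_sequence(p) for p in peptides]
    if not peptides:
        raise ValueError("cannot profile an empty peptide set")
    n = len(peptides)
    lengths = Counter(len(p) for p in peptides)
    comp = Counter()
    for p in peptides:
        comp.update(p)
    total_res = sum(comp.values())
    nterm = Counter(p[0] for p in peptides)
    cterm = Counter(p[-1] for p in peptides)
    return {
        "n_peptides": n,
        "length_histogram": {int(k): int(v) for k, v in sorted(lengths.items())},
        "residue_composition": {r: comp.get(r, 0) / total_res for r in RESIDUES},
        "n_terminal_frequency": {r: nterm.get(r, 0) / n for r in RESIDUES},
        "c_terminal_frequency": {r: cterm.get(r, 0) / n for r in RESIDUES},
    }
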