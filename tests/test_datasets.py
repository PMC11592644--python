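"""Benchmark construction: potency filtering, negatives, similarity, splits, IO."""

import numpy as np
import pytest
from scipy import stats

from acepep.datasets import (
    DatasetError,
    LabeledDataset,
    PeptideRecord,
    empirical_length_distribution,
    filter_positives,
    generate_negatives,
    pairwise_identity,
    read_dataset,
    similarity_filter,
    split_dataset,
    write_dataset,
)


def _needleman_wunsch_identity(a: str, b: str) -> float:
    """Independent oracle: NW global alignment (match 1, mismatch/gap -1),
    identity = matched positions / shorter length."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    ident = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        score[i][0] = -i
    for j in range(1, m + 1):
        score[0][j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = a[i - 1] == b[j - 1]
            cands = [
                (score[i - 1][j - 1] + (1 if match else -1), ident[i - 1][j - 1] + match),
                (score[i - 1][j] - 1, ident[i - 1][j]),
                (score[i][j - 1] - 1, ident[i][j - 1]),
            ]
            score[i][j], ident[i][j] = max(cands)
    return ident[n][m] / min(n, m)


class TestFilterPositives:
    RECORDS = [
        PeptideRecord("a", "LAF", ic50_uM=4.35),
        PeptideRecord("b", "LAL", ic50_uM=1162.34),
        PeptideRecord("c", "LLL", ic50_uM=17.99),
        PeptideRecord("d", "LLL", ic50_uM=20.0),  # duplicate sequence
        PeptideRecord("e", "AVL", ic50_uM=5.0),
        PeptideRecord("f", "AVL", ic50_uM=2000.0),  # conflicting report
    ]

    def test_potent_kept_weak_dropped(self):
        seqs = {r.sequence for r in filter_positives(self.RECORDS)}
        assert "LAF" in seqs
        assert "LAL" not in seqs

    def test_duplicates_collapse_to_one(self):
        out = [r for r in filter_positives(self.RECORDS) if r.sequence == "LLL"]
        assert len(out) == 1
        assert out[0].ic50_uM == 17.99

    def test_conflicting_reports_dropped_entirely(self):
        assert all(r.sequence != "AVL" for r in filter_positives(self.RECORDS))

    def test_all_survivors_below_threshold_and_positive(self):
        for r in filter_positives(self.RECORDS, 1000.0):
            assert r.label == "positive" and r.ic50_uM < 1000.0


class TestGenerateNegatives:
    def test_count_and_alphabet(self):
        seqs = generate_negatives(50, ["LAF", "PLVKA", "GG"], rng_seed=1)
        assert len(seqs) == 50
        assert all(set(s) <= set("ACDEFGHIKLMNPQRSTVWY") for s in seqs)

    def test_seed_reproducibility(self):
        a = generate_negatives(100, ["LAF", "PLVKA"], rng_seed=3)
        b = generate_negatives(100, ["LAF", "PLVKA"], rng_seed=3)
        assert a == b

    def test_length_histogram_matches_positives(self):
        positives = ["AA"] * 30 + ["AAAAA"] * 50 + ["AAAAAAAA"] * 20
        lengths, probs = empirical_length_distribution(positives)
        neg = generate_negatives(10_000, (lengths, probs), rng_seed=5)
        observed = np.array([sum(len(s) == L for s in neg) for L in lengths])
        _, p = stats.chisquare(observed, probs * len(neg))
        assert p > 0.001  # consistent with multinomial sampling error


class TestSimilarityFilter:
    def test_identical_candidate_removed(self):
        assert similarity_filter(["PLVKA"], ["PLVKA"]) == []

    def test_disjoint_candidate_kept(self):
        assert similarity_filter(["GGGGG"], ["PLVKA"]) == ["GGGGG"]

    def test_matches_bruteforce_alignment_oracle(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        refs = ["".join(rng.choice(alphabet, size=6)) for _ in range(3)]
        cands = ["".join(rng.choice(alphabet, size=rng.integers(3, 9))) for _ in range(10)]
        cands += [refs[0], refs[1][:-1] + "W"]  # near-duplicates
        cutoff = 0.7
        expected = [
            c for c in cands
            if all(_needleman_wunsch_identity(c, r) <= cutoff for r in refs)
        ]
        assert similarity_filter(cands, refs, cutoff) == expected

    def test_identity_convention_uses_shorter_length(self):
        # "LAF" aligned inside "LAFAA": 3 matches / min(3,5) = 1.0
        assert pairwise_identity("LAF", "LAFAA") == 1.0


class TestSplit:
    @staticmethod
    def _dataset(n_pos, n_neg):
        recs = [PeptideRecord(f"p{i}", "PLVKA", "positive") for i in range(n_pos)]
        recs += [PeptideRecord(f"n{i}", "GGGGG", "negative") for i in range(n_neg)]
        return LabeledDataset(recs)

    def test_1043_per_class_gives_313_test(self):
        ds = split_dataset(self._dataset(1043, 1043), 0.7, rng_seed=0)
        test = ds.subset("test")
        counts = test.class_counts
        assert counts == {"positive": 313, "negative": 313}

    def test_partition_is_disjoint_and_exhaustive(self):
        ds = split_dataset(self._dataset(31, 17), 0.7, rng_seed=2)
        splits = [r.split for r in ds.records]
        assert set(splits) == {"train", "test"}
        assert len(ds.subset("train")) + len(ds.subset("test")) == 48

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(DatasetError):
            split_dataset(self._dataset(10, 10), 1.0)

    def test_split_reproducible_under_seed(self):
        a = split_dataset(self._dataset(40, 40), 0.7, rng_seed=9)
        ids_a = sorted(r.id for r in a.subset("test"))
        b = split_dataset(self._dataset(40, 40), 0.7, rng_seed=9)
        assert ids_a == sorted(r.id for r in b.subset("test"))

    def test_single_class_rejected(self):
        with pytest.raises(DatasetError):
            split_dataset(LabeledDataset(
                [PeptideRecord(f"p{i}", "PLVKA", "positive") for i in range(10)]
            ))


class TestIO:
    @staticmethod
    def _ds():
        recs = [
            PeptideRecord("a", "LAF", "positive", 4.35, "assay", "train"),
            PeptideRecord("b", "GGGGG", "negative", None, "random", "test"),
        ]
        return LabeledDataset(recs, {"seed": 1})

    @pytest.mark.parametrize("fmt", ["tsv", "fasta"])
    def test_round_trip_preserves_records(self, tmp_path, fmt):
        ds = self._ds()
        path = tmp_path / f"ds.{fmt}"
        write_dataset(ds, path, fmt)
        back = read_dataset(path, fmt)
        assert [(r.id, r.sequence, r.label, r.ic50_uM, r.split) for r in back.records] == [
            (r.id, r.sequence, r.label, r.ic50_uM, r.split) for r in ds.records
        ]

    def test_duplicate_fasta_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">x label=positive\nLAF\n>x label=negative\nGG\n")
        with pytest.raises(DatasetError, match="x"):
            read_dataset(path, "fasta")

    def test_empty_file_gives_empty_dataset(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(read_dataset(path, "tsv")) == 0

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "id\tsequence\tlabel\tic50_uM\tsource\tsplit\n"
            "a\tLAF\tpositive\t4.35\t\ttrain\n"
            "b\tL1F\tpositive\t2.0\t\ttrain\n"
        )
        with pytest.raises(DatasetError, match=":3"):
            read_dataset(path, "tsv")
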