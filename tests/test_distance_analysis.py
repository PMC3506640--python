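"""Substitution-model distances, partitioning, gap statistic and histograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap.distance_analysis import (
    DistanceRecord,
    UndefinedDistanceError,
    gap_statistic,
    histogram,
    pairwise_distance,
    partition_distances,
)

# Reference F84/K2P/JC distances for ten seeded 300-bp pairs, computed with
# ape::dist.dna (pairwise.deletion=TRUE, per-pair base frequencies via
# two-sequence objects), the closed-form oracle for the DNADIST behaviour.
APE_SEED = 20120426
APE_F84 = [0.1716331534, 0.6410661731, 0.0446590333, 0.0922001968, 0.4671522347,
           0.1112145601, 0.0482416317, 0.5374062496, 0.3613058402, 0.6328646017]
APE_K2P = [0.1715417883, 0.6388597001, 0.0446523361, 0.0921729580, 0.4669858431,
           0.1111866558, 0.0482330124, 0.5367304767, 0.3612295797, 0.6325283107]
APE_JC = [0.1715359473, 0.6388141581, 0.0446355956, 0.0920966831, 0.4652323925,
          0.1111816824, 0.0481817015, 0.5367150273, 0.3612198518, 0.6310420678]


def _ape_pairs():
    rng = np.random.default_rng(APE_SEED)
    pairs = []
    for _ in range(10):
        L = 300
        a = rng.integers(0, 4, L)
        p = rng.uniform(0.02, 0.45)
        mask = rng.random(L) < p
        b = a.copy()
        b[mask] = (b[mask] + rng.integers(1, 4, mask.sum())) % 4
        pairs.append(
            ("".join("ACGT"[x] for x in a), "".join("ACGT"[x] for x in b))
        )
    return pairs


class TestPairwiseDistance:
    @pytest.mark.parametrize("model", ["f84", "k2p", "jc"])
    def test_identical_sequences_are_zero(self, model):
        assert pairwise_distance("ACGTACGTAC", "ACGTACGTAC", model) == 0.0

    def test_jc_closed_form_hand_value(self):
        # 100 sites, 10 transitions: d = -(3/4) ln(1 - (4/3) 0.10)
        a = "ACGT" * 25
        b = "GCGT" * 10 + "ACGT" * 15  # 10 A->G transitions
        d = pairwise_distance(a, b, "jc")
        assert d == pytest.approx(0.10732, abs=1e-5)
        assert d == pytest.approx(-0.75 * math.log(1 - 4 / 3 * 0.10), abs=1e-12)

    @pytest.mark.parametrize(
        "model,expected", [("f84", APE_F84), ("k2p", APE_K2P), ("jc", APE_JC)]
    )
    def test_matches_frozen_ape_reference(self, model, expected):
        for (a, b), want in zip(_ape_pairs(), expected):
            assert pairwise_distance(a, b, model) == pytest.approx(want, abs=1e-9)

    def test_f84_equals_k2p_at_equal_frequencies(self):
        # balanced pooled frequencies: paired transition swaps A<->G
        a = "ACGT" * 30
        b = "GCGT" * 5 + "ACAT" * 5 + "ACGT" * 20  # A->G and G->A swaps
        f84 = pairwise_distance(a, b, "f84")
        k2p = pairwise_distance(a, b, "k2p")
        assert f84 == pytest.approx(k2p, abs=1e-9)

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        a = "ACGTACGTNN"
        b = "ACGT--GTAC"
        # comparable sites: positions 0-3, 6, 7 -> identical
        assert pairwise_distance(a, b, "jc") == 0.0

    def test_no_comparable_sites_raises(self):
        with pytest.raises(UndefinedDistanceError):
            pairwise_distance("NNNN", "ACGT", "jc")

    def test_saturation_returns_infinity(self):
        a = "ACGT" * 10
        b = "CAGT" * 10  # heavy transversion load saturates the log
        d = pairwise_distance(a, "".join("TGCA"[["A", "C", "G", "T"].index(c)] for c in a), "jc")
        assert math.isinf(d)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance("ACGT", "ACG", "jc")

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        for model in ("f84", "k2p", "jc"):
            assert pairwise_distance(a, b, model) == pairwise_distance(b, a, model)


class TestPartition:
    SEQS = [("x1", "ACGTACGTAC"), ("x2", "ACGTACGTAT"), ("y1", "TTGTACGAAC")]
    SPECIES = {"x1": "X", "x2": "X", "y1": "Y"}

    def test_intra_inter_enumeration(self):
        records = partition_distances(self.SEQS, self.SPECIES, "jc")
        rels = sorted(r.relation for r in records)
        assert rels == ["inter", "inter", "intra"]

    def test_pair_count_is_n_choose_2(self, small_panel):
        entries = small_panel.templates
        species = {tid: tid for tid, _ in entries}  # all distinct species
        # equal-length subset so they can be compared ungapped
        entries = [(t, s) for t, s in entries if len(s) == len(entries[0][1])]
        records = partition_distances(entries, species, "jc")
        n = len(entries)
        assert len(records) == n * (n - 1) // 2
        assert all(r.relation == "inter" for r in records)

    def test_divergent_paralogs_are_one_large_intra_pair(self):
        a = "ACGT" * 50
        b = "TCGA" * 25 + "ACGT" * 25
        records = partition_distances(
            [("g1|cpn60|1", a), ("g1|cpn60|2", b)],
            {"g1|cpn60|1": "S", "g1|cpn60|2": "S"},
            "jc",
        )
        assert len(records) == 1
        assert records[0].relation == "intra"
        assert records[0].distance > 0.3

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            partition_distances([("a", "ACGT")], {"a": "A"})


class TestGapStatistic:
    @staticmethod
    def _records(intra, inter):
        recs = [DistanceRecord("a", "b", d, "intra") for d in intra]
        recs += [DistanceRecord("c", "d", d, "inter") for d in inter]
        return recs

    def test_identical_distributions_give_zero_gap(self):
        recs = self._records([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert gap_statistic(recs).gap == pytest.approx(0.0, abs=1e-12)

    def test_median_gap_robust_to_right_tail_outliers(self):
        inter = [0.40, 0.45, 0.50, 0.55, 0.60]
        base = self._records([0.01, 0.02, 0.03], inter)
        spiked = self._records([0.01, 0.02, 0.03], inter + [5.9, 5.9])
        g0 = gap_statistic(base)
        g1 = gap_statistic(spiked)
        mean_shift = np.mean(inter + [5.9, 5.9]) - np.mean(inter)
        assert abs(g1.gap - g0.gap) <= 0.06  # median barely moves...
        assert mean_shift > 1.5  # ...while the mean would explode
        assert g1.max_inter == 5.9

    def test_saturated_distances_counted_but_excluded_from_median(self):
        recs = self._records([0.01], [0.5, 0.6, math.inf])
        summary = gap_statistic(recs)
        assert summary.n_inter == 3
        assert summary.n_saturated_inter == 1
        assert summary.median_inter == pytest.approx(0.55)

    def test_empty_side_is_named_in_error(self):
        with pytest.raises(ValueError, match="intra"):
            gap_statistic(self._records([], [0.5]))
        with pytest.raises(ValueError, match="inter"):
            gap_statistic(self._records([0.5], []))


class TestHistogram:
    def test_single_bin_holds_everything(self):
        recs = [DistanceRecord("a", "b", 0.005, "intra")] * 10
        h = histogram(recs, 0.01)
        assert h.intra_percent[0] == pytest.approx(100.0)

    def test_two_values_split_between_bins(self):
        recs = [
            DistanceRecord("a", "b", 0.005, "intra"),
            DistanceRecord("a", "c", 0.015, "intra"),
        ]
        h = histogram(recs, 0.01)
        assert h.intra_percent[0] == pytest.approx(50.0)
        assert h.intra_percent[1] == pytest.approx(50.0)

    def test_cap_affects_view_not_normalization(self):
        recs = [
            DistanceRecord("a", "b", 0.5, "inter"),
            DistanceRecord("a", "c", 1.2, "inter"),
        ]
        h = histogram(recs, 0.01, cap=1.0)
        assert h.inter_percent.sum() == pytest.approx(100.0)
        assert h.capped().inter_percent.sum() == pytest.approx(50.0)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            histogram([], 0.0)
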