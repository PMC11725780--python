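import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleokin import kinship as kn, synthetic
from paleokin.kinship import (
    PairEstimate,
    classify_degree,
    consensus_degrees,
    first_degree_type_hmm,
    genotype_likelihoods,
    ml_k_coefficients,
    normalize_pmr,
    pairwise_mismatch_rate,
)
from paleokin.pedigree import Individual, Pedigree
from paleokin.synthetic import ObservationModel, ReadCounts

from conftest import panel_from_matrix


def naive_pmr(gi, gj):
    """Independent brute-force recount."""
    n = m = 0
    for a, b in zip(gi, gj):
        if a == -1 or b == -1:
            continue
        n += 1
        m += a != b
    return (m / n if n else float("nan"), n)


class TestPMR:
    def test_spec_example(self):
        # disk 9s become the in-memory missing sentinel
        panel = panel_from_matrix([[0, 0, 2, -1, 0], [0, 2, 2, 0, 0]])
        pmr, n, _ = pairwise_mismatch_rate(panel, "I0", "I1")
        assert (pmr, n) == (0.25, 4)

    def test_identical_rows(self):
        panel = panel_from_matrix([[0, 2, 0, 2], [0, 2, 0, 2]])
        pmr, n, _ = pairwise_mismatch_rate(panel, "I0", "I1")
        assert pmr == 0.0 and n == 4

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_naive_recount(self, seed):
        rng = np.random.default_rng(seed)
        geno = rng.choice([0, 2, -1], size=(2, 300), p=[0.4, 0.4, 0.2])
        panel = panel_from_matrix(geno)
        pmr, n, _ = pairwise_mismatch_rate(panel, "I0", "I1")
        e_pmr, e_n = naive_pmr(geno[0], geno[1])
        assert n == e_n
        if n:
            assert pmr == pytest.approx(e_pmr)

    def test_zero_overlap_sentinel(self):
        panel = panel_from_matrix([[0, -1], [-1, 0]])
        pmr, n, se = pairwise_mismatch_rate(panel, "I0", "I1")
        assert n == 0 and math.isnan(pmr)

    def test_jackknife_se_tracks_binomial(self):
        rng = np.random.default_rng(1)
        n = 40_000
        geno = rng.choice([0, 2], size=(2, n)).astype(np.int8)
        panel = panel_from_matrix(
            geno, cm=np.linspace(0, 3000, n),
            chrom=np.repeat([str(c) for c in range(1, 11)], n // 10),
        )
        pmr, n_ov, se = pairwise_mismatch_rate(panel, "I0", "I1")
        binom_se = math.sqrt(pmr * (1 - pmr) / n_ov)
        assert se == pytest.approx(binom_se, rel=0.25)


class TestNormalizeClassify:
    def test_explicit_baseline_arithmetic(self):
        pairs = [PairEstimate(pair=("a", "b"), pmr=0.18, n_overlap=10_000)]
        out = normalize_pmr(pairs, "explicit-baseline", baseline=0.24)
        assert out[0].normalized_pmr == pytest.approx(0.75)

    def test_median_baseline(self):
        pairs = [
            PairEstimate(pair=(f"u{i}", f"u{i+1}"), pmr=p, n_overlap=10_000)
            for i, p in enumerate([0.24, 0.25, 0.26])
        ]
        out = normalize_pmr(pairs, "median-of-unrelated")
        assert out[1].normalized_pmr == pytest.approx(1.0)

    def test_no_baseline_is_config_error(self):
        with pytest.raises(ValueError):
            normalize_pmr([], "median-of-unrelated")

    @pytest.mark.parametrize(
        "norm,expected",
        [
            (0.55, "identical"),
            (0.75, "1st"),
            (0.85, "2nd"),
            (0.93, "3rd"),
            (0.99, "unrelated"),
        ],
    )
    def test_cutoffs(self, norm, expected):
        p = PairEstimate(
            pair=("a", "b"), n_overlap=20_000, normalized_pmr=norm,
            normalized_se=0.004,
        )
        assert classify_degree(p) == expected

    def test_low_overlap_undetermined(self):
        p = PairEstimate(pair=("a", "b"), n_overlap=800, normalized_pmr=0.75)
        assert classify_degree(p) == "undetermined"

    def test_ci_spanning_cutoff_undetermined(self):
        p = PairEstimate(
            pair=("a", "b"), n_overlap=20_000, normalized_pmr=0.80,
            normalized_se=0.02,  # 2 SE spans the 0.8125 cutoff
        )
        assert classify_degree(p) == "undetermined"


class TestGenotypeLikelihoods:
    def test_ordering_ref_reads(self):
        reads = ReadCounts(ids=["x"], depth=np.array([[2]]), alt=np.array([[0]]))
        gl = genotype_likelihoods(reads, error=0.01)[0, 0]
        assert gl[0] > gl[1] > gl[2]

    def test_het_maximal(self):
        reads = ReadCounts(ids=["x"], depth=np.array([[2]]), alt=np.array([[1]]))
        gl = genotype_likelihoods(reads, error=0.01)[0, 0]
        assert gl[1] == max(gl)

    def test_hand_computed_binomials(self):
        reads = ReadCounts(
            ids=["x"], depth=np.array([[3, 2, 4]]), alt=np.array([[1, 2, 0]])
        )
        e = 0.1
        gl = genotype_likelihoods(reads, error=e)[0]
        # site 0: 1 alt of 3 reads
        assert gl[0, 0] == pytest.approx(3 * e * (1 - e) ** 2)
        assert gl[0, 1] == pytest.approx(3 * 0.5**3)
        # site 1: 2 alt of 2
        assert gl[1, 2] == pytest.approx((1 - e) ** 2)
        # site 2: 0 alt of 4
        assert gl[2, 0] == pytest.approx((1 - e) ** 4)

    def test_error_domain(self):
        reads = ReadCounts(ids=["x"], depth=np.array([[1]]), alt=np.array([[0]]))
        with pytest.raises(ValueError):
            genotype_likelihoods(reads, error=0.7)


def _pair_reads(ped, freqs, depth, seed, ids):
    dg = synthetic.gene_drop(ped, freqs, seed=seed)
    model = ObservationModel(mean_depth=depth, base_error=0.001, damage_rate=0.0)
    return synthetic.degrade_to_reads(dg, model, seed=seed + 1, individuals=ids)


class TestMLK:
    @pytest.mark.parametrize(
        "relation,expected_k",
        [("po", (0.0, 1.0, 0.0)), ("sib", (0.25, 0.5, 0.25)), ("unrel", None)],
    )
    def test_recovery(self, freqs_20k, relation, expected_k):
        if relation == "po":
            ped = Pedigree(
                [
                    Individual("A", "F"),
                    Individual("F0", "M"),
                    Individual("B", "M", mother="A", father="F0"),
                ]
            )
        elif relation == "sib":
            ped = Pedigree(
                [
                    Individual("M0", "F"),
                    Individual("F0", "M"),
                    Individual("A", "F", mother="M0", father="F0"),
                    Individual("B", "M", mother="M0", father="F0"),
                ]
            )
        else:
            ped = Pedigree([Individual("A", "F"), Individual("B", "M")])
        reads = _pair_reads(ped, freqs_20k, 30.0, 77, ["A", "B"])
        gls = genotype_likelihoods(reads, error=0.01)
        res = ml_k_coefficients(gls[0], gls[1], freqs_20k)
        k = (res["k0"], res["k1"], res["k2"])
        assert sum(k) == pytest.approx(1.0, abs=1e-6)
        if expected_k is None:
            assert res["k0"] > 0.9
        else:
            assert k == pytest.approx(expected_k, abs=0.06)
            assert res["k0"] < 0.35

    def test_likelihood_at_optimum_beats_unrelated(self, freqs_20k):
        ped = Pedigree(
            [
                Individual("A", "F"),
                Individual("F0", "M"),
                Individual("B", "M", mother="A", father="F0"),
            ]
        )
        reads = _pair_reads(ped, freqs_20k, 5.0, 3, ["A", "B"])
        gls = genotype_likelihoods(reads, error=0.01)
        res = ml_k_coefficients(gls[0], gls[1], freqs_20k)
        assert res["loglik"] >= res["loglik_unrelated"]

    def test_degenerate_all_missing(self, freqs_20k):
        n = len(freqs_20k)
        reads = ReadCounts(
            ids=["x"], depth=np.zeros((1, n), int), alt=np.zeros((1, n), int)
        )
        gls = genotype_likelihoods(reads, error=0.01)
        res = ml_k_coefficients(gls[0], gls[0], freqs_20k)
        assert res.get("undetermined")


class TestFirstDegreeHMM:
    def _observe(self, ped, freqs, seed, ids, depth=0.5):
        reads = _pair_reads(ped, freqs, depth, seed, ids)
        return synthetic.pseudohaploid_call(reads, seed=seed + 2)

    def test_po_vs_sib_discrimination(self, freqs_100k):
        freqs_20k = freqs_100k  # study-scale panel; 0.5x coverage
        po = Pedigree(
            [
                Individual("A", "F"),
                Individual("F0", "M"),
                Individual("B", "M", mother="A", father="F0"),
            ]
        )
        sib = Pedigree(
            [
                Individual("M0", "F"),
                Individual("F0", "M"),
                Individual("A", "F", mother="M0", father="F0"),
                Individual("B", "M", mother="M0", father="F0"),
            ]
        )
        baseline = kn.expected_pmr_baseline(freqs_20k)
        hits = {"po": 0, "sib": 0}
        n_rep = 10
        for r in range(n_rep):
            panel = self._observe(po, freqs_20k, 200 + 7 * r, ["A", "B"])
            typ, margin = first_degree_type_hmm(
                panel, "A", "B", baseline_pmr=baseline
            )
            hits["po"] += typ == "parent-offspring" and margin > 0
            panel = self._observe(sib, freqs_20k, 600 + 7 * r, ["A", "B"])
            typ, margin = first_degree_type_hmm(
                panel, "A", "B", baseline_pmr=baseline
            )
            hits["sib"] += typ == "sibling" and margin > 0
        assert hits["po"] >= 0.9 * n_rep
        assert hits["sib"] >= 0.9 * n_rep

    def test_too_few_windows_na(self):
        panel = panel_from_matrix([[0, 2, 0], [0, 2, 2]])
        typ, margin = first_degree_type_hmm(panel, "I0", "I1", baseline_pmr=0.25)
        assert typ == "NA" and math.isnan(margin)


class TestConsensus:
    def test_agreement(self):
        key = frozenset(("a", "b"))
        cons = consensus_degrees(
            {
                "m1": {key: ("1st", 1.0)},
                "m2": {key: ("1st", 1.0)},
                "m3": {key: ("1st", 0.5)},
            }
        )
        assert cons[key].call == "1st" and not cons[key].conflict

    def test_conflict_flagged_and_reported(self):
        key = frozenset(("a", "b"))
        cons = consensus_degrees(
            {
                "m1": {key: ("1st", 1.0)},
                "m2": {key: ("2nd", 0.5)},
                "m3": {key: ("undetermined", 0.0)},
            }
        )
        assert cons[key].conflict
        assert cons[key].call == "1st"
        assert set(cons[key].methods.values()) == {"1st", "2nd", "undetermined"}

    def test_all_undetermined(self):
        key = frozenset(("a", "b"))
        cons = consensus_degrees({"m1": {key: ("undetermined", 0.0)}})
        assert cons[key].call == "undetermined"
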