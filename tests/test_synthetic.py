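import numpy as np
import pytest

from paleokin import synthetic
from paleokin.chronology import ce_to_bp, synthetic_calibration_curves
from paleokin.pedigree import Individual, InvalidPedigreeError, Pedigree
from paleokin.synthetic import (
    ObservationModel,
    degrade_to_reads,
    draw_frequencies,
    gene_drop,
    pseudohaploid_call,
    simulate_c14,
    simulate_isotopes,
    simulate_sexchr_counts,
)


class TestDrawFrequencies:
    def test_range_and_count(self):
        f = draw_frequencies(10, (1, 1), seed=1)
        assert len(f) == 10
        assert np.all((f.freq >= 0.01) & (f.freq <= 0.99))

    def test_beta_mean_matches_theory(self):
        f = draw_frequencies(100_000, (0.5, 0.5), seed=2)
        # Beta(0.5, 0.5) mean is 1/2; truncation at [0.01, 0.99] is symmetric
        assert f.freq.mean() == pytest.approx(0.5, abs=0.01)
        f2 = draw_frequencies(100_000, (2, 6), seed=3)
        assert f2.freq.mean() == pytest.approx(0.25, abs=0.01)

    def test_determinism(self):
        a = draw_frequencies(500, (0.5, 0.5), seed=9)
        b = draw_frequencies(500, (0.5, 0.5), seed=9)
        np.testing.assert_array_equal(a.freq, b.freq)
        np.testing.assert_array_equal(a.cm, b.cm)

    def test_map_sorted_within_chromosomes(self):
        f = draw_frequencies(5000, (1, 1), seed=4)
        for c in np.unique(f.chrom):
            assert np.all(np.diff(f.cm[f.chrom == c]) >= 0)

    @pytest.mark.parametrize("bad", [0, -5])
    def test_invalid_n(self, bad):
        with pytest.raises(ValueError):
            draw_frequencies(bad, (1, 1), seed=0)

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            draw_frequencies(10, (0, 1), seed=0)


def trio_pedigree():
    return Pedigree(
        [
            Individual("M", "F"),
            Individual("F", "M"),
            Individual("C", "M", mother="M", father="F"),
        ]
    )


class TestGeneDrop:
    def test_parent_offspring_kinship(self, freqs_20k):
        ped = trio_pedigree()
        phis = []
        for seed in range(6):
            dg = gene_drop(ped, freqs_20k, seed=seed)
            phis.append(dg.realized_kinship("M", "C"))
        # phi = 1/4 exactly in expectation; 22-chromosome sampling noise
        assert np.mean(phis) == pytest.approx(0.25, abs=0.02)

    def test_full_sib_ibd_state_fractions(self, freqs_20k):
        ped = Pedigree(
            [
                Individual("M", "F"),
                Individual("F", "M"),
                Individual("S1", "M", mother="M", father="F"),
                Individual("S2", "F", mother="M", father="F"),
            ]
        )
        fr = np.zeros(3)
        n_rep = 12
        for seed in range(n_rep):
            dg = gene_drop(ped, freqs_20k, seed=100 + seed)
            fr += np.array(dg.ibd_state_fractions("S1", "S2"))
        fr /= n_rep
        assert fr == pytest.approx([0.25, 0.5, 0.25], abs=0.05)

    def test_unrelated_founders(self, freqs_20k):
        ped = Pedigree([Individual("A", "M"), Individual("B", "F")])
        dg = gene_drop(ped, freqs_20k, seed=0)
        assert dg.realized_kinship("A", "B") == 0.0

    def test_mendelian_consistency(self, freqs_20k):
        """Every child allele is traceable to a parent haplotype."""
        ped = trio_pedigree()
        dg = gene_drop(ped, freqs_20k, seed=3)
        ic, im, if_ = (dg.ids.index(x) for x in ("C", "M", "F"))
        child_mat = dg.haplotypes[ic, 0]
        mother = dg.haplotypes[im]
        assert np.all((child_mat == mother[0]) | (child_mat == mother[1]))
        # and origins point at maternal founder labels
        assert set(np.unique(dg.origins[ic, 0])) <= set(
            np.unique(dg.origins[im])
        )

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(InvalidPedigreeError, match="cycle"):
            Pedigree(
                [
                    Individual("A", "M", father="B"),
                    Individual("B", "M", father="A"),
                ]
            )

    def test_seed_reproducibility(self, freqs_20k):
        ped = trio_pedigree()
        a = gene_drop(ped, freqs_20k, seed=7)
        b = gene_drop(ped, freqs_20k, seed=7)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)


class TestObservation:
    def test_zero_depth_all_missing(self, freqs_20k):
        dg = gene_drop(trio_pedigree(), freqs_20k, seed=0)
        reads = degrade_to_reads(dg, ObservationModel(mean_depth=0.0), seed=1)
        assert reads.depth.sum() == 0
        panel = pseudohaploid_call(reads, seed=2)
        assert np.all(panel.genotypes == -1)

    def test_deep_error_free_majority_matches_truth(self, freqs_20k):
        dg = gene_drop(trio_pedigree(), freqs_20k, seed=1)
        model = ObservationModel(mean_depth=30, base_error=0.0, damage_rate=0.0)
        reads = degrade_to_reads(dg, model, seed=2)
        g = dg.genotypes[0]
        hom = (g == 0) | (g == 2)
        maj = (reads.alt[0] * 2 > reads.depth[0]).astype(int) * 2
        covered = reads.depth[0] > 0
        m = hom & covered
        assert (maj[m] == g[m]).mean() > 0.999

    def test_damage_rate_recovered(self, freqs_20k):
        """0 -> 1 miscalls at reference-homozygous sites match the setting."""
        dg = gene_drop(trio_pedigree(), freqs_20k, seed=2)
        model = ObservationModel(mean_depth=5, base_error=0.0, damage_rate=0.3)
        reads = degrade_to_reads(dg, model, seed=3)
        g = dg.genotypes[0]
        m = g == 0
        rate = reads.alt[0, m].sum() / reads.depth[0, m].sum()
        assert rate == pytest.approx(0.3, abs=0.01)

    def test_identity_preserved_at_zero_error(self, freqs_20k):
        dg = gene_drop(trio_pedigree(), freqs_20k, seed=4)
        model = ObservationModel(mean_depth=2, base_error=0.0, damage_rate=0.0)
        reads = degrade_to_reads(dg, model, seed=5)
        g = dg.genotypes[0]
        hom = (g == 0) | (g == 2)
        cov = reads.depth[0] > 0
        m = hom & cov
        assert np.all(reads.alt[0, m] * 2 == reads.depth[0, m] * g[m])


class TestPseudohaploid:
    def test_single_allele_site(self, freqs_20k):
        dg = gene_drop(trio_pedigree(), freqs_20k, seed=0)
        reads = degrade_to_reads(
            dg, ObservationModel(mean_depth=2, base_error=0.0, damage_rate=0.0),
            seed=1,
        )
        panel = pseudohaploid_call(reads, seed=2)
        g = dg.genotypes
        for r in range(3):
            m = (g[r] == 2) & (reads.depth[r] > 0)
            assert np.all(panel.genotypes[r, m] == 2)

    def test_het_sites_called_half_half(self, freqs_20k):
        dg = gene_drop(trio_pedigree(), freqs_20k, seed=1)
        reads = degrade_to_reads(
            dg, ObservationModel(mean_depth=30, base_error=0.0, damage_rate=0.0),
            seed=2,
        )
        panel = pseudohaploid_call(reads, seed=3)
        het = dg.genotypes[0] == 1
        calls = panel.genotypes[0, het]
        assert (calls == 2).mean() == pytest.approx(0.5, abs=0.03)

    def test_zero_reads_missing(self, freqs_20k):
        dg = gene_drop(trio_pedigree(), freqs_20k, seed=2)
        reads = degrade_to_reads(dg, ObservationModel(mean_depth=0.3), seed=3)
        panel = pseudohaploid_call(reads, seed=4)
        assert np.all(panel.genotypes[0, reads.depth[0] == 0] == -1)


class TestSexChrCounts:
    def test_female_ratio_low(self):
        c = simulate_sexchr_counts("F", 1_000_000, seed=1)
        assert c["nY"] / (c["nX"] + c["nY"]) < 0.016

    def test_male_ratio_high(self):
        c = simulate_sexchr_counts("M", 1_000_000, seed=2)
        assert c["nY"] / (c["nX"] + c["nY"]) > 0.075

    def test_tiny_sample_undetermined_downstream(self):
        from paleokin.uniparental import ry_sex

        c = simulate_sexchr_counts("M", 10, seed=3)
        assert ry_sex(c["nY"], c["nX"]).call == "undetermined"

    def test_invalid_n_reads(self):
        with pytest.raises(ValueError):
            simulate_sexchr_counts("M", 0, seed=0)


def _flat_curves(mu_t=1000.0, mu_m=1400.0):
    from paleokin.chronology import CalCurve

    grid = np.linspace(0, 3000, 30)
    terr = CalCurve(grid, np.full_like(grid, mu_t), np.full_like(grid, 1e-9))
    marine = CalCurve(grid, np.full_like(grid, mu_m), np.full_like(grid, 1e-9))
    return terr, marine


class TestSimulateC14:
    def test_pure_terrestrial_ignores_deltar(self, cao_pedigree):
        terr, marine = _flat_curves()
        kw = dict(
            pedigree=cao_pedigree, tissue_ages={"B1": 10.0},
            terr=terr, marine=marine, sigma_lab=1e-9, seed=5,
        )
        a = simulate_c14(marine_fracs={"B1": (0.0, 0.0)}, delta_r=0.0, **kw)
        b = simulate_c14(marine_fracs={"B1": (0.0, 0.0)}, delta_r=-500.0, **kw)
        assert a[0].age_bp == pytest.approx(b[0].age_bp, abs=1e-3)
        assert a[0].age_bp == pytest.approx(1000.0, abs=0.01)

    def test_pure_marine_offset(self, cao_pedigree):
        terr, marine = _flat_curves()
        dets = simulate_c14(
            cao_pedigree, {"B1": 10.0}, {"B1": (1.0, 0.0)}, 100.0,
            terr, marine, sigma_lab=1e-9, seed=6,
        )
        assert dets[0].age_bp == pytest.approx(1500.0, abs=0.01)


class TestSimulateIsotopes:
    def test_pure_c4_endpoint(self):
        rec = simulate_isotopes({"X": {"pC4": 1.0, "pMarine": 0.0}})["X"]
        assert rec["d13c_en"] == pytest.approx(-2.3)

    def test_linear_mixing_at_035(self):
        rec = simulate_isotopes({"X": {"pC4": 0.35, "pMarine": 0.0}})["X"]
        assert rec["d13c_en"] == pytest.approx(-11.4)

    def test_round_trip_through_diet_module(self):
        from paleokin.isotopes import percent_c4, percent_marine_closed_form

        cfg = {"X": {"pC4": 0.62, "pMarine": 0.41}}
        rec = simulate_isotopes(cfg)["X"]
        assert percent_c4(rec["d13c_en"]) == pytest.approx(62.0, abs=1e-9)
        assert percent_marine_closed_form(rec["d15n_col"]) == pytest.approx(
            41.0, abs=1e-9
        )


def test_fixture_pedigree_relationships(cao_pedigree):
    """The shipped pedigree realizes the burial group's relationship set."""
    assert cao_pedigree.degree("B1", "B3") == 1
    assert cao_pedigree.degree("B1", "B1s") == 1
    assert cao_pedigree.degree("B1", "B2") == 1
    assert cao_pedigree.degree("B1", "B4") == 2
    assert cao_pedigree.degree("B3", "B4") == 2
    assert cao_pedigree.degree("B3", "B1s") == 2
    assert cao_pedigree.degree("B3", "B3s") == 2
    assert cao_pedigree.degree("B4", "B1s") == 3
    # four generations: B4 -> P1 -> B1 -> B1s
    assert cao_pedigree.parents("B1s")[1] == "B1"
    lin = {i.id: i.mt_lineage for i in cao_pedigree if i.sampled}
    assert {lin[i] for i in ("B1", "B1s", "B2", "B3")} == {"mtD-1"}
    assert lin["B3s"] == "mtD-2"


def test_pedigree_text_round_trip(tmp_path, cao_pedigree):
    from paleokin.pedigree import read_pedigree, write_pedigree

    path = tmp_path / "ped.tsv"
    write_pedigree(cao_pedigree, path)
    back = read_pedigree(path)
    assert back.ids == cao_pedigree.ids
    for iid in back.ids:
        a, b = back.members[iid], cao_pedigree.members[iid]
        assert (a.mother, a.father, a.sex, a.mt_lineage, a.sampled) == (
            b.mother, b.father, b.sex, b.mt_lineage, b.sampled
        )
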