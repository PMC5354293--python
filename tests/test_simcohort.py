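"""Synthetic-cohort generator: invariants, planted truths, trait models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cohortgwas import simcohort as sc
from cohortgwas.gio import MISSING
from cohortgwas.harmonize import hwe_exact_test


def _pairwise_r2(col_a, col_b):
    return np.corrcoef(col_a, col_b)[0, 1] ** 2


class TestReferencePanel:
    def test_dimensions_and_polymorphism(self):
        panel = sc.generate_reference_panel(n_hap=4, n_markers=10, seed=1)
        assert panel.haplotypes.shape[0] == 4
        assert set(np.unique(panel.haplotypes)) <= {0, 1}
        counts = panel.haplotypes.sum(axis=0)
        assert counts.min() >= 2 and counts.max() <= 2  # n_hap - 2 == 2

    def test_no_singletons_at_scale(self):
        panel = sc.generate_reference_panel(n_hap=50, n_markers=500, seed=2)
        counts = panel.haplotypes.sum(axis=0)
        assert counts.min() >= 2
        assert counts.max() <= 48

    def test_same_seed_identical(self):
        a = sc.generate_reference_panel(20, 100, seed=7)
        b = sc.generate_reference_panel(20, 100, seed=7)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.alleles, b.alleles)

    def test_zero_switch_rate_copies_founders(self):
        panel = sc.generate_reference_panel(40, 200, mosaic_switch_rate=0.0,
                                            seed=3, n_founders=2)
        # every haplotype must equal one of the two founders exactly
        distinct = np.unique(panel.haplotypes, axis=0)
        assert distinct.shape[0] <= 2
        # with two founder patterns every pair of polymorphic sites is in
        # complete LD: adjacent-site r^2 == 1
        h = panel.haplotypes.astype(float)
        freqs = h.mean(axis=0)
        common = np.flatnonzero((freqs > 0.2) & (freqs < 0.8))
        r2 = [_pairwise_r2(h[:, a], h[:, b])
              for a, b in zip(common[:-1], common[1:])]
        assert np.min(r2) > 0.999

    def test_positions_strictly_increasing(self):
        panel = sc.generate_reference_panel(10, 300, seed=4)
        assert np.all(np.diff(panel.positions) > 0)

    @pytest.mark.parametrize("n_hap,n_markers", [(3, 10), (5, 10), (4, 1)])
    def test_invalid_sizes_rejected(self, n_hap, n_markers):
        with pytest.raises(ValueError):
            sc.generate_reference_panel(n_hap, n_markers, seed=0)


class TestSampleCohort:
    def test_shapes_and_values(self, small_panel):
        manifest = sc.PlatformManifest("HH", set(small_panel.marker_ids[:50]))
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 5, 5)
        ds = sc.sample_cohort(small_panel, design, seed=5, manifest=manifest)
        assert ds.genotypes.shape == (10, 50)
        assert set(np.unique(ds.genotypes)) <= {0, 1, 2}

    def test_zero_missing_rate(self, small_panel):
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 10, 10,
                                missing_rate=0.0)
        ds = sc.sample_cohort(small_panel, design, seed=6)
        assert not ds.missing_mask().any()

    def test_missing_rate_applied(self, small_panel):
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 50, 50,
                                missing_rate=0.1)
        ds = sc.sample_cohort(small_panel, design, seed=6)
        frac = ds.missing_mask().mean()
        assert 0.07 < frac < 0.13

    def test_manifest_not_in_panel_rejected(self, small_panel):
        manifest = sc.PlatformManifest("HH", {"rs_not_there"})
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 2, 2)
        with pytest.raises(ValueError, match="absent from panel"):
            sc.sample_cohort(small_panel, design, seed=1, manifest=manifest)

    def test_allele_freqs_converge_to_panel(self, small_panel):
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 400, 400)
        ds = sc.sample_cohort(small_panel, design, seed=7)
        diff = np.abs(ds.allele_freqs() - small_panel.allele_freqs())
        assert diff.mean() < 0.02
        assert diff.max() < 0.12

    def test_genotype_equals_haplotype_sum(self, small_study):
        hs = small_study.true_haplotypes
        g = hs[:, 0, :] + hs[:, 1, :]
        obs = small_study.genotypes
        ok = obs != MISSING
        assert np.array_equal(obs[ok],
                              g[:, small_study.panel_marker_index][ok].astype(np.int8))

    def test_hwe_holds_at_unplanted_markers(self, small_panel):
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 250, 250)
        ds = sc.sample_cohort(small_panel, design, seed=8)
        fails = 0
        for j in range(ds.n_markers):
            col = ds.genotypes[:, j]
            p = hwe_exact_test(int(np.sum(col == 0)), int(np.sum(col == 1)),
                               int(np.sum(col == 2)))
            fails += p < 0.001
        assert fails / ds.n_markers <= 0.01


class TestPlantRelatives:
    def test_duplicate_zero_discordance(self, small_panel, small_study):
        led = sc.TruthLedger()
        ds = sc.plant_relatives(small_study,
                                [sc.PairSpec("duplicate",
                                             small_study.sample_ids[0])],
                                small_panel, seed=1, ledger=led)
        i = 0
        j = ds.n_samples - 1
        gi, gj = ds.genotypes[i], ds.genotypes[j]
        ok = (gi != MISSING) & (gj != MISSING)
        assert np.array_equal(gi[ok], gj[ok])
        assert led.pairs[0]["kind"] == "duplicate"

    def test_duplicate_discordance_binomial_mean(self, sparse_panel):
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 0, 2)
        ds = sc.sample_cohort(sparse_panel, design, seed=3)
        n_disc = []
        for seed in range(10):
            out = sc.plant_relatives(
                ds, [sc.PairSpec("duplicate", ds.sample_ids[0],
                                 discordance=0.005)],
                sparse_panel, seed=seed)
            gi, gj = out.genotypes[0], out.genotypes[-1]
            n_disc.append(int(np.sum(gi != gj)))
        # 2,000 markers * 0.005 = 10 expected discordant calls
        assert 5 < np.mean(n_disc) < 16

    def test_full_sib_mean_ibd(self, sparse_panel):
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 0, 40)
        ds = sc.sample_cohort(sparse_panel, design, seed=4)
        led = sc.TruthLedger()
        specs = [sc.PairSpec("full_sib", sid) for sid in ds.sample_ids]
        sc.plant_relatives(ds, specs, sparse_panel, seed=5, ledger=led)
        tz = led.pairs_frame()[["true_z0", "true_z1", "true_z2"]].mean()
        assert abs(tz["true_z0"] - 0.25) < 0.06
        assert abs(tz["true_z1"] - 0.50) < 0.06
        assert abs(tz["true_z2"] - 0.25) < 0.06

    def test_half_sib_mean_ibd(self, sparse_panel):
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 0, 40)
        ds = sc.sample_cohort(sparse_panel, design, seed=6)
        led = sc.TruthLedger()
        specs = [sc.PairSpec("half_sib", sid) for sid in ds.sample_ids]
        sc.plant_relatives(ds, specs, sparse_panel, seed=7, ledger=led)
        tz = led.pairs_frame()[["true_z0", "true_z1", "true_z2"]].mean()
        assert abs(tz["true_z0"] - 0.5) < 0.07
        assert abs(tz["true_z1"] - 0.5) < 0.07
        assert tz["true_z2"] == 0.0

    def test_unknown_source_rejected(self, small_panel, small_study):
        with pytest.raises(ValueError, match="unknown individual"):
            sc.plant_relatives(small_study,
                               [sc.PairSpec("duplicate", "nobody")],
                               small_panel, seed=1)


class TestPlantArtifacts:
    def test_zero_rate_unchanged(self, small_study):
        out = sc.plant_artifacts(small_study, [small_study.marker_ids[0]],
                                 corruption_rate=0.0, seed=1)
        assert np.array_equal(out.genotypes, small_study.genotypes)

    def test_full_corruption_all_alt_hom(self, small_study):
        mid = small_study.marker_ids[3]
        out = sc.plant_artifacts(small_study, [mid], corruption_rate=1.0,
                                 seed=1)
        col = out.genotypes[:, 3]
        assert np.all(col[col != MISSING] == 2)

    def test_frequency_shift_expectation(self, small_panel):
        # shift per allele is (1 - p) * rate in expectation
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 500, 500)
        ds = sc.sample_cohort(small_panel, design, seed=9)
        rate = 0.1
        j = 5
        p0 = ds.allele_freqs()[j]
        shifts = []
        for seed in range(12):
            out = sc.plant_artifacts(ds, [ds.marker_ids[j]], rate, seed=seed)
            shifts.append(out.allele_freqs()[j] - p0)
        assert np.mean(shifts) == pytest.approx((1 - p0) * rate, abs=0.01)

    def test_marker_not_in_manifest_rejected(self, small_study):
        with pytest.raises(ValueError, match="not in study manifest"):
            sc.plant_artifacts(small_study, ["rs_missing"], 0.5, seed=1)

    def test_truth_recorded(self, small_study):
        led = sc.TruthLedger()
        mid = small_study.marker_ids[1]
        sc.plant_artifacts(small_study, [mid], 0.2, seed=1, ledger=led)
        frame = led.artifacts_frame()
        assert list(frame["marker_id"]) == [mid]
        assert frame["corruption_rate"].iloc[0] == 0.2


class TestTraits:
    def test_null_trait_unit_variance(self, small_panel, small_study):
        trait = sc.TraitModel(effects={}, sigma=1.0)
        pheno = sc.simulate_traits([small_study], trait, small_panel, seed=1)
        # no genetic or covariate effects: variance is just sigma^2
        assert np.var(pheno["trait_quant"]) == pytest.approx(1.0, rel=0.6)

    def test_quantitative_effect_recovery(self, small_panel):
        # per-allele beta = 0.45 recovered by OLS across replicate cohorts
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 0, 250)
        mid = small_panel.marker_ids[10]
        betas = []
        for seed in range(20):
            ds = sc.sample_cohort(small_panel, design, seed=seed)
            trait = sc.TraitModel(effects={mid: 0.45}, sigma=1.0)
            pheno = sc.simulate_traits([ds], trait, small_panel, seed=seed)
            col = np.flatnonzero(small_panel.marker_ids == mid)[0]
            g = ds.true_haplotypes[:, :, col].sum(axis=1)
            slope = np.polyfit(g, pheno["trait_quant"], 1)[0]
            betas.append(slope)
        assert np.mean(betas) == pytest.approx(0.45, abs=0.03)

    def test_binary_prevalence_hit(self, small_panel):
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 0, 4000)
        ds = sc.sample_cohort(small_panel, design, seed=31)
        mid = small_panel.marker_ids[0]
        trait = sc.TraitModel(effects={}, binary_effects={mid: np.log(2.17)},
                              prevalence=0.072)
        pheno = sc.simulate_traits([ds], trait, small_panel, seed=32)
        obs = pheno["trait_binary"].mean()
        se = np.sqrt(0.072 * 0.928 / len(pheno))
        assert abs(obs - 0.072) < 3 * se

    def test_unreachable_prevalence_rejected(self):
        with pytest.raises(ValueError):
            sc._solve_prevalence_intercept(np.zeros(10), 1e-23)
        with pytest.raises(ValueError, match="prevalence"):
            sc.TraitModel(effects={}, prevalence=1.0)

    def test_duplicate_subjects_share_trait(self, small_panel):
        design = sc.StudyDesign("S1", "CohortA", "t2d", "HH", 0, 20)
        ds = sc.sample_cohort(small_panel, design, seed=41)
        led = sc.TruthLedger()
        out = sc.plant_relatives(ds, [sc.PairSpec("duplicate",
                                                  ds.sample_ids[0])],
                                 small_panel, seed=42, ledger=led)
        trait = sc.TraitModel(effects={}, sigma=1.0)
        pheno = sc.simulate_traits([out], trait, small_panel, seed=43)
        p = pheno.set_index("sample_id")
        pair = led.pairs[0]
        assert p.loc[pair["id_i"], "trait_quant"] == \
            p.loc[pair["id_j"], "trait_quant"]

    def test_determinism(self, small_panel, small_study):
        trait = sc.TraitModel(effects={small_panel.marker_ids[0]: 0.3})
        a = sc.simulate_traits([small_study], trait, small_panel, seed=9)
        b = sc.simulate_traits([small_study], trait, small_panel, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestManifests:
    def test_three_way_structure(self, small_panel):
        manifests = sc.default_manifests(small_panel, seed=1)
        sets = [m.marker_ids for m in manifests]
        three_way = set.intersection(*sets)
        for s in sets:
            assert len(three_way) < len(s) / 2
            assert s <= set(small_panel.marker_ids)

    def test_ledger_round_trip(self, tmp_path, small_panel, small_study):
        led = sc.TruthLedger()
        sc.plant_relatives(small_study,
                           [sc.PairSpec("duplicate", small_study.sample_ids[0])],
                           small_panel, seed=1, ledger=led)
        sc.plant_artifacts(small_study, [small_study.marker_ids[0]], 0.1,
                           seed=1, ledger=led)
        led.causal.append({"marker_id": "rs1", "trait": "trait_quant",
                           "effect": 0.45})
        led.write(tmp_path)
        pairs = pd.read_csv(tmp_path / "pairs.truth.tsv", sep="\t")
        assert len(pairs) == 1 and pairs["kind"].iloc[0] == "duplicate"
        causal = pd.read_csv(tmp_path / "causal.truth.tsv", sep="\t")
        assert causal["effect"].iloc[0] == 0.45
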