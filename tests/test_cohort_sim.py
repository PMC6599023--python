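"""Generator behaviour: HWE sampling, penetrance rule, ascertainment, QC truth."""

from __future__ import annotations

import numpy as np
import pytest

from quasimendel.cohort_sim import (
    AlleleSpec,
    AscertainmentInfeasibleError,
    CohortConfig,
    GenotypeMatrix,
    INDEX_VARIANT,
    PLANTED_DRIVER,
    PenetranceModel,
    assign_phenotype,
    default_loci,
    default_panel_genes,
    sample_genotypes,
    simulate_annotations,
    simulate_cohort,
)


def _rp1_trio():
    return [
        AlleleSpec("m1", "RP1", 1e-3, 1.0, "severe_null"),
        AlleleSpec("m2", "RP1", 5e-5, 1.0, "severe_null"),
        AlleleSpec("m3", "RP1", 6e-3, 0.5, "hypomorph"),
    ]


class TestAlleleSpecs:
    def test_frequency_and_weight_validation(self):
        with pytest.raises(ValueError):
            AlleleSpec("x", "G", 0.0, 0.5)
        with pytest.raises(ValueError):
            AlleleSpec("x", "G", 0.5, 1.5)
        with pytest.raises(ValueError):
            AlleleSpec("x", "G", 0.5, 0.5, "severe_null")

    def test_default_panel_shape(self):
        loci = default_loci()
        in_window = [s for s in loci if 0.001 <= s.q <= 0.05 and s.klass != "severe_null"
                     and s.gene in default_panel_genes() and s.id != INDEX_VARIANT]
        assert len(in_window) == 178
        assert len({s.gene for s in in_window}) == 84
        assert len(default_panel_genes()) == 228


class TestSampleGenotypes:
    def test_same_seed_bit_identical_different_seed_not(self):
        loci = _rp1_trio()
        a = sample_genotypes(loci, 500, seed=5)
        b = sample_genotypes(loci, 500, seed=5)
        c = sample_genotypes(loci, 500, seed=6)
        assert (a.dosages == b.dosages).all()
        assert (a.dosages != c.dosages).any()

    def test_hwe_genotype_proportions_within_4_se(self):
        n = 10_000
        g = sample_genotypes([AlleleSpec("v", "G", 0.5, 0.0, "neutral")], n, seed=3)
        col = g.dosages[:, 0]
        for dosage, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
            obs = (col == dosage).mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(obs - expected) < 4 * se

    def test_carrier_count_matches_population_screen_scale(self):
        # the published population screen: q = 0.6%, 12379 individuals,
        # about 148 alt alleles expected
        g = sample_genotypes([AlleleSpec("m3", "RP1", 0.006, 0.5, "hypomorph")],
                             12379, seed=9)
        n_alt = int(g.dosages.sum())
        expected = 2 * 12379 * 0.006
        assert abs(n_alt - expected) < 4 * np.sqrt(expected)

    def test_rare_limit_all_zero(self):
        g = sample_genotypes([AlleleSpec("v", "G", 1e-9, 0.0, "neutral")], 100, seed=1)
        assert (g.dosages == 0).all()

    def test_no_linkage_disequilibrium(self):
        loci = default_loci()[:20]
        g = sample_genotypes(loci, 50_000, seed=4)
        d = g.dosages.astype(float)
        corr = np.corrcoef(d, rowvar=False)
        off = corr[~np.eye(len(loci), dtype=bool)]
        assert np.nanmax(off**2) < 0.01


class TestAssignPhenotype:
    def test_threshold_rule_on_rp1_genotypes(self):
        loci = _rp1_trio()
        model = PenetranceModel.from_loci(loci)
        cases = {
            (2, 0, 0): True,   # m1/m1 homozygote
            (1, 1, 0): True,   # m1/m2 compound het
            (1, 0, 1): True,   # m1/m3: hypomorph in trans with a null
            (0, 0, 2): False,  # m3/m3 homozygote is benign
            (0, 0, 1): False,  # m3 heterozygote alone is benign
            (0, 0, 0): False,
        }
        g = GenotypeMatrix(np.array(list(cases.keys()), dtype=np.int8),
                           [f"i{k}" for k in range(len(cases))],
                           [s.id for s in loci])
        assert assign_phenotype(g, model).tolist() == list(cases.values())

    def test_index_het_plus_severe_modifier_is_affected(self):
        loci = _rp1_trio() + [AlleleSpec("EYS:x", "EYS", 0.017, 1.0, "modifier")]
        model = PenetranceModel.from_loci(loci)
        g = GenotypeMatrix(np.array([[0, 0, 1, 1], [0, 0, 1, 0]], dtype=np.int8),
                           ["with_mod", "alone"], [s.id for s in loci])
        assert assign_phenotype(g, model).tolist() == [True, False]

    def test_missing_weight_raises(self):
        g = GenotypeMatrix(np.zeros((1, 1), dtype=np.int8), ["i"], ["unknown"])
        with pytest.raises(KeyError):
            assign_phenotype(g, PenetranceModel(weights={"other": 1.0}))


class TestSimulateCohort:
    def test_ascertainment_predicate_by_construction(self, demo_cohort):
        cases, _, _ = demo_cohort
        assert (cases.column(INDEX_VARIANT) == 1).all()
        assert (cases.column("RP1:c.4052_4053ins328") == 0).all()
        assert (cases.column("RP1:c.4196del") == 0).all()

    def test_truth_table_consistent(self, demo_cohort):
        cases, controls, truth = demo_cohort
        assert len(truth) == cases.n_samples + controls.n_samples
        case_rows = truth[truth.cohort == "case"]
        assert case_rows.affected.all()
        assert (case_rows.load >= 1.5 - 1e-9).all()

    def test_planted_modifier_enriched_in_cases(self, demo_cohort):
        cases, controls, _ = demo_cohort
        fc = cases.column(PLANTED_DRIVER).mean() / 2
        fk = controls.column(PLANTED_DRIVER).mean() / 2
        assert fc > 3 * fk

    def test_determinism_and_seed_sensitivity(self):
        cfg = CohortConfig(n_cases=4, n_controls=50, seed=7)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        c = simulate_cohort(CohortConfig(n_cases=4, n_controls=50, seed=8))
        assert (a[0].dosages == b[0].dosages).all()
        assert (a[1].dosages == b[1].dosages).all()
        assert (a[1].dosages != c[1].dosages).any()

    def test_infeasible_when_modifiers_neutralised(self):
        loci = default_loci()
        weights = {s.id: (s.w if s.gene == "RP1" else 0.0) for s in loci}
        cfg = CohortConfig(
            n_cases=2, n_controls=10, loci=tuple(loci),
            penetrance=PenetranceModel(weights=weights), seed=0,
        )
        with pytest.raises(AscertainmentInfeasibleError):
            simulate_cohort(cfg)

    def test_population_mode_is_unselected(self):
        cfg = CohortConfig(n_cases=200, n_controls=10, seed=2,
                           ascertainment="population")
        cases, _, truth = simulate_cohort(cfg)
        # overwhelmingly unaffected individuals at population frequencies
        assert truth[truth.cohort == "case"].affected.mean() < 0.05


class TestSimulateAnnotations:
    def test_zero_fail_rates_all_pass(self, demo_cohort):
        cases, _, _ = demo_cohort
        ann = simulate_annotations(cases, {}, seed=5)
        assert (ann.dp >= 8).all() and (ann.gq >= 20).all()
        s = ann.site
        assert (s.QD >= 2).all() and (s.FS <= 60).all() and (s.MQ >= 40).all()
        assert (s.MQRankSum >= -12.5).all() and (s.ReadPosRankSum >= -8).all()
        assert (s.SOR <= 3).all() and s.vqsr_pass.all()

    def test_planted_dp_failures_recorded_exactly(self, demo_cohort):
        cases, _, _ = demo_cohort
        ann = simulate_annotations(cases, {"dp": 0.1}, seed=5)
        planted = len(ann.truth["dp"])
        n_calls = cases.n_samples * cases.n_variants
        assert planted == int((ann.dp < 8).sum())
        assert abs(planted - 0.1 * n_calls) < 4 * np.sqrt(0.1 * 0.9 * n_calls)

    def test_heterozygote_excess_site_scores_high(self):
        loci = [AlleleSpec("v", "G", 0.5, 0.0, "neutral")]
        g = GenotypeMatrix(np.ones((50, 1), dtype=np.int8),
                           [f"i{k}" for k in range(50)], ["v"])
        ann = simulate_annotations(g, {}, seed=1)
        assert float(ann.site["ExcessHet"].iloc[0]) > 20

    def test_unknown_rule_rejected(self, demo_cohort):
        cases, _, _ = demo_cohort
        with pytest.raises(ValueError):
            simulate_annotations(cases, {"bogus": 0.1}, seed=0)
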