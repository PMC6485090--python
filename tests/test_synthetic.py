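"""Cohort generator: determinism, summary statistics, observers, fixture."""

import numpy as np
import pytest

from oncotier.concordance import CallSet, sensitivity_ppv, summarize_cohort
from oncotier.synthetic import (
    CohortConfig,
    ObserverConfig,
    observe_curator,
    observe_panel,
    simulate_cohort,
    study_cohort_fixture,
    write_cohort,
)


class TestSimulateCohort:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = dict(seed=42, n_samples=4)
        d1 = write_cohort(simulate_cohort(CohortConfig(**cfg)), tmp_path / "a")
        d2 = write_cohort(simulate_cohort(CohortConfig(**cfg)), tmp_path / "b")
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_degenerate_purity_sd(self):
        b = simulate_cohort(CohortConfig(seed=1, n_samples=3, purity_sd=0.0))
        assert all(b.truth[s].purity == pytest.approx(0.71) for s in b.sample_ids)

    def test_purity_within_bounds(self, cohort):
        lo, hi = cohort.config.purity_bounds
        assert all(lo <= cohort.truth[s].purity <= hi for s in cohort.sample_ids)

    def test_burden_median_matches_at_scale(self):
        b = simulate_cohort(CohortConfig(seed=5, n_samples=200))
        counts = [
            b.truth[s].exonic_snv_count
            for s in b.sample_ids
            if not b.truth[s].hypermutant
        ]
        assert np.median(counts) == pytest.approx(157, rel=0.20)

    def test_hypermutant_fraction_and_range(self, cohort):
        hyper = [s for s in cohort.sample_ids if cohort.truth[s].hypermutant]
        lo, hi = cohort.config.hypermutant_range
        assert len(hyper) == round(cohort.config.hypermutant_fraction * 30)
        assert all(lo <= cohort.truth[s].exonic_snv_count <= hi for s in hyper)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(seed=1, hypermutant_fraction=1.5)

    def test_generated_files_pass_ingest_validators(self, cohort, tmp_path):
        from oncotier.ingest import (
            read_cnv_segments,
            read_gene_model,
            read_junctions,
            read_somatic_vcf,
        )

        out = write_cohort(cohort, tmp_path / "c")
        sample = cohort.sample_ids[0]
        variants = read_somatic_vcf(out / f"{sample}.somatic.vcf", sample_id=sample)
        assert len(variants) == len(cohort.variants[sample])
        assert read_cnv_segments(out / "segments.tsv")
        assert read_junctions(out / "junctions.tsv").rows.shape[0] > 0
        assert read_gene_model(out / "gene_model.tsv").genes == cohort.model.genes


class TestObservePanel:
    def test_no_contamination_when_rate_zero(self):
        obs = ObserverConfig(seed=3, matched_normal_used=False,
                             germline_contamination_rate=0.0)
        res = observe_panel(["EGFR", "PTEN"], ["GL1"], obs, "c1")
        assert "GL1" not in res.calls

    def test_full_space_no_dropout_equals_truth(self):
        obs = ObserverConfig(seed=3)
        res = observe_panel(["EGFR", "PTEN"], [], obs, "c1")
        assert res.calls == {"EGFR", "PTEN"}

    def test_contaminants_match_seeded_draw(self):
        germ = [f"GL{i}" for i in range(10)]
        obs = ObserverConfig(seed=9, matched_normal_used=False,
                             germline_contamination_rate=0.3)
        res = observe_panel([], germ, obs, "c1")
        # reproduce the same generator stream
        rng = np.random.default_rng(9)
        expected = [g for g in sorted(germ) if rng.random() < 0.3]
        assert res.calls == set(expected)

    def test_gene_space_masking(self):
        obs = ObserverConfig(seed=1, panel_genes=frozenset({"EGFR"}))
        res = observe_panel(["EGFR", "PTEN"], [], obs, "c1")
        assert res.calls == {"EGFR"}


class TestObserveCurator:
    def test_perfect_detection(self):
        truth = [f"g{i}" for i in range(8)]
        res = observe_curator(truth, 1.0, 0.0, ["d1"], seed=5)
        cmp = sensitivity_ppv(CallSet("case", frozenset(truth)), res)
        assert cmp.sensitivity == 1.0 and cmp.ppv == 1.0

    def test_zero_detection(self):
        truth = [f"g{i}" for i in range(8)]
        res = observe_curator(truth, 0.0, 0.0, [], seed=5)
        cmp = sensitivity_ppv(CallSet("case", frozenset(truth)), res)
        assert cmp.sensitivity == 0.0

    def test_decoy_overlap_rejected(self):
        with pytest.raises(ValueError):
            observe_curator(["a"], 0.5, 0.1, ["a"], seed=1)

    def test_recovers_detection_probability(self):
        """Mean sensitivity over 200 cases approaches the detection rate."""
        truth = [f"g{i}" for i in range(10)]
        decoys = [f"d{i}" for i in range(10)]
        rows = []
        for i in range(200):
            obs = observe_curator(truth, 0.71, 0.1, decoys, seed=20_000 + i,
                                  case_id=f"c{i}")
            rows.append(sensitivity_ppv(CallSet(f"c{i}", frozenset(truth)), obs))
        s = summarize_cohort(rows)
        se = np.sqrt(0.71 * 0.29 / (10 * 200))
        assert abs(s.mean_sensitivity - 0.71) < 3 * se


class TestStudyCohortFixture:
    def test_thirty_samples(self, fixture30):
        assert len(fixture30.findings) == 30
        assert set(fixture30.findings) == set(fixture30.drugs_raw)

    def test_gbm17_braf_and_egfr(self, fixture30):
        specs = {(f.gene, f.variant_spec) for f in fixture30.findings["GBM17"]}
        assert ("BRAF", "V600E") in specs
        assert any(g == "EGFR" for g, _ in specs)

    def test_gbm8_high_mutation_burden(self, fixture30):
        assert any(
            f.finding_type == "burden" for f in fixture30.findings["GBM8"]
        )

    def test_verbatim_misspellings_preserved(self, fixture30):
        assert "Afatnib" in fixture30.drugs_raw["GBM27"]
        assert "ABT41" in fixture30.drugs_raw["GBM9"]

    def test_trial_ids_nct_format(self, fixture30):
        import re

        for trials in fixture30.trials.values():
            assert all(re.match(r"NCT\d+$", t) for t in trials)

    def test_tier_exemplars_present(self, fixture30):
        ex = fixture30.tier_exemplars
        assert ex.count(("IDH1", "R132H")) == 2
        assert ("PIK3CA", "E542K") in ex and ("TP53", "R273C") in ex
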