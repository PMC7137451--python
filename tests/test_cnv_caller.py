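import numpy as np
import pandas as pd
import pytest

from mipscreen.cnv_caller import (
    AmplificationBaseline,
    CnvConfig,
    GeneBaseline,
    build_baseline,
    call_amplifications,
    detection_floor,
    gene_normalized_coverage,
    normalize_sample,
    relative_coverage,
    simulate_dilution_curve,
    tumor_allele_count,
    z_score,
)
from mipscreen.errors import AnalysisError, ValidationError
from mipscreen.panel_model import CoverageMatrix

from conftest import constant_column


def series(values, prefix="P"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype="float64")


class TestNormalizeSample:
    def test_divides_by_median(self):
        out = normalize_sample(series([10, 20, 30]))
        assert list(out) == [0.5, 1.0, 1.5]

    def test_constant_column_maps_to_ones(self):
        out = normalize_sample(series([7] * 9))
        assert (out == 1.0).all()

    def test_median_of_output_is_one(self):
        rng = np.random.default_rng(1)
        for n in (11, 12):  # odd and even probe counts
            out = normalize_sample(series(rng.integers(10, 500, size=n)))
            assert float(out.median()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_column_is_an_error(self):
        with pytest.raises(AnalysisError, match="median"):
            normalize_sample(series([0, 0, 0]))

    def test_median_robust_to_high_level_amplification(self):
        # the reason the median (not the mean) normalizes: a single probe at
        # 100x barely moves everyone else's normalized value
        rng = np.random.default_rng(2)
        base = rng.integers(150, 250, size=101).astype(float)
        clean = normalize_sample(series(base))
        spiked = base.copy()
        spiked[0] *= 100
        with_outlier = normalize_sample(series(spiked))
        rel_change = np.abs(with_outlier[1:] / clean[1:] - 1.0)
        assert rel_change.max() < 0.01


class TestGeneAggregation:
    def test_mean_of_probe_values(self, tiny_panel):
        norm = constant_column(tiny_panel, 1).astype(float)
        norm[[f"A{i}" for i in range(10)]] = [0.9, 1.1] * 5
        assert gene_normalized_coverage(norm, tiny_panel)["GENE_A"] == pytest.approx(1.0)

    def test_uniform_threefold_gene(self, tiny_panel):
        norm = constant_column(tiny_panel, 1).astype(float)
        norm[[f"A{i}" for i in range(10)]] = 3.0
        assert gene_normalized_coverage(norm, tiny_panel)["GENE_A"] == pytest.approx(3.0)

    def test_zero_count_probe_dropped_from_mean(self, tiny_panel):
        norm = constant_column(tiny_panel, 1).astype(float)
        norm[[f"A{i}" for i in range(10)]] = [2.0] * 9 + [0.0]
        assert gene_normalized_coverage(norm, tiny_panel)["GENE_A"] == pytest.approx(2.0)

    def test_gene_not_evaluable_when_majority_dropped(self, tiny_panel):
        norm = constant_column(tiny_panel, 1).astype(float)
        norm[[f"A{i}" for i in range(10)]] = [1.0] * 4 + [0.0] * 6
        assert gene_normalized_coverage(norm, tiny_panel)["GENE_A"] is None


class TestBaseline:
    def test_identical_controls_have_zero_sd(self, tiny_panel):
        cols = {f"N{i}": constant_column(tiny_panel, 100) for i in range(10)}
        baseline = build_baseline(CoverageMatrix.from_columns(cols), tiny_panel)
        assert baseline.n_controls == 10
        assert baseline.genes["GENE_A"].sd == 0.0

    def test_mean_and_sample_sd_by_hand(self, tiny_panel):
        # per-control gene values 0.9, 1.0, 1.1 -> mean 1.0, sample SD 0.1
        cols = {}
        for name, factor in (("N0", 0.9), ("N1", 1.0), ("N2", 1.1)):
            col = constant_column(tiny_panel, 100)
            col[[f"A{i}" for i in range(10)]] = int(100 * factor)
            cols[name] = col
        baseline = build_baseline(CoverageMatrix.from_columns(cols), tiny_panel)
        assert baseline.genes["GENE_A"].mean == pytest.approx(1.0)
        assert baseline.genes["GENE_A"].sd == pytest.approx(0.1)

    def test_failing_control_excluded(self, tiny_panel):
        cols = {f"N{i}": constant_column(tiny_panel, 100) for i in range(9)}
        cols["N9"] = constant_column(tiny_panel, 0)
        with pytest.warns(UserWarning, match="N9"):
            baseline = build_baseline(CoverageMatrix.from_columns(cols), tiny_panel)
        assert baseline.n_controls == 9
        assert "N9" not in baseline.control_ids

    def test_fewer_than_two_survivors_is_an_error(self, tiny_panel):
        cols = {"N0": constant_column(tiny_panel, 100), "N1": constant_column(tiny_panel, 0)}
        with pytest.raises(AnalysisError, match=">=2"), pytest.warns(UserWarning):
            build_baseline(CoverageMatrix.from_columns(cols), tiny_panel)

    def test_json_round_trip(self, tiny_panel, tmp_path):
        cols = {f"N{i}": constant_column(tiny_panel, 100 + i) for i in range(3)}
        baseline = build_baseline(CoverageMatrix.from_columns(cols), tiny_panel)
        path = tmp_path / "baseline.json"
        baseline.to_json(path)
        back = AmplificationBaseline.from_json(path)
        assert back == baseline


BASELINE = AmplificationBaseline(
    genes={"GENE_A": GeneBaseline(mean=1.0, sd=0.2)}, n_controls=10
)


class TestScores:
    def test_relative_coverage_identity_and_alleles(self):
        assert relative_coverage(1.0, BASELINE, "GENE_A") == pytest.approx(1.0)
        assert relative_coverage(3.0, BASELINE, "GENE_A") == pytest.approx(3.0)

    def test_z_score_by_hand(self):
        assert z_score(1.0, BASELINE, "GENE_A") == pytest.approx(0.0)
        assert z_score(5.0, BASELINE, "GENE_A") == pytest.approx(20.0)
        assert z_score(0.6, BASELINE, "GENE_A") == pytest.approx(-2.0)

    def test_z_undefined_for_degenerate_controls(self):
        degenerate = AmplificationBaseline(genes={"G": GeneBaseline(1.0, 0.0)}, n_controls=5)
        assert z_score(4.0, degenerate, "G") is None

    def test_zero_baseline_mean_not_evaluable(self):
        broken = AmplificationBaseline(genes={"G": GeneBaseline(0.0, 0.1)}, n_controls=5)
        with pytest.raises(AnalysisError, match="not evaluable"):
            relative_coverage(2.0, broken, "G")


class TestPurityCorrection:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.9, 1.0])
    def test_diploid_identity_for_any_purity(self, p):
        assert tumor_allele_count(1.0, p) == pytest.approx(2.0)

    @pytest.mark.parametrize("rc", [0.5, 1.0, 2.7, 8.0])
    def test_pure_tumor_identity(self, rc):
        assert tumor_allele_count(rc, 1.0) == pytest.approx(2.0 * rc)

    def test_half_purity_example(self):
        assert tumor_allele_count(3.0, 0.5) == pytest.approx(10.0)

    def test_zero_or_unknown_purity_is_an_error(self):
        with pytest.raises(AnalysisError, match="purity"):
            tumor_allele_count(3.0, 0.0)
        with pytest.raises(AnalysisError, match="purity"):
            tumor_allele_count(3.0, None)

    @pytest.mark.parametrize("p,expected", [(1.0, 6.0), (0.5, 10.0), (0.2, 22.0)])
    def test_detection_floor(self, p, expected):
        assert detection_floor(p) == pytest.approx(expected)


class TestDilutionCurve:
    def test_mixing_formula(self):
        assert simulate_dilution_curve(3.0, [1]) == [pytest.approx(3.0)]
        assert simulate_dilution_curve(9.0, [4]) == [pytest.approx(3.0)]
        assert simulate_dilution_curve(3.0, [2]) == [pytest.approx(2.0)]

    def test_dilution_below_one_rejected(self):
        with pytest.raises(ValidationError):
            simulate_dilution_curve(3.0, [0.5])


def _column_with_gene_rc(panel, rc, depth=100):
    col = constant_column(panel, depth)
    col[[f"A{i}" for i in range(10)]] = int(depth * rc)
    return col


class TestCalling:
    @pytest.fixture
    def baseline(self, tiny_panel):
        cols = {f"N{i}": constant_column(tiny_panel, 100 + 2 * i) for i in range(4)}
        return build_baseline(CoverageMatrix.from_columns(cols), tiny_panel)

    @pytest.mark.parametrize(
        "rc,expected",
        [(3.2, "amplified"), (3.0, "amplified"), (2.99, "potentially_amplified"),
         (2.5, "potentially_amplified"), (2.0, "potentially_amplified"),
         (1.99, "not_amplified"), (1.0, "not_amplified")],
    )
    def test_status_bands(self, tiny_panel, baseline, rc, expected):
        col = constant_column(tiny_panel, 100)
        col[[f"A{i}" for i in range(10)]] = int(100 * rc)
        (result,) = [r for r in call_amplifications(col, tiny_panel, baseline) if r.gene == "GENE_A"]
        assert result.status == expected

    def test_qc_floor_is_strictly_greater_than_25(self, tiny_panel, baseline):
        at_floor = _column_with_gene_rc(tiny_panel, 5.0, depth=25)
        results = call_amplifications(at_floor, tiny_panel, baseline)
        assert all(r.status == "qc_fail" for r in results)
        above = _column_with_gene_rc(tiny_panel, 5.0, depth=26)
        (result,) = [r for r in call_amplifications(above, tiny_panel, baseline) if r.gene == "GENE_A"]
        assert result.status == "amplified"

    def test_amplified_requires_every_replicate(self, tiny_panel, baseline):
        strong = _column_with_gene_rc(tiny_panel, 4.0)
        weak = _column_with_gene_rc(tiny_panel, 2.5)
        (result,) = [
            r for r in call_amplifications(strong, tiny_panel, baseline, replicates=[weak])
            if r.gene == "GENE_A"
        ]
        assert result.status == "potentially_amplified"
        assert result.relative_coverage == pytest.approx(3.25, rel=0.02)

    def test_monotone_in_relative_coverage(self, tiny_panel, baseline):
        rank = {"not_amplified": 0, "potentially_amplified": 1, "amplified": 2}
        statuses = []
        for rc in np.linspace(0.5, 5.0, 19):
            col = constant_column(tiny_panel, 200)
            col[[f"A{i}" for i in range(10)]] = int(200 * rc)
            (r,) = [x for x in call_amplifications(col, tiny_panel, baseline) if x.gene == "GENE_A"]
            statuses.append(rank[r.status])
        assert statuses == sorted(statuses)

    def test_purity_annotations_present(self, tiny_panel, baseline):
        col = _column_with_gene_rc(tiny_panel, 3.0)
        (r,) = [x for x in call_amplifications(
            col, tiny_panel, baseline, neoplastic_fraction=0.5) if x.gene == "GENE_A"]
        assert r.tumor_allele_count == pytest.approx(10.0, rel=0.02)
        assert r.detection_floor == pytest.approx(10.0)
        assert r.alleles_per_genome_equivalent == pytest.approx(2 * r.relative_coverage)


class TestAgainstGeneratorTruth:
    def test_control_scores_near_one_against_own_baseline(self):
        from mipscreen.synthetic_data import SimulationSpec, gen_cohort

        cohort = gen_cohort(10, 0, 0, template=SimulationSpec(seed=77))
        baseline = build_baseline(cohort.coverage, cohort.design)
        for sid in cohort.coverage.sample_ids:
            results = call_amplifications(cohort.coverage.column(sid), cohort.design, baseline)
            for r in results:
                ref = baseline.genes[r.gene]
                band = 3.0 * ref.sd / ref.mean
                assert abs(r.relative_coverage - 1.0) <= max(band, 1e-9)

    def test_read_level_mixture_linearity(self, small_sim_panel):
        # brute-force oracle: molecule-level in-silico mixing of an amplified
        # and a normal sample must land on f*RC + (1-f)*1
        from dataclasses import replace

        from mipscreen.synthetic_data import SimulationSpec, gen_cohort, gen_normal_sample, gen_tumor_sample
        from mipscreen.umi_consensus import collapse, unique_coverage

        template = SimulationSpec(seed=909, panel=small_sim_panel, mean_depth=150.0,
                                  pcr_duplicate_rate=0.0, base_error_rate=0.0)
        cohort = gen_cohort(6, 0, 0, template=template)
        baseline = build_baseline(cohort.coverage, cohort.design)

        tumor_spec = replace(template, seed=5001, amplified_genes={"EGFR": 12.0},
                             neoplastic_fraction=1.0)
        tumor_reads, _ = gen_tumor_sample(tumor_spec, "T")
        normal_reads, _ = gen_normal_sample(replace(template, seed=5002), "N")

        def rc_of(reads):
            counts = unique_coverage(collapse(reads), small_sim_panel)
            norm = normalize_sample(counts.astype(float))
            value = gene_normalized_coverage(norm, small_sim_panel)["EGFR"]
            return relative_coverage(value, baseline, "EGFR")

        rc_tumor = rc_of(tumor_reads)
        rng = np.random.default_rng(17)
        f = 0.5
        mixture = [r for r in tumor_reads if rng.random() < f]
        mixture += [r for r in normal_reads if rng.random() < 1 - f]
        expected = f * rc_tumor + (1 - f) * 1.0
        assert rc_of(mixture) == pytest.approx(expected, rel=0.10)
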