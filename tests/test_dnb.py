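import numpy as np
import pandas as pd
import pytest

from dnbkit.data import ExpressionMatrix, GeneSet, SampleMetadata
from dnbkit.dnb import (
    average_correlation_strength,
    average_sd,
    correction_term,
    correction_term_mc,
    score_timecourse,
    suppression_summary,
)
from dnbkit.synthetic import SynthConfig, generate_dataset


def _cell(values, genes, week=5, group="control"):
    values = np.asarray(values, dtype=float)
    samples = [f"{group}_{week}_{j}" for j in range(values.shape[1])]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        scale="log2",
    )
    meta = SampleMetadata(pd.DataFrame(
        [(s, group, week) for s in samples], columns=["sample_id", "group", "week"]
    ))
    return matrix, meta


class TestCorrectionTerm:
    @pytest.mark.parametrize(
        "n, exact, printed",
        [(3, 2 / np.pi, 0.64), (4, 0.5, 0.50), (5, 4 / (3 * np.pi), 0.42)],
    )
    def test_printed_values(self, n, exact, printed):
        c = correction_term(n)
        assert c == pytest.approx(exact, rel=1e-12)
        assert round(c, 2) == printed

    def test_strictly_decreasing_to_zero(self):
        values = [correction_term(n) for n in range(3, 60)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert correction_term(2000) < 0.02

    def test_monte_carlo_cross_check(self):
        for n in (3, 4, 5, 8):
            estimate, se = correction_term_mc(n, n_replicates=200_000, seed=n)
            assert abs(estimate - correction_term(n)) < 3 * se

    @pytest.mark.parametrize("n", [2, 1, 0, 2.5])
    def test_small_n_rejected(self, n):
        with pytest.raises(ValueError):
            correction_term(n)


class TestAverageSd:
    def test_hand_worked(self):
        matrix, meta = _cell([[0, 2], [1, 1]], ["g1", "g2"])
        i_s, sds = average_sd(matrix, GeneSet(["g1", "g2"]), "control", 5, meta)
        assert i_s == pytest.approx(np.sqrt(2) / 2)
        assert sds["g1"] == pytest.approx(np.sqrt(2))
        assert sds["g2"] == 0.0

    def test_constant_genes_give_zero(self):
        matrix, meta = _cell([[3, 3, 3], [7, 7, 7]], ["g1", "g2"])
        i_s, _ = average_sd(matrix, GeneSet(["g1", "g2"]), "control", 5, meta)
        assert i_s == 0.0

    def test_homogeneity(self, rng):
        values = rng.normal(size=(5, 4))
        genes = [f"g{i}" for i in range(5)]
        m1, meta = _cell(values, genes)
        m3, _ = _cell(values * 3.0, genes)
        gs = GeneSet(genes)
        assert average_sd(m3, gs, "control", 5, meta)[0] == pytest.approx(
            3.0 * average_sd(m1, gs, "control", 5, meta)[0]
        )

    def test_missing_genes_excluded(self, rng):
        matrix, meta = _cell(rng.normal(size=(2, 3)), ["g1", "g2"])
        i_s, sds = average_sd(matrix, GeneSet(["g1", "g2", "ghost"]), "control", 5, meta)
        assert list(sds.index) == ["g1", "g2"]

    def test_no_gene_present_raises(self, rng):
        matrix, meta = _cell(rng.normal(size=(2, 3)), ["g1", "g2"])
        with pytest.raises(ValueError, match="no gene"):
            average_sd(matrix, GeneSet(["nope"]), "control", 5, meta)


class TestAverageCorrelationStrength:
    def test_perfect_correlation_n4(self):
        matrix, meta = _cell([[1, 2, 3, 4], [2, 4, 6, 8]], ["g1", "g2"])
        i_r = average_correlation_strength(matrix, GeneSet(["g1", "g2"]), "control", 5, meta)
        assert i_r == pytest.approx(1.0 - 0.5)

    def test_anticorrelation_same_strength(self):
        matrix, meta = _cell([[1, 2, 3, 4], [-1, -2, -3, -4]], ["g1", "g2"])
        i_r = average_correlation_strength(matrix, GeneSet(["g1", "g2"]), "control", 5, meta)
        assert i_r == pytest.approx(0.5)

    def test_independent_genes_near_zero(self):
        # average of |r| - c(5) over many replicates cancels by construction
        rng = np.random.default_rng(0)
        values = []
        for seed in range(300):
            matrix, meta = _cell(rng.normal(size=(50, 5)), [f"g{i}" for i in range(50)])
            values.append(average_correlation_strength(
                matrix, GeneSet([f"g{i}" for i in range(50)]), "control", 5, meta))
        mean = np.mean(values)
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(mean) < 3 * se

    def test_constant_gene_dropped_with_warning(self, caplog):
        matrix, meta = _cell([[1, 2, 3], [5, 5, 5], [2, 4, 6]], ["g1", "g2", "g3"])
        with caplog.at_level("WARNING", logger="dnbkit.dnb"):
            i_r = average_correlation_strength(
                matrix, GeneSet(["g1", "g2", "g3"]), "control", 5, meta)
        assert "CONSTANT_GENES" in caplog.text
        assert i_r == pytest.approx(1.0 - correction_term(3))

    def test_needs_three_samples(self):
        matrix, meta = _cell([[1, 2], [2, 1]], ["g1", "g2"])
        with pytest.raises(ValueError, match="need >= 3"):
            average_correlation_strength(matrix, GeneSet(["g1", "g2"]), "control", 5, meta)


class TestScoreTimecourse:
    def test_spike_recovery(self, default_dataset):
        scores = score_timecourse(
            default_dataset.expression, default_dataset.metadata, default_dataset.dnb_genes
        )
        control = scores.table[scores.table["group"] == "control"].set_index("week")
        assert control["I_s"].idxmax() == 5
        assert control["I_r"].idxmax() == 5
        treated_ir = scores.cell("treated", 5)["I_r"]
        assert treated_ir < 0.3 * control.loc[5, "I_r"]

    def test_null_has_no_peak(self, null_dataset):
        scores = score_timecourse(
            null_dataset.expression, null_dataset.metadata, null_dataset.dnb_genes
        )
        control = scores.table[scores.table["group"] == "control"]
        assert (control["I_r"].abs() < 0.2).all()

    def test_sample_permutation_invariance(self, null_dataset):
        base = score_timecourse(
            null_dataset.expression, null_dataset.metadata, null_dataset.dnb_genes
        )
        rng = np.random.default_rng(3)
        perm = rng.permutation(null_dataset.expression.n_samples)
        shuffled = ExpressionMatrix(
            null_dataset.expression.data.iloc[:, perm], scale="log2"
        )
        out = score_timecourse(shuffled, null_dataset.metadata, null_dataset.dnb_genes)
        pd.testing.assert_frame_equal(out.table, base.table)

    def test_power_increases_with_loading(self):
        means = []
        for loading in (0.0, 0.5, 1.0, 2.0):
            values = []
            for seed in range(5):
                ds = generate_dataset(SynthConfig(
                    n_genes=200, n_dnb=60, n_deg=0, dnb_loading=loading, seed=seed,
                ))
                scores = score_timecourse(ds.expression, ds.metadata, ds.dnb_genes)
                values.append(scores.cell("control", 5)["I_r"])
            means.append(np.mean(values))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_reports_missing_cells(self):
        config = SynthConfig(
            n_genes=40, n_dnb=10, n_deg=0, weeks=(4, 5), spike_week=5,
            deg_onset_week=5,
            samples_per_cell={("control", 4): 2, ("control", 5): 4, ("treated", 5): 1},
            seed=0,
        )
        ds = generate_dataset(config)
        scores = score_timecourse(ds.expression, ds.metadata, ds.dnb_genes)
        reasons = {(g, w): reason for g, w, reason in scores.missing_cells}
        assert ("treated", 5) in reasons  # 1 sample: skipped
        assert ("control", 4) in reasons  # n=2: I_s only
        assert np.isnan(scores.cell("control", 4)["I_r"])


class TestSuppressionSummary:
    def _scores(self, sds_by_group, ir=None):
        rows, sd_rows = [], []
        ir = ir or {"control": 0.5, "treated": 0.05}
        for group, sds in sds_by_group.items():
            rows.append((group, 5, 5, len(sds), 0.42, float(np.mean(list(sds.values()))),
                         ir[group]))
            for gene, sd in sds.items():
                sd_rows.append((gene, group, 5, sd))
        from dnbkit.dnb import DNBScoreSeries
        return DNBScoreSeries(
            table=pd.DataFrame(rows, columns=["group", "week", "n_samples", "n_genes",
                                              "c", "I_s", "I_r"]),
            per_gene_sd=pd.DataFrame(sd_rows, columns=["gene", "group", "week", "sd"]),
        )

    def test_identity_case(self):
        sds = {"g1": 1.0, "g2": 2.0}
        scores = self._scores({"control": sds, "treated": sds},
                              ir={"control": 0.5, "treated": 0.5})
        out = suppression_summary(scores, scores, 5)
        assert out.n_decreased == 0 and out.n_halved == 0
        assert out.is_ratio_pct == pytest.approx(100.0)
        assert out.ir_ratio_pct == pytest.approx(100.0)

    def test_halved_minus_epsilon(self):
        control = {"g1": 1.0, "g2": 2.0}
        treated = {g: 0.5 * v - 1e-9 for g, v in control.items()}
        scores = self._scores({"control": control, "treated": treated})
        out = suppression_summary(scores, scores, 5)
        assert out.n_decreased == 2 and out.n_halved == 2
        assert out.is_ratio_pct < 50.0

    def test_mismatched_gene_sets_rejected(self):
        scores = self._scores({"control": {"g1": 1.0, "g2": 1.0},
                               "treated": {"g1": 0.5, "g3": 0.5}})
        with pytest.raises(ValueError, match="g2"):
            suppression_summary(scores, scores, 5)

    def test_planted_suppression_recovered(self, default_dataset):
        scores = score_timecourse(
            default_dataset.expression, default_dataset.metadata, default_dataset.dnb_genes
        )
        out = suppression_summary(scores, scores, 5)
        assert out.n_genes == 147
        assert out.n_decreased > 0.8 * out.n_genes
        assert out.n_halved <= out.n_decreased
        assert out.ir_ratio_pct < 30.0
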