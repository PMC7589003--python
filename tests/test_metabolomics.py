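import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from ntcmetab import (
    MetaboliteTable,
    PipelineError,
    differential_abundance,
    generate_metabolite_dataset,
    pathway_metabolite_summary,
    qc_drift_normalize,
    rank_top_changed,
)


def build_table(values, groups, orders=None, pathways=None):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    metabolites = [f"m{i}" for i in range(values.shape[0])]
    meta_s = pd.DataFrame(
        {"group": groups, "injection_order": orders or list(range(1, values.shape[1] + 1))},
        index=pd.Index(samples, name="sample"),
    )
    meta_m = pd.DataFrame(
        {"pathway": pathways or ["other"] * values.shape[0]},
        index=pd.Index(metabolites, name="metabolite"),
    )
    return MetaboliteTable(pd.DataFrame(values, index=meta_m.index, columns=samples), meta_s, meta_m)


class TestDriftNormalize:
    def test_constant_qc_is_identity(self):
        table = build_table(
            [[10, 5, 7, 10, 9, 10]], ["QC", "WT", "KO", "QC", "WT", "QC"]
        )
        out = qc_drift_normalize(table)
        np.testing.assert_allclose(out.abundance.values, table.abundance.values, rtol=1e-12)

    def test_noiseless_linear_drift_removed(self):
        """QC values rising 100 -> 200 across the run: after normalization
        the QC coefficient of variation vanishes and the sample trend with
        injection order is gone."""
        table, _ = generate_metabolite_dataset(
            {f"m{i}": 1.0 for i in range(5)}, cv=0.0, qc_cv=0.0, drift_slope=0.08, n_per_group=6, seed=0
        )
        out = qc_drift_normalize(table)
        qc = out.abundance[out.qc_samples()]
        cv = (qc.std(axis=1, ddof=0) / qc.mean(axis=1)).max()
        assert cv < 1e-9
        study = out.abundance[out.study_samples()]
        orders = out.samples.loc[out.study_samples(), "injection_order"].to_numpy(float)
        for _, row in study.iterrows():
            slope = np.polyfit(orders, row.to_numpy(float), 1)[0]
            assert abs(slope) / row.mean() < 1e-9

    def test_sample_at_qc_position_divided_by_that_qc(self):
        # interpolation at a QC's own injection order returns that QC value
        table = build_table([[50, 80, 100]], ["QC", "WT", "QC"], orders=[1, 3, 3 + 1])
        out = qc_drift_normalize(table)
        # sample at order 3: interpolated QC = 50 + (100-50)*(2/3)... endpoint check via QC itself
        np.testing.assert_allclose(
            out.abundance[out.qc_samples()].to_numpy(float), np.median([50, 100]), rtol=1e-12
        )

    def test_zero_qc_metabolite_flagged_unchanged(self):
        table = build_table([[0, 5, 0], [10, 5, 10]], ["QC", "WT", "QC"])
        out = qc_drift_normalize(table)
        assert out.drift_flagged == ("m0",)
        np.testing.assert_array_equal(out.abundance.loc["m0"], table.abundance.loc["m0"])

    def test_idempotent_up_to_rescale(self):
        table, _ = generate_metabolite_dataset(cv=0.2, qc_cv=0.05, drift_slope=0.03, seed=8)
        once = qc_drift_normalize(table)
        twice = qc_drift_normalize(once)
        rel = np.abs(twice.abundance.values / once.abundance.values - 1)
        assert rel.max() < 1e-9

    def test_requires_two_qc_samples(self):
        table = build_table([[1, 2, 3]], ["QC", "WT", "KO"])
        with pytest.raises(PipelineError):
            qc_drift_normalize(table)


class TestDifferentialAbundance:
    def test_identical_groups_null(self):
        table = build_table([[3, 4, 5, 3, 4, 5]], ["WT"] * 3 + ["KO"] * 3)
        out = differential_abundance(table)
        assert out.loc[0, "fold_change"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert not out.loc[0, "significant"]

    def test_zero_variance_equal_means(self):
        table = build_table([[2, 2, 2, 2]], ["WT", "WT", "KO", "KO"])
        out = differential_abundance(table)
        assert out.loc[0, "p_value"] == 1.0

    def test_label_symmetry(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(3, 0.3, (6, 8))
        fwd = differential_abundance(build_table(values, ["WT"] * 4 + ["KO"] * 4))
        rev = differential_abundance(build_table(values, ["KO"] * 4 + ["WT"] * 4))
        np.testing.assert_allclose(fwd["fold_change"], 1 / rev["fold_change"], rtol=1e-12)
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-12)

    def test_injected_effect_recovered_across_seeds(self):
        """A metabolite injected at 1.9x with 10% CV and n=5/group is
        estimated within +-15% and flagged significant in >= 9/10 seeds."""
        hits, good_fc = 0, 0
        for seed in range(10):
            table, _ = generate_metabolite_dataset(
                {"target": 1.9, **{f"null{i}": 1.0 for i in range(9)}},
                n_per_group=5, cv=0.10, seed=seed,
            )
            out = differential_abundance(qc_drift_normalize(table)).set_index("metabolite")
            row = out.loc["target"]
            hits += bool(row["significant"])
            good_fc += abs(row["fold_change"] / 1.9 - 1) <= 0.15
        assert hits >= 9
        assert good_fc >= 9

    def test_type_one_error_tracks_alpha(self):
        """Null simulation: the flagged fraction tracks alpha across
        0.01 / 0.05 / 0.10 within exact binomial 95% bands."""
        n = 600
        table, _ = generate_metabolite_dataset(
            {f"M{i}": 1.0 for i in range(n)}, n_per_group=4, cv=0.2, seed=1
        )
        out = differential_abundance(table)
        for alpha in (0.01, 0.05, 0.10):
            hits = int((out["p_value"] < alpha).sum())
            lo, hi = binom.interval(0.95, n, alpha)
            assert lo <= hits <= hi, f"alpha={alpha}: {hits} outside [{lo}, {hi}]"

    def test_needs_two_per_group(self):
        table = build_table([[1, 2, 3]], ["WT", "KO", "KO"])
        with pytest.raises(PipelineError):
            differential_abundance(table)


class TestPathwaySummary:
    def test_sum_ratio_vs_mean_of_fcs(self):
        # WT means {1, 3}, KO means {2, 3}: sum-based 5/4, mean-of-FC 1.5
        values = np.array([[1, 1, 2, 2], [3, 3, 3, 3]], dtype=float)
        table = build_table(values, ["WT", "WT", "KO", "KO"], pathways=["glycolysis"] * 2)
        results = differential_abundance(table)
        summary = pathway_metabolite_summary(results, table).set_index("pathway")
        assert summary.loc["glycolysis", "cumulative_fold_change"] == pytest.approx(1.25)
        assert summary.loc["glycolysis", "mean_fold_change"] == pytest.approx(1.5)

    def test_all_unity_fold_changes(self):
        values = np.tile([[2.0, 2.0, 2.0, 2.0]], (3, 1))
        table = build_table(values, ["WT", "WT", "KO", "KO"], pathways=["p"] * 3)
        results = differential_abundance(table)
        summary = pathway_metabolite_summary(results, table)
        assert summary["cumulative_fold_change"].iloc[0] == pytest.approx(1.0)
        assert summary["mean_fold_change"].iloc[0] == pytest.approx(1.0)

    def test_three_of_ten_fraction(self):
        """Constructed fixture: glycolysis fold changes {1.9, 1.6, 1.5, 1 x 7}
        at n=5 and 10% CV flag exactly the three injected metabolites."""
        fcs = {f"gly{i:02d}": fc for i, fc in enumerate([1.9, 1.6, 1.5] + [1.0] * 7)}
        table, _ = generate_metabolite_dataset(
            fcs, {m: "glycolysis" for m in fcs}, n_per_group=5, cv=0.10, seed=0
        )
        results = differential_abundance(qc_drift_normalize(table))
        summary = pathway_metabolite_summary(results, table).set_index("pathway")
        assert summary.loc["glycolysis", "n_metabolites"] == 10
        assert summary.loc["glycolysis", "n_significant"] == 3
        assert summary.loc["glycolysis", "frac_significant"] == pytest.approx(0.30)


class TestRanking:
    def test_top_injected_metabolite_ranks_first(self):
        table, _ = generate_metabolite_dataset(n_per_group=6, cv=0.08, seed=2)
        results = differential_abundance(qc_drift_normalize(table))
        up, down = rank_top_changed(results, 5)
        assert up["metabolite"].iloc[0] == "docosapentaenoic acid"  # injected 2.2x

    def test_no_significant_gives_empty(self):
        table = build_table([[3, 4, 5, 3, 4, 5]], ["WT"] * 3 + ["KO"] * 3)
        up, down = rank_top_changed(differential_abundance(table), 5)
        assert up.empty and down.empty

    def test_n_top_larger_than_list(self):
        rng = np.random.default_rng(0)
        values = np.vstack([rng.lognormal(3, 0.05, 8) * np.r_[1, 1, 1, 1, 3, 3, 3, 3]])
        table = build_table(values, ["WT"] * 4 + ["KO"] * 4)
        up, _ = rank_top_changed(differential_abundance(table), 100)
        assert len(up) == 1
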