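import numpy as np
import pandas as pd
import pytest

from texturenet import (
    CohortDesign,
    ConnectivityMatrix,
    FunctionalNetworkSpec,
    NodeMetricTable,
    ancova_age,
    ancova_factor,
    edge_comparison,
    region_deviation,
    simulate_metric_cohort,
)
from texturenet.network import METRIC_NAMES
from texturenet.studies import read_network_specs


def design_frame(n, rng, balanced_ages=True):
    sex = np.where(np.arange(n) % 2 == 0, "F", "M")
    age = rng.uniform(20, 80, size=n)
    return CohortDesign(
        pd.DataFrame(
            {
                "subject": [f"sub-{i:04d}" for i in range(n)],
                "sex": sex,
                "age": age,
                "brain_volume": rng.normal(1200, 50, size=n),
                "intracranial_volume": rng.normal(1500, 60, size=n),
            }
        )
    )


def metric_stack(values, design):
    """values: (n_subjects, n_regions) array applied to every measure."""
    out = []
    for i, subj in enumerate(design.table["subject"]):
        df = pd.DataFrame({"label_id": np.arange(1, values.shape[1] + 1)})
        for m in METRIC_NAMES:
            df[m] = values[i]
        out.append(NodeMetricTable(table=df, subject_id=subj))
    return out


class TestEdgeComparison:
    def _matrices(self, w_stack, labels):
        return [
            ConnectivityMatrix(w=w, region_labels=labels, subject_id=f"sub-{i:04d}")
            for i, w in enumerate(w_stack)
        ]

    def test_possible_connections_formula(self):
        assert FunctionalNetworkSpec("a", list(range(12))).possible_connections == 66
        assert FunctionalNetworkSpec("b", list(range(18))).possible_connections == 153

    def test_identical_connections_no_exceedance(self):
        w = 0.5 * (1 - np.eye(5))
        mats = self._matrices([w, w, w], [1, 2, 3, 4, 5])
        res = edge_comparison(mats, FunctionalNetworkSpec("x", [1, 2, 3]))
        assert res.n_greater_than_mean == 0
        assert res.n_greater_1sd == 0
        assert res.possible_connections == 3

    def test_planted_module_exceeds_random_set(self, rng):
        n = 8
        labels = list(range(1, n + 1))
        mats = []
        for i in range(20):
            w = rng.uniform(0.1, 0.5, size=(n, n))
            w = (w + w.T) / 2
            w[np.ix_([0, 1, 2], [0, 1, 2])] = rng.uniform(0.8, 1.0)  # module {1,2,3}
            np.fill_diagonal(w, 0)
            mats.append(ConnectivityMatrix(w=w, region_labels=labels, subject_id=f"s{i}"))
        module = edge_comparison(mats, FunctionalNetworkSpec("mod", [1, 2, 3]))
        other = edge_comparison(mats, FunctionalNetworkSpec("rand", [4, 6, 8]))
        assert module.pct_greater > other.pct_greater

    def test_counts_ordering_invariant(self, rng):
        n = 6
        labels = list(range(1, n + 1))
        stack = []
        for _ in range(10):
            w = rng.random((n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            stack.append(w / w.max())
        spec = FunctionalNetworkSpec("x", [1, 3, 5])
        mats = self._matrices(stack, labels)
        res1 = edge_comparison(mats, spec)
        res2 = edge_comparison(mats[::-1], spec)
        # subject order irrelevant; common affine rescale of all matrices too
        res3 = edge_comparison(self._matrices([0.5 * w for w in stack], labels), spec)
        for r in (res2, res3):
            assert r.n_greater_than_mean == res1.n_greater_than_mean
            assert r.n_greater_1sd == res1.n_greater_1sd

    def test_missing_spec_region_rejected(self):
        w = 0.5 * (1 - np.eye(4))
        mats = self._matrices([w, w], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="missing"):
            edge_comparison(mats, FunctionalNetworkSpec("x", [1, 99]))

    def test_sd_modes_share_mean(self, rng):
        n = 5
        labels = list(range(1, n + 1))
        stack = []
        for _ in range(8):
            w = rng.random((n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            stack.append(w / w.max())
        mats = self._matrices(stack, labels)
        spec = FunctionalNetworkSpec("x", [1, 2, 3])
        a = edge_comparison(mats, spec, sd_mode="edge_means")
        b = edge_comparison(mats, spec, sd_mode="pooled")
        assert a.grand_mean == b.grand_mean
        assert a.grand_sd <= b.grand_sd_pooled

    def test_network_spec_tsv(self, tmp_path):
        path = tmp_path / "networks.tsv"
        pd.DataFrame(
            {"network_name": ["dmn", "dmn", "vis", "vis"], "label_id": [1, 2, 3, 4]}
        ).to_csv(path, sep="\t", index=False)
        specs = read_network_specs(path)
        assert [s.name for s in specs] == ["dmn", "vis"]
        assert specs[0].labels == [1, 2]
        # a 1-region network is invalid
        pd.DataFrame({"network_name": ["solo"], "label_id": [9]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="at least 2"):
            read_network_specs(path)


class TestAncova:
    def test_perfect_linear_age_fit(self, rng):
        design = design_frame(40, rng)
        vals = np.tile(design.table["age"].to_numpy()[:, None], (1, 3))
        res = ancova_age(metric_stack(vals, design), design)
        assert (res.table["r_squared"] > 0.999999).all()
        assert (res.table["p_value"] < 1e-12).all()
        assert (res.table["direction"] == 1).all()

    def test_confounded_null_not_significant(self, rng):
        # metric depends only on age; sexes get different age distributions
        n = 120
        sex = np.array(["F"] * (n // 2) + ["M"] * (n // 2))
        age = np.concatenate([rng.uniform(20, 45, n // 2), rng.uniform(45, 70, n // 2)])
        design = CohortDesign(
            pd.DataFrame(
                {
                    "subject": [f"sub-{i:04d}" for i in range(n)],
                    "sex": sex,
                    "age": age,
                    "brain_volume": rng.normal(1200, 50, size=n),
                    "intracranial_volume": rng.normal(1500, 60, size=n),
                }
            )
        )
        vals = 0.05 * age[:, None] + rng.normal(0, 0.05, size=(n, 3))
        res = ancova_factor(metric_stack(vals, design), design)
        # unadjusted group means differ hugely, but the adjusted factor is null
        assert (res.table["p_value"] > 0.01).mean() > 0.9

    def test_sex_swap_flips_direction_preserves_p(self, rng):
        metrics, design = simulate_metric_cohort(
            60, 3, seed=11, sex_effect_sd={(2, "ST"): 0.8}
        )
        res = ancova_factor(metrics, design)
        swapped = CohortDesign(
            design.table.assign(sex=design.table["sex"].map({"M": "F", "F": "M"}))
        )
        res_sw = ancova_factor(metrics, swapped)
        merged = res.table.merge(res_sw.table, on=["label_id", "measure"])
        np.testing.assert_allclose(merged["p_value_x"], merged["p_value_y"], atol=1e-10)
        nontrivial = merged["p_value_x"] < 1.0
        assert (
            merged.loc[nontrivial, "direction_x"]
            == -merged.loc[nontrivial, "direction_y"]
        ).all()

    def test_bonferroni_dominates_and_caps(self, rng):
        metrics, design = simulate_metric_cohort(40, 4, seed=5)
        res = ancova_factor(metrics, design)
        assert (res.table["p_bonferroni"] >= res.table["p_value"] - 1e-15).all()
        assert (res.table["p_bonferroni"] <= 1.0).all()
        big = res.table["p_value"] > 0.5
        assert (res.table.loc[big, "p_bonferroni"] == 1.0).all()

    def test_subject_mismatch_rejected(self, rng):
        metrics, design = simulate_metric_cohort(20, 2, seed=3)
        with pytest.raises(ValueError, match="differ"):
            ancova_factor(metrics[:-1], design)

    def test_single_level_factor_rejected(self, rng):
        metrics, design = simulate_metric_cohort(20, 2, seed=3)
        mono = CohortDesign(design.table.assign(sex="F"))
        with pytest.raises(ValueError, match="2 levels"):
            ancova_factor(metrics, mono)


class TestRegionDeviation:
    def test_identical_regions_near_zero(self, rng):
        design = design_frame(30, rng)
        vals = rng.normal(1.0, 0.2, size=(30, 6))
        res = region_deviation(metric_stack(vals, design))
        assert np.abs(res.table["deviation"]).max() < 1.0
        assert not res.table["flagged"].any()

    def test_constructed_two_sd_shift(self, rng):
        # enough regions that shifting one barely moves the global baseline
        n, r = 200, 50
        design = design_frame(n, rng)
        vals = rng.normal(0.0, 1.0, size=(n, r))
        pooled_sd = vals.std()
        vals[:, 0] += 2.0 * pooled_sd
        res = region_deviation(metric_stack(vals, design))
        st = res.table[res.table["measure"] == "ST"].set_index("label_id")
        assert st.loc[1, "deviation"] == pytest.approx(2.0, abs=0.35)
        assert bool(st.loc[1, "flagged"])
        assert not st.loc[2:, "flagged"].any()

    def test_deviations_center_on_zero(self, rng):
        design = design_frame(40, rng)
        vals = rng.normal(1.0, 0.5, size=(40, 5))
        res = region_deviation(metric_stack(vals, design))
        for m in METRIC_NAMES:
            devs = res.table.loc[res.table["measure"] == m, "deviation"]
            assert devs.mean() == pytest.approx(0.0, abs=1e-10)

    def test_shift_invariance(self, rng):
        design = design_frame(30, rng)
        vals = rng.normal(0.0, 1.0, size=(30, 5))
        res1 = region_deviation(metric_stack(vals, design))
        res2 = region_deviation(metric_stack(vals + 7.0, design))
        np.testing.assert_allclose(
            res1.table["deviation"], res2.table["deviation"], atol=1e-9
        )
        assert (res1.table["flagged"] == res2.table["flagged"]).all()

    def test_zero_sd_rejected(self, rng):
        design = design_frame(10, rng)
        vals = np.ones((10, 4))
        with pytest.raises(ValueError, match="zero global SD"):
            region_deviation(metric_stack(vals, design))


class TestCohortDesign:
    def test_missing_column_named(self, rng):
        df = pd.DataFrame({"subject": ["a"], "sex": ["F"], "age": [30]})
        with pytest.raises(ValueError, match="brain_volume"):
            CohortDesign(df)

    def test_invalid_values_rejected(self, rng):
        base = dict(
            subject=["a", "b"], sex=["F", "M"], age=[30, 40],
            brain_volume=[1200, 1100], intracranial_volume=[1500, 1400],
        )
        bad_age = {**base, "age": [30, -1]}
        with pytest.raises(ValueError, match="positive"):
            CohortDesign(pd.DataFrame(bad_age))
        bad_na = {**base, "brain_volume": [1200, np.nan]}
        with pytest.raises(ValueError, match="missing"):
            CohortDesign(pd.DataFrame(bad_na))
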