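"""One-vs-rest t-screen: closed-form examples, scipy cross-check, a
brute-force ranking oracle, and the algebraic invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from depscreen.io import DependencyProbabilityMatrix, GeneEffectMatrix, LineageAnnotation
from depscreen.screen import call_dependency, screen_all, screen_lineage, two_sample_t
from depscreen.simulate import SyntheticConfig, simulate_screen_dataset

finite_floats = st.floats(-5, 5, allow_nan=False, allow_infinity=False)


class TestTwoSampleT:
    def test_identical_groups(self):
        assert two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_constant_equal_groups_warn(self):
        with pytest.warns(UserWarning, match="constant"):
            t, p = two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_pooled_closed_form(self):
        """Pooled sd 0.1, se = 0.1*sqrt(2/3), df = 4."""
        t, p = two_sample_t([-1.0, -0.9, -1.1], [0.0, 0.1, -0.1], pooled=True)
        se = 0.1 * np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(-1.0 / se, abs=1e-10)  # -12.2474...
        assert p == pytest.approx(2 * stats.t.sf(1.0 / se, df=4), abs=1e-12)

    @pytest.mark.parametrize("pooled", [True, False])
    def test_matches_scipy_on_random_inputs(self, pooled):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.normal(size=20)
            b = rng.normal(0.5, 1.5, size=20)
            t, p = two_sample_t(a, b, pooled=pooled)
            ref = stats.ttest_ind(a, b, equal_var=pooled)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_undersized_group_raises(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_missing_values_dropped(self):
        t1, p1 = two_sample_t([1, 2, np.nan, 3], [4, 5, 6])
        t2, p2 = two_sample_t([1, 2, 3], [4, 5, 6])
        assert (t1, p1) == (t2, p2)

    @given(
        a=st.lists(finite_floats, min_size=3, max_size=8),
        b=st.lists(finite_floats, min_size=3, max_size=8),
        shift=finite_floats,
    )
    @settings(max_examples=60, deadline=None)
    def test_antisymmetry_and_location_equivariance(self, a, b, shift):
        if np.var(a) + np.var(b) == 0:
            return
        t_ab, p_ab = two_sample_t(a, b)
        t_ba, p_ba = two_sample_t(b, a)
        assert t_ab == pytest.approx(-t_ba, abs=1e-10)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)
        t_shift, _ = two_sample_t([x + shift for x in a], [x + shift for x in b])
        assert t_shift == pytest.approx(t_ab, rel=1e-9, abs=1e-9)


class TestScreenLineage:
    def test_unique_signal_ranks_first(self):
        lines = [f"l{i}" for i in range(12)]
        genes = ["G1", "G2", "G3"]
        vals = np.zeros((12, 3))
        vals[:, 1] = np.tile([0.01, -0.01], 6)  # avoid all-constant columns
        vals[:, 2] = np.tile([0.02, -0.02], 6)
        vals[:4, 0] = -1.0
        vals[4:, 0] = np.tile([0.005, -0.005], 4)
        eff = GeneEffectMatrix(pd.DataFrame(vals, index=lines, columns=genes))
        ann = LineageAnnotation({l: ("A" if i < 4 else "B") for i, l in enumerate(lines)})
        recs = screen_lineage(eff, ann, "A", k=None)
        assert recs[0].gene == "G1" and recs[0].rank == 1
        assert recs[0].t_statistic < -5

    def test_full_ranking_matches_brute_force_oracle(self, small_effects, small_annotation):
        recs = screen_lineage(small_effects, small_annotation, "A", k=None)
        # oracle: scipy t-test per gene, sorted by (t, gene)
        in_lines = small_annotation.lines_in("A")
        oracle = []
        for g in small_effects.gene_ids:
            col = small_effects.column(g)
            a = col.loc[in_lines].to_numpy()
            b = col.drop(index=in_lines).to_numpy()
            res = stats.ttest_ind(a, b, equal_var=True)
            oracle.append((float(res.statistic), g, float(res.pvalue)))
        oracle.sort()
        assert [r.gene for r in recs] == [g for _, g, _ in oracle]
        for rec, (t, _, p) in zip(recs, oracle):
            assert rec.t_statistic == pytest.approx(t, abs=1e-10)
            assert rec.p_value == pytest.approx(p, abs=1e-10)
        assert [r.rank for r in recs] == list(range(1, len(recs) + 1))

    def test_top_k_truncation(self):
        eff, _, _, ann, _ = simulate_screen_dataset(SyntheticConfig(seed=1))
        recs = screen_lineage(eff, ann, "L1", k=5)
        assert len(recs) == 5

    def test_gene_order_permutation_invariance(self, small_effects, small_annotation):
        recs = screen_lineage(small_effects, small_annotation, "A", k=None)
        shuffled = GeneEffectMatrix(small_effects.data.iloc[:, ::-1])
        recs2 = screen_lineage(shuffled, small_annotation, "A", k=None)
        assert [r.gene for r in recs] == [r.gene for r in recs2]

    def test_absent_lineage_raises(self, small_effects, small_annotation):
        with pytest.raises(ValueError, match="not present"):
            screen_lineage(small_effects, small_annotation, "Z")

    def test_min_group_skips_sparse_genes(self, small_effects, small_annotation):
        data = small_effects.data.copy()
        data.iloc[1:10, 0] = np.nan  # one present value in lineage A
        eff = GeneEffectMatrix(data)
        recs = screen_lineage(eff, small_annotation, "A", k=None, min_group=2)
        assert small_effects.gene_ids[0] not in [r.gene for r in recs]
        assert len(recs) == 9


class TestScreenAll:
    def test_single_lineage_annotation(self, small_effects):
        ann = LineageAnnotation(
            {l: ("A" if i < 10 else "rest") for i, l in enumerate(small_effects.line_ids)}
        )
        ts = screen_all(small_effects, ann, k=3, lineages=["A"])
        assert ts.lineages() == ["A"]
        assert len(ts.per_lineage["A"]) == 3

    def test_undersized_lineage_reported_and_omitted(self, small_effects):
        mapping = {l: "A" for l in small_effects.line_ids}
        mapping[small_effects.line_ids[0]] = "tiny"
        ann = LineageAnnotation(mapping)
        with pytest.warns(UserWarning, match="tiny"):
            ts = screen_all(small_effects, ann, k=3)
        assert "tiny" not in ts.per_lineage


class TestCallDependency:
    def test_extremes_and_boundary(self):
        df = pd.DataFrame(
            [[1.0, 0.0, 0.5, np.nan]],
            index=["l1"],
            columns=["G1", "G2", "G3", "G4"],
        )
        calls = call_dependency(DependencyProbabilityMatrix(df))
        assert calls.loc["l1", "G1"] == 1.0
        assert calls.loc["l1", "G2"] == 0.0
        assert calls.loc["l1", "G3"] == 0.0  # strict inequality at the threshold
        assert np.isnan(calls.loc["l1", "G4"])

    def test_bad_threshold_rejected(self):
        df = pd.DataFrame([[0.5]], index=["l1"], columns=["G1"])
        with pytest.raises(ValueError):
            call_dependency(DependencyProbabilityMatrix(df), threshold=1.5)

    def test_common_essential_mostly_dependent(self):
        cfg = SyntheticConfig(seed=5)
        _, prob, _, _, truth = simulate_screen_dataset(cfg)
        common = truth.genes_of_class("common_essential")
        calls = call_dependency(prob)
        frac = np.nanmean(calls[common].to_numpy())
        assert frac >= 0.95
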