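"""Fisher exact test (with a hypergeometric-enumeration oracle), BH-FDR,
category enrichment, and motif-class representation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from depscreen.enrichment import (
    bh_fdr,
    category_enrichment,
    classes_hit,
    fisher_exact_2x2,
    motif_class_representation,
)
from depscreen.io import AnnotationTable


def _fisher_oracle(a, b, c, d):
    """Sum hypergeometric probabilities of all tables with fixed margins
    whose probability does not exceed the observed table's."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    pmf = {k: stats.hypergeom.pmf(k, n, col1, row1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


class TestFisher:
    def test_small_table_closed_form(self):
        # [[3,1],[1,3]]: enumeration over the 5 feasible tables gives 34/70
        assert fisher_exact_2x2(3, 1, 1, 3) == pytest.approx(34 / 70, abs=1e-12)

    def test_degenerate_margin(self):
        assert fisher_exact_2x2(0, 10, 0, 90) == pytest.approx(1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    @given(
        a=st.integers(0, 12),
        b=st.integers(0, 12),
        c=st.integers(0, 12),
        d=st.integers(0, 12),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0 or a + b + c + d > 40:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            _fisher_oracle(a, b, c, d), abs=1e-10
        )

    @given(a=st.integers(0, 10), b=st.integers(0, 10), c=st.integers(0, 10), d=st.integers(0, 10))
    @settings(max_examples=40, deadline=None)
    def test_symmetry_under_transpose(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_exact_2x2(a, c, b, d), abs=1e-12
        )


class TestBhFdr:
    def test_hand_step_up(self):
        # ranks 1..4: min over j>=i of p_j * 4/j = 0.04 for all
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3] * 3)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_input_order_restored(self):
        p = [0.04, 0.001, 0.2, 0.01]
        adj = bh_fdr(p)
        # independently computed step-up in sorted order, mapped back
        order = np.argsort(p)
        sorted_adj = np.minimum.accumulate(
            (np.array(sorted(p)) * 4 / np.arange(1, 5))[::-1]
        )[::-1]
        expected = np.empty(4)
        expected[order] = np.minimum(sorted_adj, 1)
        assert np.allclose(adj, expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_monotone_in_sorted_order_and_idempotent(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = bh_fdr(p)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
        assert np.allclose(bh_fdr(np.full(20, 0.7)), np.full(20, 0.7))


def _annotation(n_bg=100, cat_size=10, category="C", seed=0):
    genes = [f"g{i}" for i in range(n_bg)]
    cats = {g: {category} for g in genes[:cat_size]}
    return genes, AnnotationTable(cats, set(genes))


class TestCategoryEnrichment:
    def test_forced_tenfold_ratio(self):
        genes, ann = _annotation(n_bg=100, cat_size=10)
        recs = category_enrichment(genes[:10], ann, min_background=2)
        rec = recs[0]
        assert rec.n_study == 10 and rec.n_bg == 10
        assert rec.fold_enrichment == pytest.approx(10.0)
        assert rec.fdr <= rec.p_raw * len(recs)

    def test_observed_over_expected_semantics(self):
        """52 of 126 study genes in a category with expected count 6.83
        gives fold enrichment about 7.61 (like a DNA-binding term over an
        annotated genome)."""
        n_bg_total = 20000
        n_study = 126
        n_bg = round(6.83 * n_bg_total / n_study)  # background size giving E=6.83
        genes = [f"g{i}" for i in range(n_bg_total)]
        cats = {g: {"dna_binding"} for g in genes[:n_bg]}
        ann = AnnotationTable(cats, set(genes))
        study = genes[:52] + genes[n_bg : n_bg + (n_study - 52)]
        rec = category_enrichment(study, ann)[0]
        assert rec.n_study == 52
        assert rec.expected == pytest.approx(6.83, abs=0.01)
        assert rec.fold_enrichment == pytest.approx(7.61, abs=0.02)
        assert rec.p_raw < 1e-20

    def test_uniform_draw_fold_near_one(self):
        rng = np.random.default_rng(7)
        folds = []
        for seed in range(20):
            genes, ann = _annotation(n_bg=400, cat_size=200)
            study = list(rng.choice(genes, size=100, replace=False))
            rec = category_enrichment(study, ann)[0]
            folds.append(rec.fold_enrichment)
        assert 0.8 <= float(np.mean(folds)) <= 1.25

    def test_null_fdr_control(self):
        """Uniform draws: few categories reach fdr < 0.05."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(300)]
        cats = {}
        for g in genes:
            for k in range(8):
                if rng.random() < 0.15:
                    cats.setdefault(g, set()).add(f"c{k}")
        ann = AnnotationTable(cats, set(genes))
        hits = total = 0
        for _ in range(50):
            study = list(rng.choice(genes, size=60, replace=False))
            for rec in category_enrichment(study, ann):
                total += 1
                hits += rec.fdr < 0.05
        assert hits / total <= 0.05 + 0.03

    def test_stray_study_genes_dropped_with_warning(self):
        genes, ann = _annotation()
        with pytest.warns(UserWarning, match="outside the background"):
            recs = category_enrichment(genes[:5] + ["alien"], ann)
        assert recs[0].n_study_total == 5

    def test_empty_study_rejected(self):
        _, ann = _annotation()
        with pytest.raises(ValueError):
            category_enrichment([], ann)

    def test_tiny_background_category_skipped(self):
        genes = [f"g{i}" for i in range(20)]
        cats = {genes[0]: {"singleton"}, genes[1]: {"pair"}, genes[2]: {"pair"}}
        ann = AnnotationTable(cats, set(genes))
        recs = category_enrichment(genes[:5], ann, min_background=2)
        assert [r.category for r in recs] == ["pair"]


class TestMotifClasses:
    def test_no_hits(self):
        genes = [f"g{i}" for i in range(10)]
        ann = AnnotationTable({g: {"HTH"} for g in genes[:4]}, set(genes))
        out = motif_class_representation(["g8", "g9"], ann)
        assert classes_hit(out) == 0

    def test_class_share_semantics(self):
        """18 study genes in a 409-gene class cover about 4.4% of the class."""
        genes = [f"g{i}" for i in range(500)]
        ann = AnnotationTable({g: {"HTH"} for g in genes[:409]}, set(genes))
        out = motif_class_representation(genes[:18], ann)[0]
        assert out.n_in_class == 18
        assert out.pct_of_class_genome_wide == pytest.approx(100 * 18 / 409, abs=0.01)
        assert out.pct_of_study == pytest.approx(100.0)

    def test_hand_counted_fixture(self):
        genes = ["a", "b", "c", "d", "e", "f"]
        cats = {"a": {"zf"}, "b": {"zf", "hth"}, "c": {"hth"}, "d": {"zf"}}
        ann = AnnotationTable(cats, set(genes))
        out = {s.motif_class: s for s in motif_class_representation(["a", "b", "e"], ann)}
        assert out["zf"].n_in_class == 2
        assert out["zf"].pct_of_study == pytest.approx(100 * 2 / 3)
        assert out["zf"].pct_of_class_genome_wide == pytest.approx(100 * 2 / 3)
        assert out["hth"].n_in_class == 1
        assert classes_hit(out.values()) == 2
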