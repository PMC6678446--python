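"""Expression filtering, Spearman/BH statistics, skew and matrix exports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from saspairs import (
    ExpressionMatrix,
    SyntheticConfig,
    bh_adjust,
    correlate_all,
    filter_expressed_pairs,
    find_opposite_strand_overlaps,
    generate_annotation,
    generate_expression,
    heatmap_matrix,
    make_pair,
    spearman,
    strand_skew,
)
from saspairs.correlation import align_strand_samples

from conftest import make_gene, midrank_spearman, stepup_bh


def toy_matrix(sense_vals, anti_vals, n=16):
    """Two-gene matrix over n biosamples split into sense/antisense columns."""
    bios = [f"b{i:02d}" for i in range(n)]
    stages = [("45d", "4mo", "6mo", "10mo")[i * 4 // n] for i in range(n)]
    cols = [f"{b}.s" for b in bios] + [f"{b}.a" for b in bios]
    values = pd.DataFrame(0.0, index=["gS", "gA"], columns=cols)
    values.loc["gS", cols[:n]] = sense_vals
    values.loc["gA", cols[n:]] = anti_vals
    meta = pd.DataFrame(
        {
            "sample_id": cols,
            "stage": stages + stages,
            "strand_label": ["sense"] * n + ["antisense"] * n,
            "biosample": bios + bios,
        }
    ).set_index("sample_id")
    return ExpressionMatrix(values=values, sample_meta=meta)


def toy_pair():
    return make_pair(make_gene("gS", 100, 1000, "+"), make_gene("gA", 500, 1500, "-"))


class TestFilterExpressedPairs:
    @pytest.mark.parametrize(
        "n_sense,n_anti,kept",
        [(16, 10, True), (13, 12, False), (16, 16, True), (13, 13, True), (0, 16, False)],
    )
    def test_26_of_32_boundary(self, n_sense, n_anti, kept):
        sense = [1.0] * n_sense + [0.0] * (16 - n_sense)
        anti = [1.0] * n_anti + [0.0] * (16 - n_anti)
        retained, table = filter_expressed_pairs([toy_pair()], toy_matrix(sense, anti))
        assert (len(retained) == 1) == kept
        assert table.loc[0, "n_expressed_total"] == n_sense + n_anti

    def test_missing_gene_dropped_not_raised(self):
        em = toy_matrix([1.0] * 16, [1.0] * 16)
        ghost = make_pair(make_gene("nope", 1, 10, "+"), make_gene("gA", 5, 15, "-"))
        retained, table = filter_expressed_pairs([ghost], em)
        assert retained == [] and table.empty

    def test_retention_matches_enumeration_of_planted_zeros(self):
        cfg = SyntheticConfig(seed=9, n_genes=120, n_planted_pairs=30, dropout_rate=0.3)
        genes, truth = generate_annotation(cfg)
        expr = generate_expression(genes, truth, cfg)
        pairs = find_opposite_strand_overlaps(genes)
        retained, table = filter_expressed_pairs(pairs, expr)
        expected = set()
        sense_cols = expr.samples_for("sense")
        anti_cols = expr.samples_for("antisense")
        for p in pairs:
            nz = int((expr.values.loc[p.sense.gene_id, sense_cols] > 0).sum()) + int(
                (expr.values.loc[p.antisense.gene_id, anti_cols] > 0).sum()
            )
            if nz >= 26:
                expected.add((p.sense.gene_id, p.antisense.gene_id))
        got = {(p.sense.gene_id, p.antisense.gene_id) for p in retained}
        assert got == expected


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0 and 0 < p <= 1

    def test_perfect_antitone(self):
        rho, _ = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == -1.0

    def test_constant_vector_flagged_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_tied_vectors_match_midrank_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.integers(0, 6, size=16).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=16).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(midrank_spearman(x, y), abs=1e-12)

    @given(st.integers(0, 1000))
    def test_invariance_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base, _ = spearman(x, y)
        for fx in (np.exp, lambda v: 3 * v + 7, lambda v: np.log(v - v.min() + 1)):
            rho, _ = spearman(fx(x), y)
            assert rho == pytest.approx(base, abs=1e-12)


class TestBHAdjust:
    def test_closed_form_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    def test_matches_independent_stepup_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(stepup_bh(p), abs=1e-12)

    def test_stable_under_input_permutation(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, size=25)
        perm = rng.permutation(25)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(1e-6, 1, size=50))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-15)


class TestCorrelateAll:
    def test_planted_sign_pattern_recovered(self):
        cfg = SyntheticConfig(
            seed=21, n_genes=6, n_planted_pairs=3,
            planted_rho=[(0, 0.95), (1, 0.0), (2, -0.95)], dropout_rate=0.0,
        )
        genes, truth = generate_annotation(cfg)
        expr = generate_expression(genes, truth, cfg)
        pairs = find_opposite_strand_overlaps(genes)
        _, _, table = correlate_all(pairs, expr)
        rho = dict(zip(table["sense_id"], table["rho"]))
        assert rho["P0000S"] > 0.6
        assert abs(rho["P0001S"]) < 0.55
        assert rho["P0002S"] < -0.6

    def test_identical_data_equalizes_rho_and_padj(self):
        vals = np.array([1.0, 4.0, 2.0, 8.0] * 4)
        em = toy_matrix(vals, vals)
        p1 = toy_pair()
        p2 = make_pair(make_gene("gS", 2000, 3000, "+"), make_gene("gA", 2500, 3500, "-"))
        # same gene ids -> same data for both pairs
        results, summary, table = correlate_all([p1, p2], em)
        assert table["rho"].nunique() == 1
        assert table["p_adj"].nunique() == 1
        assert summary.n_tested == 2

    def test_constant_pairs_excluded_from_bh(self):
        em = toy_matrix([5.0] * 16, list(range(16)))
        results, summary, table = correlate_all([toy_pair()], em)
        assert table.loc[0, "constant"] and not table.loc[0, "significant"]
        assert summary is None  # nothing testable

    def test_empty_input_warns_not_raises(self):
        em = toy_matrix([1.0] * 16, [1.0] * 16)
        results, summary, table = correlate_all([], em)
        assert results == [] and summary is None and table.empty


class TestStrandSkew:
    def test_identical_matrices_give_unit_skew(self):
        vals = np.linspace(1, 16, 16)
        skew, density = strand_skew([toy_pair()], toy_matrix(vals, vals))
        assert skew == pytest.approx(1.0)
        assert len(density) == 16

    def test_doubled_antisense_gives_skew_two(self):
        vals = np.linspace(1, 16, 16)
        skew, _ = strand_skew([toy_pair()], toy_matrix(vals, 2 * vals))
        assert skew == pytest.approx(2.0)

    def test_zero_cells_excluded_and_empty_is_nan(self):
        skew, _ = strand_skew([toy_pair()], toy_matrix([0.0] * 16, [1.0] * 16))
        assert np.isnan(skew)

    def test_planted_log_ratio_recovered(self):
        """Antisense shifted by +0.2 on the log10-FPKM scale => skew 10^0.2."""
        rng = np.random.default_rng(4)
        vals = 10 ** rng.normal(1.0, 0.5, size=16)
        skew, _ = strand_skew([toy_pair()], toy_matrix(vals, vals * 10**0.2))
        assert skew == pytest.approx(10**0.2, rel=1e-9)


class TestHeatmapMatrix:
    def test_log_transform_values(self):
        em = toy_matrix([0.0] + [9.0] * 15, [99.0] * 16)
        mat = heatmap_matrix([toy_pair()], em)
        row = mat.iloc[0]
        assert row.iloc[0] == pytest.approx(0.0)  # FPKM 0 -> 0.0
        assert row.iloc[2] == pytest.approx(1.0)  # FPKM 9 -> 1.0
        assert row.iloc[1] == pytest.approx(2.0)  # FPKM 99 -> 2.0

    def test_columns_stage_sorted_even_with_shuffled_metadata(self):
        em = toy_matrix(np.ones(16), np.ones(16))
        shuffled = ExpressionMatrix(
            values=em.values.sample(frac=1, axis=1, random_state=0),
            sample_meta=em.sample_meta,
        )
        mat = heatmap_matrix([toy_pair()], shuffled)
        stages = [c.split("|")[0] for c in mat.columns]
        order = {"45d": 0, "4mo": 1, "6mo": 2, "10mo": 3}
        assert stages == sorted(stages, key=order.__getitem__)

    def test_full_synthetic_dimensions(self, small_cohort):
        cfg, genes, truth, expr = small_cohort
        pairs = find_opposite_strand_overlaps(genes)
        retained, _ = filter_expressed_pairs(pairs, expr)
        mat = heatmap_matrix(retained, expr)
        assert mat.shape == (len(retained), 2 * cfg.n_biosamples)


class TestSampleAlignment:
    def test_biosample_column_pairs_strand_samples(self, small_cohort):
        _, _, _, expr = small_cohort
        align = align_strand_samples(expr)
        assert len(align) == 16
        for row in align.itertuples(index=False):
            assert row.sense_sample.startswith(row.biosample)
            assert row.antisense_sample.startswith(row.biosample)
        stages = list(align["stage"])
        order = {"45d": 0, "4mo": 1, "6mo": 2, "10mo": 3}
        assert stages == sorted(stages, key=order.__getitem__)
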