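"""Metric unit tests, each distance metric checked against an exhaustive
brute-force oracle implemented independently here."""

import numpy as np
import pytest

from onquant.metrics import (PairedMeasurements, aggregate_report, asd, dsc,
                             dsc_tolerance, evaluate_pair, hd95, icc_a1,
                             precision_recall)

from conftest import make_mask, random_mask_pair


# --------------------------------------------------------------------------- #
# Brute-force oracles
# --------------------------------------------------------------------------- #

def oracle_surface(mask):
    """Mask voxels with a face-adjacent background neighbour (or volume face)."""
    m = mask.voxels.astype(bool)
    out = []
    for idx in np.argwhere(m):
        i, j, k = idx
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            if not (0 <= ni < m.shape[0] and 0 <= nj < m.shape[1]
                    and 0 <= nk < m.shape[2]) or not m[ni, nj, nk]:
                out.append(idx)
                break
    return np.asarray(out).reshape(-1, 3)


def oracle_directed(a, b):
    sa = oracle_surface(a) * a.spacing
    sb = oracle_surface(b) * b.spacing
    return np.array([min(np.linalg.norm(p - q) for q in sb) for p in sa])


def oracle_hd95(a, b):
    return max(np.percentile(oracle_directed(a, b), 95),
               np.percentile(oracle_directed(b, a), 95))


def oracle_asd(a, b):
    dab, dba = oracle_directed(a, b), oracle_directed(b, a)
    return (dab.sum() + dba.sum()) / (len(dab) + len(dba))


def oracle_icc_a1(r1, r2):
    """ICC(A,1) via an explicit two-way ANOVA table."""
    x = np.column_stack([r1, r2]).astype(float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# --------------------------------------------------------------------------- #
# DSC
# --------------------------------------------------------------------------- #

class TestDsc:
    def test_identical(self):
        a = make_mask((4, 4, 4), [(1, 1, 1), (2, 2, 2)])
        assert dsc(a, a) == 1.0

    def test_disjoint(self):
        a = make_mask((4, 4, 4), [(0, 0, 0)])
        b = make_mask((4, 4, 4), [(3, 3, 3)])
        assert dsc(a, b) == 0.0

    def test_half_overlap(self):
        a = make_mask((4, 4, 4), [(0, 0, 0), (1, 0, 0)])
        b = make_mask((4, 4, 4), [(1, 0, 0), (2, 0, 0)])
        assert dsc(a, b) == 0.5

    def test_both_empty_is_one(self):
        a = make_mask((3, 3, 3), [])
        assert dsc(a, a) == 1.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = random_mask_pair(rng)
        assert dsc(a, b) == dsc(b, a)

    def test_grid_mismatch_errors(self):
        a = make_mask((4, 4, 4), [(0, 0, 0)])
        b = make_mask((4, 4, 4), [(0, 0, 0)], spacing=0.5)
        with pytest.raises(ValueError):
            dsc(a, b)


class TestDscTolerance:
    def test_identical(self):
        a = make_mask((4, 4, 4), [(1, 1, 1)])
        assert dsc_tolerance(a, a, 1.0) == 1.0

    def test_one_voxel_shift_is_one(self):
        coords = [(i, 2, 2) for i in range(1, 7)]
        a = make_mask((8, 8, 8), coords)
        b = make_mask((8, 8, 8), [(i + 1, j, k) for i, j, k in coords])
        assert dsc_tolerance(a, b, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_vs_dsc(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = random_mask_pair(rng)
            assert dsc_tolerance(a, b, 1.0) >= dsc(a, b) - 1e-12

    def test_zero_tolerance_equals_dsc(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = random_mask_pair(rng)
            assert dsc_tolerance(a, b, 0.0) == dsc(a, b)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = random_mask_pair(rng)
            assert dsc_tolerance(a, b, 1.0) <= 1.0 + 1e-12


class TestPrecisionRecall:
    def test_perfect(self):
        a = make_mask((4, 4, 4), [(1, 1, 1), (2, 2, 2)])
        assert precision_recall(a, a) == (1.0, 1.0)

    def test_subset_prediction(self):
        a = make_mask((6, 6, 6), [(i, 0, 0) for i in range(4)])
        b = make_mask((6, 6, 6), [(i, 0, 0) for i in range(2)])
        assert precision_recall(a, b) == (1.0, 0.5)

    def test_superset_prediction(self):
        a = make_mask((6, 6, 6), [(i, 0, 0) for i in range(2)])
        b = make_mask((6, 6, 6), [(i, 0, 0) for i in range(4)])
        assert precision_recall(a, b) == (0.5, 1.0)

    def test_empty_prediction_flagged(self):
        a = make_mask((4, 4, 4), [(1, 1, 1)])
        b = make_mask((4, 4, 4), [])
        p, r = precision_recall(a, b)
        assert np.isnan(p)


# --------------------------------------------------------------------------- #
# Distance metrics
# --------------------------------------------------------------------------- #

class TestDistances:
    def test_identical_zero(self):
        a = make_mask((5, 5, 5), [(1, 1, 1), (2, 1, 1)], spacing=0.3)
        assert hd95(a, a) == 0.0
        assert asd(a, a) == 0.0

    def test_single_voxels_three_apart(self):
        a = make_mask((8, 8, 8), [(1, 1, 1)], spacing=0.3)
        b = make_mask((8, 8, 8), [(4, 1, 1)], spacing=0.3)
        assert hd95(a, b) == pytest.approx(0.9, abs=1e-12)
        assert asd(a, b) == pytest.approx(0.9, abs=1e-12)

    def test_empty_mask_errors(self):
        a = make_mask((4, 4, 4), [(1, 1, 1)])
        b = make_mask((4, 4, 4), [])
        with pytest.raises(ValueError):
            hd95(a, b)
        with pytest.raises(ValueError):
            asd(a, b)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a, b = random_mask_pair(rng)
        assert hd95(a, b) == hd95(b, a)
        assert asd(a, b) == asd(b, a)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = random_mask_pair(rng, max_voxels=60)
        assert hd95(a, b) == pytest.approx(oracle_hd95(a, b), abs=1e-9)
        assert asd(a, b) == pytest.approx(oracle_asd(a, b), abs=1e-9)

    def test_linear_spacing_scaling(self):
        rng = np.random.default_rng(5)
        vox_a, vox_b = random_mask_pair(rng)
        a1 = make_mask((1, 1, 1), [])  # placeholder, rebuilt below
        from onquant.grid import BinaryMask
        a1 = BinaryMask(vox_a.voxels, np.full(3, 0.3), np.zeros(3))
        b1 = BinaryMask(vox_b.voxels, np.full(3, 0.3), np.zeros(3))
        a2 = BinaryMask(vox_a.voxels, np.full(3, 0.6), np.zeros(3))
        b2 = BinaryMask(vox_b.voxels, np.full(3, 0.6), np.zeros(3))
        assert hd95(a2, b2) == pytest.approx(2 * hd95(a1, b1), abs=1e-9)
        assert asd(a2, b2) == pytest.approx(2 * asd(a1, b1), abs=1e-9)


# --------------------------------------------------------------------------- #
# ICC
# --------------------------------------------------------------------------- #

class TestIcc:
    def test_identical_raters(self):
        p = PairedMeasurements([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert icc_a1(p) == pytest.approx(1.0, abs=1e-12)

    def test_reversed_matches_anova_oracle(self):
        r1, r2 = [1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]
        val = icc_a1(PairedMeasurements(r1, r2))
        assert val < 0
        assert val == pytest.approx(oracle_icc_a1(r1, r2), abs=1e-12)

    def test_constant_offset_below_one_and_decreasing(self):
        r1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vals = [icc_a1(PairedMeasurements(r1, r1 + c)) for c in (0.5, 1.0, 2.0)]
        assert all(v < 1.0 for v in vals)
        assert vals[0] > vals[1] > vals[2]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matches_oracle_and_pingouin(self, seed):
        rng = np.random.default_rng(seed)
        r1 = rng.normal(10, 2, 12)
        r2 = r1 + rng.normal(0.3, 0.8, 12)
        val = icc_a1(PairedMeasurements(r1, r2))
        assert val == pytest.approx(oracle_icc_a1(r1, r2), abs=1e-10)
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile([0, 1], 12),
            "score": np.column_stack([r1, r2]).ravel(),
        })
        icc2 = pg.intraclass_corr(df, "targets", "raters", "score")
        sel = icc2["Type"].isin(["ICC(A,1)", "ICC2"])
        ref = float(icc2.loc[sel, "ICC"].iloc[0])
        assert val == pytest.approx(ref, abs=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            icc_a1(PairedMeasurements([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]))

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            PairedMeasurements([1.0, 2.0], [1.0, 2.0])


# --------------------------------------------------------------------------- #
# Reporting
# --------------------------------------------------------------------------- #

class TestProperties:
    """Invariant checks over generated mask pairs (hypothesis-driven)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_dsc_bounds_symmetry_and_tolerance_order(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask_pair(rng, shape=(6, 6, 6), max_voxels=40)
        d = dsc(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dsc(b, a)
        assert d <= dsc_tolerance(a, b, 1.0) <= 1.0 + 1e-12

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=15, deadline=None)
    def test_distance_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask_pair(rng, shape=(6, 6, 6), max_voxels=40)
        assert hd95(a, b) == hd95(b, a) >= 0.0
        assert asd(a, b) == asd(b, a) >= 0.0


def test_evaluate_pair_and_aggregate():
    rng = np.random.default_rng(6)
    rows = []
    for _ in range(4):
        a, b = random_mask_pair(rng)
        row = evaluate_pair(a, b)
        assert 0 <= row["dsc"] <= row["dsc_tol1"] <= 1
        rows.append(row)
    agg = aggregate_report(rows)
    assert set(agg) == {"dsc", "dsc_tol1", "precision", "recall", "hd95_mm", "asd_mm"}
    assert "median" in agg["hd95_mm"] and "mean" in agg["dsc"]
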