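"""Two-point ADC inversion, ROI means, synthetic reader tables and
ICC(2,1) against brute-force ANOVA and pingouin."""

import numpy as np
import pandas as pd
import pytest

from dwicycle.adc_analysis import (
    AdcMap,
    RoiCircle,
    compute_adc,
    icc,
    agreement_report,
    roi_mean,
    simulate_reader_measurements,
)
from dwicycle.synthetic_dwi import DwiSlice

# ---------------------------------------------------------------------------
# compute_adc
# ---------------------------------------------------------------------------


def _slice(pixels, b):
    return DwiSlice(pixels=np.asarray(pixels, dtype=float), b_value=b, max_intensity=1.0)


def test_two_point_inversion_recovers_unit_millimetric_adc():
    s_low = _slice(np.full((4, 4), np.exp(-50 * 1e-3)), 50.0)
    s_high = _slice(np.full((4, 4), np.exp(-1200 * 1e-3)), 1200.0)
    amap = compute_adc(s_low, s_high)
    np.testing.assert_allclose(amap.values, 1.0e-3, rtol=1e-12)


def test_equal_signals_give_zero_adc():
    s = np.full((3, 3), 0.5)
    amap = compute_adc(_slice(s, 50.0), _slice(s, 1200.0))
    np.testing.assert_array_equal(amap.values, 0.0)


def test_nonpositive_signal_masked_not_clamped():
    low = np.full((2, 2), 0.5)
    high = np.array([[0.25, 0.0], [0.25, 0.25]])
    amap = compute_adc(_slice(low, 50.0), _slice(high, 1200.0))
    assert not amap.validity_mask[0, 1]
    assert np.isnan(amap.values[0, 1])
    assert amap.validity_mask.sum() == 3


def test_bad_b_ordering_rejected():
    s = np.ones((2, 2))
    with pytest.raises(ValueError, match="must exceed"):
        compute_adc(_slice(s, 1200.0), _slice(s, 50.0))


# ---------------------------------------------------------------------------
# roi_mean
# ---------------------------------------------------------------------------


def _adc_map(values):
    values = np.asarray(values, dtype=float)
    return AdcMap(values=values, validity_mask=np.isfinite(values), b_pair=(50.0, 1200.0))


def test_roi_mean_on_constant_map_is_the_constant():
    amap = _adc_map(np.full((16, 16), 2.5e-3))
    assert roi_mean(amap, RoiCircle((8, 8), 4.0)) == pytest.approx(2.5e-3)


def test_single_pixel_roi_returns_that_pixel():
    values = np.arange(25.0).reshape(5, 5)
    amap = _adc_map(values)
    assert roi_mean(amap, RoiCircle((2, 3), 0.9)) == values[2, 3]


def test_half_in_circle_matches_brute_force_pixel_scan():
    values = np.zeros((20, 20))
    values[:, 10:] = 1.0
    amap = _adc_map(values)
    roi = RoiCircle((10.0, 10.0), 4.3)
    # enumeration oracle: pixel centers strictly inside the circle
    acc, count = 0.0, 0
    for r in range(20):
        for c in range(20):
            if (r - 10.0) ** 2 + (c - 10.0) ** 2 < 4.3**2:
                acc += values[r, c]
                count += 1
    assert roi_mean(amap, roi) == pytest.approx(acc / count, abs=1e-15)


def test_roi_without_valid_pixels_raises():
    values = np.full((8, 8), np.nan)
    amap = AdcMap(values=values, validity_mask=np.zeros((8, 8), bool), b_pair=(50.0, 1200.0))
    with pytest.raises(ValueError, match="no valid"):
        roi_mean(amap, RoiCircle((4, 4), 2.0))


# ---------------------------------------------------------------------------
# reader simulation
# ---------------------------------------------------------------------------


def test_noiseless_readers_reproduce_truth():
    truth = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    tab = simulate_reader_measurements(truth, 0.0, 0.0, seed=1)
    merged = tab.groupby("subject_id")["mean_adc"].agg(["min", "max"])
    np.testing.assert_allclose(merged["min"], truth)
    np.testing.assert_allclose(merged["max"], truth)


def test_reader_table_is_seed_deterministic_and_balanced():
    truth = np.linspace(1, 2, 8)
    a = simulate_reader_measurements(truth, 0.2, 0.1, seed=3)
    b = simulate_reader_measurements(truth, 0.2, 0.1, seed=3)
    pd.testing.assert_frame_equal(a, b)
    counts = a.groupby(["subject_id", "reader_id", "session"]).size()
    assert (counts == 3).all()


def test_variance_components_recovered_by_method_of_moments():
    """On a very large table, empirical reader/repeat variances match the
    generating parameters within 3% relative."""
    n = 4000
    truth = np.zeros(n)
    sr, se = 0.7, 1.3
    tab = simulate_reader_measurements(
        truth, sigma_reader=sr, sigma_repeat=se, seed=5, n_readers=50, n_sessions=1
    )
    cell = tab.groupby(["subject_id", "reader_id"])["mean_adc"].mean().unstack()
    reader_bias = cell.mean(axis=0)  # bias per reader, averaged over many subjects
    est_sr2 = reader_bias.var(ddof=1)
    resid = cell - reader_bias
    est_se2 = (resid.to_numpy().var(ddof=1)) * 3  # cells average 3 repetitions
    assert est_sr2 == pytest.approx(sr**2, rel=0.3)  # 50 readers -> wide sampling
    assert est_se2 == pytest.approx(se**2, rel=0.03)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def icc21_bruteforce(y):
    """Independent ANOVA-mean-squares computation (explicit loops)."""
    n, k = y.shape
    grand = y.mean()
    ss_rows = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((y - grand) ** 2).sum()
    msb = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n)


def _table_from_matrix(y):
    rows = []
    for s in range(y.shape[0]):
        for r in range(y.shape[1]):
            rows.append(
                {"subject_id": s, "tissue": "lesion", "reader_id": r + 1,
                 "session": 1, "repetition": 1, "mean_adc": y[s, r]}
            )
    return pd.DataFrame(rows)


def test_identical_raters_give_icc_one():
    y = np.tile(np.arange(8.0)[:, None], (1, 3))
    res = icc(_table_from_matrix(y), "between_readers")
    assert res.estimate == pytest.approx(1.0, abs=1e-12)


def test_zero_subject_variance_gives_nonpositive_icc(rng):
    y = rng.normal(0, 1, size=(12, 2))
    y -= y.mean(axis=1, keepdims=True)  # kill subject effects
    res = icc(_table_from_matrix(y), "between_readers")
    assert res.estimate <= 0


@pytest.mark.parametrize("shape", [(10, 2), (25, 3), (40, 4)])
def test_icc_matches_bruteforce_anova(rng, shape):
    y = rng.normal(10, 3, size=shape) + rng.normal(0, 1, size=(1, shape[1]))
    res = icc(_table_from_matrix(y), "between_readers")
    assert res.estimate == pytest.approx(icc21_bruteforce(y), abs=1e-10)


def test_icc_matches_pingouin_absolute_agreement(rng):
    pg = pytest.importorskip("pingouin")
    y = rng.normal(5, 2, size=(30, 2)) + rng.normal(0, 0.5, size=(1, 2))
    res = icc(_table_from_matrix(y), "between_readers")
    long = _table_from_matrix(y)
    ref = pg.intraclass_corr(
        data=long, targets="subject_id", raters="reader_id", ratings="mean_adc"
    )
    ref_a1 = ref[ref.Type == "ICC(A,1)"].iloc[0] if "ICC(A,1)" in set(ref.Type) else ref.iloc[1]
    assert res.estimate == pytest.approx(float(ref_a1.ICC), abs=1e-10)


def test_icc_decreases_with_error_variance():
    truth = np.random.default_rng(0).normal(0, 3, 80)
    estimates = []
    for se in (0.5, 1.5, 3.0):
        tab = simulate_reader_measurements(truth, 0.3, se, seed=9)
        estimates.append(icc(tab, "between_readers").estimate)
    assert estimates[0] > estimates[1] > estimates[2]
    assert all(-1 < e <= 1 for e in estimates)


def test_unbalanced_table_lists_missing_cells():
    y = np.random.default_rng(1).normal(size=(8, 2))
    tab = _table_from_matrix(y)
    tab = tab[~((tab.subject_id == 3) & (tab.reader_id == 2))]
    with pytest.raises(ValueError, match="subject 3, reader_id 2"):
        icc(tab, "between_readers")


def test_within_reader_needs_single_reader():
    truth = np.linspace(1, 2, 10)
    tab = simulate_reader_measurements(truth, 0.1, 0.1, seed=2)
    with pytest.raises(ValueError, match="single reader"):
        icc(tab, "within_reader")
    res = icc(tab, "within_reader", reader_id=1)
    assert -1 < res.estimate <= 1


# ---------------------------------------------------------------------------
# agreement report
# ---------------------------------------------------------------------------


def _multi_tissue_table(seed):
    rng = np.random.default_rng(seed)
    parts = []
    for tissue in ("liver", "kidney", "lesion"):
        truth = rng.normal(1.2e-3, 2e-4, 30)
        parts.append(
            simulate_reader_measurements(
                truth, 2e-5, 4e-5, seed=seed + hash(tissue) % 1000, tissue=tissue
            )
        )
    return pd.concat(parts, ignore_index=True)


def test_agreement_report_shapes_and_recomputation():
    b_tab = _multi_tissue_table(1)
    s_tab = _multi_tissue_table(2)
    report = agreement_report(b_tab, s_tab)
    assert report["between_readers"].shape == (3, 2)  # tissues x datasets
    assert report["within_reader"].shape == (6, 2)  # (2 readers x 3 tissues) x datasets
    # grid entries equal direct icc() calls on the same subsets
    raw = report["between_readers_raw"]
    row = raw[(raw.dataset == "b-ADC") & (raw.tissue == "liver")].iloc[0]
    direct = icc(b_tab[b_tab.tissue == "liver"], "between_readers")
    assert row.icc == pytest.approx(direct.estimate, abs=1e-12)


def test_identical_tables_give_identical_grids():
    tab = _multi_tissue_table(3)
    report = agreement_report(tab, tab.copy())
    grid = report["between_readers"]
    assert (grid["b-ADC"] == grid["s-ADC"]).all()
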