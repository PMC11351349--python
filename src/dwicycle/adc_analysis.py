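"""Two-point ADC mapping, circular-ROI measurement, and ICC agreement
analysis.

Under the mono-exponential decay model S(b) = S0 * exp(-b * ADC), two
acquisitions at b_low and b_high invert in closed form:

    ADC = ln(S_low / S_high) / (b_high - b_low)      [mm^2/s]

computed per pixel wherever both signals are positive; nonpositive
signals are *masked*, never clamped, because clamping biases the ADC.
The clinical protocol emulated here (b = 50 and 1200 s/mm^2, circular
ROI at the lesion center, triplicate measurement per reader per session)
feeds a long-format reader table into the intraclass correlation
coefficient.

The ICC form is ICC(2,1): two-way random effects, absolute agreement,
single measurement, computed from the two-way ANOVA mean squares with
Shrout-Fleiss F-based 95% confidence intervals.  Between-reader
consistency uses the first session's measurements (readers as raters);
within-reader repeatability uses one reader's two sessions (sessions as
raters).  Triplicate repetitions are averaged to one value per (subject,
rater) cell before the ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = [
    "AdcMap",
    "RoiCircle",
    "READER_TABLE_COLUMNS",
    "compute_adc",
    "roi_mean",
    "simulate_reader_measurements",
    "icc",
    "IccResult",
    "agreement_report",
]


@dataclass
class AdcMap:
    """Per-pixel ADC values (mm^2/s) with a validity mask and the b-pair."""

    values: np.ndarray
    validity_mask: np.ndarray
    b_pair: tuple[float, float]

    def __post_init__(self):
        if self.values.shape != self.validity_mask.shape:
            raise ValueError("values and validity_mask must share a shape")
        if self.b_pair[1] <= self.b_pair[0]:
            raise ValueError("b_high must exceed b_low")
        if not np.isfinite(self.values[self.validity_mask]).all():
            raise ValueError("ADC values must be finite on the validity mask")


@dataclass
class RoiCircle:
    """Circular region of interest in pixel coordinates."""

    center: tuple[float, float]  # (row, col)
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


READER_TABLE_COLUMNS = [
    "subject_id",
    "tissue",
    "reader_id",
    "session",
    "repetition",
    "mean_adc",
]


def compute_adc(s_low, s_high, eps_fraction: float = 1e-6) -> AdcMap:
    """Two-point ADC map from DWI slices at b_low < b_high.

    Pixels where either signal is <= eps_fraction * max_intensity are
    marked invalid (value NaN) rather than clamped.
    """
    if s_low.pixels.shape != s_high.pixels.shape:
        raise ValueError("slices must share a shape")
    b_low, b_high = float(s_low.b_value), float(s_high.b_value)
    if b_high <= b_low:
        raise ValueError(f"b_high ({b_high}) must exceed b_low ({b_low})")
    eps = eps_fraction * max(s_low.max_intensity, s_high.max_intensity)
    valid = (s_low.pixels > eps) & (s_high.pixels > eps)
    values = np.full(s_low.pixels.shape, np.nan)
    values[valid] = np.log(s_low.pixels[valid] / s_high.pixels[valid]) / (b_high - b_low)
    return AdcMap(values=values, validity_mask=valid, b_pair=(b_low, b_high))


def roi_mean(adc: AdcMap, roi: RoiCircle) -> float:
    """Mean ADC over valid pixels whose centers lie strictly inside the circle."""
    h, w = adc.values.shape
    rr, cc = np.mgrid[0:h, 0:w]
    inside = (rr - roi.center[0]) ** 2 + (cc - roi.center[1]) ** 2 < roi.radius**2
    sel = inside & adc.validity_mask
    if not sel.any():
        raise ValueError("ROI contains no valid ADC pixels")
    return float(adc.values[sel].mean())


def simulate_reader_measurements(
    truth: np.ndarray,
    sigma_reader: float,
    sigma_repeat: float,
    n_subjects: int | None = None,
    seed: int = 0,
    n_readers: int = 2,
    n_sessions: int = 2,
    n_repetitions: int = 3,
    sigma_session: float = 0.0,
    tissue: str = "lesion",
) -> pd.DataFrame:
    """Synthetic stand-in for the human ROI-measurement protocol.

    Each recorded value decomposes as

        mean_adc = truth[subject] + bias[reader] + shift[reader, session]
                   + noise[repetition]

    with bias ~ N(0, sigma_reader^2), shift ~ N(0, sigma_session^2) and
    noise ~ N(0, sigma_repeat^2), all seeded.  Returns a long-format
    table with columns ``subject_id, tissue, reader_id, session,
    repetition, mean_adc``.
    """
    truth = np.asarray(truth, dtype=np.float64)
    if n_subjects is None:
        n_subjects = len(truth)
    if n_subjects > len(truth):
        raise ValueError("n_subjects exceeds the number of truth values")
    rng = np.random.default_rng(seed)
    bias = rng.normal(0.0, sigma_reader, size=n_readers)
    shift = rng.normal(0.0, sigma_session, size=(n_readers, n_sessions))
    rows = []
    for s, r, sess in product(range(n_subjects), range(n_readers), range(n_sessions)):
        for rep in range(n_repetitions):
            rows.append(
                {
                    "subject_id": s,
                    "tissue": tissue,
                    "reader_id": r + 1,
                    "session": sess + 1,
                    "repetition": rep + 1,
                    "mean_adc": truth[s]
                    + bias[r]
                    + shift[r, sess]
                    + rng.normal(0.0, sigma_repeat),
                }
            )
    return pd.DataFrame(rows, columns=READER_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------


@dataclass
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int

    def __str__(self):
        return f"{self.estimate:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f})"


def _icc21_from_matrix(y: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(2,1) and Shrout-Fleiss CI from an n x k subject-by-rater matrix."""
    n, k = y.shape
    if n < 5 or k < 2:
        raise ValueError(f"need >= 5 subjects and >= 2 raters, got {n} x {k}")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)  # between subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)  # between raters
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse_ = sse / ((n - 1) * (k - 1))
    est = (msb - mse_) / (msb + (k - 1) * mse_ + k * (msc - mse_) / n)

    # Shrout & Fleiss F-based interval for the absolute-agreement single-score ICC
    a = k * est / (n * (1.0 - est)) if est < 1.0 else np.inf
    b = 1.0 + k * est * (n - 1.0) / (n * (1.0 - est)) if est < 1.0 else np.inf
    if np.isfinite(a) and np.isfinite(b) and mse_ > 0:
        v = (a * msc + b * mse_) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse_) ** 2 / ((n - 1) * (k - 1))
        )
        f_star = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_star2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msb - f_star * mse_) / (
            f_star * (k * msc + (k * n - k - n) * mse_) + n * msb
        )
        upper = n * (f_star2 * msb - mse_) / (
            k * msc + (k * n - k - n) * mse_ + n * f_star2 * msb
        )
    else:
        lower = upper = est  # degenerate: no residual variance
    return IccResult(float(est), float(lower), float(upper), n, k)


def _cell_means(table: pd.DataFrame, rater_col: str) -> np.ndarray:
    """Average repetitions into one value per (subject, rater); verify balance."""
    cells = table.groupby(["subject_id", rater_col])["mean_adc"].mean().unstack(rater_col)
    if cells.isna().any().any():
        raise ValueError(
            "unbalanced reader table; missing cells: "
            + ", ".join(
                f"subject {cells.index[s]}, {rater_col} {cells.columns[r]}"
                for s, r in zip(*np.where(cells.isna().to_numpy()))
            )
        )
    return cells.to_numpy()


def icc(table: pd.DataFrame, design: str, reader_id=None, alpha: float = 0.05) -> IccResult:
    """ICC(2,1) for one of the two study designs.

    ``design='between_readers'``: consistency of different readers'
    first-session measurements (raters = readers, session 1 only).
    ``design='within_reader'``: repeatability of one reader across the
    two sessions (raters = sessions); pass ``reader_id`` if the table
    contains several readers.
    """
    missing_cols = set(READER_TABLE_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"reader table missing columns: {sorted(missing_cols)}")
    if design == "between_readers":
        sub = table[table.session == 1]
        y = _cell_means(sub, "reader_id")
    elif design == "within_reader":
        sub = table
        if reader_id is not None:
            sub = table[table.reader_id == reader_id]
        if sub.reader_id.nunique() != 1:
            raise ValueError(
                "within_reader design needs a single reader; pass reader_id="
                f"{sorted(table.reader_id.unique())}"
            )
        y = _cell_means(sub, "session")
    else:
        raise ValueError(f"unknown design {design!r}")
    return _icc21_from_matrix(y, alpha=alpha)


def agreement_report(b_table: pd.DataFrame, s_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Consistency/repeatability grids for reference (b) and synthetic (s) ADC.

    Returns ``{"between_readers": ..., "within_reader": ...}``: the first
    grid holds one between-reader ICC per tissue per dataset; the second
    one within-reader ICC per (reader, tissue) per dataset.  Entries are
    formatted ``estimate (ci_low-ci_high)``; the raw results are in the
    ``*_raw`` frames.
    """
    tables = {"b-ADC": b_table, "s-ADC": s_table}
    tissues = sorted(set(b_table.tissue) | set(s_table.tissue))

    between_raw, within_raw = [], []
    for ds_name, tab in tables.items():
        for tissue in tissues:
            sub = tab[tab.tissue == tissue]
            res = icc(sub, "between_readers")
            between_raw.append(
                {"dataset": ds_name, "tissue": tissue, "icc": res.estimate,
                 "ci_low": res.ci_low, "ci_high": res.ci_high}
            )
            for reader in sorted(sub.reader_id.unique()):
                res = icc(sub, "within_reader", reader_id=reader)
                within_raw.append(
                    {"dataset": ds_name, "reader": reader, "tissue": tissue,
                     "icc": res.estimate, "ci_low": res.ci_low, "ci_high": res.ci_high}
                )

    between_df = pd.DataFrame(between_raw)
    within_df = pd.DataFrame(within_raw)

    def fmt(df, index_cols):
        out = df.copy()
        out["cell"] = [
            f"{r.icc:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})" for r in df.itertuples()
        ]
        return out.pivot(index=index_cols, columns="dataset", values="cell")

    return {
        "between_readers": fmt(between_df, ["tissue"]),
        "within_reader": fmt(within_df, ["reader", "tissue"]),
        "between_readers_raw": between_df,
        "within_reader_raw": within_df,
    }
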