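"""Image-quality evaluation: MSE, PSNR, SSIM, FSIM and their
lesion-weighted variants WMSE/WPSNR.

The weighted metrics take a :class:`WeightMatrix` — a nonnegative
per-pixel weight grid summing to one — so clinically important regions
(the tumor) can dominate the score the way an expert reader's attention
does.  With uniform weights WMSE/WPSNR reduce exactly to MSE/PSNR.

SSIM follows the original definition (11x11 Gaussian window, sigma 1.5,
K1 = 0.01, K2 = 0.03, no sample-covariance correction).  FSIM combines
phase-congruency similarity with gradient-magnitude similarity, pooled
over the pixels where phase congruency is strongest:

    FSIM = sum(S_PC * S_G * PCm) / sum(PCm),   PCm = max(PC1, PC2)

with phase congruency computed from a 4-scale x 4-orientation log-Gabor
filter bank and the gradient from the Scharr operator; the stabilization
constants (T1 = 0.85, T2 = 160) are defined on the 0-255 intensity
scale, so inputs are rescaled internally.  Only the luminance channel
exists for grayscale DWI, so no chromatic term is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import correlate
from scipy.signal import convolve2d

__all__ = [
    "WeightMatrix",
    "weight_from_mask",
    "mse",
    "wmse",
    "psnr",
    "wpsnr",
    "ssim",
    "fsim",
    "phase_congruency",
    "MetricsReport",
    "evaluate_folder",
]


# ---------------------------------------------------------------------------
# weight matrices
# ---------------------------------------------------------------------------


@dataclass
class WeightMatrix:
    """Nonnegative per-pixel weights summing to one."""

    weights: np.ndarray
    provenance: str = "custom"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1 (got {total!r})")

    @classmethod
    def uniform(cls, shape) -> "WeightMatrix":
        n = int(np.prod(shape))
        return cls(np.full(shape, 1.0 / n), provenance="uniform")


def weight_from_mask(lesion_mask: np.ndarray, ratio: float = 4.0) -> WeightMatrix:
    """Weight matrix giving lesion pixels ``ratio`` times the weight of
    background pixels, normalized to sum 1.  An empty mask or ratio 1
    yields the uniform matrix."""
    mask = np.asarray(lesion_mask, dtype=bool)
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    w = np.where(mask, ratio, 1.0)
    return WeightMatrix(w / w.sum(), provenance=f"lesion_mask(ratio={ratio:g})")


# ---------------------------------------------------------------------------
# pixelwise metrics
# ---------------------------------------------------------------------------


def _check_pair(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"image shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x, y) -> float:
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def wmse(x, y, weight: WeightMatrix) -> float:
    x, y = _check_pair(x, y)
    if weight.weights.shape != x.shape:
        raise ValueError("weight matrix shape must match the images")
    return float(np.sum(weight.weights * (x - y) ** 2))


def psnr(x, y, data_range: float) -> float:
    """10 log10(MAX^2 / MSE); identical images give +inf."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    err = mse(x, y)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / err))


def wpsnr(x, y, weight: WeightMatrix, data_range: float) -> float:
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    err = wmse(x, y, weight)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / err))


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


def _gaussian_kernel1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def ssim(
    x,
    y,
    data_range: float,
    k1: float = 0.01,
    k2: float = 0.03,
    sigma: float = 1.5,
    win_size: int = 11,
) -> float:
    """Mean structural similarity with a Gaussian window.

    Local means/variances are Gaussian-weighted (sigma 1.5 over an 11x11
    window); the mean is taken over the interior region unaffected by the
    window radius.  Result lies in [-1, 1]; ssim(x, x) = 1.
    """
    x, y = _check_pair(x, y)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    radius = (win_size - 1) // 2
    if min(x.shape) < win_size:
        raise ValueError(f"images smaller than the {win_size}x{win_size} SSIM window")
    k1d = _gaussian_kernel1d(sigma, radius)
    kernel = np.outer(k1d, k1d)

    def filt(img):
        return correlate(img, kernel, mode="nearest")

    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    return float(s[radius:-radius, radius:-radius].mean())


# ---------------------------------------------------------------------------
# FSIM
# ---------------------------------------------------------------------------


def _lowpass_filter(shape, cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    radius = _radial_grids(shape)[0]
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def _freq_range(n: int) -> np.ndarray:
    if n % 2:
        return np.arange(-(n - 1) // 2, (n - 1) // 2 + 1) / (n - 1)
    return np.arange(-n // 2, n // 2) / n


def _radial_grids(shape):
    rows, cols = shape
    x, y = np.meshgrid(_freq_range(cols), _freq_range(rows))
    radius = np.fft.ifftshift(np.sqrt(x**2 + y**2))
    theta = np.fft.ifftshift(np.arctan2(-y, x))
    radius[0, 0] = 1.0  # avoid log(0) at DC; the DC gain is zeroed anyway
    return radius, theta


def phase_congruency(
    img: np.ndarray,
    nscale: int = 4,
    norient: int = 4,
    min_wavelength: float = 6.0,
    mult: float = 2.0,
    sigma_onf: float = 0.55,
    d_theta_on_sigma: float = 1.2,
    k: float = 2.0,
    epsilon: float = 1e-4,
) -> np.ndarray:
    """Phase-congruency map from a log-Gabor filter bank.

    Accumulates, over orientations, local energy (with an estimated
    Rayleigh noise threshold subtracted) against the total filter
    response amplitude.  Values lie in [0, 1]; high values mark edges and
    lines regardless of their contrast.
    """
    img = np.asarray(img, dtype=np.float64)
    if min(img.shape) < min_wavelength:
        raise ValueError(
            f"image {img.shape} smaller than the minimum filter wavelength {min_wavelength}"
        )
    rows, cols = img.shape
    imfft = np.fft.fft2(img)
    radius, theta = _radial_grids(img.shape)
    sintheta, costheta = np.sin(theta), np.cos(theta)
    lp = _lowpass_filter(img.shape)

    log_gabors = []
    for s in range(nscale):
        fo = 1.0 / (min_wavelength * mult**s)
        lg = np.exp(-(np.log(radius / fo) ** 2) / (2 * np.log(sigma_onf) ** 2)) * lp
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    theta_sigma = np.pi / norient / d_theta_on_sigma
    total_energy = np.zeros(img.shape)
    total_sum_an = np.zeros(img.shape)
    for o in range(norient):
        angl = o * np.pi / norient
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * theta_sigma**2))

        sum_e = np.zeros(img.shape)
        sum_o = np.zeros(img.shape)
        sum_an = np.zeros(img.shape)
        e_parts, o_parts = [], []
        tau = 0.0
        for s in range(nscale):
            eo = np.fft.ifft2(imfft * log_gabors[s] * spread)
            an = np.abs(eo)
            sum_an += an
            sum_e += eo.real
            sum_o += eo.imag
            e_parts.append(eo.real)
            o_parts.append(eo.imag)
            if s == 0:
                tau = np.median(an) / np.sqrt(np.log(4))
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + epsilon
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros(img.shape)
        for e_s, o_s in zip(e_parts, o_parts):
            energy += e_s * mean_e + o_s * mean_o - np.abs(e_s * mean_o - o_s * mean_e)
        # Rayleigh-based estimate of the noise energy floor
        total_tau = tau * (1.0 - (1.0 / mult) ** nscale) / (1.0 - 1.0 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        t = (noise_mean + k * noise_sigma) / 1.7  # empirical filter-overlap factor
        energy = np.maximum(energy - t, 0.0)
        total_energy += energy
        total_sum_an += sum_an
    return total_energy / (total_sum_an + epsilon)


_SCHARR_X = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = convolve2d(img, _SCHARR_X, mode="same")
    gy = convolve2d(img, _SCHARR_X.T, mode="same")
    return np.sqrt(gx**2 + gy**2)


def fsim(
    x,
    y,
    data_range: float,
    t1: float = 0.85,
    t2: float = 160.0,
) -> float:
    """Feature similarity index in [0, 1]; fsim(x, x) = 1.

    Images are rescaled to 0-255 (where the published constants live),
    downsampled by round(min(H, W)/256) with box averaging when large,
    and compared via phase congruency and Scharr gradient magnitude.
    """
    x, y = _check_pair(x, y)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    x = x * (255.0 / data_range)
    y = y * (255.0 / data_range)

    f = max(1, int(round(min(x.shape) / 256.0)))
    if f > 1:
        kernel = np.ones((f, f)) / (f * f)
        x = convolve2d(x, kernel, mode="same")[::f, ::f]
        y = convolve2d(y, kernel, mode="same")[::f, ::f]

    pc1 = phase_congruency(x)
    pc2 = phase_congruency(y)
    g1 = _gradient_magnitude(x)
    g2 = _gradient_magnitude(y)
    s_pc = (2 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_g = (2 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    pcm = np.maximum(pc1, pc2)
    return float(np.sum(s_pc * s_g * pcm) / np.sum(pcm))


# ---------------------------------------------------------------------------
# batch evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-image metric rows plus aggregates recomputable from the rows."""

    per_image: pd.DataFrame
    aggregates: pd.DataFrame
    tests: dict = field(default_factory=dict)

    def save_csv(self, path) -> None:
        self.per_image.to_csv(path, index=False)


_METRIC_COLUMNS = ["psnr", "mse", "wpsnr", "wmse", "ssim", "fsim"]


def _metric_row(pred: np.ndarray, ref: np.ndarray, weight: WeightMatrix, data_range: float) -> dict:
    return {
        "psnr": psnr(pred, ref, data_range),
        "mse": mse(pred, ref),
        "wpsnr": wpsnr(pred, ref, weight, data_range),
        "wmse": wmse(pred, ref, weight),
        "ssim": ssim(pred, ref, data_range),
        "fsim": fsim(pred, ref, data_range),
    }


def evaluate_folder(
    pred_dir,
    ref_dir,
    baseline_dir=None,
    mask_dir=None,
    weight_ratio: float = 4.0,
    data_range: float = 65535.0,
    out_csv=None,
    violin_png=None,
) -> MetricsReport:
    """Score every image in ``pred_dir`` against its same-named reference.

    When ``baseline_dir`` is given (the acquired lower-b images), the same
    metrics are computed for baseline-vs-reference and a paired Wilcoxon
    signed-rank test compares the two sets per metric.  Lesion masks (PNG,
    nonzero = lesion) drive the weighted metrics; without masks the
    weight matrix is uniform and WPSNR/WMSE equal PSNR/MSE.
    """
    from .cli_io import read_png

    pred_dir, ref_dir = Path(pred_dir), Path(ref_dir)
    rows = []
    names = sorted(p.name for p in pred_dir.glob("*.png"))
    if not names:
        raise ValueError(f"no PNG images found in {pred_dir}")
    for name in names:
        ref_path = ref_dir / name
        if not ref_path.exists():
            raise FileNotFoundError(f"reference image missing for {name}")
        pred = read_png(pred_dir / name)[0]
        ref = read_png(ref_path)[0]
        if mask_dir is not None and (Path(mask_dir) / name).exists():
            mask = read_png(Path(mask_dir) / name)[0] > 0
            weight = weight_from_mask(mask, weight_ratio)
        else:
            weight = WeightMatrix.uniform(ref.shape)
        row = {"image": name, "comparison": "pred_vs_ref"}
        row.update(_metric_row(pred, ref, weight, data_range))
        rows.append(row)
        if baseline_dir is not None:
            base = read_png(Path(baseline_dir) / name)[0]
            row = {"image": name, "comparison": "baseline_vs_ref"}
            row.update(_metric_row(base, ref, weight, data_range))
            rows.append(row)

    per_image = pd.DataFrame(rows)
    agg_rows = []
    for comp, df in per_image.groupby("comparison"):
        row = {"comparison": comp}
        for m in _METRIC_COLUMNS:
            v = df[m]
            row[f"{m}_mean"] = v.mean()
            row[f"{m}_median"] = v.median()
            row[f"{m}_q1"] = v.quantile(0.25)
            row[f"{m}_q3"] = v.quantile(0.75)
        agg_rows.append(row)
    agg = pd.DataFrame(agg_rows).set_index("comparison")
    tests = {}
    if baseline_dir is not None:
        from scipy.stats import wilcoxon

        a = per_image[per_image.comparison == "pred_vs_ref"].set_index("image")
        b = per_image[per_image.comparison == "baseline_vs_ref"].set_index("image")
        for m in _METRIC_COLUMNS:
            pa, pb = a[m].to_numpy(), b.loc[a.index, m].to_numpy()
            finite = np.isfinite(pa) & np.isfinite(pb)
            if finite.sum() >= 5 and not np.allclose(pa[finite], pb[finite]):
                tests[m] = float(wilcoxon(pa[finite], pb[finite]).pvalue)

    report = MetricsReport(per_image=per_image, aggregates=agg, tests=tests)
    if out_csv is not None:
        report.save_csv(out_csv)
    if violin_png is not None:
        _violin_plot(per_image, violin_png)
    return report


def _violin_plot(per_image: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comparisons = per_image.comparison.unique()
    fig, axes = plt.subplots(1, len(_METRIC_COLUMNS), figsize=(3 * len(_METRIC_COLUMNS), 3))
    for ax, m in zip(np.atleast_1d(axes), _METRIC_COLUMNS):
        data = [
            per_image.loc[per_image.comparison == c, m].replace([np.inf, -np.inf], np.nan).dropna()
            for c in comparisons
        ]
        if all(len(d) for d in data):
            ax.violinplot(data, showmedians=True)
        ax.set_title(m.upper())
        ax.set_xticks(range(1, len(comparisons) + 1))
        ax.set_xticklabels(comparisons, rotation=45, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
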