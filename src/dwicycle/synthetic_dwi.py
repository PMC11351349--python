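"""Physics-grounded abdominal DWI phantom generator.

Produces seeded 2D phantoms of the upper abdomen — an elliptical stomach
(water-filled lumen inside a wall annulus), a tumor arc embedded in the
wall, perigastric lymph nodes and a liver region — and simulates
diffusion-weighted acquisitions of them under the mono-exponential decay
model S(b) = S0 * exp(-b * ADC).  Tumor tissue restricts diffusion, so it
keeps a high signal at high b-value while free water in the lumen is
suppressed; that contrast is the whole point of high-b DWI and is what
the default tissue table reproduces.

Magnitude-MRI noise is Rician: each pixel v becomes
sqrt((v+n1)^2 + n2^2) with n1, n2 ~ N(0, sigma^2).  The noise level per
b-value scales as base_sigma / sqrt(number of averages), mirroring the
averages ladder of a clinical protocol (2/4/6 averages at b=50/800/1200).
Echo-planar geometric distortion is emulated by a smooth random
displacement field along the phase-encode axis.

``make_dataset`` writes the two unpaired training domains (A: noisy,
optionally distorted b=800; B: cleaner b=1200) plus a hidden folder of
paired noiseless ground truth for evaluation, all reproducible from a
single manifest seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .cli_io import DatasetManifest, derive_seed, write_nifti, write_png

__all__ = [
    "Tissue",
    "DEFAULT_TISSUE_TABLE",
    "PhantomScene",
    "DwiSlice",
    "AcquisitionSpec",
    "SimulateConfig",
    "generate_scene",
    "simulate_signal",
    "add_rician_noise",
    "make_displacement_field",
    "apply_displacement",
    "apply_distortion",
    "make_dataset",
]


class Tissue(IntEnum):
    BACKGROUND = 0
    LIVER = 1
    STOMACH_WALL = 2
    LUMEN_WATER = 3
    LESION = 4
    LYMPH_NODE = 5


#: (S0 in arbitrary signal units, ADC in mm^2/s).  Free water diffuses
#: fastest; tumor restricts diffusion most among soft tissues, giving it
#: the highest relative signal at high b-value.  Overridable per call.
DEFAULT_TISSUE_TABLE: dict[Tissue, tuple[float, float]] = {
    Tissue.LUMEN_WATER: (1.0, 3.0e-3),
    Tissue.LIVER: (0.8, 1.2e-3),
    Tissue.STOMACH_WALL: (0.7, 1.6e-3),
    Tissue.LESION: (0.9, 0.9e-3),
    Tissue.LYMPH_NODE: (0.85, 1.0e-3),
    Tissue.BACKGROUND: (0.05, 2.0e-3),
}


@dataclass
class PhantomScene:
    """Tissue-label grid with per-pixel S0 and ADC maps (the hidden truth)."""

    labels: np.ndarray  # int grid (H, W) of Tissue codes
    s0_map: np.ndarray  # signal units, >= 0
    adc_map: np.ndarray  # mm^2/s, >= 0
    tissue_table: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_TABLE))

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.labels == Tissue.LESION

    def __post_init__(self):
        if self.s0_map.shape != self.labels.shape or self.adc_map.shape != self.labels.shape:
            raise ValueError("s0_map and adc_map must have the same shape as labels")
        if (self.s0_map < 0).any() or (self.adc_map < 0).any():
            raise ValueError("S0 and ADC maps must be nonnegative")
        tt = self.tissue_table
        if not (
            tt[Tissue.LUMEN_WATER][1] > tt[Tissue.STOMACH_WALL][1] > tt[Tissue.LESION][1]
        ):
            raise ValueError(
                "tissue table must satisfy ADC(lumen_water) > ADC(stomach_wall) > ADC(lesion)"
            )


@dataclass
class DwiSlice:
    """A single 2D diffusion-weighted image with its acquisition b-value."""

    pixels: np.ndarray
    b_value: float
    max_intensity: float = 1.0
    subject_id: str = "phantom"
    slice_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.isfinite(self.pixels).all():
            raise ValueError("DwiSlice pixels must be finite everywhere")
        if self.b_value < 0:
            raise ValueError("b_value must be nonnegative")


@dataclass
class AcquisitionSpec:
    """Acquisition protocol: b-values, averages per b-value, base noise and
    distortion levels, image size and the manifest seed.

    Defaults mirror a clinical gastric protocol: b = 50/800/1200 s/mm^2
    acquired with 2/4/6 averages; noise per b-value is
    ``base_noise_sigma / sqrt(averages)``.
    """

    b_values: tuple = (50.0, 800.0, 1200.0)
    averages: tuple = (2, 4, 6)
    base_noise_sigma: float = 0.10
    distortion_amplitude: float = 1.0
    image_size: tuple = (256, 256)
    seed: int = 0

    def __post_init__(self):
        self.b_values = tuple(float(b) for b in self.b_values)
        self.averages = tuple(int(a) for a in self.averages)
        if len(self.averages) != len(self.b_values):
            raise ValueError("averages must list one entry per b-value")
        if any(a < 1 for a in self.averages):
            raise ValueError("averages must be positive integers")
        if self.base_noise_sigma < 0 or self.distortion_amplitude < 0:
            raise ValueError("noise sigma and distortion amplitude must be >= 0")

    def effective_sigma(self, b: float) -> float:
        i = self.b_values.index(float(b))
        return self.base_noise_sigma / np.sqrt(self.averages[i])


@dataclass
class SimulateConfig:
    """Dataset-level knobs for the ``simulate`` pipeline stage."""

    n_train_subjects: int = 30
    n_test_subjects: int = 10
    slices_min: int = 5
    slices_max: int = 15
    lesion_extent: float = 0.2
    max_lymph_nodes: int = 3
    save_nifti_truth: bool = False
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)


# ---------------------------------------------------------------------------
# scene geometry
# ---------------------------------------------------------------------------


def _ellipse_mask(h, w, cy, cx, ry, rx):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_scene(
    size: tuple[int, int],
    n_lymph_nodes: int,
    lesion_extent: float,
    seed: int,
    tissue_table: dict | None = None,
    jitter: float = 0.05,
) -> PhantomScene:
    """Build a seeded abdominal phantom scene.

    Parameters
    ----------
    size
        (H, W) grid size; both must be >= 32 so all structures fit.
    n_lymph_nodes
        Number of circular perigastric lymph nodes to place.
    lesion_extent
        Angular fraction of the stomach wall occupied by the tumor arc,
        in (0, 0.5).
    seed
        Seed for all geometric and tissue-parameter jitter.
    """
    h, w = int(size[0]), int(size[1])
    if h < 32 or w < 32:
        raise ValueError(f"scene size {size} too small: both dimensions must be >= 32")
    if not (0.0 < lesion_extent < 0.5):
        raise ValueError("lesion_extent must lie in (0, 0.5)")
    if n_lymph_nodes < 0:
        raise ValueError("n_lymph_nodes must be >= 0")
    table = dict(tissue_table if tissue_table is not None else DEFAULT_TISSUE_TABLE)
    rng = np.random.default_rng(seed)

    labels = np.full((h, w), Tissue.BACKGROUND, dtype=np.int64)

    # liver: large ellipse in the upper-left quadrant
    l_cy = (0.30 + 0.04 * rng.uniform(-1, 1)) * h
    l_cx = (0.28 + 0.04 * rng.uniform(-1, 1)) * w
    liver = _ellipse_mask(h, w, l_cy, l_cx, 0.24 * h, 0.26 * w)
    labels[liver] = Tissue.LIVER

    # stomach: outer ellipse = wall, inner ellipse = water-filled lumen
    s_cy = (0.58 + 0.03 * rng.uniform(-1, 1)) * h
    s_cx = (0.60 + 0.03 * rng.uniform(-1, 1)) * w
    s_ry = 0.20 * h * (1 + 0.1 * rng.uniform(-1, 1))
    s_rx = 0.23 * w * (1 + 0.1 * rng.uniform(-1, 1))
    thickness = max(2.0, 0.06 * min(h, w))
    in_ry, in_rx = s_ry - thickness, s_rx - thickness
    if in_ry < 1.5 or in_rx < 1.5:
        raise ValueError(
            f"scene size {size} too small to place structure 'stomach lumen' "
            f"(inner radii {in_ry:.1f}x{in_rx:.1f} px)"
        )
    outer = _ellipse_mask(h, w, s_cy, s_cx, s_ry, s_rx)
    inner = _ellipse_mask(h, w, s_cy, s_cx, in_ry, in_rx)
    wall = outer & ~inner
    labels[wall] = Tissue.STOMACH_WALL
    labels[inner] = Tissue.LUMEN_WATER

    # lesion: an angular arc of the wall annulus
    theta0 = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.mod(np.arctan2(yy - s_cy, xx - s_cx) - theta0, 2 * np.pi)
    sector = theta <= lesion_extent * 2 * np.pi
    lesion = wall & sector
    if not lesion.any():
        raise ValueError(f"scene size {size} too small to place structure 'lesion'")
    labels[lesion] = Tissue.LESION

    # lymph nodes: small circles in the fat outside stomach and liver
    placed = 0
    margin = 1.2
    for _ in range(400):
        if placed >= n_lymph_nodes:
            break
        r = max(1.6, (0.025 + 0.015 * rng.uniform()) * min(h, w))
        cy = rng.uniform(r + 1, h - r - 2)
        cx = rng.uniform(r + 1, w - r - 2)
        # keep clear of the stomach so nodes stay resolvable structures
        if ((cy - s_cy) / (s_ry * margin)) ** 2 + ((cx - s_cx) / (s_rx * margin)) ** 2 <= 1.0:
            continue
        node = _ellipse_mask(h, w, cy, cx, r, r)
        if (labels[node] != Tissue.BACKGROUND).any():
            continue
        labels[node] = Tissue.LYMPH_NODE
        placed += 1
    if placed < n_lymph_nodes:
        raise ValueError(
            f"scene size {size} too small to place structure 'lymph_node' "
            f"({placed} of {n_lymph_nodes} placed)"
        )

    # per-scene tissue-parameter jitter (biological variability)
    s0_map = np.zeros((h, w))
    adc_map = np.zeros((h, w))
    jittered = {}
    for tissue in Tissue:
        s0, adc = table[tissue]
        f_s0 = float(np.clip(1 + jitter * rng.normal(), 0.8, 1.2))
        f_adc = float(np.clip(1 + jitter * rng.normal(), 0.8, 1.2))
        jittered[tissue] = (s0 * f_s0, adc * f_adc)
        mask = labels == tissue
        s0_map[mask] = s0 * f_s0
        adc_map[mask] = adc * f_adc
    # keep the documented ADC ordering strict even under jitter
    if not (
        jittered[Tissue.LUMEN_WATER][1]
        > jittered[Tissue.STOMACH_WALL][1]
        > jittered[Tissue.LESION][1]
    ):
        jittered = {t: (jittered[t][0], table[t][1]) for t in Tissue}
        for tissue in Tissue:
            adc_map[labels == tissue] = table[tissue][1]

    return PhantomScene(labels=labels, s0_map=s0_map, adc_map=adc_map, tissue_table=table)


# ---------------------------------------------------------------------------
# signal model and artifacts
# ---------------------------------------------------------------------------


def simulate_signal(
    scene: PhantomScene, b: float, subject_id: str = "phantom", slice_index: int = 0
) -> DwiSlice:
    """Noiseless mono-exponential DWI signal: S(b) = S0 * exp(-b * ADC)."""
    if b < 0:
        raise ValueError("b-value must be nonnegative")
    pixels = scene.s0_map * np.exp(-float(b) * scene.adc_map)
    return DwiSlice(
        pixels=pixels,
        b_value=float(b),
        max_intensity=float(scene.s0_map.max()),
        subject_id=subject_id,
        slice_index=slice_index,
    )


def add_rician_noise(slice_: DwiSlice, sigma: float, seed: int) -> DwiSlice:
    """Magnitude-MRI (Rician) noise: v -> sqrt((v+n1)^2 + n2^2)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return replace(slice_, pixels=slice_.pixels.copy())
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=slice_.pixels.shape)
    n2 = rng.normal(0.0, sigma, size=slice_.pixels.shape)
    noisy = np.sqrt((slice_.pixels + n1) ** 2 + n2**2)
    return replace(slice_, pixels=noisy)


def make_displacement_field(shape: tuple[int, int], amplitude: float, seed: int) -> np.ndarray:
    """Smooth seeded displacement field along the phase-encode (column) axis,
    scaled so the maximum absolute displacement equals ``amplitude`` pixels."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    h, w = shape
    if amplitude == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=shape)
    smooth = gaussian_filter(raw, sigma=min(h, w) / 8.0, mode="reflect")
    return smooth * (amplitude / np.max(np.abs(smooth)))


def apply_displacement(pixels: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Warp a slice by a per-pixel column displacement (bilinear sampling)."""
    h, w = pixels.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return map_coordinates(pixels, [yy, xx + field], order=1, mode="nearest")


def apply_distortion(slice_: DwiSlice, amplitude: float, seed: int) -> DwiSlice:
    """EPI-like geometric distortion; ``amplitude`` is the max displacement
    in pixels, 0 is the identity."""
    field = make_displacement_field(slice_.pixels.shape, amplitude, seed)
    if amplitude == 0:
        return replace(slice_, pixels=slice_.pixels.copy())
    return replace(slice_, pixels=apply_displacement(slice_.pixels, field))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

_B_DOMAIN_A = 800.0
_B_DOMAIN_B = 1200.0
_B_LOW = 50.0


def make_dataset(
    n_train_subjects: int,
    n_test_subjects: int,
    slices_per_subject: tuple[int, int],
    spec: AcquisitionSpec,
    out_dir,
    lesion_extent: float = 0.2,
    max_lymph_nodes: int = 3,
    save_nifti_truth: bool = False,
) -> DatasetManifest:
    """Generate and write an unpaired two-domain phantom dataset.

    Layout under ``out_dir``: ``trainA``/``testA`` hold the noisy,
    optionally distorted b=800 slices; ``trainB``/``testB`` the cleaner
    b=1200 slices; ``truth`` holds paired noiseless b=1200 and b=50
    slices (evaluation only — training code must never read it).  A
    ``manifest.yaml`` records the seed, parameters, per-file checksums,
    the global intensity maximum used for 16-bit quantization, and the
    A-domain -> truth pairing.

    All randomness derives from ``spec.seed`` through a per-(subject,
    slice, purpose) hash, so an identical spec reproduces the dataset
    byte for byte.
    """
    lo, hi = int(slices_per_subject[0]), int(slices_per_subject[1])
    if lo < 1 or hi < lo:
        raise ValueError("slices_per_subject must be a nonempty range (lo, hi)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_total = n_train_subjects + n_test_subjects
    records = []  # (relpath, pixels) deferred until global max is known
    pairing: dict[str, str] = {}

    for s in range(n_total):
        split = "train" if s < n_train_subjects else "test"
        rng_subj = np.random.default_rng(derive_seed(spec.seed, "subject", s))
        n_slices = int(rng_subj.integers(lo, hi + 1))
        n_nodes = int(rng_subj.integers(0, max_lymph_nodes + 1))
        extent = float(lesion_extent * (0.8 + 0.4 * rng_subj.uniform()))
        extent = min(extent, 0.49)
        for k in range(n_slices):
            scene = generate_scene(
                spec.image_size, n_nodes, extent, seed=derive_seed(spec.seed, "scene", s, k)
            )
            sid = f"{s:03d}"
            clean = {
                b: simulate_signal(scene, b, subject_id=sid, slice_index=k)
                for b in (_B_LOW, _B_DOMAIN_A, _B_DOMAIN_B)
            }
            # domain A: noisy + distorted b=800
            a_img = add_rician_noise(
                clean[_B_DOMAIN_A],
                spec.effective_sigma(_B_DOMAIN_A),
                seed=derive_seed(spec.seed, "noise", s, k, int(_B_DOMAIN_A)),
            )
            a_img = apply_distortion(
                a_img, spec.distortion_amplitude, seed=derive_seed(spec.seed, "warp", s, k)
            )
            # domain B: cleaner b=1200 (more averages, no distortion)
            b_img = add_rician_noise(
                clean[_B_DOMAIN_B],
                spec.effective_sigma(_B_DOMAIN_B),
                seed=derive_seed(spec.seed, "noise", s, k, int(_B_DOMAIN_B)),
            )
            stem = f"{sid}_{k:02d}"
            a_rel = f"{split}A/{stem}.png"
            records.append((a_rel, a_img.pixels))
            records.append((f"{split}B/{stem}.png", b_img.pixels))
            truth_b = f"truth/{stem}_b{int(_B_DOMAIN_B)}.png"
            truth_low = f"truth/{stem}_b{int(_B_LOW)}.png"
            records.append((truth_b, clean[_B_DOMAIN_B].pixels))
            records.append((truth_low, clean[_B_LOW].pixels))
            pairing[a_rel] = truth_b
            if save_nifti_truth:
                write_nifti(clean[_B_DOMAIN_B].pixels, out_dir / f"truth/{stem}_b{int(_B_DOMAIN_B)}.nii")
                write_nifti(clean[_B_LOW].pixels, out_dir / f"truth/{stem}_b{int(_B_LOW)}.nii")

    global_max = float(max(p.max() for _, p in records))
    manifest = DatasetManifest(
        seed=spec.seed,
        params={
            "n_train_subjects": n_train_subjects,
            "n_test_subjects": n_test_subjects,
            "slices_per_subject": [lo, hi],
            "b_values": list(spec.b_values),
            "averages": list(spec.averages),
            "base_noise_sigma": spec.base_noise_sigma,
            "distortion_amplitude": spec.distortion_amplitude,
            "image_size": list(spec.image_size),
            "lesion_extent": lesion_extent,
            "max_lymph_nodes": max_lymph_nodes,
        },
        global_max=global_max,
        pairing=pairing,
    )
    for rel, pixels in records:
        write_png(np.clip(pixels / global_max, 0, 1) * 65535, out_dir / rel, bit_depth=16)
        manifest.add_file(out_dir, rel)
    manifest.save(out_dir / "manifest.yaml")
    return manifest
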