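"""Independent reference implementation of FSIM for oracle testing.

A deliberately separate, loop-structured transcription of the published
feature-similarity algorithm (log-Gabor phase congruency + Scharr
gradient-magnitude similarity, pooled by maximum phase congruency).  It
shares no code with the package implementation; only the published
constants are common.
"""

import numpy as np

NSCALE = 4
NORIENT = 4
MIN_WAVELENGTH = 6.0
MULT = 2.0
SIGMA_ONF = 0.55
D_THETA_ON_SIGMA = 1.2
NOISE_K = 2.0
EPS = 1e-4
T1 = 0.85
T2 = 160.0


def _shifted_grid(n):
    # frequency axis per the published convention, built centered then rolled
    if n % 2 == 0:
        vals = np.arange(-n // 2, n // 2) / n
        return np.roll(vals, -(n // 2))
    vals = np.arange(-(n - 1) // 2, (n - 1) // 2 + 1) / (n - 1)
    return np.roll(vals, -((n - 1) // 2))


def _filter_bank(shape):
    rows, cols = shape
    fy = _shifted_grid(rows)[:, None] * np.ones((1, cols))
    fx = np.ones((rows, 1)) * _shifted_grid(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0
    angle = np.arctan2(-fy, fx)
    butterworth = 1.0 / (1.0 + (radius / 0.45) ** 30)

    bank = {}
    theta_sigma = np.pi / NORIENT / D_THETA_ON_SIGMA
    for s in range(NSCALE):
        wavelength = MIN_WAVELENGTH * MULT**s
        f0 = 1.0 / wavelength
        radial = np.exp(-(np.log(radius / f0)) ** 2 / (2.0 * np.log(SIGMA_ONF) ** 2))
        radial = radial * butterworth
        radial[0, 0] = 0.0
        for o in range(NORIENT):
            phi = o * np.pi / NORIENT
            ds = np.sin(angle) * np.cos(phi) - np.cos(angle) * np.sin(phi)
            dc = np.cos(angle) * np.cos(phi) + np.sin(angle) * np.sin(phi)
            dtheta = np.abs(np.arctan2(ds, dc))
            angular = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))
            bank[(s, o)] = radial * angular
    return bank


def phase_congruency_reference(img):
    img = np.asarray(img, dtype=np.float64)
    fimg = np.fft.fft2(img)
    bank = _filter_bank(img.shape)

    energy_total = np.zeros(img.shape)
    amplitude_total = np.zeros(img.shape)
    for o in range(NORIENT):
        responses = []
        for s in range(NSCALE):
            responses.append(np.fft.ifft2(fimg * bank[(s, o)]))
        amps = [np.abs(r) for r in responses]
        sum_re = sum(r.real for r in responses)
        sum_im = sum(r.imag for r in responses)
        denom = np.hypot(sum_re, sum_im) + EPS
        unit_re, unit_im = sum_re / denom, sum_im / denom
        energy = np.zeros(img.shape)
        for r in responses:
            energy += r.real * unit_re + r.imag * unit_im
            energy -= np.abs(r.real * unit_im - r.imag * unit_re)
        tau = np.median(amps[0]) / np.sqrt(np.log(4.0))
        tau_sum = tau * (1.0 - (1.0 / MULT) ** NSCALE) / (1.0 - 1.0 / MULT)
        mean_noise = tau_sum * np.sqrt(np.pi / 2.0)
        sd_noise = tau_sum * np.sqrt((4.0 - np.pi) / 2.0)
        threshold = (mean_noise + NOISE_K * sd_noise) / 1.7
        energy = np.clip(energy - threshold, 0.0, None)
        energy_total += energy
        amplitude_total += sum(amps)
    return energy_total / (amplitude_total + EPS)


def _conv_same_zero(img, kernel):
    # plain 'same' convolution with zero boundary, written out explicitly
    kh, kw = kernel.shape
    pad_r, pad_c = kh // 2, kw // 2
    padded = np.pad(img, ((pad_r, pad_r), (pad_c, pad_c)))
    out = np.zeros_like(img)
    flipped = kernel[::-1, ::-1]
    for i in range(kh):
        for j in range(kw):
            out += flipped[i, j] * padded[i : i + img.shape[0], j : j + img.shape[1]]
    return out


def gradient_magnitude_reference(img):
    gx_kernel = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0
    gx = _conv_same_zero(img, gx_kernel)
    gy = _conv_same_zero(img, gx_kernel.T)
    return np.hypot(gx, gy)


def fsim_reference(x, y, data_range):
    x = np.asarray(x, dtype=np.float64) * (255.0 / data_range)
    y = np.asarray(y, dtype=np.float64) * (255.0 / data_range)
    factor = max(1, int(round(min(x.shape) / 256.0)))
    if factor > 1:
        box = np.ones((factor, factor)) / factor**2
        x = _conv_same_zero(x, box)[::factor, ::factor]
        y = _conv_same_zero(y, box)[::factor, ::factor]
    pc1 = phase_congruency_reference(x)
    pc2 = phase_congruency_reference(y)
    g1 = gradient_magnitude_reference(x)
    g2 = gradient_magnitude_reference(y)
    s_pc = (2.0 * pc1 * pc2 + T1) / (pc1**2 + pc2**2 + T1)
    s_g = (2.0 * g1 * g2 + T2) / (g1**2 + g2**2 + T2)
    pc_max = np.maximum(pc1, pc2)
    return np.sum(s_pc * s_g * pc_max) / np.sum(pc_max)
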