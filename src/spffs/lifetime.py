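"""TCSPC decay histograms, mono-exponential lifetime fits and phasor analysis.

The photon microtimes (start–stop times) of a stream are histogrammed over
one laser period.  Lifetimes are extracted two ways:

* **tail fit** — least squares of A·exp(−t/τ) + B on a window starting
  0.5 ns after the histogram peak, which excludes the IRF-dominated rise;
* **phasor** — the first-harmonic Fourier coordinates
  g = Σcᵢcos(ωtᵢ)/Σcᵢ, s = Σcᵢsin(ωtᵢ)/Σcᵢ with ω = 2πn/T_rep.  A clean
  mono-exponential lands on the universal semicircle at
  (g, s) = (1/(1+(ωτ)²), ωτ/(1+(ωτ)²)); mixtures fall on the chord between
  their pure components.

Phasors are calibrated with a reference dye of known lifetime (a rotation
plus modulation scale undoing the IRF delay and broadening), and phasor
clouds of images are segmented by the side of the vertical line through the
cloud centroid: left of the centroid (smaller g) = longer lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .photon_stream import PhotonStream

__all__ = [
    "DecayHistogram",
    "LifetimeFit",
    "PhasorPoint",
    "PhasorCalibration",
    "decay_histogram",
    "histogram_from_microtimes",
    "fit_monoexp",
    "phasor",
    "phasor_image",
    "phasor_theoretical",
    "calibrate_phasor",
    "phasor_segment",
    "lifetime_map_tailfit",
    "phasor_lifetime_ns",
]


@dataclass
class DecayHistogram:
    """TCSPC histogram over one laser period."""

    edges_ns: np.ndarray
    counts: np.ndarray
    rep_period_ns: float
    source: str = ""

    @property
    def centers_ns(self) -> np.ndarray:
        return 0.5 * (self.edges_ns[:-1] + self.edges_ns[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class LifetimeFit:
    tau_ns: float
    tau_stderr_ns: float
    amplitude: float
    background: float
    window_ns: tuple


@dataclass
class PhasorPoint:
    g: float
    s: float
    counts: int = 0
    harmonic: int = 1
    calibrated: bool = False

    @property
    def modulus(self) -> float:
        return float(np.hypot(self.g, self.s))


def decay_histogram(
    stream: PhotonStream, n_bins: int = 256, selection: Optional[np.ndarray] = None
) -> DecayHistogram:
    """Histogram the (folded) microtimes of a stream over [0, T_rep)."""
    if not stream.has_microtimes:
        raise ValueError("stream has no microtimes; acquire in lifetime mode")
    micro = stream.microtimes_ns
    if selection is not None:
        micro = micro[selection]
    micro = micro[np.isfinite(micro)]
    t_rep = stream.laser.rep_period_ns
    return histogram_from_microtimes(micro, t_rep, n_bins, source=stream.volume or "")


def histogram_from_microtimes(
    microtimes_ns: np.ndarray, rep_period_ns: float, n_bins: int = 256, source: str = ""
) -> DecayHistogram:
    micro = np.mod(np.asarray(microtimes_ns, dtype=np.float64), rep_period_ns)
    counts, edges = np.histogram(micro, bins=n_bins, range=(0.0, rep_period_ns))
    return DecayHistogram(edges_ns=edges, counts=counts, rep_period_ns=rep_period_ns, source=source)


def _monoexp(t, A, tau, B):
    return A * np.exp(-t / tau) + B


def fit_monoexp(hist: DecayHistogram, window_ns: Optional[tuple] = None) -> LifetimeFit:
    """Tail fit A·exp(−t/τ) + B on the decay histogram.

    The default window starts 0.5 ns after the histogram peak (excluding
    the IRF-dominated rise) and runs to the end of the period.
    """
    t = hist.centers_ns
    c = hist.counts.astype(np.float64)
    if window_ns is None:
        peak = t[int(np.argmax(c))]
        window_ns = (peak + 0.5, hist.rep_period_ns)
    lo, hi = window_ns
    m = (t >= lo) & (t <= hi)
    if m.sum() < 5:
        raise ValueError(f"fewer than 5 bins in fit window {window_ns}")
    tw, cw = t[m], c[m]
    # initial guesses: background from the last bins, tau from the log slope
    b0 = max(float(np.median(cw[-max(3, cw.size // 10):])), 0.0)
    a0 = max(float(cw[0] - b0), 1.0)
    pos = cw - b0 > a0 * 0.05
    tau0 = 1.0
    if pos.sum() > 2:
        sl = np.polyfit(tw[pos], np.log(np.maximum(cw[pos] - b0, 1e-12)), 1)[0]
        if sl < 0:
            tau0 = -1.0 / sl
    sigma = np.sqrt(np.maximum(cw, 1.0))
    try:
        popt, pcov = curve_fit(
            lambda t_, A, tau, B: _monoexp(t_ - tw[0], A, tau, B),
            tw,
            cw,
            p0=(a0, tau0, b0),
            sigma=sigma,
            absolute_sigma=True,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"mono-exponential tail fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    return LifetimeFit(
        tau_ns=float(popt[1]),
        tau_stderr_ns=float(perr[1]),
        amplitude=float(popt[0]),
        background=float(popt[2]),
        window_ns=(float(lo), float(hi)),
    )


def phasor(hist: DecayHistogram, harmonic: int = 1) -> PhasorPoint:
    """First-harmonic (by default) phasor coordinates of a decay histogram."""
    c = hist.counts.astype(np.float64)
    total = c.sum()
    if total <= 0:
        raise ValueError("zero counts: cannot compute a phasor")
    w = 2.0 * np.pi * harmonic / hist.rep_period_ns
    t = hist.centers_ns
    g = float(np.sum(c * np.cos(w * t)) / total)
    s = float(np.sum(c * np.sin(w * t)) / total)
    return PhasorPoint(g=g, s=s, counts=int(total), harmonic=harmonic)


def phasor_theoretical(tau_ns: float, rep_period_ns: float, harmonic: int = 1) -> PhasorPoint:
    """Closed-form phasor of an ideal mono-exponential decay."""
    wt = 2.0 * np.pi * harmonic / rep_period_ns * tau_ns
    return PhasorPoint(g=1.0 / (1.0 + wt**2), s=wt / (1.0 + wt**2), harmonic=harmonic, calibrated=True)


def phasor_image(
    stack: np.ndarray,
    rep_period_ns: float,
    harmonic: int = 1,
    intensity_threshold: float = 0.10,
    calibration: Optional["PhasorCalibration"] = None,
):
    """Per-pixel phasors of an (ny, nx, n_dt) time-resolved image.

    Pixels below ``intensity_threshold`` × the maximum pixel count are
    excluded.  Returns (g, s, mask) image arrays; g/s are NaN outside the
    mask.
    """
    counts = stack.sum(axis=-1)
    if counts.max() <= 0:
        raise ValueError("empty image: zero counts everywhere")
    mask = counts >= intensity_threshold * counts.max()
    if intensity_threshold >= 1.0 + 1e-12 or not mask.any():
        raise ValueError("intensity threshold leaves no pixels")
    n_dt = stack.shape[-1]
    t = (np.arange(n_dt) + 0.5) * rep_period_ns / n_dt
    w = 2.0 * np.pi * harmonic / rep_period_ns
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.tensordot(stack, np.cos(w * t), axes=([-1], [0])) / counts
        s = np.tensordot(stack, np.sin(w * t), axes=([-1], [0])) / counts
    g = np.where(mask, g, np.nan)
    s = np.where(mask, s, np.nan)
    if calibration is not None:
        g, s = calibration.apply_arrays(g, s)
    return g, s, mask


@dataclass
class PhasorCalibration:
    """Rotation + modulation scale mapping measured phasors onto the circle.

    Built from a reference dye of known lifetime; applying the calibration
    to the measured reference reproduces its theoretical phasor exactly.
    """

    rotation_rad: float
    scale: float
    tau_ref_ns: float

    def apply(self, point: PhasorPoint) -> PhasorPoint:
        if point.calibrated:
            raise ValueError("phasor already calibrated; refusing to calibrate twice")
        g, s = self.apply_arrays(np.asarray(point.g), np.asarray(point.s))
        return PhasorPoint(
            g=float(g), s=float(s), counts=point.counts, harmonic=point.harmonic, calibrated=True
        )

    def apply_arrays(self, g, s):
        cr, sr = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        return self.scale * (g * cr - s * sr), self.scale * (g * sr + s * cr)


def calibrate_phasor(
    measured_ref: PhasorPoint, tau_ref_ns: float, rep_period_ns: float
) -> PhasorCalibration:
    """Derive the calibration transform from a measured reference phasor."""
    if measured_ref.modulus < 1e-12:
        raise ValueError("degenerate reference phasor (zero modulus)")
    theo = phasor_theoretical(tau_ref_ns, rep_period_ns, measured_ref.harmonic)
    rot = np.arctan2(theo.s, theo.g) - np.arctan2(measured_ref.s, measured_ref.g)
    scale = theo.modulus / measured_ref.modulus
    return PhasorCalibration(rotation_rad=float(rot), scale=float(scale), tau_ref_ns=tau_ref_ns)


def phasor_lifetime_ns(point_or_g, s=None, rep_period_ns: float = 25.0, harmonic: int = 1):
    """Mono-exponential lifetime estimate τ = s/(ω·g) from phasor coordinates."""
    if s is None:
        g, s = point_or_g.g, point_or_g.s
    else:
        g = point_or_g
    w = 2.0 * np.pi * harmonic / rep_period_ns
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.asarray(s) / (w * np.asarray(g))


def phasor_segment(g: np.ndarray, mask: np.ndarray, min_spread: float = 1e-6):
    """Two-label segmentation of a phasor image by the cloud-centroid split.

    Pixels are partitioned by the vertical line (perpendicular to the g
    axis) through the phasor-cloud centroid: label 1 = g < centroid (longer
    lifetime), label 2 = g ≥ centroid (shorter lifetime), 0 = below the
    intensity threshold.  Returns (labels, info); a degenerate
    (single-lifetime) cloud yields a single label and ``info['degenerate']``.
    """
    if not mask.any():
        raise ValueError("empty phasor cloud: no pixels pass the threshold")
    gv = g[mask]
    centroid = float(np.nanmean(gv))
    spread = float(np.nanstd(gv))
    labels = np.zeros(mask.shape, dtype=np.uint8)
    if spread < min_spread:
        labels[mask] = 1
        return labels, {"centroid_g": centroid, "degenerate": True}
    labels[mask & (g < centroid)] = 1
    labels[mask & (g >= centroid)] = 2
    return labels, {"centroid_g": centroid, "degenerate": False}


def lifetime_map_tailfit(
    stack: np.ndarray,
    rep_period_ns: float,
    tail_offset_ns: float = 0.5,
    min_counts: int = 25,
):
    """Vectorised per-pixel tail lifetime map of an (ny, nx, n_dt) stack.

    Maximum-likelihood estimator for an exponential truncated to the
    post-peak tail window [a, T]: the mean excess arrival time m obeys
    m(τ) = τ − L·e^(−L/τ)/(1 − e^(−L/τ)) with L = T − a, inverted per
    pixel by Newton iteration.  Unbiased to histogram-discretization
    accuracy even at low counts (no log-of-counts regression).  Pixels
    with fewer than ``min_counts`` photons are NaN.
    """
    ny, nx, n_dt = stack.shape
    t = (np.arange(n_dt) + 0.5) * rep_period_ns / n_dt
    counts = stack.reshape(-1, n_dt).astype(np.float64)
    # global peak position (shared IRF) from the pooled decay
    pooled = counts.sum(axis=0)
    a = t[int(np.argmax(pooled))] + tail_offset_ns
    tail = t >= a
    tw = t[tail] - a
    cw = counts[:, tail]
    n_tail = cw.sum(axis=1)
    L = float(tw[-1] + 0.5 * rep_period_ns / n_dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = (cw * tw).sum(axis=1) / n_tail
    tau = np.where(m > 0, m, np.nan)  # start from the untruncated estimate
    for _ in range(30):
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            q = np.exp(-L / tau)
            f = tau - L * q / (1.0 - q) - m
            # d/dτ [τ − L·q/(1−q)] = 1 − (L/τ)²·q/(1−q)²
            df = 1.0 - (L / tau) ** 2 * q / (1.0 - q) ** 2
            step = np.where(np.abs(df) > 1e-12, f / df, 0.0)
            tau = np.clip(tau - step, 1e-3, 100.0 * rep_period_ns)
    total = counts.sum(axis=1)
    tau[(total < min_counts) | (n_tail < min_counts / 2) | ~np.isfinite(tau)] = np.nan
    return tau.reshape(ny, nx)
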