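"""Auto- and cross-correlation directly from photon time lists.

The correlator bins the photon absolute times at a base resolution (1 µs by
default) and evaluates

    G(τ) = ⟨δI_a(t) δI_b(t+τ)⟩ / (⟨I_a⟩⟨I_b⟩)

on a quasi-logarithmic lag grid with lag-proportional coarsening: the bin
width doubles whenever the lag exceeds 16 bins (multi-tau style), keeping
the cost linear in the number of photons while covering six decades of lag.
Normalization is symmetric — the means are taken over the two overlapping
segments of each lag — which suppresses the drift bias of a global-mean
normalization.

Long acquisitions are split into chunks (5 or 10 s), each chunk correlated
independently, automatically quality-controlled, and the surviving curves
averaged; the replicates provide per-lag error bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .photon_stream import PhotonStream, merge_channels

__all__ = [
    "LagDesign",
    "CorrelationCurve",
    "correlate_photons",
    "chunked_correlation",
    "cross_color_correlation",
    "AllChunksRejected",
]

#: lag-to-bin-width ratio kept in [_COARSEN_M, 2*_COARSEN_M)
_COARSEN_M = 8


class AllChunksRejected(RuntimeError):
    """Every chunk failed QC; carries the per-chunk report."""

    def __init__(self, report):
        super().__init__(f"all chunks rejected by QC: {report}")
        self.report = report


@dataclass
class LagDesign:
    """Quasi-logarithmic lag grid: `points_per_decade` from tau_min to tau_max."""

    points_per_decade: int = 8
    tau_min_s: float = 1e-6
    tau_max_s: float = 1.0
    base_bin_s: float = 1e-6

    def __post_init__(self) -> None:
        if self.tau_min_s < self.base_bin_s:
            raise ValueError("tau_min must be >= the base bin width")
        if self.tau_max_s <= self.tau_min_s:
            raise ValueError("tau_max must exceed tau_min")

    def grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (lags_s, level, k): lag = k * base * 2**level."""
        n_dec = np.log10(self.tau_max_s / self.tau_min_s)
        n_pts = int(np.floor(n_dec * self.points_per_decade)) + 1
        taus = self.tau_min_s * 10 ** (np.arange(n_pts) / self.points_per_decade)
        levels, ks = [], []
        for tau in taus:
            lev = max(0, int(np.floor(np.log2(tau / (self.base_bin_s * _COARSEN_M)))))
            w = self.base_bin_s * 2**lev
            k = max(1, int(round(tau / w)))
            levels.append(lev)
            ks.append(k)
        levels = np.asarray(levels)
        ks = np.asarray(ks)
        lags = ks * self.base_bin_s * 2.0**levels
        _, keep = np.unique(np.round(lags / self.base_bin_s).astype(np.int64), return_index=True)
        return lags[keep], levels[keep], ks[keep]


@dataclass
class CorrelationCurve:
    """Lag grid + G values, with per-chunk replicates when chunked."""

    lags_s: np.ndarray
    G: np.ndarray
    kind: str = "auto"
    label: str = ""
    replicates: Optional[np.ndarray] = None  # (n_used, n_lags)
    n_chunks_total: int = 1
    n_chunks_used: int = 1
    rejected: tuple = field(default_factory=tuple)

    @property
    def sem(self) -> Optional[np.ndarray]:
        if self.replicates is None or self.replicates.shape[0] < 2:
            return None
        return self.replicates.std(axis=0, ddof=1) / np.sqrt(self.replicates.shape[0])

    def to_csv(self, path) -> None:
        cols = [self.lags_s, self.G]
        header = "lag_s,G"
        if self.sem is not None:
            cols.append(self.sem)
            header += ",sem"
        np.savetxt(path, np.column_stack(cols), delimiter=",", header=header, comments="")


def _bin_counts(t_ns: np.ndarray, base_bin_s: float, n_bins: int) -> np.ndarray:
    idx = (t_ns / (base_bin_s * 1e9)).astype(np.int64)
    idx = np.minimum(idx, n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(np.float64)


def _multitau(ca: np.ndarray, cb: np.ndarray, design: LagDesign):
    """Symmetric-normalized correlation of two binned traces on the lag grid."""
    lags, levels, ks = design.grid()
    G = np.full(lags.size, np.nan)
    lev_a = {0: ca}
    lev_b = {0: cb}

    def coarsen(c):
        n = c.size // 2 * 2
        return c[:n].reshape(-1, 2).sum(axis=1)

    max_lev = int(levels.max()) if levels.size else 0
    for lev in range(1, max_lev + 1):
        lev_a[lev] = coarsen(lev_a[lev - 1])
        lev_b[lev] = lev_a[lev] if ca is cb else coarsen(lev_b[lev - 1])
    for j in range(lags.size):
        a = lev_a[levels[j]]
        b = lev_b[levels[j]] if ca is not cb else lev_a[levels[j]]
        k = int(ks[j])
        n = a.size
        if k >= n:
            continue
        m = n - k
        s_ab = float(np.dot(a[:m], b[k:]))
        s_a = float(a[:m].sum())
        s_b = float(b[k:].sum())
        if s_a <= 0 or s_b <= 0:
            raise ValueError("zero mean intensity in a correlation segment")
        G[j] = m * s_ab / (s_a * s_b) - 1.0
    valid = np.isfinite(G)
    return lags[valid], G[valid]


def correlate_photons(
    a: PhotonStream, b: Optional[PhotonStream] = None, design: Optional[LagDesign] = None
) -> CorrelationCurve:
    """Correlate two photon streams (autocorrelation when ``b`` is None)."""
    design = design or LagDesign()
    if len(a) == 0 or (b is not None and len(b) == 0):
        raise ValueError("cannot correlate an empty photon stream")
    auto = b is None or b is a
    duration = a.duration_s if auto else max(a.duration_s, b.duration_s)
    n_bins = max(1, int(np.ceil(duration / design.base_bin_s)))
    ca = _bin_counts(a.t_abs_ns, design.base_bin_s, n_bins)
    cb = ca if auto else _bin_counts(b.t_abs_ns, design.base_bin_s, n_bins)
    lags, G = _multitau(ca, cb, design)
    return CorrelationCurve(lags_s=lags, G=G, kind="auto" if auto else "cross")


def _default_qc(curves, intensities, intensity_dev, g_nsd):
    """Automated chunk QC: intensity outliers and early-lag correlation outliers."""
    n = len(curves)
    rejected = {}
    med_i = float(np.median(intensities))
    for i, inten in enumerate(intensities):
        if med_i > 0 and abs(inten - med_i) > intensity_dev * med_i:
            rejected[i] = f"intensity {inten:.3g} deviates >{intensity_dev:.0%} from median"
    g_early = np.array([c.G[:3] for c in curves])
    med = np.median(g_early, axis=0)
    mad = np.median(np.abs(g_early - med), axis=0)
    robust_sd = 1.4826 * mad + 1e-12
    for i in range(n):
        if i in rejected:
            continue
        z = np.abs(g_early[i] - med) / robust_sd
        if np.any(z > g_nsd):
            rejected[i] = f"early-lag G deviates {z.max():.1f} robust SD from replicate median"
    return rejected


def chunked_correlation(
    a: PhotonStream,
    b: Optional[PhotonStream] = None,
    chunk_s: float = 10.0,
    design: Optional[LagDesign] = None,
    qc: bool = True,
    qc_intensity_dev: float = 0.25,
    qc_g_nsd: float = 5.0,
) -> CorrelationCurve:
    """Chunked, QC'd, averaged correlation.

    The stream is cut into ``chunk_s``-long chunks (≥ 2 required), each
    correlated independently; chunks whose mean intensity deviates more
    than ``qc_intensity_dev`` from the chunk median, or whose correlation
    at the three smallest lags is a >``qc_g_nsd`` robust-SD outlier, are
    excluded; the rest are averaged pointwise.
    """
    design = design or LagDesign()
    duration = a.duration_s
    n_chunks = int(np.floor(duration / chunk_s + 1e-9))
    if n_chunks < 2:
        raise ValueError(
            f"duration {duration:.3g} s supports {n_chunks} chunk(s) of {chunk_s} s; >= 2 required"
        )
    auto = b is None
    curves, intensities = [], []
    chunk_ns = chunk_s * 1e9
    n_bins = int(round(chunk_s / design.base_bin_s))
    for i in range(n_chunks):
        lo, hi = i * chunk_ns, (i + 1) * chunk_ns
        sel_a = (a.t_abs_ns >= lo) & (a.t_abs_ns < hi)
        ta = a.t_abs_ns[sel_a] - np.uint64(lo)
        if auto:
            tb = ta
        else:
            sel_b = (b.t_abs_ns >= lo) & (b.t_abs_ns < hi)
            tb = b.t_abs_ns[sel_b] - np.uint64(lo)
        if ta.size == 0 or tb.size == 0:
            raise ValueError(f"chunk {i} contains no photons")
        ca = _bin_counts(ta, design.base_bin_s, n_bins)
        cb = ca if auto else _bin_counts(tb, design.base_bin_s, n_bins)
        lags, G = _multitau(ca, cb, design)
        curves.append(CorrelationCurve(lags_s=lags, G=G))
        intensities.append(ta.size / chunk_s if auto else np.sqrt(ta.size * tb.size) / chunk_s)

    rejected = (
        _default_qc(curves, intensities, qc_intensity_dev, qc_g_nsd) if qc and n_chunks > 2 else {}
    )
    used = [i for i in range(n_chunks) if i not in rejected]
    if not used:
        raise AllChunksRejected(rejected)
    lags = curves[used[0]].lags_s
    reps = np.array([curves[i].G for i in used])
    return CorrelationCurve(
        lags_s=lags,
        G=reps.mean(axis=0),
        kind="auto" if auto else "cross",
        replicates=reps,
        n_chunks_total=n_chunks,
        n_chunks_used=len(used),
        rejected=tuple(sorted(rejected.items())),
    )


def cross_color_correlation(
    green: PhotonStream,
    red: PhotonStream,
    design: Optional[LagDesign] = None,
    chunk_s: Optional[float] = None,
    green_volume: str = "sum3x3",
) -> CorrelationCurve:
    """Dual-color FCCS: array (green, merged volume) × single-element (red)."""
    g = merge_channels(green, green_volume) if green.volume is None else green
    r = merge_channels(red, "single_element") if red.volume is None else red
    if chunk_s is not None:
        curve = chunked_correlation(g, r, chunk_s=chunk_s, design=design)
    else:
        curve = correlate_photons(g, r, design=design)
    curve.kind = "cross"
    curve.label = f"{green_volume}×single_element"
    return curve
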