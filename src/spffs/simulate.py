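"""Synthetic photon-stream generator.

Emulates the statistical structure of single-photon SPAD-array
measurements: 3D Brownian / domain-trapped / meshwork-hopping emitters in a
periodic box, Gaussian detection volumes, Poisson photon emission,
mono-exponential microtimes convolved with a Gaussian IRF, dual-color
species with a tunable co-diffusing fraction, and circular or raster scan
trajectories.

Two detection models are provided:

* **nested-volume mode** (point and circular-scan FCS): the three named
  virtual volumes (central / sum 3×3 / sum 5×5) are *exact* 3D Gaussians at
  their calibrated waists; photons are generated from the largest volume and
  assigned to channels by hierarchical thinning so that channel merging
  reproduces the calibrated volumes exactly.  This mirrors the measurement
  practice of calibrating effective waists rather than deriving them from
  detector geometry.
* **element mode** (raster imaging): each array element detects through its
  own offset Gaussian, multiplied by the excitation profile — per-element
  images are laterally shifted by half the projected pitch, the property
  adaptive pixel reassignment exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

from . import _kernels
from .photon_stream import (
    DetectorGeometry,
    LaserConfig,
    PhotonStream,
    ScanMetadata,
    VOLUME_CHANNELS,
)

__all__ = [
    "EmitterSpecies",
    "MotionModel",
    "SimulationConfig",
    "Phantom",
    "simulate_trajectories",
    "emit_photons",
    "simulate_fcs",
    "simulate_scan",
    "simulate_microtimes",
    "disc_phantom",
    "bead_phantom",
]

_RING3 = np.array([6, 7, 8, 11, 13, 16, 17, 18], dtype=np.uint8)
_OUTER = np.array(
    [0, 1, 2, 3, 4, 5, 9, 10, 14, 15, 19, 20, 21, 22, 23, 24], dtype=np.uint8
)


@dataclass
class EmitterSpecies:
    """One diffusing fluorescent species.

    ``brightness_cps`` is the peak detected photon rate per emitter at the
    centre of its detection volume (for green species: the sum-5×5 volume).
    """

    D_um2_s: float = 10.0
    brightness_cps: float = 5e5
    lifetime_ns: float = 2.5
    color: str = "green"
    n_emitters: int = 500

    def __post_init__(self) -> None:
        if min(self.D_um2_s, self.brightness_cps, self.lifetime_ns) < 0:
            raise ValueError("species parameters must be non-negative")
        if self.color not in ("green", "red"):
            raise ValueError("color must be 'green' or 'red'")


@dataclass
class MotionModel:
    """Motion class: free Brownian, domain trapping, or meshwork hopping.

    Trap: spherical domains of radius ``domain_radius_nm`` on a cubic
    lattice with ``domain_spacing_nm`` pitch; free emitters entering a
    domain are captured at rate ``trap_rate_s`` and then diffuse with
    ``D_in_um2_s`` reflected at the boundary until a Poisson escape event
    at ``escape_rate_s``.  Hop: mesh planes every ``mesh_size_nm`` along
    each axis; a displacement crossing a plane is accepted with probability
    ``hop_probability``, else reflected.
    """

    kind: str = "free"
    domain_radius_nm: float = 100.0
    domain_spacing_nm: float = 400.0
    trap_rate_s: float = 1e4
    escape_rate_s: float = 100.0
    D_in_um2_s: float = 1.0
    mesh_size_nm: float = 150.0
    hop_probability: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("free", "trap", "hop"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if not 0.0 <= self.hop_probability <= 1.0:
            raise ValueError("hop_probability must be in [0, 1]")
        if min(self.trap_rate_s, self.escape_rate_s) < 0:
            raise ValueError("rates must be non-negative")

    @property
    def kind_code(self) -> int:
        return {"free": _kernels.KIND_FREE, "trap": _kernels.KIND_TRAP, "hop": _kernels.KIND_HOP}[
            self.kind
        ]


@dataclass
class SimulationConfig:
    """Full study configuration for one synthetic acquisition."""

    box_um: tuple = (8.0, 8.0, 8.0)
    dt_us: float = 20.0
    duration_s: float = 60.0
    geometry: DetectorGeometry = field(default_factory=DetectorGeometry)
    laser: LaserConfig = field(default_factory=LaserConfig)
    species: Sequence[EmitterSpecies] = field(default_factory=lambda: [EmitterSpecies()])
    motion: MotionModel = field(default_factory=MotionModel)
    co_diffusing_fraction: float = 0.0
    #: relative peak detection rates of the nested volumes (central, sum3x3)
    #: w.r.t. the sum-5x5 peak; must be non-decreasing and <= 1
    peak_ratio_central: float = 0.85
    peak_ratio_sum3x3: float = 0.95
    #: circular scan (0 radius = parked beam)
    scan_radius_nm: float = 0.0
    scan_period_us: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.co_diffusing_fraction <= 1.0:
            raise ValueError("co_diffusing_fraction must be in [0, 1]")
        if not 0.0 < self.peak_ratio_central <= self.peak_ratio_sum3x3 <= 1.0:
            raise ValueError("peak ratios must satisfy 0 < central <= sum3x3 <= 1")
        self.validate_dt()

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s / (self.dt_us * 1e-6)))

    def validate_dt(self) -> None:
        """Time-step precondition: rms step below a fifth of the smallest waist."""
        w_min_um = min(self.geometry.waists[v] for v in ("central", "sum3x3", "sum5x5")) * 1e-3
        dt_s = self.dt_us * 1e-6
        for sp in self.species:
            if np.sqrt(2.0 * sp.D_um2_s * dt_s) >= w_min_um / 5.0:
                raise ValueError(
                    f"dt={self.dt_us} us too coarse for D={sp.D_um2_s} um^2/s: "
                    f"rms step must stay below omega0/5 = {w_min_um / 5.0:.4f} um"
                )


def _species_by_color(config: SimulationConfig) -> dict:
    out = {}
    for sp in config.species:
        if sp.color in out:
            raise ValueError("at most one species per color")
        out[sp.color] = sp
    return out


def _motion_params(config: SimulationConfig, D_um2_s: float) -> np.ndarray:
    dt_s = config.dt_us * 1e-6
    m = config.motion
    sigma = np.sqrt(2.0 * D_um2_s * dt_s)
    if m.kind == "free":
        return np.array([sigma])
    if m.kind == "trap":
        sigma_in = np.sqrt(2.0 * m.D_in_um2_s * dt_s)
        return np.array(
            [
                sigma,
                sigma_in,
                m.domain_radius_nm * 1e-3,
                m.domain_spacing_nm * 1e-3,
                min(1.0, m.trap_rate_s * dt_s),
                min(1.0, m.escape_rate_s * dt_s),
            ]
        )
    return np.array([sigma, m.mesh_size_nm * 1e-3, m.hop_probability])


# ---------------------------------------------------------------------------
# trajectories (two-phase path, small problems)


def simulate_trajectories(config: SimulationConfig, n_emitters: Optional[int] = None) -> np.ndarray:
    """Propagate emitter positions, returning (n_steps+1, n_em, 3) in µm.

    Positions are wrapped into the periodic box; suitable for small
    problems only (the array is dense in time).
    """
    sp = config.species[0]
    n_em = n_emitters if n_emitters is not None else sp.n_emitters
    rng = np.random.default_rng(config.seed)
    box = np.asarray(config.box_um, dtype=np.float64)
    pos = rng.uniform(-0.5, 0.5, size=(n_em, 3)) * box
    mp = _motion_params(config, sp.D_um2_s)
    kseed = int(rng.integers(0, 2**31 - 1))
    n_steps = config.n_steps
    normals = rng.standard_normal((n_steps, n_em, 3))
    out = np.empty((n_steps + 1, n_em, 3))
    trapped = np.zeros(n_em, dtype=np.int8)
    dom_center = np.zeros((n_em, 3))
    _kernels.traj_from_normals(
        config.dt_us * 1e-6, pos, box, config.motion.kind_code, mp,
        trapped, dom_center, normals, kseed, out,
    )
    return out


def _nested_volume_params(config: SimulationConfig):
    g = config.geometry
    w5 = g.waists["sum5x5"] * 1e-3
    w3 = g.waists["sum3x3"] * 1e-3
    wc = g.waists["central"] * 1e-3
    z5 = g.eccentricities["sum5x5"] * w5
    z3 = g.eccentricities["sum3x3"] * w3
    zc = g.eccentricities["central"] * wc
    if not (wc <= w3 <= w5 and zc <= z3 <= z5):
        raise ValueError(
            "nested-volume emission requires non-decreasing lateral and axial "
            "extents from central to sum5x5"
        )
    return wc, w3, w5, zc, z3, z5


def _assign_channels_and_microtimes(
    t_s: np.ndarray,
    tiers: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    lifetimes: dict,
) -> PhotonStream:
    order = np.argsort(t_s, kind="stable")
    t_s = t_s[order]
    tiers = tiers[order]
    n = t_s.size
    channels = np.empty(n, dtype=np.uint8)
    channels[tiers == _kernels.TIER_CENTRAL] = config.geometry.central_channel
    m = tiers == _kernels.TIER_RING3
    channels[m] = _RING3[rng.integers(0, _RING3.size, int(m.sum()))]
    m = tiers == _kernels.TIER_OUTER
    channels[m] = _OUTER[rng.integers(0, _OUTER.size, int(m.sum()))]
    channels[tiers == _kernels.TIER_RED] = 25

    laser = config.laser
    micro = np.empty(n, dtype=np.float64)
    is_red = tiers == _kernels.TIER_RED
    for color, mask in (("green", ~is_red), ("red", is_red)):
        k = int(mask.sum())
        if k == 0:
            continue
        tau = lifetimes.get(color)
        micro[mask] = rng.exponential(tau, size=k) + rng.normal(
            laser.irf_offset_ns, laser.irf_sigma_ns, size=k
        )
    micro = np.mod(micro, laser.rep_period_ns)

    scan = None
    if config.scan_radius_nm > 0:
        scan = ScanMetadata(
            mode="circular",
            radius_nm=config.scan_radius_nm,
            period_us=config.scan_period_us,
        )
    return PhotonStream(
        channels=channels,
        t_abs_ns=np.round(t_s * 1e9).astype(np.uint64),
        microtimes_ns=micro,
        geometry=config.geometry,
        laser=laser,
        scan=scan,
        duration_s=config.duration_s,
    )


def simulate_fcs(config: SimulationConfig) -> PhotonStream:
    """Simulate a point (or circular-scan) FCS acquisition.

    Returns a channel-tagged, microtime-tagged photon stream.  Green
    photons populate the 5×5 array channels via the nested-volume model;
    red photons (if a red species is present) populate the single-element
    channel 25, detected through a Gaussian volume at the single-element
    calibrated waist.  Identical config + seed gives an identical stream.
    """
    by_color = _species_by_color(config)
    green = by_color.get("green")
    red = by_color.get("red")
    if green is None and red is None:
        raise ValueError("at least one species required")
    if green is not None and red is not None and green.D_um2_s != red.D_um2_s:
        raise ValueError("dual-color simulation assumes one shared diffusion coefficient")

    rng = np.random.default_rng(config.seed)
    box = np.asarray(config.box_um, dtype=np.float64)
    dt_s = config.dt_us * 1e-6
    g = config.geometry

    n_g = green.n_emitters if green else 0
    n_r = red.n_emitters if red else 0
    n_co = int(round(config.co_diffusing_fraction * min(n_g, n_r)))
    # ordering: [co-diffusing, green-only, red-only]
    n_green_tot = n_g
    n_em = n_g + n_r - n_co
    pos0 = rng.uniform(-0.5, 0.5, size=(n_em, 3)) * box

    ref = green if green is not None else red
    mp = _motion_params(config, ref.D_um2_s)

    wc, w3, w5, zc, z3, z5 = _nested_volume_params(config)
    bg5_dt = (green.brightness_cps * dt_s) if green else 0.0
    a3 = config.peak_ratio_sum3x3
    ac = config.peak_ratio_central / config.peak_ratio_sum3x3
    d3w = 2.0 / w3**2 - 2.0 / w5**2
    d3z = 2.0 / z3**2 - 2.0 / z5**2
    dcw = 2.0 / wc**2 - 2.0 / w3**2
    dcz = 2.0 / zc**2 - 2.0 / z3**2

    wr = g.waists["single_element"] * 1e-3
    zr = g.eccentricities["single_element"] * wr
    br_dt = (red.brightness_cps * dt_s) if red else 0.0

    w_cut = max(w5, wr)
    z_cut = max(z5, zr)

    # expected photon budget for array preallocation
    conc = n_em / float(np.prod(box))
    v5 = (np.pi / 2.0) ** 1.5 * w5**2 * z5
    vr = (np.pi / 2.0) ** 1.5 * wr**2 * zr
    n_exp = config.duration_s * conc * (
        (green.brightness_cps * v5 if green else 0.0)
        + (red.brightness_cps * vr if red else 0.0)
    )
    cap = int(1.5 * n_exp + 10.0 * np.sqrt(n_exp + 1.0) + 10000)
    times = np.empty(cap, dtype=np.float64)
    tiers = np.empty(cap, dtype=np.int8)

    trapped = np.zeros(n_em, dtype=np.int8)
    dom_center = np.zeros((n_em, 3), dtype=np.float64)
    n_steps = config.n_steps
    block = max(1, min(n_steps, int(4_000_000 // max(n_em, 1)) or 1))
    scan_r_um = config.scan_radius_nm * 1e-3
    count = 0
    for step0 in range(0, n_steps, block):
        nb = min(block, n_steps - step0)
        normals = rng.standard_normal((nb, n_em, 3), dtype=np.float32)
        steps = np.arange(step0, step0 + nb, dtype=np.float64)
        if scan_r_um > 0.0:
            ang = 2.0 * np.pi * steps * dt_s / (config.scan_period_us * 1e-6)
            cxs = scan_r_um * np.cos(ang)
            cys = scan_r_um * np.sin(ang)
        else:
            cxs = np.zeros(nb)
            cys = np.zeros(nb)
        kseed = int(rng.integers(0, 2**31 - 1))
        count = _kernels.fcs_block_kernel(
            kseed,
            dt_s,
            step0,
            pos0,
            box,
            config.motion.kind_code,
            mp,
            trapped,
            dom_center,
            normals,
            cxs,
            cys,
            n_co,
            n_green_tot,
            bg5_dt,
            2.0 / w5**2,
            2.0 / z5**2,
            a3,
            d3w,
            d3z,
            ac,
            dcw,
            dcz,
            br_dt,
            2.0 / wr**2,
            2.0 / zr**2,
            (2.5 * w_cut) ** 2,
            (2.5 * z_cut) ** 2,
            times,
            tiers,
            count,
        )
        if count < 0:
            raise RuntimeError("photon buffer overflow; brightness far above estimate")
    lifetimes = {c: s.lifetime_ns for c, s in by_color.items()}
    return _assign_channels_and_microtimes(times[:count], tiers[:count], config, rng, lifetimes)


def emit_photons(trajectories: np.ndarray, config: SimulationConfig) -> PhotonStream:
    """Emit photons from precomputed trajectories (nested-volume model).

    Vectorised two-phase counterpart of :func:`simulate_fcs` for small
    trajectory sets; the emission model is identical but the random draws
    are not in the same order, so streams differ realisation-by-realisation.
    """
    sp = config.species[0]
    if sp.color != "green":
        raise ValueError("two-phase emission supports the green (array) species")
    rng = np.random.default_rng(config.seed + 1)
    dt_s = config.dt_us * 1e-6
    pos = trajectories[1:]  # position at step start convention
    n_steps, n_em, _ = pos.shape

    wc, w3, w5, zc, z3, z5 = _nested_volume_params(config)
    r2 = pos[:, :, 0] ** 2 + pos[:, :, 1] ** 2
    z2 = pos[:, :, 2] ** 2
    lam5 = sp.brightness_cps * dt_s * np.exp(-2.0 * r2 / w5**2 - 2.0 * z2 / z5**2)
    counts = rng.poisson(lam5)
    total = int(counts.sum())
    step_idx, em_idx = np.nonzero(counts)
    reps = counts[step_idx, em_idx]
    step_of = np.repeat(step_idx, reps)
    em_of = np.repeat(em_idx, reps)
    t_s = (step_of + rng.random(total)) * dt_s

    r2p = r2[step_of, em_of]
    z2p = z2[step_of, em_of]
    a3 = config.peak_ratio_sum3x3
    ac = config.peak_ratio_central / config.peak_ratio_sum3x3
    p3 = a3 * np.exp(-r2p * (2 / w3**2 - 2 / w5**2) - z2p * (2 / z3**2 - 2 / z5**2))
    pc = ac * np.exp(-r2p * (2 / wc**2 - 2 / w3**2) - z2p * (2 / zc**2 - 2 / z3**2))
    u1 = rng.random(total)
    u2 = rng.random(total)
    tiers = np.full(total, _kernels.TIER_OUTER, dtype=np.int8)
    in3 = u1 < p3
    tiers[in3 & (u2 < pc)] = _kernels.TIER_CENTRAL
    tiers[in3 & (u2 >= pc)] = _kernels.TIER_RING3
    return _assign_channels_and_microtimes(
        t_s, tiers, config, rng, {"green": sp.lifetime_ns}
    )


def simulate_microtimes(
    n: int, lifetime_ns: float, laser: Optional[LaserConfig] = None, seed: int = 1
) -> np.ndarray:
    """Draw folded TCSPC microtimes: Exp(τ) ⊕ Gaussian IRF, mod T_rep."""
    laser = laser or LaserConfig()
    rng = np.random.default_rng(seed)
    micro = rng.exponential(lifetime_ns, size=n) + rng.normal(
        laser.irf_offset_ns, laser.irf_sigma_ns, size=n
    )
    return np.mod(micro, laser.rep_period_ns)


# ---------------------------------------------------------------------------
# raster scanning (element mode)


@dataclass
class Phantom:
    """Planar object for raster-scan simulation.

    ``brightness_cps`` — detected peak photon rate map, one value per pixel
    (rate when the excitation maximum sits on that pixel for a unit-response
    element); ``lifetime_ns`` — fluorescence lifetime map (same shape).
    """

    brightness_cps: np.ndarray
    lifetime_ns: np.ndarray
    pixel_size_nm: float = 50.0

    def __post_init__(self) -> None:
        self.brightness_cps = np.asarray(self.brightness_cps, dtype=np.float64)
        self.lifetime_ns = np.asarray(self.lifetime_ns, dtype=np.float64)
        if self.brightness_cps.shape != self.lifetime_ns.shape:
            raise ValueError("brightness and lifetime maps must share a shape")


def disc_phantom(
    shape=(64, 64),
    disc_centers=((32, 32),),
    disc_radius_px: float = 8.0,
    brightness_in_cps: float = 2e5,
    brightness_out_cps: float = 1e5,
    tau_in_ns: float = 2.0,
    tau_out_ns: float = 2.6,
    pixel_size_nm: float = 50.0,
) -> Phantom:
    """Disc-shaped 'granules' with a shorter lifetime than the background."""
    yy, xx = np.indices(shape)
    b = np.full(shape, brightness_out_cps, dtype=np.float64)
    t = np.full(shape, tau_out_ns, dtype=np.float64)
    for cy, cx in disc_centers:
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= disc_radius_px**2
        b[inside] = brightness_in_cps
        t[inside] = tau_in_ns
    return Phantom(b, t, pixel_size_nm)


def bead_phantom(
    shape=(64, 64), center=(32, 32), brightness_cps: float = 1e6,
    tau_ns: float = 2.5, pixel_size_nm: float = 50.0,
) -> Phantom:
    """Point-like sub-resolution bead (single bright pixel)."""
    b = np.zeros(shape)
    b[center] = brightness_cps
    t = np.full(shape, tau_ns)
    return Phantom(b, t, pixel_size_nm)


def element_offsets_nm(geometry: DetectorGeometry) -> np.ndarray:
    """Projected sample-plane offsets of the array elements, (25, 2) as (y, x) nm."""
    p = geometry.pitch_sample_nm
    rows, cols = np.divmod(np.arange(geometry.n_rows * geometry.n_cols), geometry.n_cols)
    return np.column_stack(
        [(rows - geometry.n_rows // 2) * p, (cols - geometry.n_cols // 2) * p]
    ).astype(np.float64)


def simulate_scan(
    phantom: Phantom,
    config: SimulationConfig,
    pixel_dwell_us: float = 100.0,
    element_waist_nm: Optional[float] = None,
) -> PhotonStream:
    """Raster-scan the phantom, emitting channel/pixel/microtime-tagged photons.

    Detection per element e at scan position c is the product of the
    excitation Gaussian (waist ω at c) and the element's detection Gaussian
    (waist ω at c + o_e), i.e. an effective Gaussian of waist ω/√2 centred
    at c + o_e/2 and weighted exp(−|o_e|²/ω²) — so each element image is a
    copy of the object shifted by −o_e/2, which pixel reassignment inverts.
    """
    ny, nx = phantom.brightness_cps.shape
    rng = np.random.default_rng(config.seed)
    g = config.geometry
    px = phantom.pixel_size_nm
    w = element_waist_nm if element_waist_nm is not None else g.waists["central"]
    offsets = element_offsets_nm(g) / px  # pixels, (y, x)
    dwell_s = pixel_dwell_us * 1e-6

    sigma_px = (w / px) / (2.0 * np.sqrt(2.0))  # std of exp(-4 d^2/w^2)
    r = int(np.ceil(4 * sigma_px + np.max(np.abs(offsets)) / 2 + 1))
    uu = np.arange(-r, r + 1, dtype=np.float64)

    n_ch = offsets.shape[0]
    channels_list, t_list, micro_list = [], [], []
    b_map = phantom.brightness_cps
    bt_map = b_map * phantom.lifetime_ns
    for e in range(n_ch):
        dy, dx = offsets[e] / 2.0
        weight = np.exp(-(offsets[e, 0] ** 2 + offsets[e, 1] ** 2) * px**2 / w**2)
        ky = np.exp(-4.0 * (uu + dy) ** 2 * px**2 / w**2)
        kx = np.exp(-4.0 * (uu + dx) ** 2 * px**2 / w**2)
        kern = weight * np.outer(ky, kx)
        lam = dwell_s * fftconvolve(b_map, kern, mode="same")
        lam_t = dwell_s * fftconvolve(bt_map, kern, mode="same")
        lam = np.clip(lam, 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            tau_eff = np.where(lam > 0, lam_t / np.maximum(lam, 1e-300), 1.0)
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        iy, ix = np.nonzero(counts)
        reps = counts[iy, ix]
        pix = np.repeat(iy * nx + ix, reps)
        taus = np.repeat(tau_eff[iy, ix], reps)
        t_s = (pix + rng.random(total)) * dwell_s
        micro = rng.exponential(taus) + rng.normal(
            config.laser.irf_offset_ns, config.laser.irf_sigma_ns, size=total
        )
        channels_list.append(np.full(total, e, dtype=np.uint8))
        t_list.append(t_s)
        micro_list.append(micro)

    if t_list:
        channels = np.concatenate(channels_list)
        t_s = np.concatenate(t_list)
        micro = np.concatenate(micro_list)
    else:
        channels = np.empty(0, dtype=np.uint8)
        t_s = np.empty(0)
        micro = np.empty(0)
    order = np.argsort(t_s, kind="stable")
    scan = ScanMetadata(
        mode="raster",
        pixel_dwell_us=pixel_dwell_us,
        n_x=nx,
        n_y=ny,
        pixel_size_nm=px,
    )
    return PhotonStream(
        channels=channels[order],
        t_abs_ns=np.round(t_s[order] * 1e9).astype(np.uint64),
        microtimes_ns=np.mod(micro[order], config.laser.rep_period_ns),
        geometry=g,
        laser=config.laser,
        scan=scan,
        duration_s=ny * nx * dwell_s,
    )
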