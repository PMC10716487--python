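"""FCS model fitting, diffusion-law regression and derived statistics.

The workhorse model is the 1-component 3D-Gaussian autocorrelation

    G(τ) = offset + (1/N) · (1 + τ/τ_D)⁻¹ · (1 + τ/(k²·τ_D))^(−1/2)

with N the mean occupancy of the detection volume (the geometric γ factor
is folded into N so amplitudes are internally consistent), τ_D the
diffusion time, and k the axial eccentricity of the volume.  The 2-component
variant is the fraction-weighted sum with shared geometry.  The circular
scanning variant multiplies G by

    exp(−4R²·sin²(πτ/T) / (ω₀²·(1 + τ/τ_D)))

which decouples the fitted waist ω₀ from any assumed diffusion coefficient —
the calibration trick used to measure the nested detection volumes.

Derived quantities: D = ω₀²/(4τ_D); the diffusion law τ_D(ω₀²) whose
intercept t₀ classifies the motion (0 free, >0 hop/domain, <0 meshwork);
the confinement strength S_conf = D_central/D_sum5x5; the relative
cross-correlation amplitude of dual-color FCCS; and the Stokes–Einstein
hydrodynamic diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np
from scipy import stats

from .correlate import CorrelationCurve

__all__ = [
    "FCSFit",
    "DiffusionLawResult",
    "ConfinementResult",
    "fit_fcs",
    "calibrate_circular_fcs",
    "diffusion_law",
    "confinement_strength",
    "relative_cc_amplitude",
    "stokes_einstein_diameter",
    "g_diff_3d",
    "g_scan_circular",
]

_KB = 1.380649e-23  # J/K


def g_diff_3d(tau, N, tau_d, k, offset=0.0):
    """1-component 3D-Gaussian diffusion autocorrelation."""
    x = tau / tau_d
    return offset + (1.0 / N) / ((1.0 + x) * np.sqrt(1.0 + x / k**2))


def g_diff_3d_2c(tau, N, f1, tau_d1, tau_d2, k, offset=0.0):
    """2-component variant; fractions f1 and (1-f1) share the geometry."""
    x1 = tau / tau_d1
    x2 = tau / tau_d2
    h1 = 1.0 / ((1.0 + x1) * np.sqrt(1.0 + x1 / k**2))
    h2 = 1.0 / ((1.0 + x2) * np.sqrt(1.0 + x2 / k**2))
    return offset + (1.0 / N) * (f1 * h1 + (1.0 - f1) * h2)


def g_scan_circular(tau, N, tau_d, k, omega_nm, radius_nm, period_s, offset=0.0):
    """Circular-scanning FCS model: 3D diffusion × scan-displacement factor."""
    x = tau / tau_d
    g3d = (1.0 / N) / ((1.0 + x) * np.sqrt(1.0 + x / k**2))
    scan = np.exp(
        -4.0 * radius_nm**2 * np.sin(np.pi * tau / period_s) ** 2
        / (omega_nm**2 * (1.0 + x))
    )
    return offset + g3d * scan


@dataclass
class FCSFit:
    """Fitted FCS parameters for one detection volume."""

    params: dict  # name -> (value, stderr or nan)
    redchi: float
    volume: Optional[str] = None
    waist_nm: Optional[float] = None
    k: float = 4.5
    n_components: int = 1
    model: str = "diff3d"

    def value(self, name: str) -> float:
        return self.params[name][0]

    def stderr(self, name: str) -> float:
        return self.params[name][1]

    def tau_d(self, component: str = "only") -> tuple[float, float]:
        """(τ_D, stderr) in seconds for the selected component."""
        if self.n_components == 1:
            return self.params["tau_d"]
        return self.params["tau_d1" if component == "fast" else "tau_d2"]

    def D(self, component: str = "only") -> tuple[float, float]:
        """(D, stderr) in µm²/s via D = ω₀²/(4τ_D); requires a waist."""
        if self.waist_nm is None:
            raise ValueError("no waist attached to this fit; cannot convert tau_D to D")
        tau, tau_err = self.tau_d(component)
        w_um = self.waist_nm * 1e-3
        d = w_um**2 / (4.0 * tau)
        d_err = d * (tau_err / tau) if np.isfinite(tau_err) and tau > 0 else np.nan
        return d, d_err

    @property
    def amplitude(self) -> float:
        """Offset-subtracted zero-lag amplitude G(0) = 1/N."""
        return 1.0 / self.params["N"][0]


@dataclass
class DiffusionLawResult:
    """Linear regression of τ_D against ω₀² over the nested volumes."""

    omega2_um2: np.ndarray
    tau_d_ms: np.ndarray
    slope_ms_per_um2: float
    intercept_ms: float
    intercept_stderr_ms: float
    D_law_um2_s: float
    motion_class: str
    z: float = 1.96


@dataclass
class ConfinementResult:
    """S_conf = D(central)/D(sum5x5) with first-order error propagation."""

    S_conf: float
    stderr: float
    component_used: str = "only"


def _initial_guess(lags, G):
    """τ_D from the half-plateau lag; N from the plateau amplitude."""
    head = G[: max(3, G.size // 20)]
    g0 = float(np.median(head))
    tail = float(np.median(G[-max(3, G.size // 10):]))
    amp = g0 - tail
    if amp <= 0:
        amp = max(g0, 1e-3)
    half = tail + amp / 2.0
    below = np.nonzero(G < half)[0]
    tau_half = lags[below[0]] if below.size else lags[lags.size // 2]
    return max(amp, 1e-6), float(tau_half), tail


def _fit_weights(curve: CorrelationCurve, lags_mask):
    sem = curve.sem
    if sem is None:
        return None
    sem = sem[lags_mask]
    floor = max(np.nanmedian(sem) * 1e-2, 1e-12)
    return 1.0 / np.maximum(sem, floor)


def _run_fit(model, params, lags, G, weights):
    result = model.fit(G, params, tau=lags, weights=weights)
    if not result.success:
        raise RuntimeError(
            f"FCS fit did not converge: {result.message}; last chi2={result.chisqr:.3g}"
        )
    return result


def _pack(result, extra=()):
    out = {}
    for name, p in result.params.items():
        out[name] = (float(p.value), float(p.stderr) if p.stderr is not None else np.nan)
    for name, val in extra:
        out[name] = val
    return out


def fit_fcs(
    curve: CorrelationCurve,
    n_components: int = 1,
    k: float = 4.5,
    waist_nm: Optional[float] = None,
    fit_range_s: Optional[tuple] = None,
    fixed: Optional[dict] = None,
    volume: Optional[str] = None,
) -> FCSFit:
    """Weighted least-squares fit of the 1- or 2-component 3D model.

    ``fixed`` maps parameter names to frozen values; weights come from the
    chunk replicates when present.  For 2 components, three perturbed
    starts are tried and the best χ² kept; components are ordered
    τ_fast < τ_slow.
    """
    fixed = fixed or {}
    mask = np.isfinite(curve.G)
    if fit_range_s is not None:
        mask &= (curve.lags_s >= fit_range_s[0]) & (curve.lags_s <= fit_range_s[1])
    lags = curve.lags_s[mask]
    G = curve.G[mask]
    n_free = (3 if n_components == 1 else 5) - len(fixed)
    if lags.size <= n_free:
        raise ValueError(f"curve has {lags.size} usable points for {n_free} free parameters")
    amp, tau0, off0 = _initial_guess(lags, G)
    weights = _fit_weights(curve, mask)

    if n_components == 1:
        model = lmfit.Model(g_diff_3d, independent_vars=["tau"])
        params = model.make_params(
            N=dict(value=1.0 / amp, min=1e-6),
            tau_d=dict(value=tau0, min=lags[0] * 1e-2, max=lags[-1] * 1e2),
            k=dict(value=k, vary=False),
            offset=dict(value=off0),
        )
        for name, val in fixed.items():
            params[name].set(value=val, vary=False)
        result = _run_fit(model, params, lags, G, weights)
    else:
        model = lmfit.Model(g_diff_3d_2c, independent_vars=["tau"])
        best = None
        rng = np.random.default_rng(0)
        for trial in range(3):
            jitter = 1.0 if trial == 0 else float(rng.uniform(0.3, 3.0))
            params = model.make_params(
                N=dict(value=1.0 / amp, min=1e-6),
                f1=dict(value=0.5, min=0.0, max=1.0),
                tau_d1=dict(value=tau0 / (3.0 * jitter), min=lags[0] * 1e-2),
                tau_d2=dict(value=tau0 * 3.0 * jitter, max=lags[-1] * 1e2),
                k=dict(value=k, vary=False),
                offset=dict(value=off0),
            )
            for name, val in fixed.items():
                params[name].set(value=val, vary=False)
            try:
                res = _run_fit(model, params, lags, G, weights)
            except RuntimeError:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            raise RuntimeError("2-component FCS fit failed for all starts")
        result = best
        # canonical ordering: component 1 fast, component 2 slow
        p = result.params
        if p["tau_d1"].value > p["tau_d2"].value:
            t1, t2 = p["tau_d2"], p["tau_d1"]
            f1 = p["f1"].value
            p["tau_d1"].value, p["tau_d2"].value = t1.value, t2.value
            p["f1"].value = 1.0 - f1

    return FCSFit(
        params=_pack(result),
        redchi=float(result.redchi),
        volume=volume or curve.label or None,
        waist_nm=waist_nm,
        k=k,
        n_components=n_components,
    )


def calibrate_circular_fcs(
    curve: CorrelationCurve,
    radius_nm: float,
    period_us: float,
    k: float = 4.1,
    fit_range_s: Optional[tuple] = None,
    volume: Optional[str] = None,
) -> FCSFit:
    """Circular-scanning calibration: fit amplitude, τ_D and waist ω₀.

    The scan radius and period are fixed instrument settings; the fitted
    waist is independent of any assumed diffusion coefficient.
    """
    mask = np.isfinite(curve.G)
    if fit_range_s is not None:
        mask &= (curve.lags_s >= fit_range_s[0]) & (curve.lags_s <= fit_range_s[1])
    lags = curve.lags_s[mask]
    G = curve.G[mask]
    amp, tau0, off0 = _initial_guess(lags, G)
    weights = _fit_weights(curve, mask)
    model = lmfit.Model(g_scan_circular, independent_vars=["tau"])
    params = model.make_params(
        N=dict(value=1.0 / amp, min=1e-6),
        tau_d=dict(value=tau0, min=lags[0] * 1e-2, max=lags[-1] * 1e2),
        k=dict(value=k, vary=False),
        omega_nm=dict(value=300.0, min=50.0, max=2000.0),
        radius_nm=dict(value=radius_nm, vary=False),
        period_s=dict(value=period_us * 1e-6, vary=False),
        offset=dict(value=off0),
    )
    result = _run_fit(model, params, lags, G, weights)
    fit = FCSFit(
        params=_pack(result),
        redchi=float(result.redchi),
        volume=volume,
        waist_nm=float(result.params["omega_nm"].value),
        k=k,
        model="scan_circular",
    )
    return fit


def diffusion_law(fits: dict, component: str = "only", z: float = 1.96) -> DiffusionLawResult:
    """Ordinary least squares of τ_D on ω₀² over ≥ 2 detection volumes.

    The intercept t₀ and its standard error classify the motion: free if
    |t₀| ≤ z·SE, hop/domain-confined if t₀ > z·SE, meshwork if t₀ < −z·SE.
    """
    if len(fits) < 2:
        raise ValueError("diffusion law requires at least 2 detection volumes")
    omega2, tau_ms = [], []
    for name, fit in fits.items():
        if fit.waist_nm is None:
            raise ValueError(f"fit for {name!r} carries no waist")
        omega2.append((fit.waist_nm * 1e-3) ** 2)
        tau_ms.append(fit.tau_d(component)[0] * 1e3)
    omega2 = np.asarray(omega2)
    tau_ms = np.asarray(tau_ms)
    order = np.argsort(omega2)
    omega2, tau_ms = omega2[order], tau_ms[order]
    res = stats.linregress(omega2, tau_ms)
    if len(fits) == 2:
        # exact line: no residual dof for an intercept error
        se = np.nan
    else:
        se = float(res.intercept_stderr)
    t0 = float(res.intercept)
    # an intercept negligible against the diffusion times is free regardless
    # of a (possibly zero) regression standard error
    thresh = max(z * se if np.isfinite(se) else 0.0, 1e-6 * float(np.mean(tau_ms)))
    if t0 > thresh:
        cls = "hop_or_domain"
    elif t0 < -thresh:
        cls = "meshwork"
    else:
        cls = "free"
    slope = float(res.slope)  # ms per um^2
    d_law = 1e3 / (4.0 * slope) if slope > 0 else np.nan  # um^2/s
    return DiffusionLawResult(
        omega2_um2=omega2,
        tau_d_ms=tau_ms,
        slope_ms_per_um2=slope,
        intercept_ms=t0,
        intercept_stderr_ms=se,
        D_law_um2_s=d_law,
        motion_class=cls,
        z=z,
    )


def confinement_strength(
    fit_central: FCSFit, fit_sum5x5: FCSFit, component: str = "only"
) -> ConfinementResult:
    """S_conf = D(central)/D(sum5x5); 1 free, <1 domain-confined, >1 meshwork."""
    d_c, e_c = fit_central.D(component)
    d_5, e_5 = fit_sum5x5.D(component)
    if d_c <= 0 or d_5 <= 0:
        raise ValueError("non-positive diffusion coefficient")
    s = d_c / d_5
    rel = np.sqrt(
        (e_c / d_c) ** 2 + (e_5 / d_5) ** 2
        if np.isfinite(e_c) and np.isfinite(e_5)
        else np.nan
    )
    return ConfinementResult(S_conf=s, stderr=s * rel, component_used=component)


def relative_cc_amplitude(auto_green: FCSFit, auto_red: FCSFit, cross: FCSFit) -> dict:
    """Relative FCCS amplitudes: G_x(0)/G_red(0) and G_x(0)/G_green(0).

    Amplitudes are fitted, offset-subtracted zero-lag values; the ratios
    report the co-diffusing (interacting) fraction relative to each species.
    """
    g_g = auto_green.amplitude
    g_r = auto_red.amplitude
    g_x = cross.amplitude
    if g_g <= 0 or g_r <= 0:
        raise ValueError("non-positive autocorrelation amplitude")
    return {"rel_to_green": g_x / g_r, "rel_to_red": g_x / g_g}


def stokes_einstein_diameter(D_um2_s: float, T_K: float = 293.0, viscosity_mPa_s: float = 1.0) -> float:
    """Hydrodynamic diameter d = k_B·T/(3π·η·D), in nm."""
    if min(D_um2_s, T_K, viscosity_mPa_s) <= 0:
        raise ValueError("inputs must be positive")
    d_m = _KB * T_K / (3.0 * np.pi * viscosity_mPa_s * 1e-3 * D_um2_s * 1e-12)
    return d_m * 1e9
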