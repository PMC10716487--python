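import numpy as np
import pytest

from spffs import (
    LaserConfig,
    calibrate_phasor,
    decay_histogram,
    fit_monoexp,
    phasor,
    phasor_image,
    phasor_segment,
)
from spffs.lifetime import (
    histogram_from_microtimes,
    lifetime_map_tailfit,
    phasor_lifetime_ns,
    phasor_theoretical,
)
from spffs.simulate import simulate_microtimes

from conftest import make_stream


class TestDecayHistogram:
    def test_single_occupied_bin(self):
        s = make_stream([12] * 4, range(4), [5.0] * 4, duration_s=1e-8)
        h = decay_histogram(s, n_bins=25)
        assert h.counts.sum() == 4
        assert (h.counts > 0).sum() == 1

    def test_analytic_exponential_bin_contents(self):
        """Histogram of Exp(2.5 ns) draws matches the analytic bin integrals."""
        rng = np.random.default_rng(2)
        tau, t_rep, n = 2.5, 25.0, 1_000_000
        micro = np.mod(rng.exponential(tau, n), t_rep)
        h = histogram_from_microtimes(micro, t_rep, n_bins=64)
        edges = h.edges_ns
        # folded exponential: sum over wraps collapses to a geometric factor
        p = (np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)) / (1 - np.exp(-t_rep / tau))
        expected = n * p
        z = (h.counts - expected) / np.sqrt(expected)
        assert np.all(np.abs(z) < 5)

    def test_channels_statistically_identical(self):
        """Per-channel decay histograms of a uniform simulation agree (χ²)."""
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(4)
        n = 60_000
        channels = rng.integers(0, 25, n).astype(np.uint8)
        micro = np.mod(rng.exponential(5.0, n), 25.0)
        s = make_stream(channels, np.sort(rng.integers(0, int(1e9), n)), micro, duration_s=1.0)
        tables = []
        for ch in range(0, 25, 6):
            h = decay_histogram(s, n_bins=16, selection=s.channels == ch)
            tables.append(h.counts)
        _, p, *_ = chi2_contingency(np.array(tables))
        assert p > 0.001

    def test_requires_microtimes(self):
        s = make_stream([12], [0], duration_s=1e-9)
        with pytest.raises(ValueError):
            decay_histogram(s)


class TestMonoexpFit:
    def test_exact_exponential(self):
        t_rep = 25.0
        edges = np.linspace(0, t_rep, 257)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = 1e5 * np.exp(-centers / 1.0)
        from spffs.lifetime import DecayHistogram

        h = DecayHistogram(edges_ns=edges, counts=counts, rep_period_ns=t_rep)
        fit = fit_monoexp(h)
        assert fit.tau_ns == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("tau_true, tol", [(1.3, 0.1), (2.55, 0.051)])
    def test_simulated_decay_recovery(self, tau_true, tol):
        """Tail fit recovers the nanosphere (1.3 ns) and eGFP-regime (2.55 ns) lifetimes."""
        micro = simulate_microtimes(100_000, tau_true, LaserConfig(), seed=6)
        h = histogram_from_microtimes(micro, 25.0, n_bins=256)
        fit = fit_monoexp(h)
        assert fit.tau_ns == pytest.approx(tau_true, abs=tol)

    def test_window_too_small(self):
        micro = simulate_microtimes(1000, 2.0, seed=1)
        h = histogram_from_microtimes(micro, 25.0, n_bins=256)
        with pytest.raises(ValueError, match="5 bins"):
            fit_monoexp(h, window_ns=(24.8, 25.0))


class TestPhasor:
    def test_delta_decay_at_unity(self):
        h = histogram_from_microtimes(np.full(1000, 0.04), 25.0, n_bins=256)
        p = phasor(h)
        assert p.g == pytest.approx(1.0, abs=1e-3)
        assert p.s == pytest.approx(0.0, abs=0.05)

    def test_closed_form_coordinates(self):
        """τ = 2.5 ns at T = 12.5 ns sits at (g, s) = (0.3877, 0.4872)."""
        theo = phasor_theoretical(2.5, 12.5)
        assert theo.g == pytest.approx(0.3877, abs=2e-4)
        assert theo.s == pytest.approx(0.4872, abs=2e-4)
        rng = np.random.default_rng(3)
        micro = np.mod(rng.exponential(2.5, 2_000_000), 12.5)
        p = phasor(histogram_from_microtimes(micro, 12.5, n_bins=512))
        assert p.g == pytest.approx(theo.g, abs=0.005)
        assert p.s == pytest.approx(theo.s, abs=0.005)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.5, 5.0])
    def test_monoexp_on_universal_circle(self, tau):
        rng = np.random.default_rng(int(tau * 10))
        micro = np.mod(rng.exponential(tau, 500_000), 25.0)
        p = phasor(histogram_from_microtimes(micro, 25.0, n_bins=512))
        assert p.g**2 + p.s**2 == pytest.approx(p.g, abs=0.01)

    def test_mixture_on_chord(self):
        """A two-lifetime mixture lies on the chord between the pure phasors."""
        rng = np.random.default_rng(9)
        t_rep = 25.0
        pures = {}
        for tau in (1.0, 4.0):
            micro = np.mod(rng.exponential(tau, 400_000), t_rep)
            pures[tau] = phasor(histogram_from_microtimes(micro, t_rep, 512))
        mix = np.concatenate(
            [rng.exponential(1.0, 240_000), rng.exponential(4.0, 160_000)]
        )
        pm = phasor(histogram_from_microtimes(np.mod(mix, t_rep), t_rep, 512))
        p1, p2 = pures[1.0], pures[4.0]
        # collinearity: cross product of (pm-p1) and (p2-p1) vanishes
        cross = (pm.g - p1.g) * (p2.s - p1.s) - (pm.s - p1.s) * (p2.g - p1.g)
        assert abs(cross) < 0.005
        # inside the circle
        assert pm.g**2 + pm.s**2 < pm.g

    def test_phasor_tau_matches_tailfit(self):
        micro = simulate_microtimes(500_000, 2.5, LaserConfig(irf_offset_ns=0.0, irf_sigma_ns=0.05), seed=11)
        h = histogram_from_microtimes(micro, 25.0, 512)
        tau_phasor = phasor_lifetime_ns(phasor(h), rep_period_ns=25.0)
        tau_fit = fit_monoexp(h).tau_ns
        assert tau_phasor == pytest.approx(tau_fit, rel=0.05)


class TestPhasorCalibration:
    def test_identity_when_measured_equals_theoretical(self):
        theo = phasor_theoretical(1.0, 25.0)
        meas = type(theo)(g=theo.g, s=theo.s, calibrated=False)
        cal = calibrate_phasor(meas, 1.0, 25.0)
        out = cal.apply(meas)
        assert out.g == pytest.approx(theo.g, abs=1e-12)
        assert out.s == pytest.approx(theo.s, abs=1e-12)

    def test_two_dye_consistency(self):
        """Calibration from the 1 ns dye puts the 3.9 ns dye on the circle."""
        laser = LaserConfig(irf_offset_ns=1.0, irf_sigma_ns=0.1)
        ref = phasor(histogram_from_microtimes(simulate_microtimes(400_000, 1.0, laser, seed=5), 25.0, 512))
        cal = calibrate_phasor(ref, 1.0, 25.0)
        sample = phasor(
            histogram_from_microtimes(simulate_microtimes(400_000, 3.9, laser, seed=6), 25.0, 512)
        )
        out = cal.apply(sample)
        theo = phasor_theoretical(3.9, 25.0)
        assert out.g == pytest.approx(theo.g, abs=0.01)
        assert out.s == pytest.approx(theo.s, abs=0.01)

    def test_double_calibration_guarded(self):
        ref = phasor_theoretical(1.0, 25.0)
        meas = type(ref)(g=0.5, s=0.4)
        cal = calibrate_phasor(meas, 1.0, 25.0)
        once = cal.apply(meas)
        with pytest.raises(ValueError, match="twice"):
            cal.apply(once)

    def test_degenerate_reference(self):
        from spffs import PhasorPoint

        with pytest.raises(ValueError, match="degenerate"):
            calibrate_phasor(PhasorPoint(g=0.0, s=0.0), 1.0, 25.0)


class TestPhasorSegmentation:
    @staticmethod
    def _two_lifetime_stack(rng, tau_map, counts_per_px=5000, t_rep=25.0, n_dt=64):
        ny, nx = tau_map.shape
        stack = np.zeros((ny, nx, n_dt))
        edges = np.linspace(0, t_rep, n_dt + 1)
        for iy in range(ny):
            for ix in range(nx):
                micro = np.mod(rng.exponential(tau_map[iy, ix], counts_per_px), t_rep)
                stack[iy, ix] = np.histogram(micro, bins=edges)[0]
        return stack

    def test_disc_layout_recovered(self, rng):
        tau_map = np.full((24, 24), 2.6)
        yy, xx = np.indices(tau_map.shape)
        inside = (yy - 12) ** 2 + (xx - 12) ** 2 <= 36
        tau_map[inside] = 2.0
        stack = self._two_lifetime_stack(rng, tau_map)
        g, s, mask = phasor_image(stack, 25.0)
        labels, info = phasor_segment(g, mask)
        assert not info["degenerate"]
        short = labels == 2
        agreement = (short == inside).mean()
        assert agreement >= 0.95

    def test_uniform_lifetime_degenerate(self):
        stack = np.zeros((4, 4, 32))
        t = (np.arange(32) + 0.5) * 25.0 / 32
        stack[:, :] = 1e4 * np.exp(-t / 2.5)
        g, s, mask = phasor_image(stack, 25.0)
        labels, info = phasor_segment(g, mask)
        assert info["degenerate"]
        assert set(np.unique(labels)) == {1}

    def test_threshold_one_raises(self):
        stack = np.random.default_rng(1).poisson(10, size=(4, 4, 32)).astype(float)
        with pytest.raises(ValueError):
            phasor_image(stack, 25.0, intensity_threshold=1.5)


def test_lifetime_map_tailfit_accuracy(rng):
    t_rep, n_dt = 25.0, 64
    stack = np.zeros((6, 6, n_dt))
    edges = np.linspace(0, t_rep, n_dt + 1)
    for iy in range(6):
        for ix in range(6):
            micro = np.mod(rng.exponential(2.5, 2000) + 1.0, t_rep)
            stack[iy, ix] = np.histogram(micro, bins=edges)[0]
    tau = lifetime_map_tailfit(stack, t_rep)
    assert np.nanmedian(np.abs(tau - 2.5) / 2.5) < 0.05
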