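import numpy as np
import pytest

from spffs import (
    EmitterSpecies,
    LaserConfig,
    MotionModel,
    SimulationConfig,
    emit_photons,
    merge_channels,
    simulate_fcs,
    simulate_trajectories,
)
from spffs.simulate import bead_phantom, disc_phantom, simulate_microtimes, simulate_scan


def unwrap(traj, box):
    """Minimum-image unwrapping of periodic trajectories (oracle-side)."""
    d = np.diff(traj, axis=0)
    d -= box * np.round(d / box)
    return traj[0] + np.concatenate([np.zeros((1,) + traj.shape[1:]), np.cumsum(d, axis=0)])


class TestTrajectories:
    def test_zero_diffusion_is_static(self):
        cfg = SimulationConfig(
            duration_s=1e-3, dt_us=10.0, seed=1,
            species=[EmitterSpecies(D_um2_s=0.0, n_emitters=5)],
        )
        traj = simulate_trajectories(cfg)
        assert np.all(traj == traj[0])

    def test_msd_slope_matches_6dt(self):
        """Free 3D diffusion: MSD(t) = 6·D·t within 5%."""
        d_true = 10.0
        cfg = SimulationConfig(
            duration_s=0.1, dt_us=1.0, seed=2,
            species=[EmitterSpecies(D_um2_s=d_true, n_emitters=50)],
        )
        traj = simulate_trajectories(cfg)
        u = unwrap(traj, np.asarray(cfg.box_um))
        lags = np.array([10, 30, 100, 300, 1000])
        msd = np.array([((u[k:] - u[:-k]) ** 2).sum(axis=-1).mean() for k in lags])
        t = lags * 1e-6
        slope = np.polyfit(t, msd, 1)[0]
        assert slope == pytest.approx(6 * d_true, rel=0.05)

    def test_hop_probability_one_is_free(self):
        base = dict(duration_s=0.01, dt_us=1.0, seed=3)
        free_cfg = SimulationConfig(
            species=[EmitterSpecies(D_um2_s=5.0, n_emitters=40)], **base
        )
        hop_cfg = SimulationConfig(
            species=[EmitterSpecies(D_um2_s=5.0, n_emitters=40)],
            motion=MotionModel(kind="hop", hop_probability=1.0, mesh_size_nm=200.0),
            **base,
        )
        box = np.asarray(free_cfg.box_um)
        msds = []
        for cfg in (free_cfg, hop_cfg):
            u = unwrap(simulate_trajectories(cfg), box)
            msds.append(((u[100:] - u[:-100]) ** 2).sum(axis=-1).mean())
        assert msds[1] == pytest.approx(msds[0], rel=0.1)

    def test_hop_partial_probability_subdiffusive(self):
        """hop_probability < 1 suppresses long-time MSD below free diffusion."""
        base = dict(duration_s=0.02, dt_us=2.0, seed=4)
        hop_cfg = SimulationConfig(
            species=[EmitterSpecies(D_um2_s=5.0, n_emitters=40)],
            motion=MotionModel(kind="hop", hop_probability=0.05, mesh_size_nm=150.0),
            **base,
        )
        free_cfg = SimulationConfig(species=[EmitterSpecies(D_um2_s=5.0, n_emitters=40)], **base)
        box = np.asarray(free_cfg.box_um)
        k = 2000
        u_hop = unwrap(simulate_trajectories(hop_cfg), box)
        u_free = unwrap(simulate_trajectories(free_cfg), box)
        msd_hop = ((u_hop[k:] - u_hop[:-k]) ** 2).sum(axis=-1).mean()
        msd_free = ((u_free[k:] - u_free[:-k]) ** 2).sum(axis=-1).mean()
        assert msd_hop < 0.6 * msd_free

    def test_trap_confines_trapped_emitters(self):
        cfg = SimulationConfig(
            duration_s=0.02, dt_us=2.0, seed=5,
            species=[EmitterSpecies(D_um2_s=5.0, n_emitters=60)],
            motion=MotionModel(
                kind="trap", domain_radius_nm=100.0, domain_spacing_nm=500.0,
                trap_rate_s=5e4, escape_rate_s=5.0, D_in_um2_s=0.5,
            ),
        )
        box = np.asarray(cfg.box_um)
        u = unwrap(simulate_trajectories(cfg), box)
        free = unwrap(
            simulate_trajectories(
                SimulationConfig(duration_s=0.02, dt_us=2.0, seed=5,
                                 species=[EmitterSpecies(D_um2_s=5.0, n_emitters=60)])
            ),
            box,
        )
        k = 5000
        msd_trap = ((u[k:] - u[:-k]) ** 2).sum(axis=-1).mean()
        msd_free = ((free[k:] - free[:-k]) ** 2).sum(axis=-1).mean()
        assert msd_trap < 0.5 * msd_free

    def test_dt_precondition_enforced(self):
        with pytest.raises(ValueError, match="dt"):
            SimulationConfig(dt_us=100.0, species=[EmitterSpecies(D_um2_s=100.0)])


class TestEmission:
    def test_zero_brightness_empty_stream(self):
        cfg = SimulationConfig(
            duration_s=0.01, dt_us=10.0, seed=1,
            species=[EmitterSpecies(D_um2_s=1.0, brightness_cps=0.0, n_emitters=10)],
        )
        assert len(simulate_fcs(cfg)) == 0

    def test_immobile_emitter_count_rate(self):
        """A parked emitter at the volume centre fires at the peak rate."""
        cfg = SimulationConfig(
            duration_s=2.0, dt_us=10.0, seed=2, box_um=(8.0, 8.0, 8.0),
            species=[EmitterSpecies(D_um2_s=0.0, brightness_cps=2e5, n_emitters=1)],
        )
        traj = np.zeros((cfg.n_steps + 1, 1, 3))
        stream = emit_photons(traj, cfg)
        expected = 2e5 * 2.0
        assert abs(len(stream) - expected) < 3 * np.sqrt(expected)

    def test_microtime_tail_recovery(self):
        """Generator→fitter round trip on microtimes, 2% accuracy."""
        from spffs.lifetime import fit_monoexp, histogram_from_microtimes

        micro = simulate_microtimes(1_000_000, 2.5, LaserConfig(), seed=3)
        fit = fit_monoexp(histogram_from_microtimes(micro, 25.0, 256))
        assert fit.tau_ns == pytest.approx(2.5, rel=0.02)

    def test_reproducible_with_seed(self):
        cfg = SimulationConfig(
            duration_s=0.5, dt_us=20.0, seed=77,
            species=[EmitterSpecies(D_um2_s=10.0, brightness_cps=5e5, n_emitters=100)],
        )
        a = simulate_fcs(cfg)
        b = simulate_fcs(cfg)
        assert a.equals(b)

    def test_folded_decay_rises_at_irf_offset(self):
        from spffs.lifetime import histogram_from_microtimes

        laser = LaserConfig(irf_offset_ns=2.0, irf_sigma_ns=0.1)
        micro = simulate_microtimes(200_000, 2.0, laser, seed=4)
        h = histogram_from_microtimes(micro, 25.0, 256)
        peak_t = h.centers_ns[np.argmax(h.counts)]
        assert peak_t == pytest.approx(laser.irf_offset_ns, abs=0.3)
        # single rising edge: counts before the rise are low
        pre = h.counts[h.centers_ns < 1.0].sum()
        assert pre < 0.02 * h.total


class TestDualColor:
    @staticmethod
    def _dual_cfg(fraction, seed=6):
        return SimulationConfig(
            duration_s=10.0, dt_us=20.0, seed=seed, co_diffusing_fraction=fraction,
            species=[
                EmitterSpecies(D_um2_s=10.0, brightness_cps=4e5, n_emitters=300, color="green"),
                EmitterSpecies(D_um2_s=10.0, brightness_cps=4e5, n_emitters=300, color="red",
                               lifetime_ns=3.5),
            ],
        )

    def test_cross_amplitude_monotone_in_bound_fraction(self):
        from spffs import LagDesign, correlate_photons, cross_color_correlation

        amps = {}
        design = LagDesign(tau_max_s=0.1)
        for f in (0.0, 0.5, 1.0):
            s = simulate_fcs(self._dual_cfg(f))
            green = merge_channels(s, "sum3x3")
            red = merge_channels(s, "single_element")
            cross = cross_color_correlation(green, red, design=design)
            early = (cross.lags_s > 50e-6) & (cross.lags_s < 300e-6)
            amps[f] = cross.G[early].mean()
        assert abs(amps[0.0]) < 0.05 * amps[1.0] + 0.01
        assert 0.2 * amps[1.0] < amps[0.5] < 0.8 * amps[1.0]


class TestRasterScan:
    def test_uniform_phantom_poisson_homogeneous(self):
        from spffs.ism import build_stack

        phantom = disc_phantom(shape=(40, 40), disc_centers=(), brightness_out_cps=2e5)
        cfg = SimulationConfig(duration_s=1.0, dt_us=10.0, seed=7,
                               species=[EmitterSpecies(D_um2_s=1.0)])
        stream = simulate_scan(phantom, cfg, pixel_dwell_us=50.0)
        stack = build_stack(stream)
        # interior only: the detection kernel runs off the frame at the edges
        per_pixel = stack.counts.sum(axis=(0, 3))[14:-14, 14:-14]
        mean = per_pixel.mean()
        assert per_pixel.var() / mean == pytest.approx(1.0, rel=0.35)

    def test_bead_channel_centroids_displaced_half_pitch(self):
        """Per-channel bead images shift by ≈ pitch/2, antisymmetric across the array."""
        from spffs.ism import build_stack

        phantom = bead_phantom(shape=(33, 33), center=(16, 16), brightness_cps=5e6,
                               pixel_size_nm=25.0)
        cfg = SimulationConfig(duration_s=1.0, dt_us=10.0, seed=8,
                               species=[EmitterSpecies(D_um2_s=1.0)])
        stream = simulate_scan(phantom, cfg, pixel_dwell_us=200.0)
        stack = build_stack(stream)
        imgs = stack.channel_images().astype(float)
        yy, xx = np.indices(imgs.shape[1:])
        pitch_px = cfg.geometry.pitch_sample_nm / 25.0

        def centroid(img):
            return np.array([(yy * img).sum(), (xx * img).sum()]) / img.sum()

        c_central = centroid(imgs[12])
        c_right = centroid(imgs[13])   # column +1 element
        c_left = centroid(imgs[11])
        dx_right = c_right[1] - c_central[1]
        dx_left = c_left[1] - c_central[1]
        assert dx_right == pytest.approx(-pitch_px / 2, abs=0.3)
        assert dx_left == pytest.approx(+pitch_px / 2, abs=0.3)
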