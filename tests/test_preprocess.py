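import numpy as np
import pytest
from scipy import signal

from bna.errors import (
    AllEpochsRejectedError,
    DegenerateMontageError,
    InterpolationError,
)
from bna.io import ERPRecord, Montage
from bna.preprocess import (
    FREQUENCY_BANDS,
    GridGeometry,
    average_epochs,
    bandpass_decompose,
    design_bandpass,
    interpolate_grid,
    project_montage,
    reject_artifacts,
)
from bna.simulate import SimConfig, ComponentSpec, simulate_dataset


def _record(data, rate=256.0, t0=0.0):
    data = np.asarray(data, dtype=float)
    times = t0 + 1000.0 / rate * np.arange(data.shape[1])
    return ERPRecord(subject_id="s", visit_id="V1", condition="Target",
                     sampling_rate_hz=rate, times_ms=times, data=data)


class TestArtifactRejection:
    def _epochs(self, rng, n_trials=60, n_ch=37, n_t=128, sd=5.0):
        return sd * rng.standard_normal((n_trials, n_ch, n_t))

    def test_clean_epochs_untouched(self, montage):
        rng = np.random.default_rng(0)
        epochs = self._epochs(rng)  # max |amp| well below 100
        clean, log = reject_artifacts(epochs, montage)
        assert log == []
        np.testing.assert_array_equal(clean, epochs)

    def test_planted_overrange_epochs_dropped_exactly(self, montage):
        rng = np.random.default_rng(1)
        epochs = self._epochs(rng, sd=20.0)
        planted = [3, 10, 25, 40, 59]
        for tr in planted:
            epochs[tr, tr % epochs.shape[1], 30:40] += 150.0
        # independent oracle: direct threshold scan
        expect = {tr for tr in range(60)
                  if np.any(np.abs(epochs[tr]) > 100.0)}
        assert set(planted) <= expect
        clean, log = reject_artifacts(epochs, montage)
        dropped = {e["index"] for e in log if e["kind"] == "epoch"}
        assert dropped == expect
        assert clean.shape[0] == 60 - len(expect)

    def test_exact_boundary_amplitude_retained(self, montage):
        rng = np.random.default_rng(2)
        epochs = self._epochs(rng, sd=20.0)
        epochs[7, 0, 50] = 100.0   # exactly at the limit: inside the range
        epochs[9, 0, 50] = -100.0
        _, log = reject_artifacts(epochs, montage)
        dropped = {e["index"] for e in log if e["kind"] == "epoch"}
        assert 7 not in dropped and 9 not in dropped

    def test_seven_sd_outlier_dropped_within_range(self, montage):
        rng = np.random.default_rng(3)
        epochs = self._epochs(rng, sd=5.0)
        epochs[12, 4, 60] = 90.0  # inside +-100 but ~18 channel sds
        _, log = reject_artifacts(epochs, montage)
        assert {"kind": "epoch", "index": 12, "rule": "sd"} in log

    def test_dissimilar_channel_repaired(self, montage):
        rng = np.random.default_rng(4)
        n_ch = montage.n_channels
        common = 10.0 * np.sin(2 * np.pi * 5 * np.arange(128) / 256.0)
        epochs = common[None, None, :] + 0.5 * rng.standard_normal(
            (20, n_ch, 128))
        epochs[:, 6, :] = 20.0 * rng.standard_normal((20, 128))  # broken
        clean, log = reject_artifacts(epochs, montage)
        assert {"kind": "channel", "index": 6,
                "rule": "dissimilarity"} in log
        # repaired channel now tracks the common signal
        corr = np.corrcoef(clean[:, 6, :].ravel(),
                           np.tile(common, 20))[0, 1]
        assert corr > 0.9

    def test_all_rejected_raises(self, montage):
        epochs = np.full((3, 37, 16), 120.0)
        epochs[:, :, :2] = 0.0  # keep channel-amplitude fraction under 1.0
        with pytest.raises(AllEpochsRejectedError):
            reject_artifacts(np.full((3, 37, 16), 150.0), montage)


class TestAveraging:
    def test_identical_epochs_average_to_one(self):
        ep = np.tile(np.arange(12.0).reshape(1, 3, 4), (5, 1, 1))
        rec = average_epochs(ep, times_ms=np.arange(4) * 4.0,
                             sampling_rate_hz=250.0, baseline=False)
        np.testing.assert_array_equal(rec.data, ep[0])

    def test_symmetric_epochs_cancel(self):
        ep = np.stack([np.ones((3, 4)), -np.ones((3, 4))])
        rec = average_epochs(ep, times_ms=np.arange(4) * 4.0,
                             sampling_rate_hz=250.0, baseline=False)
        np.testing.assert_array_equal(rec.data, np.zeros((3, 4)))

    def test_baseline_subtracts_prestimulus_mean(self):
        ep = np.ones((2, 2, 6)) * 3.0
        rec = average_epochs(ep, times_ms=np.arange(6) * 4.0 - 8.0,
                             sampling_rate_hz=250.0, baseline=True)
        np.testing.assert_allclose(rec.data, 0.0, atol=1e-12)

    def test_noisy_average_within_clt_bound(self):
        rng = np.random.default_rng(5)
        template = np.outer(np.ones(4), np.sin(np.arange(64) / 4.0))
        ep = template[None] + 2.0 * rng.standard_normal((60, 4, 64))
        rec = average_epochs(ep, times_ms=np.arange(64) * 4.0,
                             sampling_rate_hz=250.0, baseline=False)
        se = 2.0 / np.sqrt(60)
        assert np.max(np.abs(rec.data - template)) < 5.0 * se


class TestBandpass:
    def test_band_edges_as_published(self):
        assert FREQUENCY_BANDS == {"delta": (0.5, 4.0), "theta": (3.0, 8.0),
                                   "alpha": (7.0, 13.0), "beta": (12.0, 30.0)}

    def test_zero_input_zero_output(self):
        rec = _record(np.zeros((3, 257)))
        out = bandpass_decompose(rec)
        assert set(out) == set(FREQUENCY_BANDS)
        for band in out:
            np.testing.assert_array_equal(out[band], 0.0)

    def test_five_hz_tone_split_matches_designed_response(self):
        """A 5 Hz tone passes theta nearly unattenuated and is strongly
        rejected by delta, matching the designed filter's |H|^2 at 5 Hz."""
        rate, n = 256.0, 8192  # long enough to out-run the delta transient
        t = np.arange(n) / rate
        rec = _record(np.sin(2 * np.pi * 5.0 * t)[None, :], rate=rate)
        out = bandpass_decompose(rec, bands=("delta", "theta"))
        mid = slice(n // 4, 3 * n // 4)
        for band in ("delta", "theta"):
            b = design_bandpass(band, rate, n)
            _, h = signal.freqz(b, worN=[5.0], fs=rate)
            predicted = np.abs(h[0]) ** 2  # forward + reverse pass
            measured = np.sqrt(2.0) * out[band][0, mid].std()
            assert measured == pytest.approx(predicted, abs=0.02)
        theta_amp = np.sqrt(2.0) * out["theta"][0, mid].std()
        delta_amp = np.sqrt(2.0) * out["delta"][0, mid].std()
        assert abs(theta_amp - 1.0) < 0.05
        assert delta_amp < 0.15

    def test_zero_phase(self):
        """Filtering a band-limited signal must not shift it in time."""
        rate, n = 256.0, 1024
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * 5.0 * t) * signal.windows.tukey(n, 0.4)
        rec = _record(x[None, :], rate=rate)
        y = bandpass_decompose(rec, bands=("theta",))["theta"][0]
        xc = signal.correlate(y, x, mode="full")
        assert np.argmax(xc) == n - 1


class TestProjection:
    def _montage(self):
        pts = [("Vtx", 0, 0, 1.0), ("Rt", 1.0, 0, 0), ("Lt", -1.0, 0, 0),
               ("Ant", 0, 1.0, 0), ("Post", 0, -1.0, 0),
               ("RA", 0.5, 0.5, np.sqrt(0.5)), ("LA", -0.5, 0.5, np.sqrt(0.5))]
        return Montage(labels=[p[0] for p in pts],
                       pos3d=np.array([p[1:] for p in pts]))

    def test_vertex_maps_to_grid_center(self):
        m = project_montage(self._montage())
        i = m.labels.index("Vtx")
        np.testing.assert_allclose(m.pos2d[i], [0.5, 0.5], atol=1e-9)

    def test_midline_symmetry(self):
        m = project_montage(self._montage())
        ra = m.pos2d[m.labels.index("RA")]
        la = m.pos2d[m.labels.index("LA")]
        assert abs((ra[0] - 0.5) + (la[0] - 0.5)) < 1e-9
        assert abs(ra[1] - la[1]) < 1e-9

    def test_equator_arc_length(self):
        """An electrode 90 degrees from the vertex lands at planar radius
        (pi/2) x scale, where scale maps the outermost electrode to 0.45."""
        m = project_montage(self._montage())
        rt = m.pos2d[m.labels.index("Rt")]
        scale = 0.45 / (np.pi / 2)  # equator is the outermost electrode here
        np.testing.assert_allclose(rt, [0.5 + (np.pi / 2) * scale, 0.5],
                                   atol=1e-9)

    def test_orientation_preserved(self):
        m = project_montage(self._montage())
        assert m.pos2d[m.labels.index("Rt")][0] > 0.5   # right -> +u
        assert m.pos2d[m.labels.index("Ant")][1] > 0.5  # anterior -> +v

    def test_coplanar_montage_rejected(self):
        pts = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0],
                        [0.7, 0.7, 0], [-0.7, 0.7, 0]], dtype=float)
        with pytest.raises(DegenerateMontageError):
            project_montage(Montage(labels=[f"e{i}" for i in range(6)],
                                    pos3d=pts))


class TestGridInterpolation:
    def test_constant_field_reproduced(self, montage, geometry):
        mats = {"theta": np.full((montage.n_channels, 3), 7.5)}
        vols = interpolate_grid(mats, montage, geometry, np.arange(3) * 4.0)
        v = vols[0]
        assert v.data.shape == (33, 37, 3)
        inside = v.data[geometry.mask, :]
        np.testing.assert_allclose(inside, 7.5, atol=1e-9)
        assert np.isnan(v.data[~geometry.mask, :]).all()

    def test_interpolant_passes_through_electrodes(self, geometry):
        # electrodes placed exactly on grid pixels
        px = np.array([[8, 10], [16, 18], [24, 10], [16, 28], [12, 20]])
        pos2d = px / np.array([32.0, 36.0])
        m = Montage(labels=[f"e{i}" for i in range(5)],
                    pos3d=np.column_stack([pos2d, np.ones(5)]), pos2d=pos2d)
        values = np.array([[3.0], [-1.0], [4.5], [0.25], [2.0]])
        vols = interpolate_grid({"theta": values}, m, geometry, [0.0])
        for (i, j), val in zip(px, values[:, 0]):
            assert vols[0].data[i, j, 0] == pytest.approx(val, abs=1e-6)

    def test_linearity(self, montage, geometry):
        rng = np.random.default_rng(6)
        v1 = rng.normal(size=(montage.n_channels, 2))
        v2 = rng.normal(size=(montage.n_channels, 2))
        times = np.arange(2) * 4.0
        g = lambda v: interpolate_grid({"theta": v}, montage, geometry,
                                       times)[0].data
        lhs = g(2.0 * v1 - 3.0 * v2)
        rhs = 2.0 * g(v1) - 3.0 * g(v2)
        np.testing.assert_allclose(lhs[geometry.mask], rhs[geometry.mask],
                                   atol=1e-9)

    def test_too_few_electrodes(self, geometry):
        m = Montage(labels=["a", "b", "c"], pos3d=np.eye(3),
                    pos2d=np.array([[0.3, 0.3], [0.7, 0.3], [0.5, 0.7]]))
        with pytest.raises(InterpolationError):
            interpolate_grid({"theta": np.zeros((3, 1))}, m, geometry, [0.0])


class TestEndToEndLatencyPreservation:
    def test_noise_free_peak_latency_within_one_sample(self, geometry):
        """Band-pass plus grid interpolation must not move a planted
        component's spatiotemporal peak by more than one sample."""
        from bna.pipeline import erp_to_volumes

        comp = ComponentSpec(name="p3", latency_ms=300.0, amplitude_uv=10.0,
                             carrier_band="delta", center_2d=(0.5, 0.4),
                             spatial_sd=0.15, latency_jitter_sd_ms=0.0,
                             amplitude_jitter_sd_uv=0.0)
        cfg = SimConfig(n_subjects=1, n_trials=1,
                        condition_proportions={"Target": 1.0},
                        noise_sd_uv=0.0, between_subject_amp_sd_uv=0.0,
                        seed=8)
        ds = simulate_dataset(cfg, [comp])
        rec = ds.erps[("sub000", "V1", "Target")]
        vol = erp_to_volumes(rec, ds.montage, geometry, ("delta",))[0]
        data = np.where(np.isfinite(vol.data), vol.data, -np.inf)
        t_peak = vol.times_ms[np.unravel_index(np.argmax(data),
                                               data.shape)[2]]
        dt = 1000.0 / cfg.sampling_rate_hz
        assert abs(t_peak - 300.0) <= dt
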