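"""Phantom construction, breathing waveform, forward model, spike protocols."""

import numpy as np
import pytest

from eitrpca.datamodel import VoltageMatrix
from eitrpca.forward import (
    build_fem,
    drive_currents,
    forward_frame,
    forward_voltages,
    measurement_jacobian,
    solve_patterns,
)
from eitrpca.mesh import make_phantom
from eitrpca.simulate import (
    BreathingWaveform,
    SpikeSpec,
    heterogeneous_case,
    inject_spikes,
    protocol_sweep,
    synth_breathing,
)


@pytest.fixture(scope="module")
def disc():
    return make_phantom("circular")


class TestPhantom:
    def test_every_element_labelled_exactly_once(self, disc):
        labels = set(disc.element_labels)
        assert labels <= {"background", "left_lung", "right_lung"}
        assert disc.element_labels.shape == (disc.n_elements,)
        assert "left_lung" in labels and "right_lung" in labels

    def test_heterogeneous_left_has_three_lung_regions(self):
        ph = make_phantom("circular", heterogeneous_left=True)
        assert set(ph.lung_regions) == {"left_lung_a", "left_lung_b", "right_lung"}

    def test_sixteen_electrodes_each_with_boundary_edges(self, disc):
        assert disc.n_electrodes == 16
        assert all(len(e) >= 1 for e in disc.electrode_edges)

    def test_positive_element_areas(self, disc):
        assert np.all(disc.element_areas() > 0)

    def test_default_density(self, disc):
        assert disc.n_elements >= 2000

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError):
            make_phantom("cube")

    def test_conductivity_vector_assigns_roles(self, disc):
        sigma = disc.conductivity_vector(0.6, 0.09)
        assert np.all(sigma[disc.element_labels == "left_lung"] == 0.6)
        assert np.all(sigma[disc.element_labels == "right_lung"] == 0.09)
        assert np.all(sigma[disc.element_labels == "background"] == 1.0)


class TestBreathing:
    def test_small_depth_limit_is_nearly_constant(self):
        w = synth_breathing(n_frames=100, depth=1e-9)
        np.testing.assert_allclose(w.values, 1.0, atol=1e-8)

    def test_period_is_80_frames_at_15_bpm_20_fps(self):
        w = synth_breathing(n_frames=400, rate_bpm=15.0, frame_rate=20.0)
        maxima = [t for t in range(1, 399)
                  if w.values[t] >= w.values[t - 1] and w.values[t] >= w.values[t + 1]]
        assert np.all(np.diff(maxima) == 80)

    def test_minimum_equals_one_minus_depth(self):
        w = synth_breathing(n_frames=200, depth=0.4)
        assert w.values.min() == pytest.approx(0.6, abs=1e-12)
        assert w.values.max() == pytest.approx(1.0, abs=1e-12)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            synth_breathing(rate_bpm=100.0)
        with pytest.raises(ValueError):
            synth_breathing(depth=1.5)
        with pytest.raises(ValueError):
            BreathingWaveform(values=np.array([0.5, 1.2]))

    def test_jitter_is_seeded(self):
        a = synth_breathing(seed=3, jitter=0.05)
        b = synth_breathing(seed=3, jitter=0.05)
        np.testing.assert_array_equal(a.values, b.values)


class TestForwardModel:
    def test_constant_breathing_gives_identical_frames(self, disc):
        w = BreathingWaveform(values=np.full(3, 0.7), frame_rate=20.0)
        v = forward_voltages(disc, w)
        np.testing.assert_allclose(v.data[:, 1], v.data[:, 0], atol=1e-10)
        np.testing.assert_allclose(v.data[:, 2], v.data[:, 0], atol=1e-10)

    def test_current_linearity(self, disc):
        w = BreathingWaveform(values=np.array([0.8, 0.8]), frame_rate=20.0)
        v1 = forward_voltages(disc, w, current_mA=1.0)
        v2 = forward_voltages(disc, w, current_mA=2.0)
        np.testing.assert_allclose(v2.data, 2.0 * v1.data, rtol=1e-10)

    def test_reciprocity_on_homogeneous_disc(self, disc):
        """Swapping drive and measurement electrode pairs leaves the
        (amplitude) voltage unchanged on a homogeneous medium."""
        fem = build_fem(disc)
        sigma = np.ones(disc.n_elements)
        rng = np.random.default_rng(5)
        pairs = []
        for _ in range(20):
            a, b, c, d = rng.choice(16, size=4, replace=False)
            pairs.append(((a, b), (c, d)))
        for drive, meas in pairs:
            p1 = np.zeros((1, 16)); p1[0, drive[0]] = 1e-3; p1[0, drive[1]] = -1e-3
            p2 = np.zeros((1, 16)); p2[0, meas[0]] = 1e-3; p2[0, meas[1]] = -1e-3
            u1 = solve_patterns(fem, sigma, p1)[0]
            u2 = solve_patterns(fem, sigma, p2)[0]
            v12 = u1[meas[0]] - u1[meas[1]]
            v21 = u2[drive[0]] - u2[drive[1]]
            assert v12 == pytest.approx(v21, rel=1e-6)

    def test_jacobian_matches_finite_differences(self, disc):
        fem = build_fem(disc)
        sigma = np.ones(disc.n_elements)
        jac = measurement_jacobian(fem, sigma)
        v0 = forward_frame(fem, sigma)
        rng = np.random.default_rng(0)
        for e in rng.choice(disc.n_elements, 3, replace=False):
            s = sigma.copy()
            h = 1e-5
            s[e] += h
            fd = (forward_frame(fem, s) - v0) / h
            np.testing.assert_allclose(jac[:, e], fd, atol=1e-4 * np.abs(fd).max())

    def test_sum_waveform_anticorrelates_with_conductivity(self, ctx):
        from eitrpca.datamodel import sum_waveform

        r = np.corrcoef(sum_waveform(ctx.clean), ctx.breathing.values)[0, 1]
        assert r < -0.9

    def test_clean_recording_is_approximately_rank_one(self, ctx):
        from eitrpca.datamodel import singular_spectrum

        frac = singular_spectrum(ctx.clean).energy_fractions[0]
        assert frac > 0.9


class TestSpikes:
    def test_magnitude_one_is_identity(self, rng):
        v = VoltageMatrix(data=rng.uniform(1, 2, (192, 400)), frame_rate=20.0)
        out = inject_spikes(v, SpikeSpec(channels=frozenset({35}),
                                         frame_window=(299, 299), magnitude=1.0))
        np.testing.assert_array_equal(out.data, v.data)

    def test_single_entry_times_fifty(self, rng):
        v = VoltageMatrix(data=rng.uniform(1, 2, (192, 400)), frame_rate=20.0)
        out = inject_spikes(v, SpikeSpec(channels=frozenset({35}),
                                         frame_window=(299, 299), magnitude=50.0))
        diff = out.data != v.data
        assert diff.sum() == 1
        assert diff[34, 298]
        assert out.data[34, 298] == pytest.approx(50.0 * v.data[34, 298])

    def test_modified_entry_count_and_bitwise_elsewhere(self, rng):
        v = VoltageMatrix(data=rng.uniform(1, 2, (192, 400)), frame_rate=20.0)
        spec = SpikeSpec(channels=frozenset({1, 5, 20}), frame_window=(10, 29),
                         magnitude=3.0)
        out = inject_spikes(v, spec)
        mask = spec.mask(v.data.shape)
        assert mask.sum() == 3 * 20
        np.testing.assert_array_equal(out.data[~mask], v.data[~mask])
        np.testing.assert_allclose(out.data[mask], 3.0 * v.data[mask])

    def test_out_of_bounds_rejected(self, rng):
        v = VoltageMatrix(data=rng.uniform(1, 2, (192, 100)), frame_rate=20.0)
        with pytest.raises(ValueError):
            inject_spikes(v, SpikeSpec(channels=frozenset({35}),
                                       frame_window=(99, 101), magnitude=2.0))
        with pytest.raises(ValueError):
            inject_spikes(v, SpikeSpec(channels=frozenset({193}),
                                       frame_window=(1, 1), magnitude=2.0))


class TestProtocols:
    def test_magnitude_sweep(self):
        specs = protocol_sweep("magnitude")
        assert len(specs) == 19
        assert [s.magnitude for s in specs] == [1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
                                                20, 30, 40, 50, 60, 70, 80, 90, 100]
        assert all(s.channels == frozenset({35}) for s in specs)
        assert all(s.frame_window == (299, 299) for s in specs)

    def test_width_sweep(self):
        specs = protocol_sweep("width")
        assert len(specs) == 11
        assert [s.width for s in specs] == [5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        assert all(s.magnitude == 50 for s in specs)
        assert all(s.channels == frozenset({35}) for s in specs)

    def test_channel_sweep(self):
        specs = protocol_sweep("channels")
        assert len(specs) == 14
        counts = [len(s.channels) for s in specs]
        assert counts == [5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 150, 190, 192]
        assert all(s.frame_window == (300, 350) for s in specs)
        assert all(s.channels == frozenset(range(1, k + 1))
                   for s, k in zip(specs, counts))

    def test_heterogeneous_case(self):
        ph, spec = heterogeneous_case()
        assert len(spec.channels) == 50
        assert spec.magnitude == 27
        assert spec.width == 61
        assert spec.channels <= frozenset(range(1, 193))
        assert set(ph.lung_regions) == {"left_lung_a", "left_lung_b", "right_lung"}
        _, spec2 = heterogeneous_case()
        assert spec2.channels == spec.channels

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            protocol_sweep("amplitude")
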