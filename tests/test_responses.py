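"""Response extraction, effective pairs and sector back-projection."""

import numpy as np
import pytest

from vagusmap import (
    ActivationModel,
    PairResponseSet,
    backproject,
    build_response_atlas,
    default_protocol,
    effective_pair_count,
    extract_pair_response,
    extract_session,
    simulate_session,
)
from vagusmap.mapping import rotate_map, unit_disc_mask
from vagusmap.responses import is_responsive, noise_floor, sector_indices
from vagusmap.synthetic import PhysioTrace, noise_free


def _step_trace(pre=100.0, during=90.0, fs=10.0, t_on=30.0, t_off=45.0, total=90.0):
    t = np.arange(int(total * fs) + 1) / fs
    v = np.full_like(t, pre)
    v[(t >= t_on) & (t < t_off)] = during
    return PhysioTrace(
        modality="hr", time=t, value=v, schedule=((0, t_on, t_off),)
    )


class TestExtractPairResponse:
    def test_step_change(self):
        trace = _step_trace(100.0, 90.0)
        pct = extract_pair_response(trace, 0, baseline_window=15.0, response_window=15.0)
        assert pct == pytest.approx(-10.0, abs=1e-9)

    def test_flat_trace_gives_zero(self):
        trace = _step_trace(100.0, 100.0)
        assert extract_pair_response(trace, 0, 15.0, 15.0) == pytest.approx(0.0)

    def test_missing_pair_gives_nan(self):
        trace = _step_trace()
        assert np.isnan(extract_pair_response(trace, 5, 15.0, 15.0))

    def test_nonpositive_baseline_raises(self):
        trace = _step_trace(pre=-1.0, during=-2.0)
        with pytest.raises(ValueError, match="baseline"):
            extract_pair_response(trace, 0, 15.0, 15.0)

    def test_roundtrip_of_injected_magnitudes(self, nerve, cuff):
        """Noise- and delay-free sessions invert to the injected per-pair
        magnitudes, per modality, to numerical precision."""
        injected = {p: ((-1) ** p) * (2.0 + 0.7 * p) for p in range(14)}
        model = noise_free(ActivationModel())
        proto = default_protocol("cardiac_efferent")
        traces = simulate_session(
            nerve, cuff, proto, model, seed=0, magnitude_override=injected
        )
        for trace in traces:
            got = extract_session(trace, cuff)
            for p in range(14):
                assert got.values[p] == pytest.approx(injected[p], abs=1e-6)

    def test_noisy_recovery_of_bradycardia(self, nerve, cuff):
        """A -7.8% HR effect on two pairs is recovered within the noise."""
        injected = {3: -7.8, 4: -7.8}
        model = ActivationModel(noise_sd={"hr": 0.5, "etco2": 0.0, "emg_rms": 0.0})
        proto = default_protocol("cardiac_efferent")
        traces = simulate_session(
            nerve, cuff, proto, model, seed=1, magnitude_override=injected
        )
        hr = next(t for t in traces if t.modality == "hr")
        got = extract_session(hr, cuff)
        assert got.values[3] == pytest.approx(-7.8, abs=0.5 * 2)
        assert got.values[4] == pytest.approx(-7.8, abs=0.5 * 2)


class TestEffectivePairCount:
    def test_documented_example(self):
        values = np.array([-8.0, -6.2, -1.0, 0.0] + [0.0] * 10)
        resp = PairResponseSet("hr", values)
        assert effective_pair_count(resp) == 2

    def test_all_equal_nonzero(self):
        resp = PairResponseSet("hr", np.full(14, -3.3))
        assert effective_pair_count(resp) == 14

    def test_matches_bruteforce(self, rng):
        for _ in range(500):
            v = rng.normal(0, 5, 14)
            v[rng.random(14) < 0.2] = np.nan
            if np.all(np.isnan(v)):
                continue
            resp = PairResponseSet("hr", v)
            vmax = np.nanmax(np.abs(v))
            expected = sum(
                1 for x in v if not np.isnan(x) and abs(x) >= 0.75 * vmax
            )
            assert effective_pair_count(resp) == expected

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="no measured"):
            effective_pair_count(PairResponseSet("hr", np.full(14, np.nan)))


class TestBackproject:
    def test_one_hot_activates_single_sector(self, cuff):
        v = np.zeros(14)
        v[6] = -4.2
        m = backproject(PairResponseSet("hr", v), cuff, 128)
        si = sector_indices(cuff, 128)
        mask = unit_disc_mask(128)
        np.testing.assert_array_equal(
            m.grid[mask], (si[mask] == 6).astype(float)
        )

    def test_uniform_responses_give_uniform_map(self, cuff):
        m = backproject(PairResponseSet("hr", np.full(14, -5.0)), cuff, 128)
        mask = unit_disc_mask(128)
        assert np.all(m.grid[mask] == 1.0)
        assert np.all(m.grid[~mask] == 0.0)

    def test_sector_pixel_counts_equal_within_2pct(self, cuff):
        si = sector_indices(cuff, 256)
        counts = np.bincount(si[unit_disc_mask(256)], minlength=14)
        assert (counts.max() - counts.min()) / counts.mean() <= 0.02

    def test_rolling_responses_rotates_sectors(self, cuff):
        """Shifting the response vector by one pair index moves each value
        to the next angular sector (permutation equivariance)."""
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 10, 14)
        m0 = backproject(PairResponseSet("hr", v), cuff, 128)
        m1 = backproject(PairResponseSet("hr", np.roll(v, 1)), cuff, 128)
        si = sector_indices(cuff, 128)
        mask = unit_disc_mask(128)
        scaled = np.abs(v) / np.abs(v).max()
        np.testing.assert_allclose(m0.grid[mask], scaled[si[mask]])
        np.testing.assert_allclose(
            m1.grid[mask], np.roll(scaled, 1)[si[mask]]
        )

    def test_missing_pairs_paint_zero(self, cuff):
        v = np.full(14, np.nan)
        v[0] = 2.0
        m = backproject(PairResponseSet("hr", v), cuff, 64)
        si = sector_indices(cuff, 64)
        mask = unit_disc_mask(64)
        assert np.all(m.grid[mask & (si != 0)] == 0.0)


class TestResponseAtlas:
    def test_single_animal_atlas_is_own_map(self, cuff):
        v = np.abs(np.random.default_rng(3).normal(0, 5, 14))
        m = rotate_map(backproject(PairResponseSet("hr", v), cuff, 64), 0.0)
        atlas = build_response_atlas([m])
        np.testing.assert_allclose(atlas.grid, m.grid)

    def test_identical_maps_atlas_max_is_one(self, cuff):
        v = np.abs(np.random.default_rng(4).normal(0, 5, 14))
        m = rotate_map(backproject(PairResponseSet("hr", v), cuff, 64), 0.0)
        atlas = build_response_atlas([m, m, m])
        assert atlas.grid.max() == pytest.approx(1.0)
        assert np.all((atlas.grid >= 0) & (atlas.grid <= 1))


class TestResponsivenessGate:
    def test_null_session_is_flagged(self, nerve, cuff):
        proto = default_protocol("cardiac_efferent")
        model = ActivationModel()
        # noisy traces with sub-threshold amplitude: no signal, only noise
        from dataclasses import replace

        proto_low = replace(proto, amplitude=0.01)
        traces = simulate_session(nerve, cuff, proto_low, model, seed=5)
        hr = next(t for t in traces if t.modality == "hr")
        resp = extract_session(hr, cuff)
        assert not is_responsive(resp, noise_floor(hr))

    def test_real_response_passes_gate(self, nerve, cuff):
        proto = default_protocol("cardiac_efferent")
        model = ActivationModel()
        traces = simulate_session(nerve, cuff, proto, model, seed=5)
        hr = next(t for t in traces if t.modality == "hr")
        resp = extract_session(hr, cuff)
        assert is_responsive(resp, noise_floor(hr))
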