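"""QC metrics: rejection counts, noise/SNR/percent arithmetic, drift,
per-block SNR, reciprocity error, frequency response."""

import dataclasses

import numpy as np
import pytest

from conftest import make_frameset
from eitproc.frames_qc import (
    SNR_CAP_DB,
    apply_rejection,
    compare_to_filter,
    drift_metric,
    frequency_response,
    noise_metrics,
    noise_percent,
    reciprocity_error,
    snr_db,
    snr_per_block,
)
from eitproc.phantoms import cardiff_like_phantom, reciprocal_phantom, scalp_like_phantom
from eitproc.protocol import InjectionProtocol, reciprocal_pairs
from eitproc.simulator import AmplifierModel, gain_filter


class TestMetricArithmetic:
    @pytest.mark.parametrize(
        "mean_v, sd_v, exp_db, exp_pct",
        [
            (2.66e-3, 0.356e-6, 77.5, 0.013),
            (2.66e-3, 0.637e-6, 72.4, 0.024),
            (2.66e-3, 1.522e-6, 64.9, 0.057),
        ],
    )
    def test_snr_and_percent_from_mean_and_sd(self, mean_v, sd_v, exp_db, exp_pct):
        # tolerance = the printed precision (0.1 dB)
        assert snr_db(mean_v, sd_v) == pytest.approx(exp_db, abs=0.1)
        assert noise_percent(mean_v, sd_v) == pytest.approx(100 * sd_v / mean_v)

    def test_db_and_percent_are_consistent(self):
        rng = np.random.default_rng(0)
        means = rng.uniform(1e-3, 1e-2, 100)
        sds = rng.uniform(1e-7, 1e-5, 100)
        np.testing.assert_allclose(
            snr_db(means, sds), 20 * np.log10(100.0 / noise_percent(means, sds))
        )

    def test_zero_sd_capped_sentinel(self):
        assert snr_db(1e-3, 0.0) == SNR_CAP_DB


class TestRejection:
    def test_threshold_keeps_channels_above(self):
        a = np.array([[[300e-6, 200e-6, 100e-6]]] * 2)  # 2 frames, 1 pair, 3 elec
        fs = make_frameset(a)
        out = apply_rejection(fs, 250e-6, exclude_injection=False)
        assert out.n_retained == 1

    def test_zero_threshold_no_exclusion_keeps_all(self):
        fs = make_frameset(np.random.default_rng(0).uniform(0, 1e-3, (2, 3, 4)))
        assert apply_rejection(fs, 0.0, exclude_injection=False).n_retained == 12

    def test_cardiff_fixture_retains_363_of_544(self):
        prot, ph = cardiff_like_phantom()
        a = prot.current_amplitude_a * ph.transfer_ohm
        fs = make_frameset(np.stack([a, a]))
        out = apply_rejection(fs, 250e-6, exclude_injection=True, protocol=prot)
        assert fs.amplitudes.shape[1:] == (34, 16)
        assert out.rejection_mask.size == 544
        assert out.n_retained == 363

    def test_scalp_fixture_retains_540_of_930(self):
        prot, ph = scalp_like_phantom()
        a = prot.current_amplitude_a * ph.transfer_ohm
        fs = make_frameset(np.stack([a, a]))
        out = apply_rejection(fs, 1e-3, exclude_injection=True, protocol=prot)
        assert (~prot.injection_mask()).sum() == 930
        assert out.n_retained == 540

    def test_exclusion_requires_protocol(self):
        fs = make_frameset(np.ones((2, 2, 4)))
        with pytest.raises(ValueError):
            apply_rejection(fs, 0.0, exclude_injection=True)


class TestNoiseMetrics:
    def test_summary_matches_per_channel_arithmetic(self):
        rng = np.random.default_rng(1)
        a = 2.66e-3 + 0.356e-6 * rng.standard_normal((200, 4, 4))
        rep = noise_metrics(make_frameset(a))
        assert rep.noise_sd_v[0] == pytest.approx(0.356e-6, rel=0.1)
        assert rep.snr_db[0] == pytest.approx(77.5, abs=1.0)

    def test_requires_two_frames(self):
        with pytest.raises(ValueError):
            noise_metrics(make_frameset(np.ones((1, 2, 2))))

    def test_constant_channel_sentinel(self):
        rep = noise_metrics(make_frameset(np.ones((5, 1, 2))))
        assert rep.snr_db[0] == SNR_CAP_DB

    def test_invariant_to_channel_permutation_and_scale(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(1e-3, 2e-3, (50, 3, 5)) + 1e-6 * rng.standard_normal((50, 3, 5))
        rep = noise_metrics(make_frameset(a))
        perm = rng.permutation(5)
        rep_p = noise_metrics(make_frameset(a[:, :, perm]))
        assert rep_p.snr_db == pytest.approx(rep.snr_db)
        rep_s = noise_metrics(make_frameset(10 * a))
        assert rep_s.snr_db == pytest.approx(rep.snr_db)
        assert rep_s.noise_pct == pytest.approx(rep.noise_pct)
        assert rep_s.noise_sd_v[0] == pytest.approx(10 * rep.noise_sd_v[0])


class TestDrift:
    def test_printed_arithmetic(self):
        # 5.61 uV change on a 2.66 mV baseline is 0.21 %
        assert 100 * 5.61e-6 / 2.66e-3 == pytest.approx(0.21, abs=0.002)

    def test_zero_drift_simulation_near_zero(self):
        rng = np.random.default_rng(3)
        n_ch = 100
        a = 2.66e-3 + 0.356e-6 * rng.standard_normal((300, 1, n_ch))
        (dv, _), (dpct, _) = drift_metric(make_frameset(a), block_frames=100)
        se = 0.356e-6 * np.sqrt(2 / 100)
        assert dv < 3 * se

    def test_random_walk_drift_matches_folded_normal_oracle(self):
        """Mean |drift| over channels ~ r * sqrt(T_gap) * sqrt(2/pi)."""
        rng = np.random.default_rng(4)
        n_frames, n_ch, dt, rate = 400, 400, 1.0, 1e-6
        steps = rng.normal(0, rate * np.sqrt(dt), (n_frames, n_ch))
        walk = np.cumsum(steps, axis=0)
        a = 2.66e-3 + walk[:, None, :]
        (dv, _), _ = drift_metric(make_frameset(a), block_frames=100)
        # gap between block centres: (400 - 100) * dt
        expected = rate * np.sqrt(300 * dt) * np.sqrt(2 / np.pi)
        assert dv == pytest.approx(expected, rel=0.25)

    def test_fewer_frames_than_block_is_error(self):
        with pytest.raises(ValueError):
            drift_metric(make_frameset(np.ones((50, 1, 2))), block_frames=100)


class TestSnrPerBlock:
    def test_stationary_blocks_agree(self):
        rng = np.random.default_rng(5)
        a = 2.66e-3 + 0.356e-6 * rng.standard_normal((300, 2, 8))
        blocks = snr_per_block(make_frameset(a), 100)
        assert len(blocks) == 3
        assert np.ptp(blocks) < 2.0

    def test_drift_lowers_whole_record_snr_only(self):
        rng = np.random.default_rng(6)
        n = 300
        walk = np.cumsum(rng.normal(0, 2e-6, (n, 2, 8)), axis=0)
        a = 2.66e-3 + 0.356e-6 * rng.standard_normal((n, 2, 8)) + walk
        fs = make_frameset(a)
        whole = noise_metrics(fs).snr_db[0]
        blocks = snr_per_block(fs, 100)
        assert whole < np.median(blocks)
        # monotonicity of SD: whole-record SD >= typical block SD
        assert noise_metrics(fs).noise_sd_v[0] >= noise_metrics(fs, slice(0, 100)).noise_sd_v[0]

    def test_single_block_equals_noise_metrics(self):
        rng = np.random.default_rng(7)
        a = 1e-3 + 1e-6 * rng.standard_normal((100, 2, 4))
        fs = make_frameset(a)
        assert snr_per_block(fs, 100)[0] == pytest.approx(noise_metrics(fs).snr_db[0])


class TestReciprocityError:
    def _frameset_from_phantom(self, prot, ph, n_frames=2):
        a = prot.current_amplitude_a * ph.transfer_ohm
        return make_frameset(np.stack([a] * n_frames))

    def test_exactly_reciprocal_data_zero_error(self):
        prot = InjectionProtocol(((1, 2), (3, 4), (5, 6)), 6)
        ph = reciprocal_phantom(prot, seed=0)
        fs = self._frameset_from_phantom(prot, ph)
        assert reciprocity_error(fs, prot) == pytest.approx(0.0, abs=1e-9)

    def test_one_percent_gain_convention(self):
        prot = InjectionProtocol(((1, 2), (3, 4)), 4)
        ph = reciprocal_phantom(prot, seed=1)
        a = prot.current_amplitude_a * ph.transfer_ohm.copy()
        b = a.copy()
        b[0] *= 1.01  # V_ab = 1.01 V_ba on the only match
        fs = make_frameset(np.stack([b, b]))
        assert reciprocity_error(fs, prot) == pytest.approx(100 * 0.01 / 1.01, rel=1e-6)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(8)
        prot = InjectionProtocol(((1, 2), (3, 4), (5, 6), (7, 8), (1, 5)), 8)
        a = rng.uniform(1e-3, 5e-3, (3, 5, 8))
        fs = make_frameset(a)
        got = reciprocity_error(fs, prot)
        # independent enumeration
        errs = []
        for pa in range(5):
            for pb in range(pa + 1, 5):
                i, j = prot.pairs[pa]
                k, l = prot.pairs[pb]
                if len({i, j, k, l}) < 4:
                    continue
                for f in range(3):
                    vab = a[f, pa, k - 1] - a[f, pa, l - 1]
                    vba = a[f, pb, i - 1] - a[f, pb, j - 1]
                    errs.append(100 * abs(vab - vba) / max(abs(vab), abs(vba)))
        assert got == pytest.approx(np.mean(errs))

    def test_no_matches_is_error(self):
        prot = InjectionProtocol(((1, 2), (2, 3)), 3)
        fs = make_frameset(np.ones((2, 2, 3)))
        with pytest.raises(ValueError):
            reciprocity_error(fs, prot)


class TestFrequencyResponse:
    def _framesets(self, gains, base=None):
        rng = np.random.default_rng(9)
        base = base if base is not None else rng.uniform(1e-3, 5e-3, (1, 3, 6))
        out = {}
        for f, g in gains.items():
            out[f] = make_frameset(np.repeat(base * g, 2, axis=0), frequency_hz=f)
        return out

    def test_flat_system_is_100_percent(self):
        resp = frequency_response(self._framesets({20.0: 1.0, 200.0: 1.0, 2000.0: 1.0}))
        assert all(v == pytest.approx(100.0) for v in resp.values())

    def test_first_order_filter_shape_recovered(self):
        amp = AmplifierModel(64e3, "first_order", 1.7e3)
        freqs = [20.0, 200.0, 1700.0, 2000.0]
        gains = {f: gain_filter(amp, f) for f in freqs}
        resp = frequency_response(self._framesets(gains), reference_hz=20.0)
        # cutoff sits at ~70.7 % of the 20 Hz reference
        assert resp[1700.0] == pytest.approx(
            100 / np.sqrt(2) / gain_filter(amp, 20.0), rel=0.005
        )
        diffs = compare_to_filter(resp, amp, reference_hz=20.0)
        assert max(abs(d) for d in diffs.values()) < 0.5

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            frequency_response(self._framesets({100.0: 1.0}), reference_hz=20.0)
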