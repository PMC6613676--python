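"""VCG reconstruction, TVS/TVV, trajectory quantiles, QTcF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tvv.core import (
    DegenerateTrajectoryError,
    TLoop,
    UnusableBeatError,
    Vcg,
    compute_tvs,
    compute_tvv,
    extract_t_loop,
    fridericia_qtc,
    inverse_dower,
    record_quantiles,
    sg_window_length,
    trajectory_quantiles,
)
from tvv.dower import FORWARD_DOWER, INDEPENDENT_LEADS
from tvv.io import BeatAnnotation, EcgRecord
from tvv.preprocessing import InsufficientBeatsError
from tvv.synthetic import DipoleBeatParams, RepolWarp, simulate_dipole_beat
from .conftest import make_noiseless_record


def _record_from_leads(leads, fs=500.0, beats=()):
    return EcgRecord(signals=dict(leads), sampling_rate=fs, beats=list(beats))


class TestInverseDower:
    def test_zero_leads_give_zero_vcg(self):
        rec = _record_from_leads({n: np.zeros(100) for n in INDEPENDENT_LEADS})
        vcg = inverse_dower(rec)
        assert np.all(vcg.as_matrix() == 0)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        leads = {n: rng.normal(0, 100, 200) for n in INDEPENDENT_LEADS}
        rec1 = _record_from_leads(leads)
        rec2 = _record_from_leads({n: 2 * v for n, v in leads.items()})
        np.testing.assert_array_equal(inverse_dower(rec2).as_matrix(),
                                      2 * inverse_dower(rec1).as_matrix())

    def test_forward_then_inverse_recovers_dipole(self):
        dipole = np.array([[850.0], [-420.0], [310.0]])
        leads8 = FORWARD_DOWER @ dipole
        rec = _record_from_leads({
            n: np.repeat(leads8[i], 10) for i, n in enumerate(INDEPENDENT_LEADS)
        })
        rec_vcg = inverse_dower(rec).as_matrix()[:, 0]
        err = np.abs(rec_vcg - dipole[:, 0]).max()
        assert err < 0.01 * np.linalg.norm(dipole)

    def test_bad_matrix_shape_rejected(self):
        rec = _record_from_leads({n: np.zeros(10) for n in INDEPENDENT_LEADS})
        with pytest.raises(ValueError, match="3x8"):
            inverse_dower(rec, matrix=np.zeros((3, 4)))


class TestTvsTvv:
    def test_tvs_euclidean_norm(self):
        vcg = Vcg(x=np.full(5, 3.0), y=np.full(5, 4.0), z=np.zeros(5), fs=500.0)
        np.testing.assert_allclose(compute_tvs(vcg), 5.0)

    def test_tvs_rotation_invariant(self):
        rng = np.random.default_rng(5)
        xyz = rng.normal(0, 300, (3, 200))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = compute_tvs(Vcg(*xyz, fs=500.0))
        b = compute_tvs(Vcg(*(q @ xyz), fs=500.0))
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_tvv_exact_on_linear_ramp(self):
        # x(t) = v * t with v = 2 uV/ms: the order-3 filter is exact
        fs = 500.0
        t_ms = np.arange(300) * (1000.0 / fs)
        vcg = Vcg(x=2.0 * t_ms, y=np.zeros(300), z=np.zeros(300), fs=fs)
        tvv = compute_tvv(vcg)
        np.testing.assert_allclose(tvv[20:-20], 2.0, rtol=1e-9)

    def test_tvv_zero_for_static_point(self):
        vcg = Vcg(x=np.full(100, 7.0), y=np.full(100, -3.0),
                  z=np.full(100, 1.0), fs=500.0)
        np.testing.assert_allclose(compute_tvv(vcg), 0.0, atol=1e-9)

    def test_tvv_circular_speed(self):
        # planar circle radius 500 uV, period 400 ms -> speed 2*pi*500/400
        fs = 500.0
        t_ms = np.arange(1000) * (1000.0 / fs)
        omega = 2 * np.pi / 400.0
        vcg = Vcg(x=500 * np.cos(omega * t_ms), y=500 * np.sin(omega * t_ms),
                  z=np.zeros(1000), fs=fs)
        tvv = compute_tvv(vcg)
        expected = 2 * np.pi * 500 / 400.0
        np.testing.assert_allclose(tvv[30:-30], expected, rtol=5e-3)

    def test_too_short_signal_rejected(self):
        vcg = Vcg(x=np.zeros(10), y=np.zeros(10), z=np.zeros(10), fs=500.0)
        with pytest.raises(UnusableBeatError):
            compute_tvv(vcg)


class TestSgWindow:
    @pytest.mark.parametrize("fs, expected", [(500.0, 31), (1000.0, 61),
                                              (250.0, 15), (100.0, 7)])
    def test_window_tracks_60ms(self, fs, expected):
        assert sg_window_length(fs) == expected


class TestExtractTLoop:
    def test_window_arithmetic(self):
        rng = np.random.default_rng(0)
        vcg = Vcg(*rng.normal(0, 100, (3, 500)), fs=500.0)
        beat = BeatAnnotation(p_idx=30, q_idx=110, j_idx=175, tend_idx=300)
        loop = extract_t_loop(vcg, beat)
        assert loop.start_idx == 185
        assert loop.end_idx == 300
        assert loop.n_samples == 116
        assert loop.duration_ms == pytest.approx((300 - 175 - 10) / 500.0 * 1000)

    def test_too_short_window_unusable(self):
        vcg = Vcg(*np.zeros((3, 500)), fs=500.0)
        beat = BeatAnnotation(p_idx=30, q_idx=110, j_idx=175, tend_idx=180)
        with pytest.raises(UnusableBeatError, match="unusable beat"):
            extract_t_loop(vcg, beat)


def _uniform_speed_loop(n=101, fs=500.0, speed=1.0):
    seg = Vcg(x=np.zeros(n), y=np.zeros(n), z=np.zeros(n), fs=fs)
    return TLoop(segment=seg, start_idx=0, end_idx=n - 1,
                 tvs=np.zeros(n), tvv=np.full(n, speed))


class TestTrajectoryQuantiles:
    def test_constant_speed_quantiles_linear(self):
        loop = _uniform_speed_loop()  # 200 ms duration at 500 Hz
        trx = trajectory_quantiles(loop)
        for x in range(10, 101, 10):
            assert trx[x] == pytest.approx(2.0 * x, abs=0.01)
        assert trx[50] == pytest.approx(100.0, abs=0.01)

    def test_two_phase_speed(self):
        # speed 2v over [0, 100 ms], v over [100, 200 ms]: half of the total
        # length 300v is reached at t = 75 ms
        tvv = np.where(np.arange(101) < 50, 2.0, 1.0)
        loop = _uniform_speed_loop()
        loop.tvv = tvv
        trx = trajectory_quantiles(loop)
        assert trx[50] == pytest.approx(75.0, abs=1.0)

    def test_tr100_is_loop_duration(self, default_beat):
        vcg = Vcg(*default_beat.vcg_xyz, fs=500.0)
        loop = extract_t_loop(vcg, default_beat.annotation)
        trx = trajectory_quantiles(loop)
        assert trx[100] == pytest.approx(loop.duration_ms, abs=1e-9)

    def test_degenerate_loop_rejected(self):
        loop = _uniform_speed_loop(speed=0.0)
        with pytest.raises(DegenerateTrajectoryError, match="degenerate"):
            trajectory_quantiles(loop)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_quantiles_monotone_on_random_speed_profiles(self, seed):
        rng = np.random.default_rng(seed)
        tvv = rng.uniform(0.05, 5.0, 101)
        loop = _uniform_speed_loop()
        loop.tvv = tvv
        trx = trajectory_quantiles(loop)
        values = [trx[x] for x in range(10, 101, 10)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
        assert 0.0 <= values[0]
        assert values[-1] == pytest.approx(loop.duration_ms)


class TestFridericia:
    def test_identity_at_rr_1000(self):
        assert fridericia_qtc(400.0, 1000.0) == pytest.approx(400.0)

    def test_closed_form_at_rr_800(self):
        assert fridericia_qtc(400.0, 800.0) == pytest.approx(400.0 / 0.8 ** (1 / 3),
                                                             abs=0.01)
        assert fridericia_qtc(400.0, 800.0) == pytest.approx(430.89, abs=0.01)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            fridericia_qtc(400.0, 0.0)


class TestRecordQuantiles:
    def test_identical_beats_average_to_single_beat(self, default_beat):
        rec = make_noiseless_record(default_beat, n_beats=3)
        tq = record_quantiles(rec, preprocess=False)
        vcg = inverse_dower(rec)
        single = trajectory_quantiles(extract_t_loop(vcg, rec.beats[1]))
        for x in range(10, 101, 10):
            assert tq.trx[x] == pytest.approx(single[x], abs=0.5)
        assert tq.n_beats_used == 3

    def test_quantiles_average_across_beats(self):
        # three beats with different repolarization durations: the record
        # value is the arithmetic mean of the per-beat values
        params = DipoleBeatParams()
        durations = [200.0, 220.0, 240.0]
        beats_v, annots = [], []
        offset = 0
        for d in durations:
            b = simulate_dipole_beat(params, warp=RepolWarp(base_duration_ms=d))
            beats_v.append(b.vcg_xyz)
            a = b.annotation
            annots.append(BeatAnnotation(a.p_idx + offset, a.q_idx + offset,
                                         a.j_idx + offset, a.tend_idx + offset,
                                         rr_ms=1000.0))
            offset += b.n_samples
        from tvv.synthetic import forward_project_12lead
        leads = forward_project_12lead(np.concatenate(beats_v, axis=1))
        rec = EcgRecord(signals=leads, sampling_rate=500.0, beats=annots)
        tq = record_quantiles(rec, preprocess=False)
        assert tq.trx[100] == pytest.approx(np.mean(durations), abs=1.0)
        assert tq.trx[50] == pytest.approx(np.mean(durations) / 2, abs=1.5)

    def test_two_beats_insufficient(self, default_beat):
        rec = make_noiseless_record(default_beat, n_beats=2)
        with pytest.raises(InsufficientBeatsError):
            record_quantiles(rec, preprocess=False)

    def test_all_zero_leads_degenerate(self, clean_record):
        rec = clean_record.with_signals(
            {n: np.zeros(clean_record.n_samples) for n in clean_record.signals})
        with pytest.raises(DegenerateTrajectoryError):
            record_quantiles(rec, preprocess=False)
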