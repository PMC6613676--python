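"""Dipole beat generator, time warps, PK model and study simulation."""

import numpy as np
import pytest

from tvv.core import DegenerateTrajectoryError, record_quantiles
from tvv.synthetic import (
    Arm,
    DipoleBeatParams,
    DrugSpec,
    RepolWarp,
    apply_repolarization_warp,
    forward_project_12lead,
    herg_like_delta,
    pk_tmax,
    reduced_design,
    simulate_dipole_beat,
    simulate_pk_profile,
    simulate_study,
    smoothstep_traversal,
    sodium_like_delta,
)
from .conftest import make_noiseless_record


def _loop_polyline_length(beat):
    a = beat.annotation
    start = a.j_idx + 10
    pts = beat.vcg_xyz[:, start:a.tend_idx + 1].T
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


class TestDipoleBeat:
    def test_fiducials_ordered(self, default_beat):
        a = default_beat.annotation
        assert a.p_idx < a.q_idx < a.j_idx < a.tend_idx < default_beat.n_samples

    def test_degenerate_t_loop_flagged_and_rejected_downstream(self):
        beat = simulate_dipole_beat(DipoleBeatParams(t_amplitude_uv=0.0))
        assert beat.degenerate
        rec = make_noiseless_record(beat)
        with pytest.raises(DegenerateTrajectoryError):
            record_quantiles(rec, preprocess=False)

    def test_rendered_loop_length_matches_path_oracle(self, default_beat):
        # polyline length of the rendered samples vs the high-resolution
        # quadrature length of the specified path
        rendered = _loop_polyline_length(default_beat)
        assert rendered == pytest.approx(default_beat.path.total_length_uv,
                                         rel=0.01)

    def test_true_arc_table_normalized(self, default_beat):
        arc = default_beat.arc_length_uv
        assert arc[0] == pytest.approx(0.0)
        assert arc[-1] == pytest.approx(default_beat.path.total_length_uv)
        assert np.all(np.diff(arc) >= -1e-9)


class TestRepolWarp:
    def test_tau_zero_at_origin_and_duration_at_one(self):
        warp = RepolWarp(base_duration_ms=230.0)
        assert warp.tau(0.0) == pytest.approx(0.0)
        assert warp.duration_ms == pytest.approx(230.0)

    def test_non_monotone_warp_rejected(self):
        strong_negative = sodium_like_delta(-500.0)
        with pytest.raises(ValueError, match="increasing"):
            RepolWarp(base_duration_ms=100.0, delta=strong_negative,
                      concentration_ratio=1.0)

    def test_quadratic_warp_closed_form_truth(self):
        # tau(q) = 200 * q^2: Tr50 = 50 ms, Tr100 = 200 ms
        warp = RepolWarp(base_duration_ms=200.0,
                         shape=lambda q: np.asarray(q) ** 2)
        truth = warp.true_trx()
        assert truth[50] == pytest.approx(50.0)
        assert truth[100] == pytest.approx(200.0)
        assert truth[10] == pytest.approx(2.0)

    def test_identity_rewarp_preserves_beat(self, default_beat):
        rewarped, trx = apply_repolarization_warp(default_beat,
                                                  default_beat.warp)
        np.testing.assert_allclose(rewarped.vcg_xyz, default_beat.vcg_xyz)
        for x, v in default_beat.true_trx.items():
            assert trx[x] == pytest.approx(v, abs=1.0)

    def test_pipeline_recovers_nonuniform_warp(self):
        # bounded-speed nonuniform re-timing: measured TrX within
        # one sample + 1% of the closed-form truth
        shape = lambda q: (0.7 * smoothstep_traversal(q)
                           + 0.3 * smoothstep_traversal(q) ** 2)
        warp = RepolWarp(base_duration_ms=200.0, shape=shape)
        assert warp.true_trx()[50] == pytest.approx(85.0)
        beat = simulate_dipole_beat(DipoleBeatParams(), warp=warp)
        tq = record_quantiles(make_noiseless_record(beat), preprocess=False)
        for x, truth in warp.true_trx().items():
            assert abs(tq.trx[x] - truth) <= 2.0 + 0.01 * truth

    def test_warp_preserves_path_length(self, default_beat):
        warp = RepolWarp(base_duration_ms=260.0, delta=herg_like_delta(8.0),
                         concentration_ratio=1.0)
        rewarped, _ = apply_repolarization_warp(default_beat, warp)
        a = _loop_polyline_length(default_beat)
        b = _loop_polyline_length(rewarped)
        assert b == pytest.approx(a, rel=0.01)


class TestEffectShapes:
    def test_herg_shape_monotone_increasing_from_zero(self):
        delta = herg_like_delta(10.0)
        q = np.linspace(0, 1, 101)
        values = delta(q)
        assert values[0] == pytest.approx(0.0)
        assert np.all(np.diff(values) >= -1e-9)
        assert values[-1] == pytest.approx(10.0)

    def test_sodium_shape_negative_early_then_flat(self):
        delta = sodium_like_delta(-6.0)
        q = np.linspace(0, 1, 101)
        values = delta(q)
        assert values[0] == pytest.approx(0.0)
        early = values[(q > 0.05) & (q <= 0.4)]
        assert np.all(np.diff(early) <= 1e-9)  # continuously decreased
        late = values[q >= 0.5]
        assert np.allclose(late, -6.0, atol=0.1)  # plateau maintained


class TestPk:
    def test_zero_at_dose_time(self):
        assert simulate_pk_profile(1.0, 0.0, ka=1.5, ke=0.35) == 0.0

    def test_peak_time_closed_form(self):
        ka, ke = 1.5, 0.35
        t = np.linspace(0, 24, 20001)
        conc = simulate_pk_profile(1.0, t, ka, ke)
        assert t[np.argmax(conc)] == pytest.approx(pk_tmax(ka, ke), abs=0.01)
        assert pk_tmax(ka, ke) == pytest.approx(np.log(ka / ke) / (ka - ke))

    def test_decays_to_zero(self):
        ka, ke = 1.5, 0.35
        cmax = simulate_pk_profile(1.0, pk_tmax(ka, ke), ka, ke)
        assert simulate_pk_profile(1.0, 100 / ke, ka, ke) < 1e-3 * cmax

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_pk_profile(1.0, 1.0, ka=0.5, ke=0.5)

    def test_superposition_over_repeated_doses(self):
        single = simulate_pk_profile(1.0, 10.0, 1.5, 0.35)
        shifted = simulate_pk_profile(1.0, 10.0 - 4.0, 1.5, 0.35)
        both = simulate_pk_profile(1.0, 10.0, 1.5, 0.35,
                                   dose_times_h=(0.0, 4.0))
        assert both == pytest.approx(single + shifted)


class TestForwardProjection:
    def test_zero_dipole_gives_zero_leads(self):
        leads = forward_project_12lead(np.zeros((3, 50)))
        assert all(np.all(v == 0) for v in leads.values())

    def test_einthoven_identity_exact(self, default_beat):
        leads = forward_project_12lead(default_beat.vcg_xyz)
        np.testing.assert_allclose(leads["II"] - leads["I"] - leads["III"],
                                   0.0, atol=1e-9)

    def test_round_trip_dipole_recovery(self, default_beat):
        from tvv.core import inverse_dower

        rec = make_noiseless_record(default_beat, n_beats=1)
        vcg = inverse_dower(rec)
        truth = default_beat.vcg_xyz
        scale = np.abs(truth).max()
        assert np.abs(vcg.as_matrix() - truth).max() < 0.01 * scale


class TestSimulateStudy:
    def test_same_seed_identical_truth_tables(self):
        design = reduced_design(2, 2, arms=[Arm("Placebo")])
        a = simulate_study(design, seed=5)
        b = simulate_study(design, seed=5)
        assert a.truth_table.to_csv(index=False) == b.truth_table.to_csv(index=False)
        assert a.pk_table.to_csv(index=False) == b.pk_table.to_csv(index=False)

    def test_placebo_truth_has_no_injected_effect(self):
        design = reduced_design(2, 2, arms=[Arm("Placebo")])
        study = simulate_study(design, seed=6)
        injected = study.truth_table.filter(like="injected_")
        assert np.allclose(injected.to_numpy(float), 0.0)

    def test_truth_trx_monotone_and_rr_dependent(self):
        design = reduced_design(4, 3, arms=[Arm("Placebo")])
        study = simulate_study(design, seed=8)
        truth = study.truth_table
        cols = [f"true_Tr{x}" for x in range(10, 101, 10)]
        values = truth[cols].to_numpy(float)
        assert np.all(np.diff(values, axis=1) > 0)
        # longer beats carry longer repolarization (positive RR dependence)
        r = np.corrcoef(truth["rr_ms"], truth["true_Tr100"])[0, 1]
        assert r > 0.3

    def test_drug_truth_matches_injected_shape(self):
        drug = DrugSpec("HergDrug", herg_like_delta(10.0))
        design = reduced_design(2, 3, arms=[Arm("Placebo"),
                                            Arm("Herg", [drug])])
        study = simulate_study(design, seed=9)
        herg = study.truth_table[study.truth_table.treatment == "Herg"]
        expected = (herg[f"conc_{drug.name}"] / drug.c_ref
                    * float(herg_like_delta(10.0)(1.0)))
        np.testing.assert_allclose(herg["injected_Tr100"], expected, rtol=1e-9)

    def test_write_produces_readable_records(self, tmp_path):
        from tvv.io import read_ecg_record

        design = reduced_design(2, 2, arms=[Arm("Placebo")], replicates=3)
        study = simulate_study(design, seed=10)
        study.write(tmp_path)
        assert (tmp_path / "pk.csv").exists()
        assert (tmp_path / "truth.csv").exists()
        csvs = sorted(tmp_path.glob("rec_*.csv"))
        assert len(csvs) == len(study.records)
        rec = read_ecg_record(csvs[0].with_suffix(""))
        assert rec.n_samples == study.records[0].n_samples
        assert len(rec.beats) == len(study.records[0].beats)
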