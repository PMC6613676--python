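"""Synthetic annotated 12-lead ECG crossover studies with known ground truth.

The generator works in the domain where the biomarkers live: a smooth 3-D
dipole path (the T loop geometry) is traversed according to a monotone
time-warp tau(q) that maps arc-length fraction q in [0, 1] to the time at
which that fraction is reached.  Drug effects are injected directly into the
warp — tau_C(q) = T0*h(q) + (C/C_ref)*delta(q)*(1 + b_subject) — so the true
trajectory quantile TrX = tau(X/100) is available in closed form for every
simulated beat.  Heart-rate dependence enters through the baseline duration
T0(RR) = T_base + beta_subject * (RR - 1000).

The dipole beat is completed with plausible P and QRS deflections and
projected to the 12-lead ECG through the forward Dower matrix; measurement
noise (broadband white noise plus sinusoidal baseline wander) is added in
lead space on the eight independent leads, with the limb leads derived
afterwards so the Einthoven/Goldberger identities hold exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .dower import FORWARD_DOWER, INDEPENDENT_LEADS, derived_limb_leads
from .io import NORMAL_SINUS, BeatAnnotation, EcgRecord

QUANTILE_GRID = tuple(x / 100.0 for x in range(10, 101, 10))


class DegenerateRepolarizationError(ValueError):
    """Zero-amplitude T loop: no repolarization trajectory exists."""


# ---------------------------------------------------------------------------
# T-loop geometry
# ---------------------------------------------------------------------------

@dataclass
class TLoopPath:
    """A smooth 3-D loop path parameterized by arc-length fraction.

    The raw curve is m(u) * d(u) for u in [0, 1], where the magnitude
    m(u) = amplitude * sin(pi u)^1.5 grows from and returns to zero (the
    dipole vanishes at both ends of repolarization) and the unit direction
    d(u) rotates by ``sweep_rad`` around an oblique axis, tracing an open
    loop.  The curve is re-parameterized numerically by cumulative arc
    length on a fine grid.
    """

    amplitude_uv: float = 600.0
    azimuth0_rad: float = 0.6
    elevation_rad: float = 0.5
    sweep_rad: float = 2.2
    n_grid: int = 2001

    def __post_init__(self) -> None:
        u = np.linspace(0.0, 1.0, self.n_grid)
        mag = self.amplitude_uv * np.sin(np.pi * u) ** 1.5
        ang = self.azimuth0_rad + self.sweep_rad * u
        ce, se = math.cos(self.elevation_rad), math.sin(self.elevation_rad)
        d = np.stack([np.cos(ang), np.sin(ang) * ce, np.sin(ang) * se])
        self._points = (mag * d).T  # (n_grid, 3)
        seg = np.linalg.norm(np.diff(self._points, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        self.total_length_uv = float(arc[-1])
        self._arc_frac = arc / arc[-1] if arc[-1] > 0 else arc
        self._u = u

    @property
    def degenerate(self) -> bool:
        return self.total_length_uv <= 0.0

    def point_at_fraction(self, q: np.ndarray) -> np.ndarray:
        """Position (uV, shape (..., 3)) after traversing fraction q of the path."""
        if self.degenerate:
            raise DegenerateRepolarizationError(
                "degenerate repolarization: T-loop path has zero length"
            )
        q = np.asarray(q, dtype=float)
        u = np.interp(q, self._arc_frac, self._u)
        out = np.empty(q.shape + (3,))
        for k in range(3):
            out[..., k] = np.interp(u, self._u, self._points[:, k])
        return out


# ---------------------------------------------------------------------------
# Repolarization time warp (ground-truth injection)
# ---------------------------------------------------------------------------

def _pchip_shape(values: np.ndarray) -> PchipInterpolator:
    grid = np.linspace(0.0, 1.0, len(values))
    return PchipInterpolator(grid, values)


_SMOOTHSTEP_U = np.linspace(0.0, 1.0, 4097)
_SMOOTHSTEP_S = 3 * _SMOOTHSTEP_U ** 2 - 2 * _SMOOTHSTEP_U ** 3


def smoothstep_traversal(q) -> np.ndarray:
    """Default drug-free traversal shape: inverse of the smoothstep.

    The arc fraction covered per unit time, dq/dt = 6u(1-u), rises smoothly
    from zero, peaks mid-loop and decays to zero — the dipole speed tapers
    at both ends of repolarization as in a real T wave, so the derivative
    filter sees no velocity jump at the loop boundaries.
    """
    return np.interp(np.asarray(q, dtype=float), _SMOOTHSTEP_S, _SMOOTHSTEP_U)


def herg_like_delta(amplitude_ms: float = 10.0):
    """Effect shape of a pure outward-potassium (hERG/iKr) block.

    A monotonically increasing delay over the whole repolarization course:
    every quantile is reached later, increasingly so toward Tr100.
    ``amplitude_ms`` is the delay of Tr100 at the reference concentration.
    """
    shape = np.array([0.0, 0.10, 0.21, 0.32, 0.44, 0.55, 0.66, 0.77, 0.87, 0.94, 1.0])
    return _pchip_shape(amplitude_ms * shape)


def sodium_like_delta(amplitude_ms: float = -6.0):
    """Effect shape of an inward (late sodium / calcium) current block.

    Early repolarization is accelerated — the low quantiles up to ~Tr40 are
    continuously decreased — and the accumulated lead is then maintained,
    leaving the upper quantiles at a roughly constant negative level.
    ``amplitude_ms`` (negative) is the plateau level at the reference
    concentration.
    """
    shape = np.array([0.0, 0.35, 0.65, 0.90, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    return _pchip_shape(amplitude_ms * shape)


def combined_delta(components: list) -> "callable":
    """Superposition of effect shapes (multichannel block)."""
    def delta(q):
        q = np.asarray(q, dtype=float)
        return sum(c(q) for c in components)
    return delta


class RepolWarp:
    """Monotone map tau: arc fraction q -> time (ms) at which q is reached.

    tau(q) = base_duration_ms * h(q) + concentration_ratio * delta(q) * (1 + subject_slope)

    where h is the drug-free traversal shape (default
    :func:`smoothstep_traversal`; pass ``shape=lambda q: q`` for constant
    arc speed), ``delta`` the per-reference-concentration effect shape
    (ms, delta(0)=0) and ``subject_slope`` the subject's random deviation
    of effect size.
    """

    def __init__(self, base_duration_ms: float, delta=None,
                 concentration_ratio: float = 0.0, subject_slope: float = 0.0,
                 shape=None) -> None:
        self.base_duration_ms = float(base_duration_ms)
        self.delta = delta
        self.concentration_ratio = float(concentration_ratio)
        self.subject_slope = float(subject_slope)
        self.shape = shape
        self._validate()

    def tau(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        base = self.base_duration_ms * (
            smoothstep_traversal(q) if self.shape is None else self.shape(q)
        )
        if self.delta is None or self.concentration_ratio == 0.0:
            return base
        return base + self.concentration_ratio * np.asarray(self.delta(q)) * (
            1.0 + self.subject_slope
        )

    def _validate(self) -> None:
        grid = np.linspace(0.0, 1.0, 513)
        t = self.tau(grid)
        if abs(float(t[0])) > 1e-9:
            raise ValueError(f"warp must satisfy tau(0) = 0, got {t[0]:.3g}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("warp tau(q) must be strictly increasing")

    @property
    def duration_ms(self) -> float:
        return float(self.tau(1.0))

    def true_trx(self, quantiles=QUANTILE_GRID) -> dict[int, float]:
        """Ground-truth TrX = tau(X/100) in ms."""
        return {int(round(q * 100)): float(self.tau(q)) for q in quantiles}

    def fraction_at_time(self, t_ms: np.ndarray) -> np.ndarray:
        """Inverse warp: arc fraction reached at each time (ms)."""
        grid = np.linspace(0.0, 1.0, 2049)
        return np.interp(t_ms, self.tau(grid), grid)


# ---------------------------------------------------------------------------
# Single-beat dipole simulation
# ---------------------------------------------------------------------------

@dataclass
class DipoleBeatParams:
    """Layout and amplitudes for one simulated dipole beat."""

    rr_ms: float = 1000.0
    fs: float = 500.0
    p_onset_ms: float = 60.0
    pq_ms: float = 160.0
    qrs_ms: float = 80.0
    p_amplitude_uv: float = 60.0
    qrs_amplitude_uv: float = 1100.0
    t_amplitude_uv: float = 600.0

    def validate(self) -> None:
        if min(self.rr_ms, self.pq_ms, self.qrs_ms) <= 0 or self.fs <= 0:
            raise ValueError("durations and sampling rate must be positive")


@dataclass
class SyntheticBeat:
    """One rendered beat with its annotation and closed-form ground truth."""

    vcg_xyz: np.ndarray  # (3, n_samples)
    annotation: BeatAnnotation
    params: DipoleBeatParams
    path: TLoopPath
    warp: RepolWarp
    true_trx: dict[int, float]
    arc_length_uv: np.ndarray  # true cumulative arc length per loop sample
    degenerate: bool = False

    @property
    def n_samples(self) -> int:
        return self.vcg_xyz.shape[1]


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_dipole_beat(params: DipoleBeatParams,
                         warp: RepolWarp | None = None,
                         path: TLoopPath | None = None) -> SyntheticBeat:
    """Render one beat of the dipole (VCG) with consistent fiducials.

    P and QRS are modelled as Gaussian deflections (the PQ segment between
    them stays near zero, providing the isoelectric reference); the T loop
    is the arc-length path traversed under ``warp``.  The returned arc-length
    table holds the true cumulative trajectory length at each loop sample.
    """
    params.validate()
    fs = params.fs
    dt_ms = 1000.0 / fs
    if warp is None:
        warp = RepolWarp(base_duration_ms=230.0)
    if path is None:
        path = TLoopPath(amplitude_uv=params.t_amplitude_uv)
    degenerate = params.t_amplitude_uv <= 0 or path.degenerate

    n = int(round(params.rr_ms / dt_ms))
    p_idx = int(round(params.p_onset_ms / dt_ms))
    q_idx = p_idx + int(round(params.pq_ms / dt_ms))
    j_idx = q_idx + int(round(params.qrs_ms / dt_ms))
    t_start = j_idx + int(round(0.020 * fs))
    tend_idx = t_start + int(round(warp.duration_ms / dt_ms))
    if tend_idx >= n - 2:
        raise ValueError(
            f"beat layout does not fit: Tend index {tend_idx} vs beat of {n} samples"
        )

    xyz = np.zeros((3, n))
    t_ms = np.arange(n) * dt_ms

    # P wave: small, brief deflection early in the PQ interval, leaving the
    # majority of the PQ samples on the isoelectric level so the PQ median
    # remains a clean baseline estimate
    p_center = params.p_onset_ms + 30.0
    p_dirs = np.array([0.8, 0.55, -0.25])
    xyz += params.p_amplitude_uv * p_dirs[:, None] * _gauss(t_ms, p_center, 10.0)

    # QRS: fast large loop between Q and J, staggered per component
    qrs_on = params.p_onset_ms + params.pq_ms
    sigma = params.qrs_ms * 0.13
    centers = qrs_on + params.qrs_ms * np.array([0.40, 0.50, 0.62])
    amps = params.qrs_amplitude_uv * np.array([1.0, 0.75, -0.45])
    for k in range(3):
        xyz[k] += amps[k] * _gauss(t_ms, centers[k], sigma)

    # T loop: path traversed under the warp on [J+20 ms, Tend]
    loop_slice = slice(t_start, tend_idx + 1)
    loop_t = (np.arange(t_start, tend_idx + 1) - t_start) * dt_ms
    arc_length = np.zeros(len(loop_t))
    if not degenerate:
        q_frac = warp.fraction_at_time(loop_t)
        xyz[:, loop_slice] += path.point_at_fraction(q_frac).T
        arc_length = q_frac * path.total_length_uv

    annotation = BeatAnnotation(
        p_idx=p_idx, q_idx=q_idx, j_idx=j_idx, tend_idx=tend_idx,
        beat_class=NORMAL_SINUS, rr_ms=params.rr_ms,
    )
    return SyntheticBeat(
        vcg_xyz=xyz, annotation=annotation, params=params, path=path,
        warp=warp, true_trx=warp.true_trx() if not degenerate else {},
        arc_length_uv=arc_length, degenerate=degenerate,
    )


def apply_repolarization_warp(beat: SyntheticBeat,
                              warp: RepolWarp) -> tuple[SyntheticBeat, dict[int, float]]:
    """Re-time the beat's T loop under a new warp; geometry is unchanged.

    Returns the re-rendered beat and the new ground-truth TrX map
    (tau(X/100)).  The spatial path — hence the total arc length — is
    preserved; only the traversal timing changes.
    """
    new_beat = simulate_dipole_beat(beat.params, warp=warp, path=beat.path)
    return new_beat, dict(new_beat.true_trx)


def forward_project_12lead(vcg_xyz: np.ndarray) -> dict[str, np.ndarray]:
    """Project a dipole (3, n) to the 12 leads via the forward Dower matrix.

    The eight independent leads are D @ (x, y, z); the limb leads III and
    aVR/aVL/aVF are derived from I and II, so the Einthoven and Goldberger
    identities hold exactly.
    """
    eight = FORWARD_DOWER @ np.asarray(vcg_xyz, dtype=float)
    leads = {name: eight[i] for i, name in enumerate(INDEPENDENT_LEADS)}
    leads.update(derived_limb_leads(leads["I"], leads["II"]))
    return leads


# ---------------------------------------------------------------------------
# Pharmacokinetics
# ---------------------------------------------------------------------------

def simulate_pk_profile(dose: float, times_h, ka: float, ke: float,
                        scale: float = 1.0, dose_times_h=(0.0,)) -> np.ndarray:
    """One-compartment oral PK with first-order absorption.

    C(t) = scale * dose * (exp(-ke*t) - exp(-ka*t)) for t >= 0, summed over
    the dosing times (superposition).  ``ka`` and ``ke`` are in 1/h and must
    differ.
    """
    if ka <= 0 or ke <= 0 or ka == ke:
        raise ValueError(f"need distinct positive rates, got ka={ka}, ke={ke}")
    t = np.atleast_1d(np.asarray(times_h, dtype=float))
    conc = np.zeros_like(t)
    for td in dose_times_h:
        dt = t - td
        mask = dt > 0
        conc[mask] += scale * dose * (np.exp(-ke * dt[mask]) - np.exp(-ka * dt[mask]))
    return conc if np.ndim(times_h) else float(conc[0])


def pk_tmax(ka: float, ke: float) -> float:
    """Time of the single-dose concentration peak: ln(ka/ke)/(ka - ke)."""
    return math.log(ka / ke) / (ka - ke)


def pk_cmax(dose: float, ka: float, ke: float, scale: float = 1.0) -> float:
    return simulate_pk_profile(dose, pk_tmax(ka, ke), ka, ke, scale)


# ---------------------------------------------------------------------------
# Study-level simulation
# ---------------------------------------------------------------------------

class DrugSpec:
    """One drug in an arm: PK and its ground-truth effect shape.

    ``delta`` is the effect shape in ms at the reference concentration
    ``c_ref`` (default: the single-dose Cmax, so the injected profile at
    peak concentration equals the shape's amplitude); ``sigma_b`` is the
    relative SD of the per-subject random effect slope.
    """

    def __init__(self, name, delta=None, dose=1.0, ka=1.5, ke=0.35, pk_scale=1.0,
                 dose_times_h=(0.0,), c_ref=None, sigma_b=0.2):
        self.name = name
        self.delta = delta
        self.dose = dose
        self.ka = ka
        self.ke = ke
        self.pk_scale = pk_scale
        self.dose_times_h = tuple(dose_times_h)
        self.c_ref = pk_cmax(dose, ka, ke, pk_scale) if c_ref is None else float(c_ref)
        self.sigma_b = sigma_b

    def concentration(self, t_h) -> np.ndarray:
        return simulate_pk_profile(self.dose, t_h, self.ka, self.ke, self.pk_scale,
                                   self.dose_times_h)


@dataclass
class Arm:
    """One crossover treatment period."""

    name: str
    drugs: list = field(default_factory=list)


#: Nominal post-dose sampling grid of a dense single-day crossover period.
DEFAULT_TIMEPOINTS_H = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0,
                        6.0, 7.0, 8.0, 12.0, 14.0, 24.0)


def _default_arms() -> list:
    return [
        Arm("Placebo"),
        Arm("HergBlockerA", [DrugSpec("HergBlockerA", herg_like_delta(10.0))]),
        Arm("HergBlockerB", [DrugSpec("HergBlockerB", herg_like_delta(7.0))]),
        Arm("SodiumBlocker", [DrugSpec("SodiumBlocker", sodium_like_delta(-6.0))]),
        Arm("Multichannel", [
            DrugSpec("HergBlockerA", herg_like_delta(10.0)),
            DrugSpec("SodiumBlocker", sodium_like_delta(-6.0)),
        ]),
    ]


@dataclass
class StudyDesign:
    """Design of a simulated crossover study.

    Defaults mirror a dense thorough-ECG crossover: 22 subjects, 5 treatment
    periods, triplicate 10-s ECGs at 16 nominal timepoints, 500 Hz sampling.
    Repolarization times carry a per-subject RR dependence with mean slope
    ``beta_true_ms_per_ms`` (ms of Tr100 per ms of RR).
    """

    n_subjects: int = 22
    arms: list = field(default_factory=_default_arms)
    timepoints_h: tuple = DEFAULT_TIMEPOINTS_H
    replicates: int = 3
    record_duration_s: float = 10.0
    fs: float = 500.0
    t_base_ms: float = 230.0             # drug-free Tr100 at RR = 1000 ms
    t_subject_sd_ms: float = 8.0
    t_replicate_sd_ms: float = 2.0       # biological per-ECG repolarization jitter
    beta_true_ms_per_ms: float = 0.05
    beta_sd: float = 0.01
    rr_mean_ms: float = 1000.0
    rr_subject_sd_ms: float = 70.0
    rr_circadian_amp_ms: float = 60.0
    rr_replicate_sd_ms: float = 15.0
    pk_subject_cv: float = 0.15
    noise_white_sd_uv: float = 10.0
    wander_amp_uv: float = 150.0
    wander_freq_hz: float = 0.33

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.replicates < 3:
            raise ValueError("need at least 3 replicates per timepoint")


@dataclass
class SimulatedStudy:
    """Output of :func:`simulate_study`: records plus PK and truth tables."""

    records: list
    pk_table: pd.DataFrame
    truth_table: pd.DataFrame
    design: StudyDesign

    def write(self, out_dir) -> None:
        """Write records (CSV+JSON dialect), pk.csv and truth.csv."""
        from pathlib import Path

        from .io import write_ecg_record

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, rec in enumerate(self.records):
            base = out / (
                f"rec_{rec.subject_id}_{rec.treatment}_"
                f"t{int(round(rec.nominal_time_h * 10)):04d}_r{rec.replicate_index}"
            )
            write_ecg_record(rec, base)
        self.pk_table.to_csv(out / "pk.csv", index=False)
        self.truth_table.to_csv(out / "truth.csv", index=False)


def _drug_free_duration(design: StudyDesign, t_subj: float, beta_subj: float,
                        rr: float) -> float:
    return design.t_base_ms + t_subj + beta_subj * (rr - 1000.0)


def simulate_study(design: StudyDesign, seed: int = 0) -> SimulatedStudy:
    """Simulate a full annotated crossover study with known ground truth.

    Deterministic under ``seed``.  Every record's beats share one rendered
    dipole beat (replicate- and timepoint-level variability enters through
    RR, PK and noise), which keeps the generator fast while preserving the
    record-level averaging semantics of the pipeline.

    The truth table holds, per record and quantile X: the realized true
    TrX = tau(X/100) (including the subject's random effect slope) and the
    injected population effect sum_d (C_d / C_ref,d) * delta_d(X/100).
    """
    design.validate()
    rng = np.random.default_rng(seed)
    fs = design.fs
    n_samples = int(round(design.record_duration_s * fs))
    path = TLoopPath()

    drug_names = sorted({d.name for arm in design.arms for d in arm.drugs})
    subj_beta = {}
    subj_t_off = {}
    subj_rr = {}
    subj_pk = {}
    subj_b = {}
    subjects = [f"S{i + 1:03d}" for i in range(design.n_subjects)]
    for s in subjects:
        subj_beta[s] = rng.normal(design.beta_true_ms_per_ms, design.beta_sd)
        subj_t_off[s] = rng.normal(0.0, design.t_subject_sd_ms)
        subj_rr[s] = rng.normal(design.rr_mean_ms, design.rr_subject_sd_ms)
        subj_pk[s] = {d: float(np.exp(rng.normal(0.0, design.pk_subject_cv)))
                      for d in drug_names}
        subj_b[s] = {}

    records: list[EcgRecord] = []
    pk_rows = []
    truth_rows = []
    for arm in design.arms:
        for s in subjects:
            for drug in arm.drugs:
                if drug.name not in subj_b[s]:
                    subj_b[s][drug.name] = rng.normal(0.0, drug.sigma_b)
            for t_h in design.timepoints_h:
                concs = {}
                for drug in arm.drugs:
                    c = float(drug.concentration(t_h)) * subj_pk[s][drug.name]
                    concs[drug.name] = c
                    pk_rows.append({
                        "subject_id": s, "treatment": arm.name,
                        "nominal_time_h": t_h, "drug": drug.name,
                        "concentration": c,
                    })
                for rep in range(1, design.replicates + 1):
                    rr = float(np.clip(
                        subj_rr[s]
                        + design.rr_circadian_amp_ms * math.sin(2 * math.pi * (t_h - 14.0) / 24.0)
                        + rng.normal(0.0, design.rr_replicate_sd_ms),
                        680.0, 1400.0,
                    ))
                    t0 = _drug_free_duration(design, subj_t_off[s], subj_beta[s], rr)
                    t0 += rng.normal(0.0, design.t_replicate_sd_ms)
                    deltas = [
                        (concs[d.name] / d.c_ref, d.delta, subj_b[s][d.name])
                        for d in arm.drugs if d.delta is not None
                    ]

                    def delta_sum(q, _deltas=deltas):
                        q = np.asarray(q, dtype=float)
                        out = np.zeros_like(q)
                        for ratio, dfun, b in _deltas:
                            out += ratio * np.asarray(dfun(q)) * (1.0 + b)
                        return out

                    warp = RepolWarp(base_duration_ms=t0,
                                     delta=delta_sum if deltas else None,
                                     concentration_ratio=1.0 if deltas else 0.0)
                    params = DipoleBeatParams(rr_ms=rr, fs=fs)
                    beat = simulate_dipole_beat(params, warp=warp, path=path)
                    record = _assemble_record(beat, design, n_samples, rng)
                    record.subject_id = s
                    record.treatment = arm.name
                    record.nominal_time_h = t_h
                    record.replicate_index = rep
                    records.append(record)

                    row = {
                        "subject_id": s, "treatment": arm.name,
                        "nominal_time_h": t_h, "replicate": rep, "rr_ms": rr,
                    }
                    for x, v in warp.true_trx().items():
                        row[f"true_Tr{x}"] = v
                    for x in range(10, 101, 10):
                        q = x / 100.0
                        row[f"injected_Tr{x}"] = float(sum(
                            ratio * float(np.asarray(dfun(q)))
                            for ratio, dfun, _ in deltas
                        ))
                    for d, c in concs.items():
                        row[f"conc_{d}"] = c
                    truth_rows.append(row)

    return SimulatedStudy(
        records=records,
        pk_table=pd.DataFrame(pk_rows),
        truth_table=pd.DataFrame(truth_rows),
        design=design,
    )


def _assemble_record(beat: SyntheticBeat, design: StudyDesign, n_samples: int,
                     rng: np.random.Generator) -> EcgRecord:
    """Tile one beat to record length, project to leads and add noise."""
    beat_len = beat.n_samples
    n_beats = n_samples // beat_len
    xyz = np.tile(beat.vcg_xyz, (1, n_beats))
    if xyz.shape[1] < n_samples:
        xyz = np.pad(xyz, ((0, 0), (0, n_samples - xyz.shape[1])))
    leads = forward_project_12lead(xyz)

    t = np.arange(n_samples) / design.fs
    noisy = {}
    for name in INDEPENDENT_LEADS:
        phase = rng.uniform(0, 2 * math.pi)
        amp = design.wander_amp_uv * rng.uniform(0.5, 1.0)
        wander = amp * np.sin(2 * math.pi * design.wander_freq_hz * t + phase)
        white = rng.normal(0.0, design.noise_white_sd_uv, n_samples)
        noisy[name] = leads[name] + wander + white
    noisy.update(derived_limb_leads(noisy["I"], noisy["II"]))

    beats = []
    a = beat.annotation
    for k in range(n_beats):
        off = k * beat_len
        beats.append(BeatAnnotation(
            p_idx=a.p_idx + off, q_idx=a.q_idx + off, j_idx=a.j_idx + off,
            tend_idx=a.tend_idx + off, beat_class=NORMAL_SINUS,
            rr_ms=None if k == 0 else beat.params.rr_ms,
        ))
    return EcgRecord(
        signals=noisy, sampling_rate=design.fs, amplitude_resolution=2.5,
        beats=beats,
    )


def reduced_design(n_subjects: int = 8, n_timepoints: int = 8,
                   arms: list | None = None, **overrides) -> StudyDesign:
    """A scaled-down design for fast tests: fewer subjects and timepoints."""
    timepoints = DEFAULT_TIMEPOINTS_H[:n_timepoints]
    kwargs = dict(n_subjects=n_subjects, timepoints_h=timepoints)
    if arms is not None:
        kwargs["arms"] = arms
    kwargs.update(overrides)
    return StudyDesign(**kwargs)


def recovery_design(n_subjects: int = 8, n_timepoints: int = 8,
                    herg_amp_ms: float = 10.0,
                    sodium_amp_ms: float = -6.0, **overrides) -> StudyDesign:
    """Crossover design for effect-profile recovery studies.

    Five periods: placebo, a drug with pharmacokinetics but no
    repolarization effect (null), a pure outward-potassium blocker, a pure
    inward-current blocker, and their combination (shared drug names, so the
    combination pools naturally with the single-drug period).
    """
    herg = DrugSpec("HergDrug", herg_like_delta(herg_amp_ms))
    sodium = DrugSpec("SodiumDrug", sodium_like_delta(sodium_amp_ms))
    arms = [
        Arm("Placebo"),
        Arm("NullDrug", [DrugSpec("NullDrug", None)]),
        Arm("Herg", [herg]),
        Arm("Sodium", [sodium]),
        Arm("Combined", [herg, sodium]),
    ]
    return reduced_design(n_subjects, n_timepoints, arms=arms, **overrides)


def discrimination_design(n_subjects: int = 8, n_timepoints: int = 8,
                          **overrides) -> StudyDesign:
    """Crossover design for the group I vs group II discrimination fixture.

    Group I arms carry pure outward-potassium block (monotone increasing
    effect profiles of different strength); group II arms add an
    inward-current blocker, producing sigmoid profiles with negative early
    quantiles — the contrast that mid-range trajectory quantiles separate
    best.
    """
    herg_a = DrugSpec("HergA", herg_like_delta(10.0))
    arms = [
        Arm("Placebo"),
        Arm("HergA", [herg_a]),
        Arm("HergB", [DrugSpec("HergB", herg_like_delta(7.0))]),
        Arm("MultiA", [herg_a, DrugSpec("SodiumA", sodium_like_delta(-6.0))]),
        Arm("MultiB", [herg_a, DrugSpec("SodiumB", sodium_like_delta(-5.0))]),
    ]
    return reduced_design(n_subjects, n_timepoints, arms=arms, **overrides)

GROUP1_ARMS = ("HergA", "HergB")
GROUP2_ARMS = ("MultiA", "MultiB")
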