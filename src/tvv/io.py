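"""ECG data model and on-disk formats.

An :class:`EcgRecord` bundles the 12-lead signal matrix (microvolts), the
sampling rate, per-beat fiducial annotations (P, Q, J, Tend) and the study
metadata (subject, treatment, nominal time, replicate) needed by the
downstream biomarker pipeline.

The supported on-disk dialect is deliberately simple and self-contained:

* ``<base>.csv`` — wide CSV, one column per lead, amplitudes in microvolts;
* ``<base>.json`` — sidecar with sampling rate, amplitude resolution, study
  metadata, the zeroed-lead set and the beat annotations.

``format="wfdb"`` is reserved for environments with the optional ``wfdb``
package installed and raises a :class:`FormatError` otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dower import INDEPENDENT_LEADS, derived_limb_leads

logger = logging.getLogger(__name__)

NORMAL_SINUS = "normal_sinus"
OTHER_BEAT = "other"

#: Minimum number of usable normal sinus beats per record.
MIN_NORMAL_BEATS = 3


class EcgValidationError(ValueError):
    """Structural violation of the ECG data model."""


class MissingLeadError(EcgValidationError):
    """A required independent lead is absent ("missing lead")."""


class AnnotationError(EcgValidationError):
    """A fiducial annotation is inconsistent ("invalid annotation")."""


class FormatError(ValueError):
    """Unknown or unsupported on-disk format ("format error")."""


@dataclass(frozen=True)
class BeatAnnotation:
    """Fiducial indices (0-based samples) for one heartbeat.

    ``rr_ms`` is the interval to the previous beat and is ``None`` for the
    first beat of a record.
    """

    p_idx: int
    q_idx: int
    j_idx: int
    tend_idx: int
    beat_class: str = NORMAL_SINUS
    rr_ms: float | None = None

    def __post_init__(self) -> None:
        if self.beat_class not in (NORMAL_SINUS, OTHER_BEAT):
            raise AnnotationError(f"invalid annotation: unknown beat class {self.beat_class!r}")

    @property
    def ordered(self) -> bool:
        """Whether the fiducials satisfy P < Q < J < Tend."""
        return self.p_idx < self.q_idx < self.j_idx < self.tend_idx

    def t_window_samples(self, fs: float, half_window: int = 15) -> bool:
        """Whether the repolarization window [J+20 ms, Tend] is usable.

        A beat is usable when the window exceeds 20 ms plus one derivative
        half-window, so the trajectory speed is defined on every sample.
        """
        return self.tend_idx - self.j_idx >= int(round(0.020 * fs)) + half_window


@dataclass
class EcgRecord:
    """A 12-lead ECG with beat annotations and study metadata.

    ``signals`` maps lead name to a 1-D float array in microvolts; all leads
    share one sample count and ``sampling_rate`` (Hz).
    """

    signals: dict[str, np.ndarray]
    sampling_rate: float
    amplitude_resolution: float = 2.5
    subject_id: str = ""
    treatment: str = ""
    nominal_time_h: float = 0.0
    replicate_index: int = 1
    beats: list[BeatAnnotation] = field(default_factory=list)
    zeroed_leads: set[str] = field(default_factory=set)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def lead_matrix(self, leads: tuple[str, ...] = INDEPENDENT_LEADS) -> np.ndarray:
        """Stack the named leads into a (n_leads, n_samples) matrix."""
        missing = [name for name in leads if name not in self.signals]
        if missing:
            raise MissingLeadError(f"missing lead: {', '.join(missing)}")
        return np.vstack([np.asarray(self.signals[name], dtype=float) for name in leads])

    def with_signals(self, signals: dict[str, np.ndarray]) -> "EcgRecord":
        """Copy of the record with replaced signals (annotations kept)."""
        return replace(self, signals=signals, beats=list(self.beats),
                       zeroed_leads=set(self.zeroed_leads))

    def validate(self, check_lead_consistency: bool = False) -> None:
        """Raise on structural violations of the data model."""
        if self.sampling_rate <= 0:
            raise EcgValidationError("sampling_rate must be positive")
        if not self.signals:
            raise MissingLeadError("missing lead: record has no signals")
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) != 1:
            raise EcgValidationError(f"leads have unequal sample counts: {sorted(lengths)}")
        missing = [name for name in INDEPENDENT_LEADS if name not in self.signals]
        if missing:
            raise MissingLeadError(f"missing lead: {', '.join(missing)}")
        n = self.n_samples
        prev_q = -1
        for beat in self.beats:
            if not beat.ordered:
                raise AnnotationError(
                    "invalid annotation: fiducials must satisfy P < Q < J < Tend, got "
                    f"({beat.p_idx}, {beat.q_idx}, {beat.j_idx}, {beat.tend_idx})"
                )
            if beat.tend_idx >= n or beat.p_idx < 0:
                raise AnnotationError(
                    f"invalid annotation: tend_idx {beat.tend_idx} beyond record length {n}"
                )
            if beat.q_idx <= prev_q:
                raise AnnotationError("invalid annotation: beats not sorted by Q index")
            prev_q = beat.q_idx
        if check_lead_consistency and "III" in self.signals:
            dev = np.max(np.abs(
                self.signals["II"] - self.signals["I"] - self.signals["III"]
            ))
            if dev > 1.0:
                raise EcgValidationError(
                    f"derived lead III inconsistent with Einthoven identity (max {dev:.2f} uV)"
                )


def synthesize_derived_leads(record: EcgRecord) -> EcgRecord:
    """Fill in III, aVR, aVL, aVF from I and II where absent."""
    signals = dict(record.signals)
    lead_i = np.asarray(signals["I"], dtype=float)
    lead_ii = np.asarray(signals["II"], dtype=float)
    for name, sig in derived_limb_leads(lead_i, lead_ii).items():
        signals.setdefault(name, sig)
    return record.with_signals(signals)


def validate_annotations(record: EcgRecord) -> list[str]:
    """Report-only validation of beat annotations.

    Returns a list of human-readable violations; an empty list means the
    record is fit for biomarker extraction (ordered fiducials, in-range
    indices, and at least three normal sinus beats with usable repolarization
    windows).
    """
    violations: list[str] = []
    n = record.n_samples
    prev_q = -1
    usable_normal = 0
    for i, beat in enumerate(record.beats):
        if not beat.ordered:
            violations.append(f"beat {i}: fiducial ordering violated "
                              "(need P < Q < J < Tend)")
            continue
        if beat.tend_idx >= n or beat.p_idx < 0:
            violations.append(f"beat {i}: annotation index out of range")
            continue
        if beat.q_idx <= prev_q:
            violations.append(f"beat {i}: beats not sorted by Q index")
        prev_q = beat.q_idx
        if beat.beat_class == NORMAL_SINUS and beat.t_window_samples(record.sampling_rate):
            usable_normal += 1
    if usable_normal < MIN_NORMAL_BEATS:
        violations.append(
            f"insufficient normal beats: {usable_normal} usable normal sinus beats "
            f"(minimum {MIN_NORMAL_BEATS})"
        )
    return violations


def _beat_to_dict(beat: BeatAnnotation) -> dict:
    return {
        "p_idx": int(beat.p_idx),
        "q_idx": int(beat.q_idx),
        "j_idx": int(beat.j_idx),
        "tend_idx": int(beat.tend_idx),
        "beat_class": beat.beat_class,
        "rr_ms": None if beat.rr_ms is None else float(beat.rr_ms),
    }


def _paths_for(path: str | Path) -> tuple[Path, Path]:
    # append extensions by string concatenation: record base names may
    # contain dots (e.g. a nominal time "t2.5"), which Path.with_suffix
    # would clobber
    base = str(path)
    for ext in (".csv", ".json"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    return Path(base + ".csv"), Path(base + ".json")


def write_ecg_record(record: EcgRecord, path: str | Path, format: str = "csv_json") -> None:
    """Write a record to disk in the CSV + JSON sidecar dialect.

    Signals are quantized to the record's amplitude resolution, so a
    round-trip reproduces each sample within half a resolution step and the
    annotations and metadata exactly.
    """
    if format != "csv_json":
        raise FormatError(f"format error: cannot write format {format!r}")
    record.validate()
    csv_path, json_path = _paths_for(path)
    res = record.amplitude_resolution
    # only the eight independent leads are stored; the limb leads III and
    # aVR/aVL/aVF are re-derived on read, so the Einthoven/Goldberger
    # identities survive quantization exactly
    data = {
        name: np.round(np.asarray(record.signals[name], dtype=float) / res) * res
        for name in INDEPENDENT_LEADS
    }
    pd.DataFrame(data).to_csv(csv_path, index=False, float_format="%.4f")
    meta = {
        "sampling_rate": record.sampling_rate,
        "amplitude_resolution": record.amplitude_resolution,
        "subject_id": record.subject_id,
        "treatment": record.treatment,
        "nominal_time_h": record.nominal_time_h,
        "replicate_index": record.replicate_index,
        "zeroed_leads": sorted(record.zeroed_leads),
        "beats": [_beat_to_dict(b) for b in record.beats],
    }
    json_path.write_text(json.dumps(meta, indent=1))


def read_ecg_record(path: str | Path, format: str = "csv_json") -> EcgRecord:
    """Read and validate a record; missing derived limb leads are synthesized."""
    if format == "wfdb":
        raise FormatError(
            "format error: wfdb support requires the optional wfdb package; "
            "use the csv_json dialect"
        )
    if format != "csv_json":
        raise FormatError(f"format error: unknown format {format!r}")
    csv_path, json_path = _paths_for(path)
    if not csv_path.exists() or not json_path.exists():
        raise FileNotFoundError(f"record files not found for base {csv_path.with_suffix('')}")
    frame = pd.read_csv(csv_path)
    meta = json.loads(json_path.read_text())
    signals = {name: frame[name].to_numpy(dtype=float) for name in frame.columns}
    beats = [
        BeatAnnotation(
            p_idx=b["p_idx"], q_idx=b["q_idx"], j_idx=b["j_idx"], tend_idx=b["tend_idx"],
            beat_class=b.get("beat_class", NORMAL_SINUS), rr_ms=b.get("rr_ms"),
        )
        for b in meta.get("beats", [])
    ]
    record = EcgRecord(
        signals=signals,
        sampling_rate=float(meta["sampling_rate"]),
        amplitude_resolution=float(meta.get("amplitude_resolution", 2.5)),
        subject_id=str(meta.get("subject_id", "")),
        treatment=str(meta.get("treatment", "")),
        nominal_time_h=float(meta.get("nominal_time_h", 0.0)),
        replicate_index=int(meta.get("replicate_index", 1)),
        beats=beats,
        zeroed_leads=set(meta.get("zeroed_leads", [])),
    )
    record.validate(check_lead_consistency=True)
    return synthesize_derived_leads(record)
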