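"""Signal conditioning ahead of vectorcardiogram reconstruction.

The pipeline order is: isoelectric baseline correction (PQ-segment medians
interpolated by a cubic spline), zero-phase low-pass filtering (bidirectional
Bessel, 36 Hz), optional zeroing of noise-corrupted leads, and selection of
normal sinus beats with usable repolarization windows.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import bessel, sosfiltfilt

from .io import (
    MIN_NORMAL_BEATS,
    NORMAL_SINUS,
    BeatAnnotation,
    EcgRecord,
    EcgValidationError,
    MissingLeadError,
)

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_HZ = 36.0
#: Analog-prototype Bessel order per pass; forward+backward doubles it.
BESSEL_ORDER = 2


class InsufficientBeatsError(EcgValidationError):
    """Fewer than the minimum number of usable normal sinus beats."""


def correct_isoelectric(record: EcgRecord) -> EcgRecord:
    """Remove baseline wander using PQ-segment isoelectric levels.

    For each lead, one knot per beat is placed at the PQ midpoint with value
    equal to the median amplitude over [P, Q]; a natural cubic spline through
    the knots (held constant beyond the first/last beat) estimates the
    baseline, which is subtracted.  With fewer than two beats the single
    PQ median (or overall median with no beats) is subtracted as a constant.
    """
    n = record.n_samples
    t = np.arange(n)
    knots_x = np.array([(b.p_idx + b.q_idx) / 2.0 for b in record.beats])
    corrected: dict[str, np.ndarray] = {}
    for name, sig in record.signals.items():
        sig = np.asarray(sig, dtype=float)
        if len(record.beats) == 0:
            baseline = np.full(n, np.median(sig))
        else:
            knots_y = np.array([
                np.median(sig[b.p_idx:b.q_idx + 1]) for b in record.beats
            ])
            if len(record.beats) == 1:
                baseline = np.full(n, knots_y[0])
            else:
                spline = CubicSpline(knots_x, knots_y, bc_type="natural")
                # constant extrapolation outside the knot span
                baseline = spline(np.clip(t, knots_x[0], knots_x[-1]))
        corrected[name] = sig - baseline
    return record.with_signals(corrected)


def design_bessel_sos(sampling_rate: float, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                      order: int = BESSEL_ORDER) -> np.ndarray:
    """Second-order sections of the per-pass digital Bessel low-pass."""
    nyquist = sampling_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    return bessel(order, cutoff_hz, btype="low", fs=sampling_rate,
                  output="sos", norm="mag")


def bessel_lowpass(record: EcgRecord, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                   order: int = BESSEL_ORDER) -> EcgRecord:
    """Zero-phase low-pass: Bessel filter run forward then backward per lead.

    The bidirectional pass cancels the phase response (zero group delay) and
    squares the magnitude response.  Edges are reflect-padded by roughly one
    settling length to suppress startup transients.
    """
    sos = design_bessel_sos(record.sampling_rate, cutoff_hz, order)
    n = record.n_samples
    padlen = min(n - 1, int(3 * record.sampling_rate / cutoff_hz))
    filtered = {
        name: sosfiltfilt(sos, np.asarray(sig, dtype=float), padlen=padlen)
        for name, sig in record.signals.items()
    }
    return record.with_signals(filtered)


def zero_noisy_leads(record: EcgRecord, leads: set[str]) -> EcgRecord:
    """Replace the named leads by all-zero signals and record the fact.

    Mirrors the handling of isolated noise-corrupted leads: rather than
    dropping the record, the offending leads contribute nothing to the
    dipole reconstruction.
    """
    unknown = set(leads) - set(record.signals)
    if unknown:
        raise MissingLeadError(f"missing lead: {', '.join(sorted(unknown))}")
    n = record.n_samples
    signals = {
        name: (np.zeros(n) if name in leads else np.asarray(sig, dtype=float))
        for name, sig in record.signals.items()
    }
    out = record.with_signals(signals)
    out.zeroed_leads = set(record.zeroed_leads) | set(leads)
    return out


def select_normal_beats(record: EcgRecord, min_beats: int = MIN_NORMAL_BEATS,
                        half_window: int | None = None) -> list[BeatAnnotation]:
    """Return the normal sinus beats with usable repolarization windows.

    Raises :class:`InsufficientBeatsError` when fewer than ``min_beats``
    remain, matching the minimum-three-beats rule for a reliable record.
    """
    if half_window is None:
        from .core import sg_window_length
        half_window = sg_window_length(record.sampling_rate) // 2
    beats = [
        b for b in record.beats
        if b.beat_class == NORMAL_SINUS
        and b.t_window_samples(record.sampling_rate, half_window)
    ]
    if len(beats) < min_beats:
        raise InsufficientBeatsError(
            f"insufficient normal beats: {len(beats)} usable of {len(record.beats)} "
            f"annotated (minimum {min_beats})"
        )
    return beats


def preprocess(record: EcgRecord, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
               zero_leads: set[str] | None = None) -> EcgRecord:
    """Standard conditioning chain: isoelectric -> low-pass -> lead zeroing."""
    out = correct_isoelectric(record)
    out = bessel_lowpass(out, cutoff_hz)
    if zero_leads:
        out = zero_noisy_leads(out, zero_leads)
    elif record.zeroed_leads:
        out = zero_noisy_leads(out, set(record.zeroed_leads))
    return out
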