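"""Physiological effect metrics per stimulation event.

Four effects are quantified for every stimulation train:

* **ΔHR** (BPM): difference between the mean heart rate shortly after
  stimulation onset and the mean over a pre-onset baseline segment; the
  three segmentation parameters (pre-length, gap after onset, post-length)
  are optimised per session by maximising the R² of a linear regression of
  ΔHR on the stimulation parameters. Negative = bradycardia.
* **ΔBR** (%): relative change between the baseline breathing rate (5 s
  before onset) and the minimum breathing rate between onset and 3 s after
  train end. Negative = bradypnea; floor −100 %.
* **Laryngeal twitches**: per-pulse L2-norm of the EMG 2.5-10 ms after
  each pulse; the twitch count is the number of pulses exceeding a
  noise-calibrated threshold (mean + 5 SD of pre-stimulation window norms).
* **Laryngeal spasm** (ΔlEMG): relative increase of the EMG L1-norm in the
  second after train end over the second before onset; a score above 0.3
  (exclusive) is a strong spasm.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks

from .errors import BoundsError, NumericalError, ValidationError
from .session import ChannelTrace, Session, StimulationEvent

STRONG_SPASM_BOUNDARY = 0.3  # exclusive: score > 0.3 is a strong spasm


@dataclass(frozen=True)
class Segmentation:
    """ΔHR segmentation: pre-onset baseline, gap after onset, post segment."""

    pre_len: float  # s
    gap: float  # s (may be 0: post window starts at onset)
    post_len: float  # s

    def __post_init__(self) -> None:
        if self.pre_len <= 0 or self.post_len <= 0 or self.gap < 0:
            raise ValidationError(
                "pre_len and post_len must be > 0 and gap >= 0")


DEFAULT_SEGMENTATION_GRID: tuple[Segmentation, ...] = tuple(
    Segmentation(pre, gap, post)
    for pre, gap, post in itertools.product((2.0, 5.0, 10.0),
                                            (0.0, 1.0, 2.0, 5.0),
                                            (2.0, 5.0, 10.0)))


@dataclass
class PhysioResponse:
    """All physiological metrics for one stimulation event."""

    event_id: str
    delta_hr: float  # BPM, negative = bradycardia
    delta_br: float  # %, negative = bradypnea, >= -100
    twitch_amplitudes: np.ndarray  # per-pulse L2-norms, µV·sample^1/2
    twitch_count: int
    spasm_score: float
    strong_spasm: bool

    def __post_init__(self) -> None:
        if self.delta_br < -100.0 - 1e-9:
            raise ValidationError("delta_br cannot fall below -100%")
        if self.spasm_score < -1.0 - 1e-9:
            raise ValidationError("spasm_score cannot fall below -1")


# ---------------------------------------------------------------------------
# Heart rate
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: ChannelTrace, prominence_frac: float = 0.5,
                   refractory_s: float = 0.25) -> np.ndarray:
    """R-peak times (s) by prominence-based peak finding.

    Prominence threshold is ``prominence_frac`` times the signal SD; the
    refractory distance suppresses double detections within one beat.
    """
    if ecg.modality != "ecg":
        raise ValidationError(f"expected an ecg trace, got {ecg.modality}")
    x = ecg.samples
    prominence = prominence_frac * float(np.std(x))
    distance = max(1, int(round(refractory_s * ecg.sampling_rate)))
    idx, _ = find_peaks(x, prominence=prominence, distance=distance)
    if idx.size == 0:
        warnings.warn("no R-peaks detected", stacklevel=2)
        return np.array([])
    return ecg.start_time + idx / ecg.sampling_rate


def hr_series(r_peaks: np.ndarray,
              out_fs: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous heart rate (BPM) on a uniform grid.

    HR = 60/RR is assigned at each interval's endpoints and interpolated
    with shape-preserving monotone piecewise-cubic (PCHIP) interpolation,
    which never overshoots local extrema.
    """
    r_peaks = np.asarray(r_peaks, dtype=float)
    if r_peaks.size < 3:
        raise ValidationError("need >= 3 R-peaks for a heart-rate series")
    rr = np.diff(r_peaks)
    hr = 60.0 / rr
    # value at an interval's terminating peak; the first peak carries the
    # first interval's rate so the series covers [first peak, last peak]
    knots_t = np.concatenate([[r_peaks[0]], r_peaks[1:]])
    knots_v = np.concatenate([[hr[0]], hr])
    interp = PchipInterpolator(knots_t, knots_v)
    t = np.arange(r_peaks[0], r_peaks[-1], 1.0 / out_fs)
    return t, interp(t)


def _window_mean(t: np.ndarray, v: np.ndarray, t0: float, t1: float) -> float:
    dt = t[1] - t[0] if t.size > 1 else 0.0
    if t0 < t[0] - 1e-9 or t1 > t[-1] + dt + 1e-9:
        raise BoundsError(
            f"window [{t0}, {t1}) outside series span [{t[0]}, {t[-1]}]")
    mask = (t >= t0) & (t < t1)
    if not np.any(mask):
        raise BoundsError(f"window [{t0}, {t1}) contains no samples")
    return float(np.mean(v[mask]))


def delta_hr(hr_t: np.ndarray, hr_v: np.ndarray, event: StimulationEvent,
             segmentation: Segmentation) -> float:
    """Mean HR over the post window minus the pre-onset baseline (BPM)."""
    onset = event.onset_time
    pre = _window_mean(hr_t, hr_v, onset - segmentation.pre_len, onset)
    post = _window_mean(hr_t, hr_v, onset + segmentation.gap,
                        onset + segmentation.gap + segmentation.post_len)
    return post - pre


def optimize_segmentation(
        session: Session, hr_t: np.ndarray, hr_v: np.ndarray,
        candidates: Sequence[Segmentation] = DEFAULT_SEGMENTATION_GRID,
) -> Segmentation:
    """Pick the segmentation maximising the stimulation-parameter fit.

    For each candidate, ΔHR is computed for every event and regressed (OLS,
    main effects) on current, pulse width, frequency and duration; the
    candidate with the highest R² wins, ties broken by smallest gap, then
    smallest post length, then smallest pre length.
    """
    if len(session.events) < 8:
        raise ValidationError(
            "segmentation optimisation needs >= 8 events in the grid")
    X = pd.DataFrame({
        "current_mA": [e.pulse.current for e in session.events],
        "pulse_width_us": [e.pulse.pulse_width for e in session.events],
        "frequency_hz": [e.train.frequency for e in session.events],
        "duration_s": [e.train.duration for e in session.events],
    })
    varying = [c for c in X.columns if X[c].nunique() > 1]
    design = sm.add_constant(X[varying]) if varying else None
    if design is None or np.linalg.matrix_rank(design.to_numpy()) < \
            design.shape[1]:
        raise NumericalError(
            "degenerate stimulation-parameter design matrix")

    best: tuple[float, float, float, float, Segmentation] | None = None
    for seg in candidates:
        try:
            r2 = segmentation_r2(session, hr_t, hr_v, seg, design)
        except BoundsError:
            continue
        key = (-r2, seg.gap, seg.post_len, seg.pre_len)
        if best is None or key < best[:4]:
            best = (*key, seg)
    if best is None:
        raise BoundsError("no segmentation candidate fits inside the series")
    return best[4]


def segmentation_r2(session: Session, hr_t: np.ndarray, hr_v: np.ndarray,
                    segmentation: Segmentation,
                    design: pd.DataFrame | None = None) -> float:
    """R² of the ΔHR-on-stimulation-parameters OLS fit for one segmentation."""
    if design is None:
        X = pd.DataFrame({
            "current_mA": [e.pulse.current for e in session.events],
            "pulse_width_us": [e.pulse.pulse_width for e in session.events],
            "frequency_hz": [e.train.frequency for e in session.events],
            "duration_s": [e.train.duration for e in session.events],
        })
        varying = [c for c in X.columns if X[c].nunique() > 1]
        design = sm.add_constant(X[varying]) if varying else None
        if design is None:
            raise NumericalError("no varying stimulation parameters")
    y = np.array([delta_hr(hr_t, hr_v, ev, segmentation)
                  for ev in session.events])
    if np.allclose(y, y[0]):
        return 0.0
    return float(sm.OLS(y, design).fit().rsquared)


# ---------------------------------------------------------------------------
# Breathing rate
# ---------------------------------------------------------------------------

def breathing_rate(pressure: ChannelTrace, prominence_frac: float = 0.5,
                   refractory_s: float = 1.0,
                   out_fs: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Breathing rate (breaths/min) by peak finding and forward filling.

    Each inter-breath interval's rate (60/interval) is assigned at the
    interval's terminating peak and held (forward-filled) until the next
    breath, so an apnea keeps the last known rate until breathing resumes.
    """
    if pressure.modality != "pressure":
        raise ValidationError(
            f"expected a pressure trace, got {pressure.modality}")
    x = pressure.samples
    prominence = prominence_frac * float(np.std(x))
    distance = max(1, int(round(refractory_s * pressure.sampling_rate)))
    idx, _ = find_peaks(x, prominence=prominence, distance=distance)
    if idx.size < 2:
        raise ValidationError("need >= 2 breath peaks for a breathing rate")
    peaks = pressure.start_time + idx / pressure.sampling_rate
    br = 60.0 / np.diff(peaks)
    t = np.arange(peaks[0], pressure.end_time, 1.0 / out_fs)
    # forward fill: value at t is the rate of the last completed interval
    pos = np.searchsorted(peaks[1:], t, side="right") - 1
    v = np.where(pos >= 0, br[np.clip(pos, 0, br.size - 1)], br[0])
    return t, v


def delta_br(br_t: np.ndarray, br_v: np.ndarray,
             event: StimulationEvent, baseline_s: float = 5.0,
             post_end_s: float = 3.0) -> float:
    """Relative breathing-rate change (%), negative = bradypnea.

    100 × (minimum BR between onset and train end + 3 s, minus the baseline
    BR over the 5 s before onset) / baseline.
    """
    onset, end = event.onset_time, event.end_time
    baseline = _window_mean(br_t, br_v, onset - baseline_s, onset)
    if baseline == 0:
        raise ValidationError("zero baseline breathing rate")
    mask = (br_t >= onset) & (br_t <= end + post_end_s)
    if not np.any(mask):
        raise BoundsError("no breathing-rate samples in the effect window")
    minimum = float(np.min(br_v[mask]))
    return 100.0 * (minimum - baseline) / baseline


# ---------------------------------------------------------------------------
# Laryngeal EMG
# ---------------------------------------------------------------------------

_TWITCH_WINDOW_MS = (2.5, 10.0)


def _emg_window_norm(x: np.ndarray, i0: int, n: int) -> float:
    seg = x[i0:i0 + n]
    return float(np.linalg.norm(seg - np.mean(seg)))


def laryngeal_twitches(emg: ChannelTrace, event: StimulationEvent,
                       threshold: float | None = None,
                       ) -> tuple[np.ndarray, int]:
    """Per-pulse EMG L2-norms (2.5-10 ms post pulse) and the twitch count.

    The suprathreshold criterion is calibrated on the session itself:
    threshold = mean + 5 SD of window norms taken from the 2 s of EMG
    immediately before stimulation onset. When every pulse is
    suprathreshold the count equals the pulse count.
    """
    if emg.modality != "emg":
        raise ValidationError(f"expected an emg trace, got {emg.modality}")
    if 1.0 / event.train.frequency < _TWITCH_WINDOW_MS[1] * 1e-3:
        raise ValidationError(
            f"inter-pulse interval at {event.train.frequency} Hz collides "
            "with the 2.5-10 ms twitch window (frequencies > 100 Hz are "
            "out of scope)")
    fs = emg.sampling_rate
    off = int(round(_TWITCH_WINDOW_MS[0] * 1e-3 * fs))
    n = int(round((_TWITCH_WINDOW_MS[1] - _TWITCH_WINDOW_MS[0]) * 1e-3 * fs))
    x = emg.samples
    amps = []
    for t_pulse in event.pulse_onset_times:
        i = int(round((t_pulse - emg.start_time) * fs)) + off
        if i < 0 or i + n > x.size:
            raise BoundsError(f"twitch window for pulse at {t_pulse} s "
                              "extends past the EMG trace")
        amps.append(_emg_window_norm(x, i, n))
    amps = np.asarray(amps)

    if threshold is None:
        i_onset = int(round((event.onset_time - emg.start_time) * fs))
        start = i_onset - int(round(2.0 * fs))
        if start < 0:
            raise BoundsError("need 2 s of pre-stimulation EMG to "
                              "calibrate the twitch threshold")
        step = int(round(0.015 * fs))
        ref = np.array([_emg_window_norm(x, i, n)
                        for i in range(start, i_onset - n, step)])
        threshold = float(np.mean(ref) + 5.0 * np.std(ref))
    count = int(np.sum(amps > threshold))
    return amps, count


def spasm_score(emg: ChannelTrace,
                event: StimulationEvent) -> tuple[float, bool]:
    """Relative post-train EMG L1 increase and the strong-spasm flag.

    score = L1[end, end+1 s) / L1[onset-1 s, onset) − 1; a score above 0.3
    (strictly) is a strong spasm.
    """
    if emg.modality != "emg":
        raise ValidationError(f"expected an emg trace, got {emg.modality}")
    fs = emg.sampling_rate
    n = int(round(1.0 * fs))
    i_on = int(round((event.onset_time - emg.start_time) * fs))
    i_end = int(round((event.end_time - emg.start_time) * fs))
    if i_on - n < 0 or i_end + n > emg.samples.size:
        raise BoundsError("need 1 s of EMG before onset and after train end")
    pre = float(np.sum(np.abs(emg.samples[i_on - n:i_on])))
    post = float(np.sum(np.abs(emg.samples[i_end:i_end + n])))
    if pre == 0:
        raise ValidationError("zero baseline EMG L1-norm")
    score = post / pre - 1.0
    return score, is_strong_spasm(score)


def is_strong_spasm(score: float) -> bool:
    """Strong-spasm classification: relative increase above 0.3, exclusive."""
    return score > STRONG_SPASM_BOUNDARY


# ---------------------------------------------------------------------------
# Session-level pipeline
# ---------------------------------------------------------------------------

def compute_physio_responses(session: Session,
                             segmentation: Segmentation | None = None,
                             optimize: bool = True) -> pd.DataFrame:
    """All physiological metrics for every event of a session.

    When ``segmentation`` is None and ``optimize`` is set, the ΔHR
    segmentation is chosen by :func:`optimize_segmentation` (falling back
    to (5 s, 2 s, 2 s) for sessions with fewer than 8 events).
    """
    ecg = session.channels("ecg")[0]
    emg = session.channels("emg")[0]
    pressure = session.channels("pressure")[0]
    hr_t, hr_v = hr_series(detect_r_peaks(ecg))
    br_t, br_v = breathing_rate(pressure)
    if segmentation is None:
        if optimize and len(session.events) >= 8:
            segmentation = optimize_segmentation(session, hr_t, hr_v)
        else:
            segmentation = Segmentation(5.0, 2.0, 2.0)
    rows = []
    for ev in session.events:
        amps, count = laryngeal_twitches(emg, ev)
        score, strong = spasm_score(emg, ev)
        resp = PhysioResponse(
            event_id=ev.event_id,
            delta_hr=delta_hr(hr_t, hr_v, ev, segmentation),
            delta_br=delta_br(br_t, br_v, ev),
            twitch_amplitudes=amps,
            twitch_count=count,
            spasm_score=score,
            strong_spasm=strong,
        )
        rows.append({
            "event_id": resp.event_id,
            "delta_hr_bpm": resp.delta_hr,
            "delta_br_pct": resp.delta_br,
            "twitch_count": resp.twitch_count,
            "twitch_amp_mean": float(np.mean(amps)) if amps.size else 0.0,
            "spasm_score": resp.spasm_score,
            "strong_spasm": resp.strong_spasm,
            "current_mA": ev.pulse.current,
            "pulse_width_us": ev.pulse.pulse_width,
            "contact_pair": ev.pulse.contact_pair,
            "polarity": ev.pulse.polarity,
            "frequency_hz": ev.train.frequency,
            "duration_s": ev.train.duration,
        })
    return pd.DataFrame(rows)


__all__ = [
    "DEFAULT_SEGMENTATION_GRID", "PhysioResponse", "STRONG_SPASM_BOUNDARY",
    "Segmentation", "breathing_rate", "compute_physio_responses",
    "delta_br", "delta_hr", "detect_r_peaks", "hr_series",
    "is_strong_spasm", "laryngeal_twitches", "optimize_segmentation",
    "segmentation_r2", "spasm_score",
]
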