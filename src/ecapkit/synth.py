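"""Synthetic VNS session generator with known ground truth.

The generator embodies the mechanistic structure the analysis pipeline
assumes, so every downstream stage can be tested against exact ground truth
without animal recordings:

* **strength-duration recruitment** — each fiber population is recruited as
  a sigmoid of current whose threshold follows the Lapicque/Weiss hyperbolic
  law ``I_th(pw) = rheobase * (1 + chronaxie / pw)``;
* **conduction-velocity latencies** — each fiber's eCAP appears on a
  recording cuff at ``distance / velocity``, while the laryngeal muscle
  artefact sits at a fixed 4-8 ms latency independent of distance;
* **pulse/train separation** — recruitment depends only on pulse parameters
  (current, pulse width, contact, polarity); frequency and train duration
  only control how per-pulse recruitment integrates into physiology;
* **frequency-dependent integration** — heart rate change combines an
  A-gamma tachycardia term and a B-fiber bradycardia term whose gain grows
  with frequency; breathing suppression scales with the per-train summed
  A-gamma recruitment; laryngeal twitches and spasms follow A-beta.

All stochasticity flows from a single seeded ``numpy.random.Generator``;
identical seeds give byte-identical sessions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .session import (
    ANODIC,
    CATHODIC,
    MONOPHASIC,
    ChannelTrace,
    CuffGeometry,
    Session,
    StimPulseParams,
    StimTrainParams,
    StimulationEvent,
)

# Erlanger-Gasser conduction-velocity ranges (m/s) used for validation.
TABLE_VELOCITY_RANGES: dict[str, tuple[float, float]] = {
    "Aalpha": (70.0, 120.0),
    "Abeta": (30.0, 70.0),
    "Agamma": (15.0, 30.0),
    "Agamma2": (15.0, 30.0),  # second, higher-threshold A-gamma population
    "Adelta": (5.0, 30.0),
    "B": (3.0, 15.0),
    "C": (0.6, 2.0),
}

#: Logit width factor: the recruitment sigmoid reaches 5% at threshold and
#: 95% at saturation.
_LOGIT_95 = float(np.log(19.0))


# ---------------------------------------------------------------------------
# Nerve model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberSpec:
    """One fiber population and its recruitment / waveform parameters.

    ``rheobase`` and ``saturation_current`` are the asymptotic (long-pulse)
    threshold and saturation currents in mA; both scale with the
    strength-duration factor ``1 + chronaxie/pw``. ``rheobase`` may be a
    single float or a per-contact mapping (spatial selectivity).
    """

    fiber_type: str
    conduction_velocity: float  # m/s
    rheobase: float | Mapping[str, float]  # mA
    chronaxie: float  # µs
    saturation_current: float  # mA (asymptotic, same per-contact scaling)
    max_amplitude: float  # µV
    waveform_width: float  # ms

    def __post_init__(self) -> None:
        if self.fiber_type not in TABLE_VELOCITY_RANGES:
            raise ValidationError(
                f"unknown fiber_type {self.fiber_type!r}; expected one of "
                f"{sorted(TABLE_VELOCITY_RANGES)}")
        lo, hi = TABLE_VELOCITY_RANGES[self.fiber_type]
        if not (lo <= self.conduction_velocity <= hi):
            raise ValidationError(
                f"{self.fiber_type} conduction velocity "
                f"{self.conduction_velocity} outside [{lo}, {hi}] m/s")
        rb = self.rheobase
        values = rb.values() if isinstance(rb, Mapping) else [rb]
        if any(v <= 0 for v in values):
            raise ValidationError(f"{self.fiber_type}: rheobase must be > 0")
        if self.saturation_current <= min(values):
            raise ValidationError(
                f"{self.fiber_type}: saturation_current must exceed rheobase")

    def rheobase_at(self, contact: str | None) -> float:
        if isinstance(self.rheobase, Mapping):
            if contact is None or contact not in self.rheobase:
                raise ConfigurationError(
                    f"{self.fiber_type}: no rheobase configured for contact "
                    f"{contact!r}")
            return float(self.rheobase[contact])
        return float(self.rheobase)


#: logistic value at the threshold / saturation anchor points; the clipped
#: sigmoid maps them to exactly 0 and 1 (no axon fires below the smallest
#: axonal threshold, the whole population above the largest)
_EDGE_P = 0.05


def _sd_anchors(fiber: FiberSpec, pulse_width: float,
                contact: str | None) -> tuple[float, float]:
    """Strength-duration-scaled (midpoint, scale) of the recruitment curve."""
    rb = fiber.rheobase_at(contact)
    g = 1.0 + fiber.chronaxie / pulse_width
    i_th = rb * g
    # saturation scales with the same per-contact factor as the threshold
    i_sat = fiber.saturation_current * (rb / _scalar_rheobase(fiber)) * g
    mid = 0.5 * (i_th + i_sat)
    scale = (i_sat - i_th) / (2.0 * _LOGIT_95)
    return mid, scale


def recruitment(fiber: FiberSpec, current: float, pulse_width: float,
                contact: str | None = None) -> float:
    """Fraction of the fiber population recruited by one pulse, in [0, 1].

    Clipped sigmoid of current: exactly 0 at the strength-duration
    threshold ``I_th = rheobase * (1 + chronaxie/pw)``, exactly 1 at the
    equally scaled saturation current, logistic in between (the logistic
    describes the spread of axonal thresholds across the population, so
    its tails outside [I_th, I_sat] are cut). Monotone non-decreasing in
    both current and pulse width; independent of train parameters.
    """
    if current <= 0 or pulse_width <= 0:
        raise ValidationError("current and pulse_width must be > 0")
    mid, scale = _sd_anchors(fiber, pulse_width, contact)
    raw = 1.0 / (1.0 + np.exp(-(current - mid) / scale))
    return float(np.clip((raw - _EDGE_P) / (1.0 - 2.0 * _EDGE_P), 0.0, 1.0))


def _scalar_rheobase(fiber: FiberSpec) -> float:
    """Reference rheobase used to anchor the saturation/threshold ratio."""
    if isinstance(fiber.rheobase, Mapping):
        return float(min(fiber.rheobase.values()))
    return float(fiber.rheobase)


def threshold_current(fiber: FiberSpec, pulse_width: float,
                      level: float = 0.15,
                      contact: str | None = None) -> float:
    """Closed-form current at which recruitment equals ``level``.

    This is the generator-side ground truth the pipeline's neural-threshold
    estimator (15% of maximal activation by default) is validated against.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError("level must lie strictly inside (0, 1)")
    mid, scale = _sd_anchors(fiber, pulse_width, contact)
    raw = _EDGE_P + level * (1.0 - 2.0 * _EDGE_P)
    return float(mid + scale * np.log(raw / (1.0 - raw)))


@dataclass(frozen=True)
class NerveModel:
    """Fiber populations plus artefact and noise parameters of the neurogram.

    The muscle artefact occupies a fixed latency window (4-8 ms) regardless
    of the stimulation-to-recording distance, with gain proportional to
    A-beta recruitment; the stimulation artefact is an exponential decay at
    each pulse onset scaled by current; the virtual cathode effect shifts
    the depolarisation site of anodic pulses toward the recording cuffs
    linearly in the supra-threshold current.
    """

    fibers: tuple[FiberSpec, ...]
    muscle_latency_ms: tuple[float, float] = (4.0, 8.0)
    muscle_center_ms: float = 5.0  # artefact peak, inside the 4-8 ms band
    muscle_width_ms: float = 1.2
    muscle_gain: float = 8.0  # µV at full A-beta recruitment
    stim_artefact_gain: float = 400.0  # µV per mA at pulse onset
    stim_artefact_tau_ms: float = 0.15
    virtual_cathode_mm_per_ma: float = 2.0
    noise_sd: float = 2.0  # µV

    def fiber(self, fiber_type: str) -> FiberSpec:
        for f in self.fibers:
            if f.fiber_type == fiber_type:
                return f
        raise ConfigurationError(f"no fiber of type {fiber_type!r}")

    def has_fiber(self, fiber_type: str) -> bool:
        return any(f.fiber_type == fiber_type for f in self.fibers)


def default_fibers(include_agamma2: bool = False,
                   include_aalpha: bool = False,
                   include_c: bool = False) -> tuple[FiberSpec, ...]:
    """Default fiber populations.

    Velocities sit in the interior of the non-overlapping classification
    bins used by the extractor; thresholds at 260 µs mirror the ordering
    seen on porcine DRCs (A-beta ~0.15 mA, A-gamma ~0.5 mA, B ~1.1 mA).
    A-alpha (masked by the stimulation artefact) and C (not recruited below
    2.5 mA) default to off.
    """
    fibers = [
        FiberSpec("Abeta", 50.0, 0.06, 250.0, 0.145, 40.0, 0.30),
        FiberSpec("Agamma", 22.0, 0.15, 250.0, 0.60, 15.0, 0.40),
        FiberSpec("Adelta", 11.0, 0.25, 250.0, 0.90, 8.0, 0.60),
        FiberSpec("B", 5.5, 0.40, 250.0, 1.10, 20.0, 1.00),
    ]
    if include_agamma2:
        fibers.insert(2, FiberSpec("Agamma2", 26.0, 0.35, 250.0, 1.20,
                                   10.0, 0.40))
    if include_aalpha:
        fibers.insert(0, FiberSpec("Aalpha", 90.0, 0.05, 250.0, 0.12,
                                   60.0, 0.25))
    if include_c:
        fibers.append(FiberSpec("C", 1.2, 3.0, 250.0, 8.0, 3.0, 2.0))
    return tuple(fibers)


def default_nerve_model(**kwargs) -> NerveModel:
    return NerveModel(fibers=default_fibers(), **kwargs)


# ---------------------------------------------------------------------------
# Physiology model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysioModel:
    """Mechanistic mapping from per-pulse recruitment to physiology.

    * ``ΔHR = α(f) * mean A-gamma recruitment − β(f) * B-eCAP count``, where
      the B-eCAP count is the recruitment-weighted number of pulses evoking
      a B response (so recruiting both polarities of a biphasic train
      doubles the count), and β(f) is non-decreasing in frequency;
    * ``ΔBR = −min(100, k * Σ_pulses A-gamma recruitment)`` in percent;
    * twitches: one EMG burst (2.5-10 ms post pulse) per pulse with
      amplitude ``twitch_gain * A-beta recruitment``;
    * spasm score: relative post-train EMG elevation
      ``spasm_gain * frequency * duration * A-beta recruitment``.
    """

    baseline_hr: float = 90.0  # BPM
    baseline_br: float = 30.0  # breaths/min
    hr_alpha: Mapping[float, float] = field(
        default_factory=lambda: {5.0: 2.4, 10.0: 3.2, 20.0: 4.0})
    hr_beta: Mapping[float, float] = field(
        default_factory=lambda: {5.0: 0.20, 10.0: 0.30, 20.0: 0.45})
    br_slope_k: float = 0.5  # % per (pulse × A-gamma recruitment)
    twitch_gain: float = 80.0  # µV at full A-beta recruitment
    twitch_visibility: float = 0.05  # recruitment making a twitch countable
    spasm_gain: float = 0.004  # score per (Hz × s × A-beta recruitment)
    hr_ramp_s: float = 2.0  # HR reaches its new level this long after onset
    hr_hold_s: float = 3.0  # plateau persists this long after train end
    hr_recovery_tau_s: float = 5.0
    #: the dip persists through the ΔBR metric's window (train end + 3 s)
    #: so at least one full slowed breath completes inside it
    br_hold_s: float = 3.0
    br_recovery_s: float = 2.0
    ecg_noise_sd: float = 0.005
    emg_noise_sd: float = 1.0  # µV
    pressure_noise_sd: float = 0.01
    r_peak_jitter_sd_s: float = 0.001  # physiological beat-to-beat jitter

    def alpha(self, frequency: float) -> float:
        return _interp_coefficient(self.hr_alpha, frequency)

    def beta(self, frequency: float) -> float:
        b = _interp_coefficient(self.hr_beta, frequency)
        return b

    def __post_init__(self) -> None:
        freqs = sorted(self.hr_beta)
        betas = [self.hr_beta[f] for f in freqs]
        if any(b2 < b1 for b1, b2 in zip(betas, betas[1:])):
            raise ValidationError(
                "bradycardia gain β(f) must be non-decreasing in frequency")


def _interp_coefficient(table: Mapping[float, float], f: float) -> float:
    keys = np.array(sorted(table))
    vals = np.array([table[k] for k in keys])
    return float(np.interp(f, keys, vals))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class EventGroundTruth:
    """Exact per-event quantities the pipeline is expected to recover."""

    event_id: str
    recruitment: dict[tuple[str, str], float]  # (fiber, polarity) -> frac
    latency_ms: dict[tuple[str, str, str], float]  # (fiber, chan, pol) -> ms
    mean_recruitment: dict[str, float]  # fiber -> mean over pulses
    b_ecap_count: float  # recruitment-weighted pulses evoking a B eCAP
    delta_hr: float  # BPM
    delta_br: float  # %
    twitch_count: int
    spasm_score: float
    pulse_count: int


@dataclass
class GroundTruth:
    """Session-level oracle produced alongside each synthetic session."""

    events: dict[str, EventGroundTruth]
    r_peak_times: np.ndarray
    nerve: NerveModel
    physio: PhysioModel

    def event(self, event_id: str) -> EventGroundTruth:
        return self.events[event_id]

    def threshold_current(self, fiber_type: str, pulse_width: float,
                          level: float = 0.15,
                          contact: str | None = None) -> float:
        return threshold_current(self.nerve.fiber(fiber_type), pulse_width,
                                 level, contact)


def event_ground_truth(event: StimulationEvent, nerve: NerveModel,
                       physio: PhysioModel,
                       geometry: CuffGeometry,
                       neural_channels: Sequence[str]) -> EventGroundTruth:
    """Compute the closed-form ground truth for one event."""
    pulse = event.pulse
    polarities = event.pulse_polarities()
    rec: dict[tuple[str, str], float] = {}
    lat: dict[tuple[str, str, str], float] = {}
    for fiber in nerve.fibers:
        for pol in set(polarities):
            source = pulse.source_contact(pol)
            r = recruitment(fiber, pulse.current, pulse.pulse_width, source)
            rec[(fiber.fiber_type, pol)] = r
            for chan in neural_channels:
                d_eff = effective_distance(
                    geometry.distance(source, chan), pol, pulse.current,
                    fiber, nerve, source)
                lat[(fiber.fiber_type, chan, pol)] = \
                    d_eff / fiber.conduction_velocity
    mean_rec = {
        fiber.fiber_type: float(np.mean(
            [rec[(fiber.fiber_type, p)] for p in polarities]))
        for fiber in nerve.fibers
    }
    pc = event.train.pulse_count
    f = event.train.frequency
    b_count = float(sum(rec.get(("B", p), 0.0) for p in polarities))
    delta_hr = physio.alpha(f) * mean_rec.get("Agamma", 0.0) \
        - physio.beta(f) * b_count
    delta_br = -min(100.0, physio.br_slope_k * pc
                    * mean_rec.get("Agamma", 0.0))
    twitch_count = int(sum(
        rec.get(("Abeta", p), 0.0) >= physio.twitch_visibility
        for p in polarities))
    spasm = physio.spasm_gain * f * event.train.duration \
        * mean_rec.get("Abeta", 0.0)
    return EventGroundTruth(
        event_id=event.event_id,
        recruitment=rec,
        latency_ms=lat,
        mean_recruitment=mean_rec,
        b_ecap_count=b_count,
        delta_hr=float(delta_hr),
        delta_br=float(delta_br),
        twitch_count=twitch_count,
        spasm_score=float(spasm),
        pulse_count=pc,
    )


def effective_distance(distance_mm: float, polarity: str, current: float,
                       fiber: FiberSpec, nerve: NerveModel,
                       contact: str | None = None) -> float:
    """Distance from depolarisation site to recording cuff in mm.

    For anodic pulses the virtual cathode shifts the depolarisation site
    toward the recording cuffs by ``shift * max(0, I - I_th)``.
    """
    if polarity == CATHODIC:
        return distance_mm
    rb = fiber.rheobase_at(contact)
    i_th = rb * (1.0 + fiber.chronaxie / 1e9)  # asymptotic threshold
    shift = nerve.virtual_cathode_mm_per_ma * max(0.0, current - i_th)
    return max(1.0, distance_mm - shift)


# ---------------------------------------------------------------------------
# Waveform primitives
# ---------------------------------------------------------------------------

def _ecap_template(latency_axis_ms: np.ndarray, center_ms: float,
                   width_ms: float) -> np.ndarray:
    """Zero-mean compact eCAP waveform with unit peak exactly at center.

    Ricker (Mexican-hat) shape: a positive main lobe flanked by two
    negative side lobes, the narrow-band limit of a difference of
    Gaussians. Its surround decays like the main lobe, so neighbouring
    fiber latency windows see essentially none of it.
    """
    s = width_ms / 3.0
    t = (latency_axis_ms - center_ms) / s
    return (1.0 - t ** 2) * np.exp(-0.5 * t ** 2)


def _stim_artefact(latency_axis_ms: np.ndarray, amplitude: float,
                   tau_ms: float, sign: float) -> np.ndarray:
    w = np.zeros_like(latency_axis_ms)
    mask = latency_axis_ms >= 0
    w[mask] = sign * amplitude * np.exp(-latency_axis_ms[mask] / tau_ms)
    return w


def _emg_burst(latency_axis_ms: np.ndarray, start_ms: float = 2.5,
               end_ms: float = 10.0) -> np.ndarray:
    """Unit-amplitude damped-oscillation laryngeal twitch burst."""
    w = np.zeros_like(latency_axis_ms)
    mask = (latency_axis_ms >= start_ms) & (latency_axis_ms < end_ms)
    tau = latency_axis_ms[mask] - start_ms
    w[mask] = np.sin(2 * np.pi * 0.8 * tau) * np.exp(-tau / 2.0)
    return w


# ---------------------------------------------------------------------------
# Neural rendering
# ---------------------------------------------------------------------------

_EPOCH_RENDER_MS = 30.0


def _event_epoch_template(event: StimulationEvent, polarity: str,
                          channel_id: str, nerve: NerveModel,
                          geometry: CuffGeometry, fs: float) -> np.ndarray:
    """Noise-free per-pulse response template for one polarity group."""
    n = int(round(_EPOCH_RENDER_MS * 1e-3 * fs))
    lat_ms = np.arange(n) / fs * 1e3
    pulse = event.pulse
    source = pulse.source_contact(polarity)
    sign = 1.0 if polarity == CATHODIC else -1.0
    epoch = _stim_artefact(lat_ms, nerve.stim_artefact_gain * pulse.current,
                           nerve.stim_artefact_tau_ms, sign)
    rec_abeta = 0.0
    for fiber in nerve.fibers:
        r = recruitment(fiber, pulse.current, pulse.pulse_width, source)
        if fiber.fiber_type == "Abeta":
            rec_abeta = r
        if r <= 1e-6:
            continue
        d_eff = effective_distance(geometry.distance(source, channel_id),
                                   polarity, pulse.current, fiber, nerve,
                                   source)
        center = d_eff / fiber.conduction_velocity
        epoch += fiber.max_amplitude * r * _ecap_template(
            lat_ms, center, fiber.waveform_width)
    # muscle artefact: fixed latency window, independent of distance
    epoch += nerve.muscle_gain * rec_abeta * _ecap_template(
        lat_ms, nerve.muscle_center_ms, nerve.muscle_width_ms)
    return epoch


def _add_event_neural(samples: np.ndarray, t0: float, fs: float,
                      event: StimulationEvent, channel_id: str,
                      nerve: NerveModel, geometry: CuffGeometry) -> None:
    templates = {
        pol: _event_epoch_template(event, pol, channel_id, nerve, geometry,
                                   fs)
        for pol in set(event.pulse_polarities())
    }
    n = samples.size
    for t_pulse, pol in zip(event.pulse_onset_times,
                            event.pulse_polarities()):
        i = int(round((t_pulse - t0) * fs))
        tpl = templates[pol]
        j = min(n, i + tpl.size)
        if i < 0 or j <= i:
            continue
        samples[i:j] += tpl[:j - i]


def render_neurogram_trace(event: StimulationEvent, channel_id: str,
                           nerve: NerveModel, geometry: CuffGeometry,
                           rng: np.random.Generator,
                           sampling_rate: float = 20_000.0,
                           pad_s: float = 1.0) -> ChannelTrace:
    """Render a standalone neural cuff trace covering one event.

    The trace is the stimulation artefact at each pulse onset, plus one eCAP
    per recruited fiber at latency ``effective_distance / velocity``, plus a
    distance-invariant muscle artefact in the 4-8 ms window, plus Gaussian
    noise.
    """
    t0 = np.floor((event.onset_time - pad_s) * sampling_rate) / sampling_rate
    t1 = event.end_time + pad_s
    n = int(round((t1 - t0) * sampling_rate))
    samples = rng.normal(0.0, nerve.noise_sd, n) if nerve.noise_sd > 0 \
        else np.zeros(n)
    _add_event_neural(samples, t0, sampling_rate, event, channel_id, nerve,
                      geometry)
    return ChannelTrace(channel_id=channel_id, modality="neural",
                        sampling_rate=sampling_rate, start_time=t0,
                        samples=samples)


# ---------------------------------------------------------------------------
# Physiology rendering
# ---------------------------------------------------------------------------

def _hr_shape(t: np.ndarray, onset: float, end: float,
              physio: PhysioModel) -> np.ndarray:
    """Unitless 0..1 time course of the HR deviation for one event."""
    shape = np.zeros_like(t)
    ramp = (t >= onset) & (t < onset + physio.hr_ramp_s)
    shape[ramp] = (t[ramp] - onset) / physio.hr_ramp_s
    hold_end = end + physio.hr_hold_s
    shape[(t >= onset + physio.hr_ramp_s) & (t < hold_end)] = 1.0
    decay = t >= hold_end
    shape[decay] = np.exp(-(t[decay] - hold_end) / physio.hr_recovery_tau_s)
    return shape


def _instantaneous_hr(tgrid: np.ndarray, events: Sequence[StimulationEvent],
                      truths: Mapping[str, EventGroundTruth],
                      physio: PhysioModel) -> np.ndarray:
    hr = np.full_like(tgrid, physio.baseline_hr)
    for ev in events:
        gt = truths[ev.event_id]
        if gt.delta_hr != 0.0:
            hr += gt.delta_hr * _hr_shape(tgrid, ev.onset_time, ev.end_time,
                                          physio)
    return np.maximum(hr, 20.0)


def _r_peak_times(duration: float, events: Sequence[StimulationEvent],
                  truths: Mapping[str, EventGroundTruth],
                  physio: PhysioModel,
                  rng: np.random.Generator) -> np.ndarray:
    tgrid = np.arange(0.0, duration, 0.02)
    rate = _instantaneous_hr(tgrid, events, truths, physio) / 60.0  # beats/s
    beats = np.concatenate([[0.0], np.cumsum(rate[:-1] * np.diff(tgrid))])
    n_beats = int(np.floor(beats[-1]))
    times = np.interp(np.arange(1, n_beats + 1) - 0.5, beats, tgrid)
    if physio.r_peak_jitter_sd_s > 0:
        times = times + rng.normal(0.0, physio.r_peak_jitter_sd_s,
                                   times.size)
        times.sort()
    return times


def _ecg_samples(duration: float, fs: float, r_times: np.ndarray,
                 physio: PhysioModel, rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration * fs))
    x = rng.normal(0.0, physio.ecg_noise_sd, n)
    # QRS-like template: sharp positive peak with a shallow after-wave
    tt = np.arange(-0.03, 0.06, 1.0 / fs)
    tpl = np.exp(-(tt / 0.006) ** 2 / 2) - 0.25 * np.exp(
        -((tt - 0.025) / 0.012) ** 2 / 2)
    half = int(round(0.03 * fs))
    for t_r in r_times:
        i = int(round(t_r * fs)) - half
        j = min(n, i + tpl.size)
        if i < 0 or j <= i:
            continue
        x[i:j] += tpl[:j - i]
    return x


def _breathing_rate_course(tgrid: np.ndarray,
                           events: Sequence[StimulationEvent],
                           truths: Mapping[str, EventGroundTruth],
                           physio: PhysioModel) -> np.ndarray:
    br = np.full_like(tgrid, physio.baseline_br)
    for ev in events:
        gt = truths[ev.event_id]
        dipped = physio.baseline_br * (1.0 + gt.delta_br / 100.0)
        hold_end = ev.end_time + physio.br_hold_s
        br[(tgrid >= ev.onset_time) & (tgrid < hold_end)] = dipped
        ramp = (tgrid >= hold_end) & (tgrid < hold_end + physio.br_recovery_s)
        frac = (tgrid[ramp] - hold_end) / physio.br_recovery_s
        br[ramp] = dipped + (physio.baseline_br - dipped) * frac
    return br


def _pressure_samples(duration: float, fs: float,
                      events: Sequence[StimulationEvent],
                      truths: Mapping[str, EventGroundTruth],
                      physio: PhysioModel,
                      rng: np.random.Generator) -> np.ndarray:
    tgrid = np.arange(int(round(duration * fs))) / fs
    rate = _breathing_rate_course(tgrid, events, truths, physio)  # br/min
    dphi = 2 * np.pi * rate / 60.0 / fs
    phase = np.cumsum(dphi)
    x = np.sin(phase)
    x += rng.normal(0.0, physio.pressure_noise_sd, x.size)
    return x


def _emg_samples(duration: float, fs: float,
                 events: Sequence[StimulationEvent],
                 truths: Mapping[str, EventGroundTruth],
                 physio: PhysioModel, rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration * fs))
    x = rng.normal(0.0, physio.emg_noise_sd, n)
    n_burst = int(round(10.0e-3 * fs))
    lat_ms = np.arange(n_burst) / fs * 1e3
    burst = _emg_burst(lat_ms)
    for ev in events:
        gt = truths[ev.event_id]
        for t_pulse, pol in zip(ev.pulse_onset_times, ev.pulse_polarities()):
            r = gt.recruitment.get(("Abeta", pol), 0.0)
            if r <= 1e-6:
                continue
            i = int(round(t_pulse * fs))
            j = min(n, i + n_burst)
            if i < 0 or j <= i:
                continue
            x[i:j] += physio.twitch_gain * r * burst[:j - i]
        # sustained post-train elevation encodes the spasm score: the noise
        # floor in [end, end+1 s) is scaled so that the post/pre L1 ratio
        # equals 1 + spasm_score in expectation
        if gt.spasm_score > 0:
            i = int(round(ev.end_time * fs))
            j = min(n, i + int(round(1.0 * fs)))
            x[i:j] *= 1.0 + gt.spasm_score
    return x


def render_physio_traces(events: Sequence[StimulationEvent] | StimulationEvent,
                         truths: Mapping[str, EventGroundTruth],
                         physio: PhysioModel,
                         rng: np.random.Generator,
                         duration: float,
                         ecg_fs: float = 1000.0,
                         emg_fs: float = 5000.0,
                         pressure_fs: float = 1000.0,
                         ) -> tuple[dict[str, ChannelTrace], np.ndarray]:
    """Render ECG, laryngeal EMG and breathing-pressure channels.

    Returns the traces plus the exact R-peak times used for the ECG.
    """
    if isinstance(events, StimulationEvent):
        events = [events]
    r_times = _r_peak_times(duration, events, truths, physio, rng)
    traces = {
        "ecg": ChannelTrace("ecg", "ecg", ecg_fs, 0.0,
                            _ecg_samples(duration, ecg_fs, r_times, physio,
                                         rng)),
        "emg": ChannelTrace("emg", "emg", emg_fs, 0.0,
                            _emg_samples(duration, emg_fs, events, truths,
                                         physio, rng)),
        "pressure": ChannelTrace("pressure", "pressure", pressure_fs, 0.0,
                                 _pressure_samples(duration, pressure_fs,
                                                   events, truths, physio,
                                                   rng)),
    }
    return traces, r_times


# ---------------------------------------------------------------------------
# Session configuration and generation
# ---------------------------------------------------------------------------

def default_geometry(contacts: Sequence[str] = tuple(
        f"C{i}" for i in range(1, 9)),
        channel_distances: Mapping[str, float] | None = None,
        ring_offset_mm: float = 3.0) -> CuffGeometry:
    """Stimulation cuff C1..C8 recorded on two cuffs at 50.0 and 54.5 mm.

    Contacts C1-C4 form the rostral ring, C5-C8 the caudal ring
    ``ring_offset_mm`` farther from the recording cuffs.
    """
    channel_distances = channel_distances or {"cuffA": 50.0, "cuffB": 54.5}
    distances = {}
    for c in contacts:
        offset = 0.0 if int(c[1:]) <= 4 else ring_offset_mm
        for chan, d in channel_distances.items():
            distances[(c, chan)] = d + offset
    cuff_contacts = tuple(("C", c) for c in contacts) + tuple(
        (chan, "ring") for chan in channel_distances)
    return CuffGeometry(contacts=cuff_contacts,
                        stim_to_record_distance=distances)


@dataclass(frozen=True)
class SessionConfig:
    """Parameter grid and model configuration for one synthetic session.

    The default grid emulates a biomarker experiment: monophasic cathodic
    trains from one longitudinal pair, twelve currents spanning
    0.05-2.5 mA at 260 µs, two frequencies (10, 20 Hz), 5 s trains, and the
    protocol's 30 s minimum gap between stimulations.
    """

    subject_id: str = "synthetic"
    currents: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2, 0.25, 0.35, 0.5,
                                   0.65, 0.8, 1.0, 1.2, 1.7, 2.2, 2.5)
    pulse_widths: tuple[float, ...] = (260.0,)
    frequencies: tuple[float, ...] = (10.0, 20.0)
    durations: tuple[float, ...] = (5.0,)
    contact_pairs: tuple[str, ...] = ("C1-C8",)
    polarities: tuple[str, ...] = (CATHODIC,)
    waveform: str = MONOPHASIC
    inter_event_gap: float = 30.0  # s, >= 30 s for physiology grids
    lead_in: float = 10.0  # s of baseline before the first event
    tail: float = 15.0  # s after the last train
    neural_fs: float = 20_000.0
    ecg_fs: float = 1000.0
    emg_fs: float = 5000.0
    pressure_fs: float = 1000.0
    neural_channels: tuple[str, ...] = ("cuffA", "cuffB")
    nerve: NerveModel = field(default_factory=default_nerve_model)
    physio: PhysioModel = field(default_factory=PhysioModel)
    geometry: CuffGeometry = field(default_factory=default_geometry)


def recruitment_grid(**overrides) -> SessionConfig:
    """Neural-focus grid: two pulse widths, short low-frequency trains.

    Physiological integration is irrelevant here, so trains are 3 s at
    10 Hz (30 pulses averaged per neurogram) and the inter-stimulus gap is
    relaxed to 10 s (the 30 s protocol minimum applies to stimulations
    affecting physiology).
    """
    defaults = dict(
        pulse_widths=(130.0, 260.0),
        frequencies=(10.0,),
        durations=(3.0,),
        inter_event_gap=10.0,
        lead_in=8.0,
        tail=5.0,
    )
    defaults.update(overrides)
    return SessionConfig(**defaults)


def latent_grid(**overrides) -> SessionConfig:
    """Activation-vector grid: five probe currents from ten locations.

    Eight longitudinal pairs plus two radial pairs, 260 µs, with
    per-contact rheobase scaling so locations differ in recruitment
    readiness and in their A-gamma vs B balance.
    """
    scale = {"C1": 0.80, "C2": 0.90, "C3": 1.00, "C4": 1.10,
             "C5": 1.25, "C6": 1.40, "C7": 0.85, "C8": 1.15}
    gamma_scale = {"C1": 1.20, "C2": 0.85, "C3": 1.05, "C4": 0.90,
                   "C5": 1.10, "C6": 0.80, "C7": 1.30, "C8": 0.95}
    base = default_fibers()
    fibers = []
    for f in base:
        per_contact = {
            c: f.rheobase * scale[c]
            * (gamma_scale[c] if f.fiber_type in ("Agamma", "B") else 1.0)
            for c in scale
        }
        fibers.append(replace(f, rheobase=per_contact))
    defaults = dict(
        currents=(0.1, 0.25, 0.5, 1.0, 2.0),
        pulse_widths=(260.0,),
        frequencies=(10.0,),
        durations=(1.0,),
        contact_pairs=("C1-C8", "C2-C7", "C3-C6", "C4-C5", "C1-C5",
                       "C2-C6", "C3-C7", "C4-C8", "C2-C3", "C6-C7"),
        inter_event_gap=10.0,
        lead_in=8.0,
        tail=5.0,
        nerve=NerveModel(fibers=tuple(fibers)),
    )
    defaults.update(overrides)
    return SessionConfig(**defaults)


def generate_session(config: SessionConfig | None = None,
                     seed: int = 0) -> tuple[Session, GroundTruth]:
    """Generate a synthetic session and its exact ground truth.

    Events are laid out sequentially with the configured inter-stimulation
    gap; event onsets are snapped to the neural sampling grid so that
    noise-free per-pulse epochs are sample-aligned. Deterministic given
    ``seed``.
    """
    config = config or SessionConfig()
    grid = list(itertools.product(
        config.contact_pairs, config.polarities, config.pulse_widths,
        config.frequencies, config.durations, config.currents))
    if not grid:
        raise ConfigurationError("empty stimulation parameter grid")
    rng = np.random.default_rng(seed)

    events: list[StimulationEvent] = []
    t = config.lead_in
    for k, (pair, pol, pw, f, dur, cur) in enumerate(grid):
        onset = np.round(t * config.neural_fs) / config.neural_fs
        events.append(StimulationEvent(
            event_id=f"ev{k:03d}",
            onset_time=float(onset),
            pulse=StimPulseParams(current=cur, pulse_width=pw,
                                  contact_pair=pair, polarity=pol,
                                  waveform=config.waveform),
            train=StimTrainParams(frequency=f, duration=dur),
        ))
        t = onset + dur + config.inter_event_gap
    duration = events[-1].end_time + config.tail

    truths = {
        ev.event_id: event_ground_truth(ev, config.nerve, config.physio,
                                        config.geometry,
                                        config.neural_channels)
        for ev in events
    }

    traces: list[ChannelTrace] = []
    n_neural = int(round(duration * config.neural_fs))
    for chan in config.neural_channels:
        samples = rng.normal(0.0, config.nerve.noise_sd, n_neural) \
            if config.nerve.noise_sd > 0 else np.zeros(n_neural)
        for ev in events:
            _add_event_neural(samples, 0.0, config.neural_fs, ev, chan,
                              config.nerve, config.geometry)
        traces.append(ChannelTrace(chan, "neural", config.neural_fs, 0.0,
                                   samples))

    physio_traces, r_times = render_physio_traces(
        events, truths, config.physio, rng, duration,
        ecg_fs=config.ecg_fs, emg_fs=config.emg_fs,
        pressure_fs=config.pressure_fs)
    traces.extend(physio_traces.values())

    session = Session(
        subject_id=config.subject_id,
        geometry=config.geometry,
        events=events,
        traces=traces,
        metadata={
            "baseline_hr_bpm": config.physio.baseline_hr,
            "baseline_br_bpm": config.physio.baseline_br,
            "seed": int(seed),
        },
    )
    truth = GroundTruth(events=truths, r_peak_times=r_times,
                        nerve=config.nerve, physio=config.physio)
    return session, truth


__all__ = [
    "EventGroundTruth", "FiberSpec", "GroundTruth", "NerveModel",
    "PhysioModel", "SessionConfig", "TABLE_VELOCITY_RANGES",
    "default_fibers", "default_geometry", "default_nerve_model",
    "effective_distance", "event_ground_truth", "generate_session",
    "latent_grid", "recruitment", "recruitment_grid",
    "render_neurogram_trace", "render_physio_traces", "threshold_current",
]
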