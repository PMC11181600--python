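"""Core data model for vagus-nerve-stimulation (VNS) sessions.

A *session* bundles everything recorded for one subject: the table of
stimulation events (pulse parameters: current, pulse width, contact pair,
polarity, waveform; train parameters: frequency, duration), the continuous
channel traces (neural cuff channels, ECG, laryngeal EMG, breathing
pressure), and the cuff geometry (stimulation-to-recording distances).

Conventions used throughout the package:

* time is in seconds, 0-based from session start; per-pulse latencies are in
  milliseconds from pulse onset; all windows are half-open ``[start, end)``;
* units are mA (current), µs (pulse width), Hz, s, mm, µV.

Serialization is a directory containing a JSON manifest plus one ``.npy``
array per channel; the format is lossless and byte-deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, ValidationError

CATHODIC = "cathodic"
ANODIC = "anodic"
POLARITIES = (CATHODIC, ANODIC)
MONOPHASIC = "monophasic"
BIPHASIC_ALTERNATING = "biphasic_alternating"
WAVEFORMS = (MONOPHASIC, BIPHASIC_ALTERNATING)
MODALITIES = ("neural", "ecg", "emg", "pressure")


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValidationError(message)


@dataclass(frozen=True)
class StimPulseParams:
    """Parameters of a single rectangular stimulation pulse.

    ``polarity`` states which contact of ``contact_pair`` acts as the current
    source for the *first* pulse of the train: ``cathodic`` means the first
    named contact, ``anodic`` the second.
    """

    current: float  # mA
    pulse_width: float  # µs
    contact_pair: str  # e.g. "C1-C8"
    polarity: str = CATHODIC
    waveform: str = MONOPHASIC

    def __post_init__(self) -> None:
        _require(self.current > 0, f"current must be > 0, got {self.current}")
        _require(self.pulse_width > 0,
                 f"pulse_width must be > 0, got {self.pulse_width}")
        parts = self.contact_pair.split("-")
        _require(len(parts) == 2 and parts[0] != parts[1] and all(parts),
                 f"contact_pair must name two distinct contacts, "
                 f"got {self.contact_pair!r}")
        _require(self.polarity in POLARITIES,
                 f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        _require(self.waveform in WAVEFORMS,
                 f"waveform must be one of {WAVEFORMS}, got {self.waveform!r}")

    @property
    def contacts(self) -> tuple[str, str]:
        a, b = self.contact_pair.split("-")
        return a, b

    def source_contact(self, polarity: str) -> str:
        """Contact acting as current source for a pulse of given polarity."""
        a, b = self.contacts
        return a if polarity == CATHODIC else b


@dataclass(frozen=True)
class StimTrainParams:
    """Train parameters: pulse repetition frequency and train duration."""

    frequency: float  # Hz
    duration: float  # s

    def __post_init__(self) -> None:
        _require(self.frequency > 0,
                 f"frequency must be > 0, got {self.frequency}")
        _require(self.duration > 0,
                 f"duration must be > 0, got {self.duration}")
        _require(self.pulse_count >= 1,
                 "train must contain at least one pulse")

    @property
    def pulse_count(self) -> int:
        return int(round(self.frequency * self.duration))


@dataclass(frozen=True)
class StimulationEvent:
    """One stimulation train applied at ``onset_time``.

    ``pulse_onset_times`` are absolute times (s) of each pulse, spaced
    ``1/frequency``. For ``biphasic_alternating`` waveforms polarity
    alternates pulse-by-pulse starting from ``pulse.polarity``.
    """

    event_id: str
    onset_time: float
    pulse: StimPulseParams
    train: StimTrainParams
    pulse_onset_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.pulse_onset_times:
            times = self.onset_time + np.arange(self.train.pulse_count) / \
                self.train.frequency
            object.__setattr__(self, "pulse_onset_times", tuple(times))
        times = np.asarray(self.pulse_onset_times)
        _require(len(times) == self.train.pulse_count,
                 f"event {self.event_id}: pulse_onset_times length "
                 f"{len(times)} != pulse_count {self.train.pulse_count}")
        _require(bool(np.all(np.diff(times) > 0)),
                 f"event {self.event_id}: pulse_onset_times must be "
                 "strictly increasing")
        expected_dt = 1.0 / self.train.frequency
        if len(times) > 1:
            _require(bool(np.allclose(np.diff(times), expected_dt,
                                      rtol=1e-6, atol=1e-9)),
                     f"event {self.event_id}: pulses must be spaced "
                     f"1/frequency = {expected_dt} s")

    @property
    def end_time(self) -> float:
        """End of the train (last pulse onset + one inter-pulse interval)."""
        return self.pulse_onset_times[-1] + 1.0 / self.train.frequency

    def pulse_polarities(self) -> list[str]:
        """Polarity of each pulse; alternates for biphasic trains."""
        first = self.pulse.polarity
        other = ANODIC if first == CATHODIC else CATHODIC
        if self.pulse.waveform == MONOPHASIC:
            return [first] * self.train.pulse_count
        return [first if k % 2 == 0 else other
                for k in range(self.train.pulse_count)]


@dataclass
class ChannelTrace:
    """Uniformly sampled recording of one channel.

    Samples are µV for electrophysiology channels and arbitrary pressure
    units for breathing. The time of sample ``k`` is
    ``start_time + k / sampling_rate``.
    """

    channel_id: str
    modality: str
    sampling_rate: float  # Hz
    start_time: float  # s
    samples: np.ndarray

    def __post_init__(self) -> None:
        _require(self.modality in MODALITIES,
                 f"modality must be one of {MODALITIES}, got {self.modality!r}")
        _require(self.sampling_rate > 0,
                 f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        _require(self.samples.ndim == 1 and self.samples.size > 0,
                 f"channel {self.channel_id}: samples must be a non-empty "
                 "1-D array")

    @property
    def end_time(self) -> float:
        return self.start_time + self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / \
            self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the first sample at time >= t."""
        return int(np.ceil((t - self.start_time) * self.sampling_rate - 1e-9))


def slice_trace(trace: ChannelTrace, t0: float, t1: float) -> ChannelTrace:
    """Return the half-open window [t0, t1) of ``trace`` as a new trace.

    Sample ``k`` of the result is the first original sample at time >= t0;
    the number of samples equals ``round(fs * (t1 - t0))`` for windows
    aligned to the sampling grid.
    """
    if not (trace.start_time <= t0 < t1 <= trace.end_time + 1e-12):
        raise BoundsError(
            f"window [{t0}, {t1}) outside trace span "
            f"[{trace.start_time}, {trace.end_time})")
    i0 = trace.index_at(t0)
    i1 = trace.index_at(t1)
    if i1 <= i0:
        raise BoundsError(f"window [{t0}, {t1}) contains no samples")
    return ChannelTrace(
        channel_id=trace.channel_id,
        modality=trace.modality,
        sampling_rate=trace.sampling_rate,
        start_time=trace.start_time + i0 / trace.sampling_rate,
        samples=trace.samples[i0:i1].copy(),
    )


@dataclass(frozen=True)
class CuffGeometry:
    """Cuff contacts and stimulation-to-recording distances.

    ``stim_to_record_distance`` maps ``(stimulation contact, neural channel
    id)`` to the distance in mm between the depolarisation site and the
    recording cuff. The nominal inter-cuff distance in the emulated
    preparation is 50 mm.
    """

    contacts: tuple[tuple[str, str], ...]  # (cuff_id, contact_label)
    stim_to_record_distance: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for key, d in self.stim_to_record_distance.items():
            _require(d > 0, f"distance for {key} must be > 0, got {d}")

    def distance(self, stim_contact: str, channel_id: str) -> float:
        try:
            return self.stim_to_record_distance[(stim_contact, channel_id)]
        except KeyError:
            raise ValidationError(
                f"no distance configured for stimulation contact "
                f"{stim_contact!r} and channel {channel_id!r}") from None


@dataclass
class Session:
    """All data recorded for one subject in one experimental session."""

    subject_id: str
    geometry: CuffGeometry
    events: list[StimulationEvent]
    traces: list[ChannelTrace]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = [e.onset_time for e in self.events]
        _require(onsets == sorted(onsets), "events must be sorted by onset")
        ids = [t.channel_id for t in self.traces]
        _require(len(ids) == len(set(ids)), "channel_ids must be unique")
        for ev in self.events:
            for tr in self.traces:
                _require(
                    tr.start_time <= ev.onset_time
                    and ev.end_time <= tr.end_time,
                    f"event {ev.event_id} ([{ev.onset_time}, {ev.end_time}] s)"
                    f" extends outside trace {tr.channel_id} span "
                    f"[{tr.start_time}, {tr.end_time}] s")

    def trace(self, channel_id: str) -> ChannelTrace:
        for tr in self.traces:
            if tr.channel_id == channel_id:
                return tr
        raise ValidationError(f"unknown channel {channel_id!r}")

    def channels(self, modality: str) -> list[ChannelTrace]:
        return [t for t in self.traces if t.modality == modality]

    def event(self, event_id: str) -> StimulationEvent:
        for ev in self.events:
            if ev.event_id == event_id:
                return ev
        raise ValidationError(f"unknown event {event_id!r}")

    def __iter__(self) -> Iterator[StimulationEvent]:
        return iter(self.events)


# ---------------------------------------------------------------------------
# Serialization: JSON manifest + one .npy file per channel
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


def events_table(session: Session) -> pd.DataFrame:
    """Event table with one row per stimulation event (CSV-exportable)."""
    rows = []
    for ev in session.events:
        rows.append({
            "event_id": ev.event_id,
            "onset_time_s": ev.onset_time,
            "current_mA": ev.pulse.current,
            "pulse_width_us": ev.pulse.pulse_width,
            "contact_pair": ev.pulse.contact_pair,
            "polarity": ev.pulse.polarity,
            "waveform": ev.pulse.waveform,
            "frequency_hz": ev.train.frequency,
            "duration_s": ev.train.duration,
        })
    return pd.DataFrame(rows)


def _event_to_dict(ev: StimulationEvent) -> dict:
    return {
        "event_id": ev.event_id,
        "onset_time_s": ev.onset_time,
        "current_mA": ev.pulse.current,
        "pulse_width_us": ev.pulse.pulse_width,
        "contact_pair": ev.pulse.contact_pair,
        "polarity": ev.pulse.polarity,
        "waveform": ev.pulse.waveform,
        "frequency_hz": ev.train.frequency,
        "duration_s": ev.train.duration,
        "pulse_onset_times_s": list(ev.pulse_onset_times),
    }


def _event_from_dict(d: Mapping) -> StimulationEvent:
    return StimulationEvent(
        event_id=str(d["event_id"]),
        onset_time=float(d["onset_time_s"]),
        pulse=StimPulseParams(
            current=float(d["current_mA"]),
            pulse_width=float(d["pulse_width_us"]),
            contact_pair=str(d["contact_pair"]),
            polarity=str(d["polarity"]),
            waveform=str(d["waveform"]),
        ),
        train=StimTrainParams(
            frequency=float(d["frequency_hz"]),
            duration=float(d["duration_s"]),
        ),
        pulse_onset_times=tuple(d.get("pulse_onset_times_s", ())),
    )


def write_session(session: Session, path: str | Path) -> Path:
    """Write ``session`` under directory ``path``; returns the manifest path.

    Layout: ``manifest.json`` (subject, geometry, events, channel registry)
    plus one little-endian float64 ``.npy`` file per channel. The format
    round-trips exactly (``read_session(write_session(s)) == s``) and is
    byte-deterministic for identical sessions.
    """
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create session directory {path}: {exc}") from exc
    channels = []
    for tr in session.traces:
        fname = f"{tr.channel_id}.npy"
        np.save(path / fname, tr.samples.astype("<f8"))
        channels.append({
            "channel_id": tr.channel_id,
            "modality": tr.modality,
            "sampling_rate_hz": tr.sampling_rate,
            "start_time_s": tr.start_time,
            "file": fname,
        })
    manifest = {
        "format": "ecapkit-session",
        "version": 1,
        "subject_id": session.subject_id,
        "metadata": session.metadata,
        "geometry": {
            "contacts": [list(c) for c in session.geometry.contacts],
            "stim_to_record_distance_mm": [
                [stim, chan, d] for (stim, chan), d in
                sorted(session.geometry.stim_to_record_distance.items())
            ],
        },
        "events": [_event_to_dict(ev) for ev in session.events],
        "channels": channels,
    }
    manifest_path = path / MANIFEST_NAME
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest_path


def read_session(manifest_path: str | Path) -> Session:
    """Read a session previously written by :func:`write_session`.

    ``manifest_path`` may be either the manifest file or its directory.
    Missing files raise ``FileNotFoundError`` naming the file; invariant
    violations raise :class:`~ecapkit.errors.ValidationError`.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    geometry = CuffGeometry(
        contacts=tuple(tuple(c) for c in manifest["geometry"]["contacts"]),
        stim_to_record_distance={
            (stim, chan): float(d) for stim, chan, d in
            manifest["geometry"]["stim_to_record_distance_mm"]
        },
    )
    events = [_event_from_dict(d) for d in manifest["events"]]
    traces = []
    for ch in manifest["channels"]:
        fpath = base / ch["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"channel file not found: {fpath}")
        traces.append(ChannelTrace(
            channel_id=str(ch["channel_id"]),
            modality=str(ch["modality"]),
            sampling_rate=float(ch["sampling_rate_hz"]),
            start_time=float(ch["start_time_s"]),
            samples=np.load(fpath),
        ))
    return Session(
        subject_id=str(manifest["subject_id"]),
        geometry=geometry,
        events=events,
        traces=traces,
        metadata=dict(manifest.get("metadata", {})),
    )


def session_digest(path: str | Path) -> str:
    """SHA-256 over the manifest and all channel files (determinism checks)."""
    path = Path(path)
    if path.is_file():
        path = path.parent
    h = hashlib.sha256()
    for f in sorted(path.iterdir()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


def sessions_equal(a: Session, b: Session) -> bool:
    """Field-by-field equality up to floating-point representation."""
    if a.subject_id != b.subject_id or len(a.events) != len(b.events) \
            or len(a.traces) != len(b.traces):
        return False
    if dict(a.geometry.stim_to_record_distance) != \
            dict(b.geometry.stim_to_record_distance):
        return False
    if a.geometry.contacts != b.geometry.contacts:
        return False
    for ea, eb in zip(a.events, b.events):
        if ea.event_id != eb.event_id or ea.pulse != eb.pulse \
                or ea.train != eb.train:
            return False
        if not np.allclose(ea.pulse_onset_times, eb.pulse_onset_times,
                           rtol=0, atol=0):
            return False
    for ta, tb in zip(a.traces, b.traces):
        if (ta.channel_id, ta.modality, ta.sampling_rate, ta.start_time) != \
                (tb.channel_id, tb.modality, tb.sampling_rate, tb.start_time):
            return False
        if not np.array_equal(ta.samples, tb.samples):
            return False
    return True


__all__ = [
    "ANODIC", "BIPHASIC_ALTERNATING", "CATHODIC", "ChannelTrace",
    "CuffGeometry", "MONOPHASIC", "Session", "StimPulseParams",
    "StimTrainParams", "StimulationEvent", "events_table", "read_session",
    "session_digest", "sessions_equal", "slice_trace", "write_session",
]
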