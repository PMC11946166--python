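"""Recordings, events, SNIRF (HDF5) I/O and two-performer synchronization.

A :class:`Recording` holds the raw detector intensities of one performer
together with the montage, sampling rate and labelled events.  Two
performers recorded on separate laptops share event labels streamed between
the machines; :func:`synchronize` estimates the clock offset from those
shared labels and aligns the second recording, the in-silico counterpart of
an LSL-linked hyperscanning setup.

SNIRF files are read and written directly as HDF5 following the SNIRF v1.1
group layout (one continuous-wave data block, `/nirs/data1`, `measurementListN`
channel descriptors, `/nirs/probe` and `/nirs/stimN` groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .montage import ChannelDef, Montage, Optode

#: Default acquisition rate of the wearable system, Hz.
DEFAULT_FS = 75.0

#: Tolerance (s) within which shared-label onsets count as synchronized.
SYNC_TOLERANCE_S = 0.1


class FormatError(ValueError):
    """Raised for malformed or non-conformant SNIRF content."""


@dataclass(frozen=True)
class Event:
    label: str
    onset: float  # s from recording start
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration < 0:
            raise ValueError(f"event {self.label!r}: negative onset/duration")


@dataclass
class Recording:
    """Raw intensity time series [n_samples x n_channels] for one subject."""

    montage: Montage
    fs: float
    intensity: np.ndarray
    events: list[Event] = field(default_factory=list)
    subject_id: str = ""
    aligned: bool = False  # set once a sync offset has been applied

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2-D [samples x channels]")
        if self.intensity.shape[1] != len(self.montage.channels):
            raise ValueError(
                f"intensity has {self.intensity.shape[1]} columns, montage defines "
                f"{len(self.montage.channels)} channels"
            )
        if not np.all(self.intensity > 0):
            bad = np.unique(np.nonzero(~(self.intensity > 0))[1])
            raise ValueError(f"non-positive intensity in channel columns {bad.tolist()}")
        self.events = sorted(self.events, key=lambda e: e.onset)
        if self.events and self.events[-1].onset >= self.n_samples / self.fs:
            raise ValueError("event onset beyond end of recording")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def shifted_events(self, offset: float) -> list[Event]:
        return [replace(e, onset=e.onset + offset) for e in self.events]


@dataclass
class HyperscanSession:
    """Two aligned performer recordings plus the estimated clock offset (s)."""

    recordings: tuple[Recording, Recording]
    clock_offset: float
    residuals: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# SNIRF I/O
# ---------------------------------------------------------------------------

def write_snirf(recording: Recording, path) -> None:
    """Write one continuous-wave SNIRF v1.1 file (one /nirs block)."""
    m = recording.montage
    sources = [o for o in m.optodes if o.kind == "source"]
    detectors = [o for o in m.optodes if o.kind == "detector"]
    src_index = {o.id: i + 1 for i, o in enumerate(sources)}  # SNIRF is 1-based
    det_index = {o.id: i + 1 for i, o in enumerate(detectors)}
    wavelengths = list(m.wavelengths)

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.1")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=recording.subject_id or "unknown")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, float))
        probe.create_dataset(
            "sourcePos3D", data=np.array([o.position for o in sources], float)
        )
        probe.create_dataset(
            "detectorPos3D", data=np.array([o.position for o in detectors], float)
        )
        probe.create_dataset("sourceLabels", data=[o.id for o in sources])
        probe.create_dataset("detectorLabels", data=[o.id for o in detectors])

        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=recording.intensity)
        data.create_dataset(
            "time", data=np.arange(recording.n_samples, dtype=float) / recording.fs
        )
        for j, ch in enumerate(m.channels, start=1):
            ml = data.create_group(f"measurementList{j}")
            ml.create_dataset("sourceIndex", data=src_index[ch.source_id])
            ml.create_dataset("detectorIndex", data=det_index[ch.detector_id])
            ml.create_dataset(
                "wavelengthIndex", data=wavelengths.index(ch.wavelength) + 1
            )
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)
            # SSC flag is not part of the core SNIRF measurementList; carried
            # as a sourcePower-adjacent auxiliary integer for roundtripping.
            ml.create_dataset("detectorGain", data=1.0)
            ml.attrs["isShortChannel"] = int(ch.is_short)

        labels = sorted({e.label for e in recording.events})
        for k, label in enumerate(labels, start=1):
            rows = [
                [e.onset, e.duration, 1.0]
                for e in recording.events
                if e.label == label
            ]
            stim = nirs.create_group(f"stim{k}")
            stim.create_dataset("name", data=label)
            stim.create_dataset("data", data=np.asarray(rows, float))


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path) -> Recording:
    """Read a one-block continuous-wave SNIRF v1.x file."""
    with h5py.File(path, "r") as f:
        if "nirs" in f:
            nirs = f["nirs"]
        elif "nirs1" in f:
            nirs = f["nirs1"]
        else:
            raise FormatError("no /nirs group")
        if "probe" not in nirs:
            raise FormatError("missing /nirs/probe group")
        probe = nirs["probe"]
        wavelengths = np.asarray(probe["wavelengths"][()], float)
        spos = np.asarray(probe["sourcePos3D"][()], float)
        dpos = np.asarray(probe["detectorPos3D"][()], float)
        slabels = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in probe["sourceLabels"][()]
        ] if "sourceLabels" in probe else [f"S{i+1}" for i in range(len(spos))]
        dlabels = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in probe["detectorLabels"][()]
        ] if "detectorLabels" in probe else [f"D{i+1}" for i in range(len(dpos))]

        data = nirs["data1"]
        t = np.asarray(data["time"][()], float)
        dt = np.diff(t)
        if len(dt) and (np.max(dt) - np.min(dt)) > 1e-6 * np.mean(dt) + 1e-9:
            raise FormatError("non-uniform time vector")
        fs = 1.0 / float(np.mean(dt)) if len(dt) else DEFAULT_FS
        intensity = np.asarray(data["dataTimeSeries"][()], float)

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        channels = []
        for k in ml_names:
            ml = data[k]
            sid = slabels[int(ml["sourceIndex"][()]) - 1]
            did = dlabels[int(ml["detectorIndex"][()]) - 1]
            wl = float(wavelengths[int(ml["wavelengthIndex"][()]) - 1])
            short = bool(ml.attrs.get("isShortChannel", 0))
            channels.append(ChannelDef(sid, did, wl, short))

        optodes = [Optode(l, "source", tuple(p)) for l, p in zip(slabels, spos)]
        optodes += [Optode(l, "detector", tuple(p)) for l, p in zip(dlabels, dpos)]
        montage = Montage(optodes, channels)

        events = []
        for k in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[k]
            label = _read_str(stim["name"])
            rows = np.atleast_2d(np.asarray(stim["data"][()], float))
            for row in rows:
                events.append(Event(label, float(row[0]), float(row[1])))

        subject = ""
        if "metaDataTags" in nirs and "SubjectID" in nirs["metaDataTags"]:
            subject = _read_str(nirs["metaDataTags"]["SubjectID"])

    if not np.all(intensity > 0):
        raise FormatError("file contains non-positive intensity samples")
    return Recording(montage, fs, intensity, events, subject_id=subject)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def events_to_tsv(events: list[Event], path) -> None:
    pd.DataFrame(
        [{"label": e.label, "onset": e.onset, "duration": e.duration} for e in events]
    ).to_csv(path, sep="\t", index=False)


def events_from_tsv(path) -> list[Event]:
    df = pd.read_csv(path, sep="\t")
    return [
        Event(str(r.label), float(r.onset), float(r.duration))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Hyperscanning synchronization
# ---------------------------------------------------------------------------

class SynchronizationError(RuntimeError):
    pass


def synchronize(
    rec_a: Recording,
    rec_b: Recording,
    shared_labels: list[str] | None = None,
    tolerance: float = SYNC_TOLERANCE_S,
) -> HyperscanSession:
    """Align recording B's clock to recording A via shared event labels.

    The offset model is a pure clock translation: the estimated offset is the
    mean over shared labels of (onset_A - onset_B), B's events are shifted by
    it, and the per-label residual discrepancies are reported.  Recordings
    that already carry an applied offset are refused (re-applying a
    translation would silently double it).
    """
    if rec_b.aligned:
        raise SynchronizationError("recording B is already aligned; refusing to re-apply")
    onsets_a = _first_onsets(rec_a)
    onsets_b = _first_onsets(rec_b)
    labels = shared_labels or sorted(set(onsets_a) & set(onsets_b))
    labels = [l for l in labels if l in onsets_a and l in onsets_b]
    if not labels:
        raise SynchronizationError("no shared event labels between recordings")

    deltas = {l: onsets_a[l] - onsets_b[l] for l in labels}
    offset = float(np.mean(list(deltas.values())))
    residuals = {l: d - offset for l, d in deltas.items()}

    aligned_b = Recording(
        rec_b.montage,
        rec_b.fs,
        rec_b.intensity,
        [e for e in rec_b.shifted_events(offset) if 0 <= e.onset < rec_b.duration],
        subject_id=rec_b.subject_id,
        aligned=True,
    )
    max_resid = max((abs(r) for r in residuals.values()), default=0.0)
    if max_resid > tolerance + 1e-12:
        raise SynchronizationError(
            f"shared-label residual {max_resid:.3f}s exceeds tolerance {tolerance}s"
        )
    return HyperscanSession((rec_a, aligned_b), clock_offset=offset, residuals=residuals)


def _first_onsets(rec: Recording) -> dict[str, float]:
    out: dict[str, float] = {}
    for e in rec.events:
        out.setdefault(e.label, e.onset)
    return out
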