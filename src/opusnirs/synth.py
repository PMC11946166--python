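"""Synthetic two-performer concert sessions with known ground truth.

The generator emulates the statistical structure the analysis chain
assumes: piece-locked cortical activations (boxcar convolved with a
canonical double-gamma hemodynamic response) forward-projected through the
diffuse-optical sensitivity matrix into channel optical densities; shared
superficial physiology (Mayer waves ~0.1 Hz, respiration ~0.25 Hz, cardiac
~1.2 Hz, slow drift) added undiluted to the short channels and with a
coupling coefficient to the long channels; white measurement noise; sparse
motion artifacts; and per-performer "hair attenuation" scaling the cortical
contribution (the mechanism behind recordings whose short-channel signal
dominates the cortical channels).

The default seven-concert fixture mirrors the concert study design: a
programme of nine pieces of which exactly five exceed three minutes, 75 Hz
sampling, 762/842 nm, a linearly decreasing rIFG activation across
concerts, and the loss pattern in which concert 4 is missing for the first
performer and concerts 4 and 6 for the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gamma as gamma_fn

from .montage import Montage, default_brite_montage
from .preprocess import default_mbll_params
from .recording import Event, HyperscanSession, Recording, synchronize
from .roi import Scout, default_scouts
from .source_model import (
    CortexMesh,
    SensitivityMatrix,
    build_sensitivity,
    spherical_cap_mesh,
)

DEFAULT_FS = 75.0

#: Concerts in the default series and which are missing per performer.
ALL_CONCERTS = [1, 2, 3, 4, 5, 6, 7]
MISSING_CONCERTS = {"first": {4}, "second": {4, 6}}


@dataclass
class ConcertScript:
    """Programme of one concert: (piece id, start s, duration s) triples."""

    pieces: list[tuple[str, float, float]]
    concert_index: int = 1
    duration_s: float | None = None  # total recording length; default = last end + 30 s

    def __post_init__(self) -> None:
        for pid, start, dur in self.pieces:
            if dur <= 0:
                raise ValueError(f"piece {pid!r}: nonpositive duration")
            if start < 0:
                raise ValueError(f"piece {pid!r}: negative start")

    @property
    def total_duration(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        return max(s + d for _, s, d in self.pieces) + 30.0

    def events(self) -> list[Event]:
        ev = [Event("sync", 1.0)]
        for pid, start, dur in self.pieces:
            ev.append(Event(f"{pid}/start", start))
            ev.append(Event(f"{pid}/end", start + dur))
        return sorted(ev, key=lambda e: e.onset)


@dataclass
class GroundTruth:
    """Generator parameters; defaults are the package's nominal study
    conditions (amplitudes in M*mm on the partial-path concentration scale).
    """

    # cortical activation: peak dHbO per scout, M*mm
    scout_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"PRG": 2.0e-6, "POG": 1.6e-6, "STG": 1.2e-6,
                                 "rIFG": 2.0e-6}
    )
    hbr_ratio: float = -1.0 / 3.0       # dHbR = ratio * dHbO
    onset_lag_s: float = 0.0
    # superficial physiology, M*mm equivalent amplitude of the shared trace
    mayer_amp: float = 0.1e-6           # ~0.1 Hz
    resp_amp: float = 0.05e-6           # ~0.25 Hz
    cardiac_amp: float = 0.2e-6         # ~1.2 Hz (removed by the bandpass)
    drift_amp: float = 0.1e-6           # very slow baseline wander
    long_coupling: float = 1.0          # superficial share reaching long channels
    noise_od_sd: float = 5.0e-6         # white OD noise per sample
    motion_rate_per_min: float = 0.1    # exponential-decay spike artifacts
    motion_amp_od: float = 5.0e-3
    # across-concert modulation of the rIFG amplitude: linear 1 -> end factor
    rifg_trend_end_factor: float = 0.1
    hair_attenuation: dict[str, float] = field(
        default_factory=lambda: {"first": 0.35, "second": 1.0}
    )
    label_jitter_sd: float = 0.0        # manual-labelling error model, off by default

    def rifg_factor(self, concert_index: int) -> float:
        if len(ALL_CONCERTS) == 1:
            return 1.0
        frac = (concert_index - ALL_CONCERTS[0]) / (ALL_CONCERTS[-1] - ALL_CONCERTS[0])
        return 1.0 + frac * (self.rifg_trend_end_factor - 1.0)


def canonical_hrf(t: np.ndarray | float) -> np.ndarray | float:
    """Canonical double-gamma hemodynamic response, unit peak amplitude.

    Peak occurs ~5 s after onset (within the 4-6 s window of the BOLD
    response); the late gamma produces the post-stimulus undershoot.
    h(0) = 0 and h(t<0) = 0.
    """
    t = np.asarray(t, float)
    a1, b1, a2, b2, c = 6.0, 1.0, 16.0, 1.0, 1.0 / 6.0
    pos = (
        t ** (a1 - 1) * np.exp(-t / b1) / (b1**a1 * gamma_fn(a1))
        - c * t ** (a2 - 1) * np.exp(-t / b2) / (b2**a2 * gamma_fn(a2))
    )
    pos = np.where(t > 0, pos, 0.0)
    peak = _hrf_peak_value()
    out = pos / peak
    return float(out) if out.ndim == 0 else out


def _hrf_peak_value() -> float:
    tt = np.linspace(0, 30, 3001)
    a1, b1, a2, b2, c = 6.0, 1.0, 16.0, 1.0, 1.0 / 6.0
    h = (
        tt ** (a1 - 1) * np.exp(-tt / b1) / (b1**a1 * gamma_fn(a1))
        - c * tt ** (a2 - 1) * np.exp(-tt / b2) / (b2**a2 * gamma_fn(a2))
    )
    return float(h.max())


# ---------------------------------------------------------------------------


def _superficial_trace(n: int, fs: float, truth: GroundTruth, rng) -> np.ndarray:
    """Shared superficial 'HbT-like' trace, M*mm."""
    t = np.arange(n) / fs
    trace = np.zeros(n)
    for amp, freq in (
        (truth.mayer_amp, 0.1),
        (truth.resp_amp, 0.25),
        (truth.cardiac_amp, 1.2),
    ):
        trace += amp * np.sin(2 * np.pi * (freq * (1 + 0.05 * rng.standard_normal()))
                              * t + rng.uniform(0, 2 * np.pi))
    # slow positive drift so superficial piece-means are nonzero (what the
    # per-piece SSC subtraction targets)
    trace += truth.drift_amp * (0.5 + 0.5 * np.sin(2 * np.pi * t / (t[-1] + 1)
                                                   + rng.uniform(0, 2 * np.pi)))
    return trace


def _neural_drive(script: ConcertScript, n: int, fs: float, lag: float) -> np.ndarray:
    box = np.zeros(n)
    for _, start, dur in script.pieces:
        i0 = int(np.floor((start + lag) * fs))
        i1 = min(int(np.floor((start + lag + dur) * fs)), n)
        box[i0:i1] = 1.0
    kern = canonical_hrf(np.arange(0, 30.0, 1.0 / fs))
    kern = kern / kern.max()
    drive = np.convolve(box, kern)[:n]
    m = drive.max()
    return drive / m if m > 0 else drive


def generate_recording(
    script: ConcertScript,
    montage: Montage,
    sensitivity: SensitivityMatrix,
    scouts: dict[str, Scout],
    truth: GroundTruth,
    seed: int,
    role: str = "first",
    fs: float = DEFAULT_FS,
) -> tuple[Recording, dict]:
    """One performer's raw-intensity recording plus a ground-truth report."""
    rng = np.random.default_rng(seed)
    n = int(round(script.total_duration * fs))
    mbll = default_mbll_params()
    wls = montage.wavelengths
    mesh = sensitivity.mesh

    # cortical field restricted to scout vertices
    drive = _neural_drive(script, n, fs, truth.onset_lag_s)
    od_long = {wl: np.zeros((len(sensitivity.pairs), n)) for wl in wls}
    hair = truth.hair_attenuation.get(role, 1.0)
    for name, scout in scouts.items():
        amp = truth.scout_amplitudes.get(name, 0.0)
        if name == "rIFG":
            amp *= truth.rifg_factor(script.concert_index)
        if amp == 0.0:
            continue
        ids = np.asarray(scout.vertex_ids)
        hbo_v = amp * drive  # same trace at every scout vertex
        hbr_v = truth.hbr_ratio * hbo_v
        for wl in wls:
            e_hbo, e_hbr = mbll.extinction[wl]
            A_scout = sensitivity.per_wavelength[wl][:, ids]
            od_long[wl] += hair * np.outer(
                A_scout.sum(axis=1), e_hbo * hbo_v + e_hbr * hbr_v
            )

    # superficial physiology: shared trace, undiluted on SSCs
    sup = _superficial_trace(n, fs, truth, rng)
    sup_hbo, sup_hbr = 0.7 * sup, 0.3 * sup
    sup_od = {}
    for wl in wls:
        e_hbo, e_hbr = mbll.extinction[wl]
        sup_od[wl] = e_hbo * sup_hbo + e_hbr * sup_hbr

    # assemble per wavelength-channel OD
    pair_row = {p: i for i, p in enumerate(sensitivity.pairs)}
    od = np.zeros((n, len(montage.channels)))
    for j, ch in enumerate(montage.channels):
        if ch.is_short:
            od[:, j] = sup_od[ch.wavelength]
        else:
            od[:, j] = (
                od_long[ch.wavelength][pair_row[ch.pair]]
                + truth.long_coupling * sup_od[ch.wavelength]
            )

    # motion artifacts: exponential-decay spikes on random channels
    n_motion = rng.poisson(truth.motion_rate_per_min * script.total_duration / 60.0)
    motion_schedule = []
    for _ in range(n_motion):
        t0 = int(rng.uniform(0, n - 1))
        ch = int(rng.integers(0, od.shape[1]))
        span = np.arange(t0, min(t0 + int(2 * fs), n))
        od[span, ch] += truth.motion_amp_od * np.exp(-(span - t0) / (0.3 * fs))
        motion_schedule.append({"sample": t0, "channel": ch})

    od += rng.normal(0.0, truth.noise_od_sd, size=od.shape)

    # invert OD around a per-channel baseline into strictly positive intensity
    baseline = rng.lognormal(mean=0.0, sigma=0.1, size=od.shape[1])
    intensity = baseline[None, :] * np.exp(-od)

    events = script.events()
    if truth.label_jitter_sd > 0:
        events = [
            replace(e, onset=max(0.0, e.onset + rng.normal(0, truth.label_jitter_sd)))
            for e in events
        ]
    rec = Recording(montage, fs, intensity, events, subject_id=f"violinist-{role}")
    report = {
        "seed": seed,
        "role": role,
        "concert_index": script.concert_index,
        "fs": fs,
        "n_samples": n,
        "hair_attenuation": hair,
        "rifg_factor": truth.rifg_factor(script.concert_index),
        "scout_amplitudes": dict(truth.scout_amplitudes),
        "motion_events": motion_schedule,
    }
    return rec, report


def generate_session(
    script: ConcertScript,
    montage: Montage | None = None,
    mesh: CortexMesh | None = None,
    scouts: dict[str, Scout] | None = None,
    truth: GroundTruth | None = None,
    seed: int = 0,
    sensitivity: SensitivityMatrix | None = None,
) -> tuple[HyperscanSession, dict]:
    """Two synchronized performer recordings of one concert + truth report."""
    montage = montage or default_brite_montage()
    if sensitivity is None:
        mesh = mesh or spherical_cap_mesh(montage=montage)
        sensitivity = build_sensitivity(montage, mesh)
    scouts = scouts or default_scouts(sensitivity.mesh)
    truth = truth or GroundTruth()
    rec_a, rep_a = generate_recording(
        script, montage, sensitivity, scouts, truth, seed=seed * 2 + 1, role="first"
    )
    rec_b, rep_b = generate_recording(
        script, montage, sensitivity, scouts, truth, seed=seed * 2 + 2, role="second"
    )
    session = synchronize(rec_a, rec_b)
    return session, {"first": rep_a, "second": rep_b}


# ---------------------------------------------------------------------------
# default fixture
# ---------------------------------------------------------------------------

def default_programme(concert_index: int = 1) -> ConcertScript:
    """Nine-piece programme with exactly five pieces longer than 3 minutes.

    Durations are the generator's declared study conditions (the concert
    programme's piece lengths are not on record); 20 s gaps between pieces,
    60 s lead-in, 30 s tail.
    """
    durations = [90.0, 200.0, 120.0, 240.0, 300.0, 150.0, 360.0, 420.0, 170.0]
    pieces = []
    t = 60.0
    for i, dur in enumerate(durations, start=1):
        pieces.append((f"piece{i:02d}", t, dur))
        t += dur + 20.0
    return ConcertScript(pieces, concert_index=concert_index)


def default_fixture(seed: int = 0, concert: int = 1) -> HyperscanSession:
    """One concert of the default seven-concert fixture."""
    session, _ = generate_session(default_programme(concert), seed=seed + 100 * concert)
    return session


def available_concerts(role: str) -> list[int]:
    return [c for c in ALL_CONCERTS if c not in MISSING_CONCERTS[role]]


def default_concert_series(
    seed: int = 0,
    montage: Montage | None = None,
    sensitivity: SensitivityMatrix | None = None,
    truth: GroundTruth | None = None,
):
    """Iterate (concert_index, role, Recording, report) over the default
    series, honouring the loss pattern (first: concert 4; second: 4 and 6).

    Recordings are generated lazily so callers can reduce each concert to
    statistics without holding the whole series in memory.
    """
    montage = montage or default_brite_montage()
    if sensitivity is None:
        mesh = spherical_cap_mesh(montage=montage)
        sensitivity = build_sensitivity(montage, mesh)
    scouts = default_scouts(sensitivity.mesh)
    truth = truth or GroundTruth()
    for concert in ALL_CONCERTS:
        script = default_programme(concert)
        for k, role in enumerate(("first", "second")):
            if concert in MISSING_CONCERTS[role]:
                continue
            rec, rep = generate_recording(
                script, montage, sensitivity, scouts, truth,
                seed=seed + 100 * concert + k, role=role,
            )
            yield concert, role, rec, rep
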