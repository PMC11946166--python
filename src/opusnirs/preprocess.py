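"""Homer-style hemodynamic preprocessing chain.

Raw detector intensities are converted to optical-density changes
(dOD = -ln(I / mean I)), screened for bad channels, band-pass filtered
with a zero-phase IIR, and inverted through the modified Beer-Lambert law
(MBLL) into chromophore concentration changes dHbO/dHbR/dHbT per
source-detector pair.  Event-aligned epochs are then block-averaged.

Units: with path-length scaling disabled (the default) concentrations are in
molar*mm (the product of concentration change and partial path length, the
quantity CW-fNIRS actually determines); enabling scaling divides by
distance*DPF and yields molar.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .montage import Montage
from .recording import Recording

#: Default band edges, Hz.  The upper edge of 0.5 Hz keeps the slow
#: hemodynamic band and attenuates the cardiac pulsation (~1.2 Hz).
DEFAULT_BAND_HZ = (0.01, 0.5)

#: Differential pathlength factor, dimensionless, both wavelengths.
DEFAULT_DPF = 6.0


@dataclass
class ODSeries:
    """Optical-density changes [n_samples x n_channels], dimensionless."""

    data: np.ndarray
    fs: float
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite OD values")


@dataclass
class ConcSeries:
    """Chromophore concentration changes [n_samples x n_pairs]."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    pairs: list[tuple[str, str]]
    units: str = "molar*mm"

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, float)
        self.hbr = np.asarray(self.hbr, float)

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hbr


@dataclass
class BadChannelMask:
    flagged: set[int]
    criteria: pd.DataFrame  # per channel: cv, variance, reason


@dataclass
class MbllParams:
    """Extinction table, DPF and per-pair distances for the MBLL inversion.

    ``extinction`` maps wavelength (nm) -> (eps_hbo, eps_hbr) in 1/(M*mm).
    """

    extinction: dict[float, tuple[float, float]]
    dpf: dict[float, float] = field(default_factory=dict)
    scale_by_pathlength: bool = False

    def eps_matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        return np.array([self.extinction[wl] for wl in wavelengths], float)

    def dpf_for(self, wl: float) -> float:
        return self.dpf.get(wl, DEFAULT_DPF)

    @property
    def condition_number(self) -> float:
        wls = tuple(sorted(self.extinction))[:2]
        return float(np.linalg.cond(self.eps_matrix(wls)))


def default_extinction() -> dict[float, tuple[float, float]]:
    """Shipped nominal HbO2/HHb extinction values, 1/(M*mm)."""
    ref = importlib.resources.files("opusnirs.data") / "extinction_hb.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    return {
        float(r.wavelength_nm): (float(r.eps_hbo), float(r.eps_hbr))
        for r in df.itertuples(index=False)
    }


def default_mbll_params() -> MbllParams:
    return MbllParams(extinction=default_extinction())


# ---------------------------------------------------------------------------


def intensity_to_od(recording: Recording) -> ODSeries:
    """dOD(t) = -ln(I(t) / mean_t I), per channel (mean reference)."""
    I = recording.intensity
    if not np.all(I > 0):
        bad = np.unique(np.nonzero(~(I > 0))[1])
        raise ValueError(f"non-positive intensity in channels {bad.tolist()}")
    od = -np.log(I / I.mean(axis=0, keepdims=True))
    return ODSeries(od, recording.fs, recording.montage)


def detect_bad_channels(
    recording: Recording,
    cv_threshold: float = 0.15,
    flat_threshold: float = 1e-9,
) -> BadChannelMask:
    """Flag channels by intensity coefficient of variation or flatness.

    The screening criterion is a package default: a channel is bad when the
    CV of its raw intensity exceeds ``cv_threshold`` (saturating dropouts,
    decoupled optodes) or falls below ``flat_threshold`` (a dead, constant
    channel).  Both thresholds are recorded in the criteria table.
    """
    if recording.duration < 10.0:
        raise ValueError("need at least 10 s of data for channel screening")
    I = recording.intensity
    mean = I.mean(axis=0)
    var = I.var(axis=0)
    cv = np.sqrt(var) / mean
    rows = []
    flagged: set[int] = set()
    for i in range(I.shape[1]):
        reason = ""
        if cv[i] < flat_threshold:
            reason = "flat"
        elif cv[i] > cv_threshold:
            reason = "cv"
        if reason:
            flagged.add(i)
        rows.append(
            {"channel": i, "cv": cv[i], "variance": var[i], "reason": reason,
             "cv_threshold": cv_threshold, "flat_threshold": flat_threshold}
        )
    return BadChannelMask(flagged, pd.DataFrame(rows))


def bandpass(
    series: ODSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = 3,
) -> ODSeries:
    """Zero-phase Butterworth band-pass (forward-backward, no phase lag)."""
    nyq = series.fs / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) Hz at fs={series.fs}")
    if low_hz > 0:
        sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=series.fs,
                     output="sos")
    else:
        sos = butter(order, high_hz, btype="lowpass", fs=series.fs, output="sos")
    out = sosfiltfilt(sos, series.data, axis=0)
    return ODSeries(out, series.fs, series.montage)


def od_to_conc(od: ODSeries, params: MbllParams | None = None) -> ConcSeries:
    """MBLL inversion: solve the 2x2 spectral system per pair and sample.

    dOD(lambda) = [eps_HbO(lambda)*dHbO + eps_HbR(lambda)*dHbR] * L(lambda)
    where L = distance*DPF when path-length scaling is enabled and L = 1
    otherwise (molar*mm convention).
    """
    params = params or default_mbll_params()
    m = od.montage
    wls = m.wavelengths
    if len(wls) != 2:
        raise ValueError(f"MBLL needs exactly 2 wavelengths, montage has {wls}")
    E = params.eps_matrix(wls)  # rows: wavelength, cols: (HbO, HbR)
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("singular extinction matrix")
    Einv = np.linalg.inv(E)

    col = {(ch.pair, ch.wavelength): j for j, ch in enumerate(m.channels)}
    pairs = m.pairs
    n_t = od.data.shape[0]
    hbo = np.empty((n_t, len(pairs)))
    hbr = np.empty((n_t, len(pairs)))
    for p_idx, pair in enumerate(pairs):
        rhs = np.empty((2, n_t))
        for w_idx, wl in enumerate(wls):
            if (pair, wl) not in col:
                raise ValueError(f"pair {pair} missing wavelength {wl}")
            y = od.data[:, col[(pair, wl)]]
            if params.scale_by_pathlength:
                d = m.pair_distance(pair)
                if d <= 0:
                    raise ValueError(f"pair {pair}: zero source-detector distance")
                y = y / (d * params.dpf_for(wl))
            rhs[w_idx] = y
        sol = Einv @ rhs
        hbo[:, p_idx] = sol[0]
        hbr[:, p_idx] = sol[1]
    units = "molar" if params.scale_by_pathlength else "molar*mm"
    return ConcSeries(hbo, hbr, od.fs, pairs, units=units)


def block_average(
    conc: ConcSeries,
    epochs: list[tuple[float, float]],
    baseline: tuple[float, float] | None = None,
) -> dict[str, np.ndarray]:
    """Pointwise mean across equal-length epochs, per pair and chromophore.

    ``epochs`` are [start, end) windows in seconds; ``baseline`` is an
    optional window *relative to each epoch start* whose per-epoch mean is
    subtracted before averaging.  Returns mean and across-epoch SD arrays of
    shape [epoch_samples x n_pairs] per chromophore.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    fs = conc.fs
    n_total = conc.hbo.shape[0]
    lengths = {int(np.floor(e * fs)) - int(np.floor(s * fs)) for s, e in epochs}
    if len(lengths) != 1:
        raise ValueError(f"epochs must have equal sample lengths, got {sorted(lengths)}")
    n_len = lengths.pop()
    out: dict[str, np.ndarray] = {}
    for name, mat in (("hbo", conc.hbo), ("hbr", conc.hbr), ("hbt", conc.hbt)):
        stack = []
        for s, e in epochs:
            i0, i1 = int(np.floor(s * fs)), int(np.floor(e * fs))
            if i0 < 0 or i1 > n_total:
                raise ValueError(f"epoch [{s}, {e}) outside recording")
            seg = mat[i0:i1].copy()
            if baseline is not None:
                b0 = i0 + int(np.floor(baseline[0] * fs))
                b1 = i0 + int(np.floor(baseline[1] * fs))
                if b0 < 0 or b1 > n_total or b1 <= b0:
                    raise ValueError(f"baseline window invalid for epoch [{s}, {e})")
                seg -= mat[b0:b1].mean(axis=0, keepdims=True)
            stack.append(seg)
        arr = np.stack(stack)  # [n_epochs x n_len x n_pairs]
        out[name] = arr.mean(axis=0)
        out[f"{name}_sd"] = arr.std(axis=0, ddof=1) if len(stack) > 1 else np.zeros(
            (n_len, arr.shape[2])
        )
    out["n_epochs"] = np.array(len(epochs))
    return out
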