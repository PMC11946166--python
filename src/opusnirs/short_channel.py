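"""Averaged short-separation-channel (SSC) subtraction with negative zeroing.

Short channels sample scalp/superficial hemodynamics only.  The correction
implemented here works on per-piece summary means (time-mean of HbT per
pair for each musical piece): the mean of the short-channel values is
subtracted from every long channel, and long channels that go negative are
clamped to zero and flagged low-trust.  A sample-wise variant of the same
subtraction is provided as an explicitly labelled extension.

The companion diagnostic reports how large the superficial (SSC) signal is
relative to the cortical channels and what fraction of channels the zeroing
rule silenced — a direct indicator of recordings dominated by superficial
physiology or optode-coupling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PieceChannelMeans:
    """Per-piece time-mean signal value per source-detector pair."""

    piece_id: str
    values: dict[tuple[str, str], float]  # pair -> molar*mm
    ssc_ids: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.ssc_ids:
            raise ValueError(f"piece {self.piece_id!r}: no short channels given")
        missing = [p for p in self.ssc_ids if p not in self.values]
        if missing:
            raise ValueError(f"piece {self.piece_id!r}: SSC pairs {missing} not in values")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"piece {self.piece_id!r}: non-finite channel means")


@dataclass
class SscCorrection:
    piece_id: str
    ssc_mean: float
    corrected: dict[tuple[str, str], float]  # long pairs only, clamped at 0
    zeroed: set[tuple[str, str]] = field(default_factory=set)  # low-trust flags

    def to_frame(self, raw: PieceChannelMeans) -> pd.DataFrame:
        rows = []
        for pair, val in self.corrected.items():
            rows.append(
                {
                    "piece": self.piece_id,
                    "source": pair[0],
                    "detector": pair[1],
                    "raw_mean": raw.values[pair],
                    "ssc_mean": self.ssc_mean,
                    "corrected": val,
                    "zeroed": pair in self.zeroed,
                }
            )
        return pd.DataFrame(rows)


def ssc_subtract(means: PieceChannelMeans) -> SscCorrection:
    """corrected[i] = max(0, long[i] - mean(SSC)); zeroed pairs flagged."""
    ssc_mean = float(np.mean([means.values[p] for p in means.ssc_ids]))
    corrected: dict[tuple[str, str], float] = {}
    zeroed: set[tuple[str, str]] = set()
    for pair, val in means.values.items():
        if pair in means.ssc_ids:
            continue
        diff = val - ssc_mean
        if diff < 0:
            corrected[pair] = 0.0
            zeroed.add(pair)
        else:
            corrected[pair] = float(diff)
    return SscCorrection(means.piece_id, ssc_mean, corrected, zeroed)


def ssc_subtract_samplewise(
    long_data: np.ndarray, ssc_data: np.ndarray, clamp: bool = True
) -> np.ndarray:
    """Extension (not the per-piece summary correction): subtract the
    instantaneous SSC mean trace from every long-channel trace.

    ``long_data`` is [n_samples x n_long], ``ssc_data`` [n_samples x n_ssc].
    """
    out = long_data - ssc_data.mean(axis=1, keepdims=True)
    if clamp:
        out = np.clip(out, 0.0, None)
    return out


def ssc_dominance(pieces: list[PieceChannelMeans]) -> pd.DataFrame:
    """SSC-vs-long scale report: per piece and overall.

    Columns: ``ssc_long_ratio`` = mean(SSC) / mean(long) (NaN when the long
    mean is 0) and ``zeroed_fraction`` = share of long channels the negative
    zeroing silenced.  The final row (piece == "overall") pools all pieces.
    """
    if not pieces:
        raise ValueError("need at least one piece")
    rows = []
    all_ssc: list[float] = []
    all_long: list[float] = []
    total_zeroed = 0
    total_long = 0
    for pm in pieces:
        corr = ssc_subtract(pm)
        ssc_vals = [pm.values[p] for p in pm.ssc_ids]
        long_vals = [v for p, v in pm.values.items() if p not in pm.ssc_ids]
        long_mean = float(np.mean(long_vals))
        ratio = float(np.mean(ssc_vals)) / long_mean if long_mean != 0 else np.nan
        rows.append(
            {
                "piece": pm.piece_id,
                "ssc_mean": float(np.mean(ssc_vals)),
                "long_mean": long_mean,
                "ssc_long_ratio": ratio,
                "zeroed_fraction": len(corr.zeroed) / len(long_vals),
            }
        )
        all_ssc.extend(ssc_vals)
        all_long.extend(long_vals)
        total_zeroed += len(corr.zeroed)
        total_long += len(long_vals)
    overall_long = float(np.mean(all_long))
    rows.append(
        {
            "piece": "overall",
            "ssc_mean": float(np.mean(all_ssc)),
            "long_mean": overall_long,
            "ssc_long_ratio": float(np.mean(all_ssc)) / overall_long
            if overall_long != 0
            else np.nan,
            "zeroed_fraction": total_zeroed / total_long,
        }
    )
    return pd.DataFrame(rows)
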