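"""Event-driven segmentation: pieces and the three analysis protocols.

Pieces are delimited by "<id>/start" / "<id>/end" event pairs placed during
the recording.  Three windowing protocols are derived from each piece:

* ``whole_piece`` — the full piece, no baseline (a pure averaging protocol
  with no external reference);
* ``initial``     — a 5 s pre-piece baseline and the first 20 s of the piece;
* ``mid``         — for pieces longer than 3 minutes only: a 20 s pre-piece
  baseline, the first 3 minutes modelled, and the 60-120 s span extracted.

All time-to-sample conversion is floor(t*fs) with half-open [start, end)
windows, so a 20 s window at 75 Hz is exactly 1500 samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .recording import Event

#: Mid-protocol piece duration filter, s (strictly greater-than).
MID_MIN_DURATION_S = 180.0


@dataclass(frozen=True)
class Piece:
    id: str
    start: float  # s
    end: float    # s

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"piece {self.id!r}: end {self.end} <= start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ProtocolWindows:
    protocol: str                           # whole_piece | initial | mid
    baseline: tuple[float, float] | None    # [s, s) or None
    analysis: tuple[float, float]           # [s, s)
    model_span: tuple[float, float] | None = None  # mid protocol only

    def __post_init__(self) -> None:
        if self.baseline is not None and self.baseline[1] > self.analysis[0]:
            raise ValueError("baseline must precede the analysis window")


class PieceSkipped(ValueError):
    """A piece does not satisfy a protocol's preconditions."""


def time_to_index(t: float, fs: float) -> int:
    """Sample index of time t: floor(t*fs). Intervals map half-open."""
    if t < 0:
        raise ValueError(f"negative time {t}")
    return int(math.floor(t * fs))


def window_to_indices(window: tuple[float, float], fs: float) -> tuple[int, int]:
    return time_to_index(window[0], fs), time_to_index(window[1], fs)


def pieces_from_events(events: list[Event]) -> list[Piece]:
    """Match "<id>/start" and "<id>/end" labels into sorted pieces.

    Unmatched labels are reported with a warning and excluded; an end
    preceding its start is a labelling error.
    """
    starts: dict[str, float] = {}
    ends: dict[str, float] = {}
    for e in events:
        if e.label.endswith("/start"):
            starts.setdefault(e.label[: -len("/start")], e.onset)
        elif e.label.endswith("/end"):
            ends.setdefault(e.label[: -len("/end")], e.onset)
    pieces = []
    unmatched = sorted((set(starts) ^ set(ends)))
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} unmatched piece label(s) excluded: {unmatched}",
            stacklevel=2,
        )
    for pid in set(starts) & set(ends):
        if ends[pid] <= starts[pid]:
            raise ValueError(f"piece {pid!r}: end marker precedes start marker")
        pieces.append(Piece(pid, starts[pid], ends[pid]))
    return sorted(pieces, key=lambda p: p.start)


def windows_whole_piece(piece: Piece) -> ProtocolWindows:
    """Whole-piece averaging: no baseline, analysis spans the piece."""
    return ProtocolWindows("whole_piece", None, (piece.start, piece.end))


def windows_initial(piece: Piece) -> ProtocolWindows:
    """Piece-onset response: 5 s baseline before the piece, first 20 s analysed."""
    if piece.start < 5.0:
        raise PieceSkipped(f"piece {piece.id!r}: needs 5 s pre-roll, starts at {piece.start}")
    if piece.duration < 20.0:
        raise PieceSkipped(f"piece {piece.id!r}: duration {piece.duration} s < 20 s")
    return ProtocolWindows(
        "initial",
        baseline=(piece.start - 5.0, piece.start),
        analysis=(piece.start, piece.start + 20.0),
    )


def windows_mid(piece: Piece) -> ProtocolWindows:
    """Mid-piece development: pieces > 3 min, 20 s baseline, 60-120 s extracted."""
    if piece.duration <= MID_MIN_DURATION_S:
        raise PieceSkipped(
            f"piece {piece.id!r}: duration {piece.duration} s not > {MID_MIN_DURATION_S} s"
        )
    if piece.start < 20.0:
        raise PieceSkipped(f"piece {piece.id!r}: needs 20 s pre-roll")
    return ProtocolWindows(
        "mid",
        baseline=(piece.start - 20.0, piece.start),
        analysis=(piece.start + 60.0, piece.start + 120.0),
        model_span=(piece.start, piece.start + 180.0),
    )


def select_mid_pieces(pieces: list[Piece]) -> list[Piece]:
    """Pieces eligible for the mid protocol (duration strictly > 3 minutes)."""
    return [p for p in pieces if p.duration > MID_MIN_DURATION_S]


def protocol_windows(piece: Piece, protocol: str) -> ProtocolWindows:
    dispatch = {
        "whole_piece": windows_whole_piece,
        "initial": windows_initial,
        "mid": windows_mid,
    }
    try:
        fn = dispatch[protocol]
    except KeyError:
        raise ValueError(f"unknown protocol {protocol!r}") from None
    return fn(piece)
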