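"""Optode/channel geometry for a wearable two-wavelength CW-fNIRS headcap.

The default layout mirrors an 18-pair right-hemisphere montage arranged as
four optode groups (4 + 4 + 5 + 5 source-detector pairs) of which two pairs
are short-separation channels (SSCs).  With two wavelengths per pair this
gives 36 wavelength-channels.  Published coordinates for the concert caps do
not exist (positions were registered manually on the acquisition software's
head model), so the default montage uses nominal, idealized coordinates on a
sphere-approximated right hemisphere; it is geometry for bookkeeping and
forward modelling, not subject anatomy.

Coordinate convention: right-handed RAS, millimetres, origin at mid-head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: Default laser wavelengths, nm.  The shorter wavelength sits on the
#: deoxy-dominant side of the ~800 nm isosbestic point, the longer on the
#: oxy-dominant side.
DEFAULT_WAVELENGTHS = (762.0, 842.0)

#: Nominal scalp sphere radius, mm.
HEAD_RADIUS_MM = 80.0

#: Nominal source-detector separations, mm.
LONG_SEPARATION_MM = 30.0
SHORT_SEPARATION_MM = 8.0


@dataclass(frozen=True)
class Optode:
    """A single source (Tx) or detector (Rx) position on the scalp."""

    id: str
    kind: str  # "source" | "detector"
    position: tuple[float, float, float]  # mm, RAS

    def __post_init__(self) -> None:
        if self.kind not in ("source", "detector"):
            raise ValueError(f"optode kind must be source/detector, got {self.kind!r}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"optode {self.id}: non-finite position {self.position}")


@dataclass(frozen=True)
class ChannelDef:
    """One wavelength-channel: a source-detector pair at one wavelength."""

    source_id: str
    detector_id: str
    wavelength: float  # nm
    is_short: bool = False

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source_id, self.detector_id)


@dataclass
class Montage:
    """Optode set plus channel table plus named channel groupings."""

    optodes: list[Optode]
    channels: list[ChannelDef]
    groups: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [o.id for o in self.optodes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate optode ids in montage")
        self._by_id = {o.id: o for o in self.optodes}
        for ch in self.channels:
            src = self._optode(ch.source_id)
            det = self._optode(ch.detector_id)
            if src.kind != "source":
                raise ValueError(f"{ch.source_id} is not a source")
            if det.kind != "detector":
                raise ValueError(f"{ch.detector_id} is not a detector")
        # every pair must carry an identical wavelength set
        wl_by_pair: dict[tuple[str, str], set[float]] = {}
        for ch in self.channels:
            wl_by_pair.setdefault(ch.pair, set())
            if ch.wavelength in wl_by_pair[ch.pair]:
                raise ValueError(f"pair {ch.pair} repeated at {ch.wavelength} nm")
            wl_by_pair[ch.pair].add(ch.wavelength)
        wl_sets = {frozenset(s) for s in wl_by_pair.values()}
        if len(wl_sets) > 1:
            raise ValueError("wavelength set differs across pairs")

    def _optode(self, oid: str) -> Optode:
        try:
            return self._by_id[oid]
        except KeyError:
            raise KeyError(f"unresolved optode id {oid!r}") from None

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted({ch.wavelength for ch in self.channels}))

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """Unique source-detector pairs, in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for ch in self.channels:
            seen.setdefault(ch.pair, None)
        return list(seen)

    @property
    def short_pairs(self) -> list[tuple[str, str]]:
        return [p for p in self.pairs if self.pair_is_short(p)]

    @property
    def long_pairs(self) -> list[tuple[str, str]]:
        return [p for p in self.pairs if not self.pair_is_short(p)]

    def pair_is_short(self, pair: tuple[str, str]) -> bool:
        for ch in self.channels:
            if ch.pair == pair:
                return ch.is_short
        raise KeyError(f"unknown pair {pair}")

    def pair_positions(self, pair: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
        s = np.asarray(self._optode(pair[0]).position, float)
        d = np.asarray(self._optode(pair[1]).position, float)
        return s, d

    def pair_distance(self, pair: tuple[str, str]) -> float:
        s, d = self.pair_positions(pair)
        return float(np.linalg.norm(s - d))

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "optodes": [
                {"id": o.id, "kind": o.kind, "position": list(map(float, o.position))}
                for o in self.optodes
            ],
            "channels": [
                {
                    "source": c.source_id,
                    "detector": c.detector_id,
                    "wavelength": float(c.wavelength),
                    "short": bool(c.is_short),
                }
                for c in self.channels
            ],
            "groups": {k: [list(p) for p in v] for k, v in self.groups.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Montage":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        optodes = [
            Optode(o["id"], o["kind"], tuple(o["position"])) for o in doc["optodes"]
        ]
        channels = [
            ChannelDef(c["source"], c["detector"], c["wavelength"], c.get("short", False))
            for c in doc["channels"]
        ]
        groups = {
            k: [tuple(p) for p in v] for k, v in doc.get("groups", {}).items()
        }
        return cls(optodes, channels, groups)


def channel_distances(montage: Montage) -> dict[tuple[str, str, float], float]:
    """Euclidean source-detector distance (mm) per wavelength-channel.

    Both wavelengths of a pair share the same geometric distance.
    """
    return {
        (ch.source_id, ch.detector_id, ch.wavelength): montage.pair_distance(ch.pair)
        for ch in montage.channels
    }


def _sph(theta_deg: float, phi_deg: float, r: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Point on the head sphere. theta: polar from vertex; phi: azimuth from +x (right ear)."""
    th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    return r * np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _project(p: np.ndarray, r: float = HEAD_RADIUS_MM) -> np.ndarray:
    return p * (r / np.linalg.norm(p))


def default_brite_montage() -> Montage:
    """Nominal 18-pair right-hemisphere montage (16 long + 2 short pairs).

    Four groups — two 4-pair strips over the sensorimotor strip (near C4),
    one 5-pair strip over the superior temporal region (near T8) containing
    one SSC, and one 5-pair strip over the inferior frontal region (near F8)
    containing the second SSC.  Returns 36 wavelength-channels.
    """
    # group centers: polar angle from vertex / azimuth from right ear, degrees
    group_specs = [
        ("Sensorimotor-1", 30.0, -15.0, 4, 0),   # near C4, slightly posterior
        ("Sensorimotor-2", 42.0, -5.0, 4, 0),    # below it
        ("Temporal", 72.0, 5.0, 5, 1),           # STG scalp projection near T8
        ("Frontal", 62.0, 50.0, 5, 1),           # rIFG scalp projection near F8
    ]
    optodes: list[Optode] = []
    channels: list[ChannelDef] = []
    groups: dict[str, list[tuple[str, str]]] = {"SSC": []}
    tx = rx = 0
    for name, theta, phi, n_pairs, n_short in group_specs:
        groups[name] = []
        center = _sph(theta, phi)
        # local tangent frame at the group center
        n = center / np.linalg.norm(center)
        t1 = np.cross(n, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(n, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        for i in range(n_pairs):
            is_short = i >= n_pairs - n_short
            sep = SHORT_SEPARATION_MM if is_short else LONG_SEPARATION_MM
            # lay pairs out in a strip along t1, staggered along t2; the
            # source/detector sit at exact chord separation on the sphere
            row = (i - (n_pairs - 1) / 2.0) * 22.0
            mid = _project(center + row * t1 + (6.0 if i % 2 else -6.0) * t2)
            n_mid = mid / np.linalg.norm(mid)
            u = t2 - np.dot(t2, n_mid) * n_mid
            u /= np.linalg.norm(u)
            theta = np.arcsin(sep / (2.0 * HEAD_RADIUS_MM))
            src = HEAD_RADIUS_MM * (n_mid * np.cos(theta) - u * np.sin(theta))
            det = HEAD_RADIUS_MM * (n_mid * np.cos(theta) + u * np.sin(theta))
            tx += 1
            rx += 1
            sid, did = f"Tx{tx}", f"Rx{rx}"
            optodes.append(Optode(sid, "source", tuple(src)))
            optodes.append(Optode(did, "detector", tuple(det)))
            for wl in DEFAULT_WAVELENGTHS:
                channels.append(ChannelDef(sid, did, wl, is_short))
            groups[name].append((sid, did))
            if is_short:
                groups["SSC"].append((sid, did))
    return Montage(optodes, channels, groups)
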