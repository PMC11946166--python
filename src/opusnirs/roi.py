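"""Functional dissection: scout (ROI) averaging and confidence intervals.

A *scout* is a named set of cortical mesh vertices (precentral gyrus PRG,
postcentral gyrus POG, superior temporal gyrus STG, combined right inferior
frontal gyrus rIFG).  Source-estimate matrices are averaged over the scout
vertices and the analysis window; per-concert summaries carry the
symmetric Student-t confidence interval

    CI = mean(X) +/- T * SEM,   SEM = sd(X)/sqrt(n),  T = t_(1-alpha/2, n-1)

(the one-sided literal form mean(X) + T*SEM is available via a flag).
Across the concert sequence, scout summaries are assembled into trend
tables; concerts with lost recordings appear as explicit gap rows — missing
data stays missing, never interpolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import window_to_indices
from .source_model import CortexMesh, SourceEstimate

#: Scout vertex counts of the reference 10,000-vertex dissection.
REFERENCE_SCOUT_SIZES = {"PRG": 107, "POG": 97, "STG": 92, "rIFG": 144}


@dataclass(frozen=True)
class Scout:
    name: str
    vertex_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.vertex_ids:
            raise ValueError(f"scout {self.name!r} is empty")

    def validate(self, mesh: CortexMesh) -> None:
        ids = np.asarray(self.vertex_ids)
        if ids.min() < 0 or ids.max() >= mesh.n_vertices:
            raise ValueError(f"scout {self.name!r}: vertex id outside mesh")


@dataclass
class RoiStat:
    scout: str
    piece_id: str
    concert_index: int
    chromophore: str  # HbO | HbR | HbT
    mean: float
    sem: float
    ci_low: float
    ci_high: float
    n: int
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            if not (self.ci_low <= self.mean <= self.ci_high):
                raise ValueError("CI must bracket the mean")
            if self.sem < 0:
                raise ValueError("SEM must be nonnegative")


@dataclass
class TrendTable:
    rows: list[RoiStat] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"meta": self.meta, "rows": [vars(r) for r in self.rows]}, fh,
                      indent=1, default=float)


# ---------------------------------------------------------------------------


def scout_average(
    est: SourceEstimate,
    scout: Scout,
    window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Mean over (scout vertices x window samples) per chromophore.

    Equivalently: the matrix is summed over the scout's vertices and window
    samples and multiplied by the reciprocal of (n_vertices * n_samples).
    """
    scout.validate(est.mesh)
    ids = np.asarray(scout.vertex_ids)
    if window is None:
        i0, i1 = 0, est.hbo.shape[1]
    else:
        i0, i1 = window_to_indices(window, est.fs)
    if i0 < 0 or i1 > est.hbo.shape[1] or i1 <= i0:
        raise ValueError(f"window samples [{i0}, {i1}) outside estimate span")
    return {
        "HbO": float(est.hbo[ids, i0:i1].mean()),
        "HbR": float(est.hbr[ids, i0:i1].mean()),
        "HbT": float(est.hbt[ids, i0:i1].mean()),
    }


def ci_eq1(
    x: np.ndarray, alpha: float = 0.05, two_sided: bool = True
) -> tuple[float, float, float, float]:
    """Student-t confidence interval of the sample mean.

    Returns (mean, sem, ci_low, ci_high) with sem = sd(x)/sqrt(n) (n-1
    denominator) and T the t quantile at 1-alpha/2 with n-1 degrees of
    freedom.  With ``two_sided=False`` the literal one-sided upper form
    mean + T*SEM is returned (ci_low = mean).
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 2:
        raise ValueError(f"need n >= 2 samples for a confidence interval, got {n}")
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(n))
    t = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    if two_sided:
        return mean, sem, mean - t * sem, mean + t * sem
    return mean, sem, mean, mean + t * sem


def trend_table(
    concert_results: dict[int, dict[str, list[float]]],
    scout_name: str,
    all_concerts: list[int],
    protocol: str = "mid",
    alpha: float = 0.05,
) -> TrendTable:
    """Assemble per-concert scout statistics into a trend table.

    ``concert_results`` maps concert index -> chromophore -> list of
    per-piece scout-averaged summaries (the CI sample X).  Concerts in
    ``all_concerts`` absent from the results become gap rows with NaN
    statistics and ``missing=True``; values are never interpolated.
    """
    rows: list[RoiStat] = []
    for ci_idx in sorted(all_concerts):
        if ci_idx not in concert_results:
            for chrom in ("HbO", "HbR", "HbT"):
                rows.append(
                    RoiStat(scout_name, "", ci_idx, chrom,
                            np.nan, np.nan, np.nan, np.nan, 0, missing=True)
                )
            continue
        for chrom, samples in concert_results[ci_idx].items():
            x = np.asarray(samples, float)
            if x.size >= 2:
                mean, sem, lo, hi = ci_eq1(x, alpha=alpha)
            else:
                mean, sem = float(x.mean()), 0.0
                lo = hi = mean
            rows.append(
                RoiStat(scout_name, "all-pieces", ci_idx, chrom,
                        mean, sem, lo, hi, int(x.size))
            )
    return TrendTable(rows, meta={"scout": scout_name, "protocol": protocol,
                                  "alpha": alpha, "sample": "per-piece scout means"})


def trend_slope(table: TrendTable, chromophore: str = "HbT") -> float:
    """Least-squares slope of the scout mean across concert indices
    (gap rows excluded)."""
    pts = [(r.concert_index, r.mean) for r in table.rows
           if r.chromophore == chromophore and not r.missing]
    if len(pts) < 2:
        raise ValueError("need >= 2 concerts for a trend")
    x, y = np.array(pts).T
    return float(np.polyfit(x, y, 1)[0])


# ---------------------------------------------------------------------------
# scout construction and I/O
# ---------------------------------------------------------------------------

def geodesic_scout(
    mesh: CortexMesh, name: str, center_direction: np.ndarray, n_vertices: int
) -> Scout:
    """The n mesh vertices nearest (by Euclidean distance) to the point of
    the cortex surface in the given direction — a contiguous patch sized to
    a reference atlas count."""
    d = center_direction / np.linalg.norm(center_direction)
    radius = np.linalg.norm(mesh.vertices, axis=1).mean()
    target = d * radius
    dist = np.linalg.norm(mesh.vertices - target[None, :], axis=1)
    ids = np.argsort(dist, kind="stable")[:n_vertices]
    return Scout(name, tuple(int(i) for i in sorted(ids)))


def default_scouts(mesh: CortexMesh) -> dict[str, Scout]:
    """Template-mesh stand-ins for the four dissection ROIs, sized to the
    reference vertex counts (PRG 107, POG 97, STG 92, rIFG 144)."""
    directions = {
        "PRG": np.array([0.45, 0.55, 0.72]),
        "POG": np.array([0.35, 0.70, 0.63]),
        "STG": np.array([0.85, 0.45, 0.27]),
        "rIFG": np.array([0.75, 0.25, 0.61]),
    }
    return {
        name: geodesic_scout(mesh, name, vec, REFERENCE_SCOUT_SIZES[name])
        for name, vec in directions.items()
    }


def scouts_to_tsv(scouts: dict[str, Scout], path) -> None:
    rows = [
        {"scout_name": s.name, "vertex_id": v}
        for s in scouts.values()
        for v in s.vertex_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def scouts_from_tsv(path) -> dict[str, Scout]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for name, grp in df.groupby("scout_name"):
        out[str(name)] = Scout(str(name), tuple(int(v) for v in grp.vertex_id))
    return out


def scouts_from_json(path) -> dict[str, Scout]:
    with open(path) as fh:
        doc = json.load(fh)
    return {k: Scout(k, tuple(int(i) for i in v)) for k, v in doc.items()}
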