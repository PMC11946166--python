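"""Diffuse-optical forward and inverse modelling on a template cortex.

The forward model assigns each long channel a sensitivity profile over a
cortical mesh using the adjoint (Rytov) formulation: the sensitivity of
channel (s, d) to an absorption change at vertex v is

    A[ch, v] = Phi(s -> v) * Phi(v -> d) / Phi(s -> d),

with photon fluence Phi given by the extrapolated-boundary Green's function
of the diffusion approximation in a homogeneous semi-infinite medium.  A
template spherical-cap cortex of exactly 10,000 vertices stands in for an
anatomical surface; fluences are tabulated per vertex within a maximum
range, and vertices outside that range borrow the fluence of the physically
closest tabulated vertex (ties resolved to the lowest vertex index).

The inverse model is a depth-weighted Tikhonov minimum-norm estimate per
wavelength — the sensor data are compatible with infinitely many source
patterns, so the estimate is the minimum-weighted-norm one — followed by a
per-vertex 2x2 spectral (MBLL) inversion to oxy-/deoxy-hemoglobin images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .montage import Montage
from .preprocess import MbllParams, ODSeries, default_mbll_params

#: Template mesh resolution (vertex count).
DEFAULT_N_VERTICES = 10_000

#: Scalp and cortex sphere radii of the template geometry, mm.
SCALP_RADIUS_MM = 80.0
CORTEX_RADIUS_MM = 67.0

#: Fluence tabulation range, mm; beyond it the nearest-vertex rule applies.
FLUENCE_RANGE_MM = 100.0


@dataclass
class CortexMesh:
    vertices: np.ndarray  # [n_v x 3] mm
    faces: np.ndarray     # [n_f x 3] vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face indexes out-of-range vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def save_off(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{len(self.vertices)} {len(self.faces)} 0\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")

    @classmethod
    def load_off(cls, path) -> "CortexMesh":
        with open(path) as fh:
            tokens = fh.read().split()
        if tokens[0] != "OFF":
            raise ValueError("not an OFF file")
        n_v, n_f = int(tokens[1]), int(tokens[2])
        k = 4
        verts = np.array(tokens[k : k + 3 * n_v], float).reshape(n_v, 3)
        k += 3 * n_v
        faces = []
        for _ in range(n_f):
            cnt = int(tokens[k])
            faces.append([int(x) for x in tokens[k + 1 : k + 1 + cnt]])
            k += 1 + cnt
        return cls(verts, np.array(faces, int))


@dataclass
class OpticalProps:
    """Homogeneous tissue optical properties per wavelength.

    ``mu_a``: absorption coefficient, 1/mm; ``mu_s_prime``: reduced
    scattering coefficient, 1/mm.  Defaults are generic adult-head values.
    """

    mu_a: dict[float, float] = field(default_factory=lambda: {762.0: 0.019, 842.0: 0.021})
    mu_s_prime: dict[float, float] = field(
        default_factory=lambda: {762.0: 1.1, 842.0: 1.0}
    )

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.mu_a.values()) or any(
            v <= 0 for v in self.mu_s_prime.values()
        ):
            raise ValueError("optical coefficients must be positive")

    def at(self, wavelength: float) -> tuple[float, float]:
        try:
            return self.mu_a[wavelength], self.mu_s_prime[wavelength]
        except KeyError:
            raise KeyError(f"no optical properties at {wavelength} nm") from None


@dataclass
class SensitivityMatrix:
    per_wavelength: dict[float, np.ndarray]  # wl -> [n_long x n_v]
    pairs: list[tuple[str, str]]             # long pairs, row order
    mesh: CortexMesh
    zero_rows: dict[float, list[int]] = field(default_factory=dict)


@dataclass
class SourceEstimate:
    hbo: np.ndarray  # [n_v x n_t]
    hbr: np.ndarray
    mesh: CortexMesh
    fs: float
    regularization: dict = field(default_factory=dict)

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hbr


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def spherical_cap_mesh(
    n_vertices: int = DEFAULT_N_VERTICES,
    montage: Montage | None = None,
    radius: float = CORTEX_RADIUS_MM,
    cap_half_angle_deg: float = 65.0,
) -> CortexMesh:
    """Template cortex: a Fibonacci-lattice spherical cap beneath the montage.

    The cap axis points at the montage centroid (or +x, the right ear, when
    no montage is given); triangulation is a Delaunay mesh of the azimuthal
    projection.  Vertex count is exact.
    """
    if montage is not None:
        center = np.mean([o.position for o in montage.optodes], axis=0)
        axis = center / np.linalg.norm(center)
    else:
        axis = np.array([1.0, 0.0, 0.0])
    alpha = np.deg2rad(cap_half_angle_deg)
    i = np.arange(n_vertices)
    # uniform in cos(theta) over the cap, golden-angle azimuth
    z = 1.0 - (1.0 - np.cos(alpha)) * (i + 0.5) / n_vertices
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    sin_t = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), z])
    # rotate +z cap onto the montage axis
    rot = _rotation_from_z(axis)
    verts = radius * (pts @ rot.T)
    # planar Delaunay of the cap coordinates (gnomonic-style projection)
    uv = np.column_stack([pts[:, 0] / (1.0 + pts[:, 2]), pts[:, 1] / (1.0 + pts[:, 2])])
    tri = Delaunay(uv)
    return CortexMesh(verts, tri.simplices)


def _rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying +z onto the (unit) axis."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


# ---------------------------------------------------------------------------
# fluence
# ---------------------------------------------------------------------------

def semi_infinite_fluence(
    r: float | np.ndarray, props: OpticalProps, wavelength: float
) -> float | np.ndarray:
    """Extrapolated-boundary diffusion fluence at distance r (mm) from an
    optode on the surface of a homogeneous semi-infinite medium.

    The source is modelled as an isotropic point at depth z0 = 1/mu_s' with
    a negative image source mirrored across the extrapolated boundary at
    height z_b; the fluence is the difference of the two diffusion Green's
    functions.  Strictly decreasing in r, relative units.
    """
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    mu_a, mu_sp = props.at(wavelength)
    D = 1.0 / (3.0 * (mu_a + mu_sp))
    mu_eff = np.sqrt(mu_a / D)
    z0 = 1.0 / mu_sp
    # extrapolated boundary (refractive-index mismatch folded into Reff~0.493)
    reff = 0.493
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    r1 = np.sqrt(r**2 + z0**2)
    r2 = np.sqrt(r**2 + (z0 + 2.0 * zb) ** 2)
    phi = (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4.0 * np.pi * D)
    return float(phi) if phi.ndim == 0 else phi


def _optode_fluence_at_vertices(
    pos: np.ndarray,
    mesh: CortexMesh,
    props: OpticalProps,
    wavelength: float,
    max_range: float = FLUENCE_RANGE_MM,
) -> np.ndarray:
    """Tabulated per-vertex fluence from one optode, with the nearest-vertex
    substitution for vertices beyond the tabulation range (ties -> lowest
    vertex index)."""
    d = np.linalg.norm(mesh.vertices - pos[None, :], axis=1)
    d = np.maximum(d, 1e-6)
    phi = np.asarray(semi_infinite_fluence(d, props, wavelength))
    out_of_range = d > max_range
    if np.any(out_of_range):
        in_idx = np.nonzero(~out_of_range)[0]
        if len(in_idx) == 0:
            raise ValueError("no vertex within fluence tabulation range")
        tree = cKDTree(mesh.vertices[in_idx])
        _, nn = tree.query(mesh.vertices[out_of_range])
        # cKDTree ties already resolve to the first (lowest) index in in_idx order
        phi[out_of_range] = phi[in_idx[nn]]
    return phi


def build_sensitivity(
    montage: Montage,
    mesh: CortexMesh,
    props: OpticalProps | None = None,
    max_range: float = FLUENCE_RANGE_MM,
) -> SensitivityMatrix:
    """Adjoint-form sensitivity of every long channel to each mesh vertex."""
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    props = props or OpticalProps()
    pairs = montage.long_pairs
    per_wl: dict[float, np.ndarray] = {}
    zero_rows: dict[float, list[int]] = {}
    for wl in montage.wavelengths:
        A = np.empty((len(pairs), mesh.n_vertices))
        fl_cache: dict[str, np.ndarray] = {}
        for row, pair in enumerate(pairs):
            s_pos, d_pos = montage.pair_positions(pair)
            for oid, pos in ((pair[0], s_pos), (pair[1], d_pos)):
                if oid not in fl_cache:
                    fl_cache[oid] = _optode_fluence_at_vertices(
                        pos, mesh, props, wl, max_range
                    )
            sd = montage.pair_distance(pair)
            phi_sd = semi_infinite_fluence(max(sd, 1e-6), props, wl)
            A[row] = fl_cache[pair[0]] * fl_cache[pair[1]] / phi_sd
        per_wl[wl] = A
        zero_rows[wl] = [int(i) for i in np.nonzero(~A.any(axis=1))[0]]
    return SensitivityMatrix(per_wl, pairs, mesh, zero_rows)


# ---------------------------------------------------------------------------
# inverse
# ---------------------------------------------------------------------------

def mne_inverse(
    sensitivity: SensitivityMatrix,
    od_window: ODSeries,
    lam: float | None = None,
    depth_exponent: float = 0.5,
    depth_limit: float = 10.0,
    snr: float = 3.0,
    mbll: MbllParams | None = None,
    bad_channels: set[int] | None = None,
) -> SourceEstimate:
    """Depth-weighted minimum-norm estimate of vertex-wise hemoglobin changes.

    Per wavelength the under-determined system  y = A x  is solved as

        x = R A^T (A R A^T + lam I)^-1 y,   R = diag(||a_v||^(-2p)),

    with depth exponent p (default 0.5) compensating the superficial bias of
    the unweighted solution, and lam defaulting to the trace-scaled 1/SNR^2
    convention lam = trace(A R A^T)/n_ch / SNR^2.  The two wavelength images
    are then converted vertex-wise to HbO/HbR via the 2x2 extinction system.
    Short channels take no part; ``bad_channels`` are pair indices (rows of
    the sensitivity matrix) to exclude.
    """
    if lam is not None and lam <= 0:
        raise ValueError("regularization lam must be > 0")
    mbll = mbll or default_mbll_params()
    m = od_window.montage
    wls = m.wavelengths
    bad = bad_channels or set()

    col = {(ch.pair, ch.wavelength): j for j, ch in enumerate(m.channels)}
    keep = [i for i in range(len(sensitivity.pairs)) if i not in bad]
    if not keep:
        raise ValueError("all channels excluded")

    n_v = sensitivity.mesh.n_vertices
    n_t = od_window.data.shape[0]
    images: dict[float, np.ndarray] = {}
    lam_used: dict[float, float] = {}
    for wl in wls:
        A_full = sensitivity.per_wavelength[wl]
        if not A_full.any():
            raise ValueError(f"all-zero sensitivity at {wl} nm")
        A = A_full[keep]
        y = np.stack(
            [od_window.data[:, col[(sensitivity.pairs[i], wl)]] for i in keep]
        )  # [n_ch x n_t]
        col_norm = np.linalg.norm(A, axis=0)
        col_norm = np.where(col_norm > 0, col_norm, col_norm.max() or 1.0)
        r_diag = col_norm ** (-2.0 * depth_exponent)  # source covariance diag
        # clip the depth prior (weight-limit convention) so poorly sensed
        # vertices cannot amplify noise without bound
        r_diag = np.minimum(r_diag, depth_limit**2 * r_diag.min())
        AR = A * r_diag[None, :]
        gram = AR @ A.T  # A R A^T
        lam_wl = lam if lam is not None else float(np.trace(gram)) / len(keep) / snr**2
        lam_used[wl] = lam_wl
        alpha = np.linalg.solve(gram + lam_wl * np.eye(len(keep)), y)
        images[wl] = AR.T @ alpha  # [n_v x n_t]

    E = mbll.eps_matrix(tuple(wls))
    Einv = np.linalg.inv(E)
    stacked = np.stack([images[wl] for wl in wls])  # [2 x n_v x n_t]
    hb = np.einsum("cw,wvt->cvt", Einv, stacked)
    assert hb.shape == (2, n_v, n_t)
    return SourceEstimate(
        hbo=hb[0],
        hbr=hb[1],
        mesh=sensitivity.mesh,
        fs=od_window.fs,
        regularization={
            "lam": lam_used,
            "depth_exponent": depth_exponent,
            "depth_limit": depth_limit,
            "snr": snr,
            "excluded_rows": sorted(bad),
        },
    )


def forward_project(
    sensitivity: SensitivityMatrix,
    hbo: np.ndarray,
    hbr: np.ndarray,
    mbll: MbllParams | None = None,
) -> dict[float, np.ndarray]:
    """Map vertex-wise hemoglobin changes [n_v x n_t] to channel dOD per
    wavelength — the forward counterpart of :func:`mne_inverse`, used to
    simulate sensor data from a known cortical field."""
    mbll = mbll or default_mbll_params()
    out = {}
    for wl, A in sensitivity.per_wavelength.items():
        e_hbo, e_hbr = mbll.extinction[wl]
        out[wl] = A @ (e_hbo * hbo + e_hbr * hbr)
    return out
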