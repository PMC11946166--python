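import numpy as np
import pytest

from opusnirs.preprocess import ODSeries, default_mbll_params
from opusnirs.source_model import (
    CortexMesh,
    OpticalProps,
    build_sensitivity,
    forward_project,
    mne_inverse,
    semi_infinite_fluence,
    spherical_cap_mesh,
)


def _od_from_forward(montage, sens, od_by_wl, fs=5.0):
    """Assemble an ODSeries (montage channel order) from per-wavelength
    long-channel forward projections."""
    n_t = next(iter(od_by_wl.values())).shape[1]
    data = np.zeros((n_t, len(montage.channels)))
    col = {(ch.pair, ch.wavelength): j for j, ch in enumerate(montage.channels)}
    for wl, Y in od_by_wl.items():
        for i, pair in enumerate(sens.pairs):
            data[:, col[(pair, wl)]] = Y[i]
    return ODSeries(data, fs, montage)


class TestFluence:
    def test_strictly_decreasing(self):
        props = OpticalProps()
        r = np.linspace(5.0, 80.0, 200)
        phi = semi_infinite_fluence(r, props, 762.0)
        assert np.all(np.diff(phi) < 0)

    def test_reciprocity(self):
        props = OpticalProps()
        assert semi_infinite_fluence(23.0, props, 842.0) == semi_infinite_fluence(
            23.0, props, 842.0
        )

    def test_matches_independent_evaluation(self):
        """Independent re-derivation of the extrapolated-boundary Green's
        function at r = 30 mm, mu_a = 0.01/mm, mu_s' = 1.0/mm."""
        mu_a, mu_sp, r = 0.01, 1.0, 30.0
        D = 1.0 / (3.0 * (mu_a + mu_sp))
        mu_eff = np.sqrt(3.0 * mu_a * (mu_a + mu_sp))
        z0 = 1.0 / mu_sp
        zb = 2.0 * D * (1.0 + 0.493) / (1.0 - 0.493)
        r1 = np.hypot(r, z0)
        r2 = np.hypot(r, z0 + 2 * zb)
        expected = (
            np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2
        ) / (4 * np.pi * D)
        props = OpticalProps(mu_a={762.0: mu_a}, mu_s_prime={762.0: mu_sp})
        assert semi_infinite_fluence(r, props, 762.0) == pytest.approx(
            expected, abs=1e-9
        )

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            semi_infinite_fluence(0.0, OpticalProps(), 762.0)


class TestMesh:
    def test_exact_vertex_count(self, mesh):
        assert mesh.n_vertices == 10_000

    def test_faces_index_valid_vertices(self, mesh):
        assert mesh.faces.min() >= 0
        assert mesh.faces.max() < mesh.n_vertices

    def test_off_roundtrip(self, tmp_path):
        small = spherical_cap_mesh(n_vertices=200)
        path = tmp_path / "mesh.off"
        small.save_off(path)
        back = CortexMesh.load_off(path)
        assert np.allclose(back.vertices, small.vertices, atol=1e-5)
        assert np.array_equal(back.faces, small.faces)


class TestSensitivity:
    def test_shape_and_nonnegative(self, sensitivity, montage):
        for wl, A in sensitivity.per_wavelength.items():
            assert A.shape == (len(montage.long_pairs), 10_000)
            assert np.all(A >= 0)
        assert sensitivity.zero_rows == {762.0: [], 842.0: []}

    def test_midpoint_vertex_is_row_maximal(self, sensitivity, montage, mesh):
        """The most sensitive vertex of each channel sits under the channel
        midpoint (within mesh discretization)."""
        A = sensitivity.per_wavelength[842.0]
        for i, pair in enumerate(sensitivity.pairs[:4]):
            s, d = montage.pair_positions(pair)
            mid = 0.5 * (s + d)
            mid_cortex = mid / np.linalg.norm(mid) * np.linalg.norm(
                mesh.vertices, axis=1
            ).mean()
            v_max = int(np.argmax(A[i]))
            assert np.linalg.norm(mesh.vertices[v_max] - mid_cortex) < 6.0

    def test_distant_vertices_negligible(self, montage):
        wide = spherical_cap_mesh(n_vertices=3000, montage=montage,
                                  cap_half_angle_deg=89.0)
        sens = build_sensitivity(montage, wide)
        A = sens.per_wavelength[762.0]
        for i, pair in enumerate(sens.pairs[:3]):
            s, d = montage.pair_positions(pair)
            dist = np.minimum(
                np.linalg.norm(wide.vertices - s, axis=1),
                np.linalg.norm(wide.vertices - d, axis=1),
            )
            far = dist > 100.0
            if far.any():
                assert A[i, far].max() < 1e-6 * A[i].max()

    def test_absorption_monotonicity(self, montage, mesh):
        base = build_sensitivity(montage, mesh).per_wavelength[762.0]
        doubled_props = OpticalProps(
            mu_a={762.0: 0.038, 842.0: 0.042}, mu_s_prime={762.0: 1.1, 842.0: 1.0}
        )
        doubled = build_sensitivity(montage, mesh, doubled_props).per_wavelength[762.0]
        assert np.all(doubled < base)

    def test_empty_mesh_rejected(self, montage):
        empty = CortexMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValueError, match="empty mesh"):
            build_sensitivity(montage, empty)


class TestInverse:
    def test_zero_od_gives_zero_estimate(self, sensitivity, montage):
        od = ODSeries(np.zeros((10, len(montage.channels))), 5.0, montage)
        est = mne_inverse(sensitivity, od)
        assert np.allclose(est.hbo, 0) and np.allclose(est.hbr, 0)
        assert est.hbo.shape == (10_000, 10)

    def test_single_source_localized_within_15mm(self, sensitivity, montage, mesh):
        """Noiseless single source: the |HbT| peak lies within 15 mm of the
        true vertex — comfortably inside the 2-3 cm resolution class of
        sparse-optode CW-fNIRS."""
        A = sensitivity.per_wavelength[842.0]
        v_true = int(np.argmax(A.sum(axis=0)))
        hbo = np.zeros((mesh.n_vertices, 20))
        hbo[v_true] = 1e-6
        od = _od_from_forward(
            montage, sensitivity, forward_project(sensitivity, hbo, -hbo / 3)
        )
        est = mne_inverse(sensitivity, od)
        v_peak = int(np.argmax(np.abs(est.hbt).max(axis=1)))
        assert np.linalg.norm(mesh.vertices[v_peak] - mesh.vertices[v_true]) < 15.0

    def test_linearity(self, sensitivity, montage, rng):
        data = rng.normal(0, 1e-5, (8, len(montage.channels)))
        od1 = ODSeries(data, 5.0, montage)
        od3 = ODSeries(3 * data, 5.0, montage)
        e1, e3 = mne_inverse(sensitivity, od1), mne_inverse(sensitivity, od3)
        assert np.allclose(e3.hbo, 3 * e1.hbo, rtol=1e-9, atol=1e-18)

    def test_ridge_shrinkage_monotone(self, sensitivity, montage, rng):
        data = rng.normal(0, 1e-5, (5, len(montage.channels)))
        od = ODSeries(data, 5.0, montage)
        norms = []
        lam0 = mne_inverse(sensitivity, od).regularization["lam"][762.0]
        for lam in (lam0, 10 * lam0, 100 * lam0):
            est = mne_inverse(sensitivity, od, lam=lam)
            norms.append(np.linalg.norm(est.hbo) + np.linalg.norm(est.hbr))
        assert norms[0] > norms[1] > norms[2]

    def test_hbt_conservation(self, sensitivity, montage, rng):
        od = ODSeries(rng.normal(0, 1e-5, (5, len(montage.channels))), 5.0, montage)
        est = mne_inverse(sensitivity, od)
        assert np.allclose(est.hbt, est.hbo + est.hbr, atol=1e-18)

    def test_invalid_lambda_rejected(self, sensitivity, montage):
        od = ODSeries(np.zeros((5, len(montage.channels))), 5.0, montage)
        with pytest.raises(ValueError, match="lam"):
            mne_inverse(sensitivity, od, lam=-1.0)

    def test_two_sources_recovered_with_rank_order(
        self, sensitivity, montage, mesh, rng
    ):
        """Two well-separated sources at SNR >= 10: both recovered peaks
        within 20 mm, amplitude rank order preserved.  Source separation is
        chosen well above the 2-3 cm point-spread of the sparse montage."""
        import itertools

        A = sensitivity.per_wavelength[842.0]
        best = [int(v) for v in np.argmax(A, axis=1)]
        i, j = max(
            itertools.combinations(range(len(best)), 2),
            key=lambda ij: np.linalg.norm(
                mesh.vertices[best[ij[0]]] - mesh.vertices[best[ij[1]]]
            ),
        )
        v1, v2 = best[i], best[j]
        hbo = np.zeros((mesh.n_vertices, 20))
        hbo[v1] = 1.5e-6
        hbo[v2] = 1e-6
        od_clean = _od_from_forward(
            montage, sensitivity, forward_project(sensitivity, hbo, -hbo / 3)
        )
        noise_sd = np.sqrt((od_clean.data**2).mean()) / 10.0
        od = ODSeries(
            od_clean.data + rng.normal(0, noise_sd, od_clean.data.shape),
            od_clean.fs,
            montage,
        )
        est = mne_inverse(sensitivity, od)
        act = np.abs(est.hbt).max(axis=1)
        p1 = int(np.argmax(act))
        # second peak: outside the first blob (point-spread ~3 cm)
        mask = (
            np.linalg.norm(mesh.vertices - mesh.vertices[p1], axis=1) > 40.0
        )
        p2_candidates = np.nonzero(mask)[0]
        p2 = int(p2_candidates[np.argmax(act[mask])])
        found = {p1, p2}
        for v_true in (v1, v2):
            assert min(
                np.linalg.norm(mesh.vertices[p] - mesh.vertices[v_true])
                for p in found
            ) < 20.0
        # rank order: the stronger true source's neighbourhood is stronger
        near1 = np.linalg.norm(mesh.vertices - mesh.vertices[v1], axis=1) < 15.0
        near2 = np.linalg.norm(mesh.vertices - mesh.vertices[v2], axis=1) < 15.0
        assert act[near1].max() > act[near2].max()

    def test_close_sources_may_merge(self, sensitivity, montage, mesh):
        """Resolution honesty: two sources 10 mm apart need not be resolved;
        the merged estimate must still peak near the pair."""
        A = sensitivity.per_wavelength[842.0]
        v1 = int(np.argmax(A.sum(axis=0)))
        d = np.linalg.norm(mesh.vertices - mesh.vertices[v1], axis=1)
        v2 = int(np.argmin(np.abs(d - 10.0)))
        hbo = np.zeros((mesh.n_vertices, 10))
        hbo[[v1, v2]] = 1e-6
        od = _od_from_forward(
            montage, sensitivity, forward_project(sensitivity, hbo, -hbo / 3)
        )
        est = mne_inverse(sensitivity, od)
        v_peak = int(np.argmax(np.abs(est.hbt).max(axis=1)))
        mid = 0.5 * (mesh.vertices[v1] + mesh.vertices[v2])
        assert np.linalg.norm(mesh.vertices[v_peak] - mid) < 20.0
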