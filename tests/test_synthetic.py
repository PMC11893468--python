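"""Generator contracts: determinism, geometry, atlases, dynamics."""

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import kurtosis, spearmanr

import corticarta as ca
from corticarta import synthetic
from corticarta.synthetic import (
    CORTICAL_TYPES,
    GroundTruth,
    generate_atlases,
    generate_connectome,
    generate_dcm_timeseries,
    generate_landscape,
    generate_profiles,
    generate_sheet,
    peakedness_field,
    smooth_vertex_field,
)


class TestSheet:
    def test_same_seed_gives_bitwise_identical_sheets(self):
        a = generate_sheet(162, seed=7)
        b = generate_sheet(162, seed=7)
        assert np.array_equal(a.outer_vertices, b.outer_vertices)
        assert np.array_equal(a.inner_vertices, b.inner_vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_zero_folding_gives_constant_radius(self):
        s = generate_sheet(162, folding_amplitude=0.0, seed=1)
        for label in ("L", "R"):
            idx = s.hemisphere == label
            r = np.linalg.norm(s.outer_vertices[idx] - s.hemisphere_centers[label], axis=1)
            assert np.all(np.abs(r - r[0]) < 1e-9)

    def test_thickness_positive_and_within_range(self):
        s = generate_sheet(162, thickness_range=(1.0, 2.0), seed=3)
        t = s.thickness()
        assert t.min() > 0
        assert t.min() >= 1.0 - 1e-9 and t.max() <= 2.0 + 1e-9

    def test_sphere_coordinates_unit_norm(self, small_sheet):
        norms = np.linalg.norm(small_sheet.sphere_coordinates, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_rejects_nonpositive_thickness(self):
        with pytest.raises(ValueError):
            generate_sheet(162, thickness_range=(0.0, 1.0), seed=0)

    def test_faces_reference_valid_vertices(self, small_sheet):
        assert small_sheet.faces.min() >= 0
        assert small_sheet.faces.max() < small_sheet.n_vertices


class TestAtlases:
    def test_every_parcel_is_mesh_connected(self, small_sheet, small_atlases):
        parc, _, _ = small_atlases
        g = small_sheet.graph()
        for pid in range(parc.n_parcels):
            members = np.flatnonzero(parc.vertex_to_parcel == pid)
            sub = g[np.ix_(members, members)]
            n_comp, _ = connected_components(sub, directed=False)
            assert n_comp == 1, f"parcel {pid} has {n_comp} components"

    def test_dmn_overlaps_at_least_five_types(self, small_atlases):
        _, type_atlas, net_atlas = small_atlases
        dmn_types = set(type_atlas.vertex_types[net_atlas.dmn_vertices()])
        assert len(dmn_types) >= 5

    def test_all_six_types_present_cortexwide(self, small_atlases):
        _, type_atlas, _ = small_atlases
        assert set(type_atlas.vertex_types) == set(range(len(CORTICAL_TYPES)))

    def test_no_parcel_spans_hemispheres(self, small_sheet, small_atlases):
        parc, _, _ = small_atlases
        for pid in range(parc.n_parcels):
            hemis = set(small_sheet.hemisphere[parc.vertex_to_parcel == pid])
            assert len(hemis) == 1

    def test_dmn_has_four_disjoint_subregions_per_hemisphere(self, small_atlases):
        parc, _, net = small_atlases
        for label in ("L", "R"):
            subs = net.dmn_subregion[
                (net.dmn_subregion >= 0) & (parc.parcel_hemisphere == label)
            ]
            assert len(set(subs)) >= 4

    def test_rejects_bad_dmn_fraction(self, small_sheet):
        with pytest.raises(ValueError):
            generate_atlases(small_sheet, n_parcels=24, dmn_fraction=1.5, seed=0)


class TestProfiles:
    def test_full_peakedness_peaks_in_mid_deep_band(self, small_sheet):
        p = np.ones(small_sheet.n_vertices)
        pm, _ = generate_profiles(small_sheet, p, noise_sd=0.0, seed=0)
        frac = np.argmax(pm.intensities, axis=0) / (pm.n_depths - 1)
        assert np.all((frac >= 0.5) & (frac <= 0.8))

    def test_zero_peakedness_gives_flat_profiles(self, small_sheet):
        p = np.zeros(small_sheet.n_vertices)
        pm, _ = generate_profiles(small_sheet, p, noise_sd=0.0, seed=0)
        assert np.all(pm.intensities.var(axis=0) == 0)

    def test_kurtosis_tracks_peakedness_under_noise(self, small_sheet):
        p = peakedness_field(small_sheet, seed=5)
        pm, _ = generate_profiles(small_sheet, p, noise_sd=0.1, seed=6)
        k = kurtosis(pm.intensities, axis=0)
        rho = spearmanr(p, k).statistic
        assert rho > 0

    def test_rejects_negative_noise(self, small_sheet):
        with pytest.raises(ValueError):
            generate_profiles(small_sheet, np.zeros(small_sheet.n_vertices), noise_sd=-1.0)

    def test_peakedness_field_is_bounded_and_deterministic(self, small_sheet):
        a = peakedness_field(small_sheet, seed=9)
        b = peakedness_field(small_sheet, seed=9)
        assert np.array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 1


class TestLandscapeGen:
    def test_gradient_is_strictly_monotone_along_x(self):
        ls = generate_landscape(16, "gradient", noise_sd=0.0, seed=0)
        grid = ls.values.reshape(16, 16)
        assert np.all(np.diff(grid, axis=1) > 0)

    def test_interdigitated_has_2k_sign_changes_per_row(self):
        for k in (2, 4):
            ls = generate_landscape(64, "interdigitated", frequency=k, seed=0)
            grid = (ls.values - ls.values.mean()).reshape(64, 64)
            for row in grid:
                assert int(np.sum(row[:-1] * row[1:] < 0)) == 2 * k

    def test_same_seed_identical_field(self):
        a = generate_landscape(12, "noise", seed=3)
        b = generate_landscape(12, "noise", seed=3)
        assert np.array_equal(a.values, b.values)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(16, "fractal", seed=0)


@pytest.fixture(scope="module")
def conn(small_atlases):
    parc, _, _ = small_atlases
    c, gt = generate_connectome(parc, decay_length=30.0, density=0.4, seed=4)
    return c, gt


class TestConnectome:
    def test_symmetric_nonnegative_zero_diagonal(self, conn):
        c, _ = conn
        assert np.array_equal(c.W, c.W.T)
        assert c.W.min() >= 0
        assert np.all(np.diag(c.W) == 0)

    def test_weight_decays_with_distance(self, conn):
        c, _ = conn
        d = c.distances()
        iu = np.triu_indices(c.n_nodes, k=1)
        w, dd = c.W[iu], d[iu]
        rho = spearmanr(w[w > 0], dd[w > 0]).statistic
        assert rho < 0

    def test_each_hemisphere_connected_no_isolated_nodes(self, conn):
        c, _ = conn
        assert np.all(c.W.sum(axis=0) > 0)
        for label in ("L", "R"):
            sub = np.flatnonzero(c.hemisphere == label)
            n_comp, _ = connected_components(
                sparse.csr_matrix(c.W[np.ix_(sub, sub)] > 0), directed=False
            )
            assert n_comp == 1

    def test_rejects_bad_decay(self, small_atlases):
        with pytest.raises(ValueError):
            generate_connectome(small_atlases[0], decay_length=-1.0, seed=0)


class TestDcmTimeseries:
    def test_decay_to_zero_without_noise(self):
        A = -0.5 * np.eye(3)
        x0 = np.array([3.0, -2.0, 1.0])
        ts, _ = generate_dcm_timeseries(
            A, duration=120, TR=0.5, noise_sd=0.0, process_noise_sd=0.0, x0=x0, seed=0
        )
        assert np.abs(ts.values[-1]).max() < 1e-3 * np.abs(ts.values).max()

    def test_bounded_over_ten_minutes(self):
        rng = np.random.default_rng(11)
        A = rng.normal(scale=0.2, size=(5, 5)) - 1.0 * np.eye(5)
        while np.max(np.linalg.eigvals(A).real) >= 0:
            A -= 0.1 * np.eye(5)
        ts, _ = generate_dcm_timeseries(A, duration=600, TR=0.5, noise_sd=0.05, seed=1)
        assert np.abs(ts.values).max() < 50.0

    def test_same_seed_identical_timeseries(self):
        A = -0.5 * np.eye(2)
        a, _ = generate_dcm_timeseries(A, duration=60, TR=0.5, seed=5)
        b, _ = generate_dcm_timeseries(A, duration=60, TR=0.5, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_unstable_matrix_rejected_with_message(self):
        with pytest.raises(ValueError, match="unstable"):
            generate_dcm_timeseries(np.eye(2) * 0.1, duration=60, TR=0.5, seed=0)


def test_ground_truth_roundtrips_through_json():
    gt = GroundTruth(
        peakedness=np.array([0.1, 0.9]),
        A_true=-0.5 * np.eye(2),
        decay_length=30.0,
        seeds={"sheet": 1},
    )
    back = GroundTruth.from_json(gt.to_json())
    assert np.array_equal(back.peakedness, gt.peakedness)
    assert np.array_equal(back.A_true, gt.A_true)
    assert back.decay_length == gt.decay_length
    assert back.seeds == gt.seeds


def test_smooth_field_is_homotopically_symmetric(small_sheet):
    f = smooth_vertex_field(small_sheet, seed=2)
    left = f[small_sheet.hemisphere == "L"]
    right = f[small_sheet.hemisphere == "R"]
    assert np.allclose(left, right)
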