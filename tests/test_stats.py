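"""Parcel averaging, axis correlations, KL balance, spin inference."""

import numpy as np
import pytest

import corticarta as ca
from corticarta.stats import (
    composition_test,
    correlate_with_axis,
    kl_balance,
    parcel_average,
    spin_rotation_indices,
    spin_test,
)
from corticarta.synthetic import smooth_vertex_field


class TestParcelAverage:
    def test_constant_field(self, small_atlases):
        parc, _, _ = small_atlases
        out = parcel_average(np.full(parc.vertex_to_parcel.size, 3.7), parc)
        assert np.allclose(out, 3.7)

    def test_matches_naive_loop(self, small_atlases):
        parc, _, _ = small_atlases
        rng = np.random.default_rng(0)
        field = rng.random(parc.vertex_to_parcel.size)
        field[5] = np.nan  # masked vertex
        out = parcel_average(field, parc)
        for pid in range(parc.n_parcels):
            vals = [
                field[v]
                for v in np.flatnonzero(parc.vertex_to_parcel == pid)
                if np.isfinite(field[v])
            ]
            assert out[pid] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_length_mismatch_rejected(self, small_atlases):
        parc, _, _ = small_atlases
        with pytest.raises(ValueError):
            parcel_average(np.zeros(3), parc)


class TestCorrelateWithAxis:
    def test_perfect_negative_relation(self):
        e1 = np.linspace(-1, 1, 30)
        res = correlate_with_axis(e1, -e1, seed=0)
        assert res.r == pytest.approx(-1.0, abs=1e-12)
        assert res.subsample_sd == pytest.approx(0.0, abs=1e-12)

    def test_shuffled_summary_has_small_correlation(self):
        rng = np.random.default_rng(1)
        e1 = rng.random(100)
        hits = 0
        for _ in range(100):
            res = correlate_with_axis(e1, rng.permutation(e1), seed=0)
            hits += abs(res.r) < 0.2
        # at P=100 the null sd of r is ~0.1, so |r| < 0.2 holds at the ~95%
        # level; allow binomial slack on 100 draws
        assert hits >= 90

    def test_matches_manual_product_moment_formula(self):
        x = np.array([1.0, 2, 4, 4.5, 7, 9])
        y = np.array([2.0, 1, 5, 6, 8, 7.5])
        res = correlate_with_axis(x, y, seed=0)
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.r == pytest.approx(manual, abs=1e-12)

    def test_per_type_correlations_reported(self):
        e1 = np.linspace(0, 1, 40)
        res = correlate_with_axis(
            e1, -e1, type_summaries={"kon": -2 * e1, "ag": e1**2}, seed=0
        )
        assert res.per_type_r["kon"] == pytest.approx(-1.0, abs=1e-12)
        assert -1 <= res.per_type_r["ag"] <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_axis(np.ones(10), np.arange(10.0), seed=0)


class TestKlBalance:
    def test_uniform_is_zero(self):
        for k in (2, 5, 6):
            assert kl_balance(np.full(k, 0.37)) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_two_types_is_ln2(self):
        assert kl_balance(np.array([1.0, 0.0])) == pytest.approx(np.log(2), abs=1e-9)

    def test_half_quarter_quarter(self):
        expected = 0.5 * np.log(1.5) + 0.5 * np.log(0.75)
        got = kl_balance(np.array([0.5, 0.25, 0.25]))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.0589, abs=1e-4)

    def test_invariant_to_positive_rescaling(self):
        v = np.array([0.2, 1.3, 0.6, 0.01])
        assert kl_balance(v * 7.3) == pytest.approx(kl_balance(v), abs=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            kl_balance(np.array([0.5, -0.1]))


class TestSpinTest:
    def test_identical_maps_beat_all_permutations(self, small_sheet):
        a = smooth_vertex_field(small_sheet, seed=3)
        res = spin_test(
            a,
            a,
            small_sheet.sphere_coordinates,
            small_sheet.hemisphere,
            n_perm=200,
            seed=0,
            tail="greater",
        )
        assert res.observed == pytest.approx(1.0)
        assert res.p == 0.0

    def test_p_matches_printed_formula(self, small_sheet):
        a = smooth_vertex_field(small_sheet, seed=4)
        b = smooth_vertex_field(small_sheet, seed=5)
        res = spin_test(
            a,
            b,
            small_sheet.sphere_coordinates,
            small_sheet.hemisphere,
            n_perm=150,
            seed=1,
            tail="greater",
        )
        manual = 1.0 - np.sum(res.observed > res.null) / res.n_perm
        assert res.p == pytest.approx(manual, abs=1e-12)

    def test_reproducible_given_seed(self, small_sheet):
        a = smooth_vertex_field(small_sheet, seed=6)
        b = smooth_vertex_field(small_sheet, seed=7)
        args = (a, b, small_sheet.sphere_coordinates, small_sheet.hemisphere)
        r1 = spin_test(*args, n_perm=50, seed=42)
        r2 = spin_test(*args, n_perm=50, seed=42)
        assert np.array_equal(r1.null, r2.null)
        assert r1.p == r2.p

    def test_mismatched_meshes_rejected(self, small_sheet):
        with pytest.raises(ValueError, match="mesh"):
            spin_test(
                np.zeros(10),
                np.zeros(10),
                small_sheet.sphere_coordinates,
                small_sheet.hemisphere,
                n_perm=10,
                seed=0,
            )

    def test_rotation_preserves_value_multiset_per_hemisphere(self, small_sheet):
        idx = spin_rotation_indices(
            small_sheet.sphere_coordinates, small_sheet.hemisphere, n_perm=5, seed=3
        )
        left = small_sheet.hemisphere == "L"
        for k in range(5):
            assert np.all(left[idx[k][left]])  # reassignments stay in-hemisphere


class TestCompositionTest:
    def test_dmn_coinciding_with_one_type(self, small_sheet, small_atlases):
        _, type_atlas, net_atlas = small_atlases
        from dataclasses import replace

        vertex_networks = np.where(
            type_atlas.vertex_types == 2, net_atlas.dmn_label, "other"
        ).astype(object)
        na = replace(
            net_atlas, vertex_networks=vertex_networks, parcel_networks=net_atlas.parcel_networks
        )
        out = composition_test(
            na,
            type_atlas,
            small_sheet.sphere_coordinates,
            small_sheet.hemisphere,
            n_perm=20,
            seed=0,
        )
        assert out["proportions"][2] == pytest.approx(1.0)
        assert np.all(out["proportions"][[0, 1, 3, 4, 5]] == 0)

    def test_proportions_sum_to_one(self, small_sheet, small_atlases):
        _, type_atlas, net_atlas = small_atlases
        out = composition_test(
            net_atlas,
            type_atlas,
            small_sheet.sphere_coordinates,
            small_sheet.hemisphere,
            n_perm=30,
            seed=1,
        )
        assert out["proportions"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_null_counts_conserve_rotated_dmn_size(self, small_sheet, small_atlases):
        _, type_atlas, net_atlas = small_atlases
        n_perm, seed = 10, 2
        out = composition_test(
            net_atlas,
            type_atlas,
            small_sheet.sphere_coordinates,
            small_sheet.hemisphere,
            n_perm=n_perm,
            seed=seed,
        )
        # recompute the rotations independently: same seed -> same table
        idx = spin_rotation_indices(
            small_sheet.sphere_coordinates, small_sheet.hemisphere, n_perm, seed
        )
        net = np.asarray(net_atlas.vertex_networks)
        valid = type_atlas.vertex_types >= 0
        for k in range(n_perm):
            rotated_dmn = net[idx[k]] == net_atlas.dmn_label
            assert out["null_counts"][k].sum() == (rotated_dmn & valid).sum()

    def test_empty_dmn_rejected(self, small_sheet, small_atlases):
        _, type_atlas, net_atlas = small_atlases
        from dataclasses import replace

        na = replace(
            net_atlas,
            vertex_networks=np.full(small_sheet.n_vertices, "other", dtype=object),
        )
        with pytest.raises(ValueError):
            composition_test(
                na,
                type_atlas,
                small_sheet.sphere_coordinates,
                small_sheet.hemisphere,
                n_perm=5,
                seed=0,
            )


def test_correlate_with_axis_reports_spin_p(small_sheet):
    peak = smooth_vertex_field(small_sheet, seed=10)
    summary = -2.0 * peak + np.random.default_rng(0).normal(0, 0.05, peak.size)
    res = correlate_with_axis(peak, summary, seed=0)
    st = spin_test(
        peak,
        summary,
        small_sheet.sphere_coordinates,
        small_sheet.hemisphere,
        n_perm=200,
        seed=0,
        tail="less",
    )
    assert res.r < -0.9
    assert st.p < 0.05
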