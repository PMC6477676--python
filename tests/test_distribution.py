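import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stau_rnaloc import make_oocyte
from stau_rnaloc.distribution import (
    average_matrices,
    build_matrix,
    center_of_mass,
    compare_groups,
    normalize_coords,
    posterior_fraction,
)
from stau_rnaloc.errors import InvalidParameterError
from tests.conftest import spot_frame


def _normalized_frame(u, v, intensity=1.0):
    df = pd.DataFrame({"u": np.atleast_1d(u), "v": np.atleast_1d(v)})
    df["intensity"] = np.broadcast_to(intensity, len(df)).astype(float)
    return df


class TestNormalizeCoords:
    def test_poles_map_to_axis_endpoints(self, oocyte):
        pts = spot_frame(np.vstack([oocyte.anterior, oocyte.posterior]))
        norm, n_exc = normalize_coords(pts, oocyte)
        assert n_exc == 0
        assert norm["u"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert norm["u"].iloc[1] == pytest.approx(1.0, abs=1e-12)

    def test_axis_midpoint_maps_to_half(self, oocyte):
        mid = 0.5 * (oocyte.anterior + oocyte.posterior)
        norm, _ = normalize_coords(spot_frame(mid), oocyte)
        assert norm["u"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_rigid_rotation_leaves_coordinates_unchanged(self, oocyte):
        from stau_rnaloc.annotation import OocyteAnnotation

        rng = np.random.default_rng(3)
        pts = oocyte.sample_uniform(200, rng)
        norm0, _ = normalize_coords(spot_frame(pts), oocyte)

        ang = np.deg2rad(37.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([13.0, -7.0])
        moved = OocyteAnnotation(
            outline=oocyte.outline @ rot.T + shift,
            anterior=oocyte.anterior @ rot.T + shift,
            posterior=oocyte.posterior @ rot.T + shift,
        )
        norm1, _ = normalize_coords(spot_frame(pts @ rot.T + shift), moved)
        np.testing.assert_allclose(
            norm0[["u", "v"]].to_numpy(), norm1[["u", "v"]].to_numpy(), atol=1e-9
        )

    def test_points_outside_outline_are_excluded_with_warning(self, oocyte):
        pts = spot_frame(np.array([[50.0, 25.0], [500.0, 500.0]]))
        with pytest.warns(UserWarning, match="1 point"):
            norm, n_exc = normalize_coords(pts, oocyte)
        assert n_exc == 1
        assert len(norm) == 1


class TestBuildMatrix:
    def test_point_near_posterior_lands_in_last_column(self):
        mat = build_matrix(_normalized_frame(0.995, 0.5))
        assert mat[:, 99].sum() == pytest.approx(1.0)

    def test_two_equal_points_split_between_end_columns(self):
        mat = build_matrix(_normalized_frame([0.005, 0.995], [0.5, 0.5]))
        assert mat[:, 0].sum() == pytest.approx(0.5)
        assert mat[:, 99].sum() == pytest.approx(0.5)

    def test_uniform_points_give_near_uniform_column_sums(self):
        rng = np.random.default_rng(0)
        n = 100_000
        mat = build_matrix(_normalized_frame(rng.uniform(size=n), rng.uniform(size=n)))
        cols = mat.sum(axis=0)
        assert cols.min() >= 0.005 and cols.max() <= 0.015

    def test_total_is_one_regardless_of_intensity_scaling(self):
        rng = np.random.default_rng(1)
        base = _normalized_frame(rng.uniform(size=50), rng.uniform(size=50),
                                 rng.uniform(1, 5, size=50))
        m1 = build_matrix(base)
        scaled = base.assign(intensity=base["intensity"] * 137.0)
        np.testing.assert_allclose(build_matrix(scaled), m1)
        assert m1.sum() == pytest.approx(1.0, abs=1e-9)

    def test_boundary_value_one_maps_to_last_cell(self):
        mat = build_matrix(_normalized_frame(1.0, 1.0))
        assert mat[99, 99] == pytest.approx(1.0)

    def test_zero_total_intensity_raises(self):
        with pytest.raises(InvalidParameterError):
            build_matrix(_normalized_frame(0.5, 0.5, 0.0))


class TestAverageMatrices:
    def test_identical_matrices_have_zero_variability(self):
        m = build_matrix(_normalized_frame([0.2, 0.8], [0.4, 0.6]))
        mean, sd = average_matrices([m, m, m])
        np.testing.assert_allclose(sd, 0.0)
        np.testing.assert_allclose(mean, m)

    def test_disjoint_support_averages_to_half_each(self):
        a = build_matrix(_normalized_frame(0.1, 0.5))
        b = build_matrix(_normalized_frame(0.9, 0.5))
        mean, sd = average_matrices([a, b])
        assert mean.sum() == pytest.approx(1.0)
        support = (a + b) > 0
        assert np.all(sd[support] > 0)
        assert np.all(sd[~support] == 0)
        np.testing.assert_allclose(mean[support], 0.5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(InvalidParameterError):
            average_matrices([np.zeros((100, 100)), np.zeros((50, 50))])


class TestCenterOfMass:
    def test_uniform_matrix_is_centred(self):
        mat = np.full((100, 100), 1e-4)
        com = center_of_mass(mat)
        assert com == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_all_mass_in_last_column_gives_half_minus_halfcell(self):
        mat = np.zeros((100, 100))
        mat[:, 99] = 1.0 / 100
        com_ap, _ = center_of_mass(mat)
        assert com_ap == pytest.approx(0.495, abs=1e-12)

    def test_ap_mirror_negates_ap_component(self):
        rng = np.random.default_rng(5)
        mat = rng.uniform(size=(100, 100))
        mat /= mat.sum()
        com_ap, com_orth = center_of_mass(mat)
        m_ap, m_orth = center_of_mass(mat[:, ::-1])
        assert m_ap == pytest.approx(-com_ap, abs=1e-12)
        assert m_orth == pytest.approx(com_orth, abs=1e-12)


class TestPosteriorFraction:
    def test_uniform_matrix_has_no_posterior_domain(self):
        assert posterior_fraction(np.full((100, 100), 1e-4)) == 0.0

    def test_all_mass_in_last_column_gives_one(self):
        mat = np.zeros((100, 100))
        mat[50, 99] = 1.0
        assert posterior_fraction(mat) == pytest.approx(1.0)

    def test_two_enriched_posterior_columns(self):
        # columns 99-100 hold 0.05 each; the rest uniform
        mat = np.zeros((100, 100))
        mat[0, 98] = 0.05
        mat[0, 99] = 0.05
        mat[0, :98] = 0.9 / 98
        assert posterior_fraction(mat) == pytest.approx(0.10)

    def test_enrichment_must_exceed_one(self):
        with pytest.raises(InvalidParameterError):
            posterior_fraction(np.full((100, 100), 1e-4), enrichment=1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        transfer=st.floats(0.01, 0.3),
    )
    def test_monotone_under_anterior_to_posterior_transfer(self, seed, transfer):
        """Moving mass from column 1 to column 100 never decreases it."""
        rng = np.random.default_rng(seed)
        mat = rng.uniform(size=(100, 100))
        mat /= mat.sum()
        before = posterior_fraction(mat)
        moved = mat.copy()
        amount = min(transfer, moved[:, 0].sum())
        col = moved[:, 0]
        take = np.minimum(col, amount * col / max(col.sum(), 1e-300))
        moved[:, 0] -= take
        moved[:, 99] += take
        assert posterior_fraction(moved) >= before - 1e-12


class TestCompareGroups:
    def test_bonferroni_divisor_counts_pairwise_tests(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(i * 0.1, 1, 10) for i in range(5)}
        cmp = compare_groups(groups, reference="g0", alpha=0.05)
        assert cmp.corrected_alpha == pytest.approx(0.05 / 4)
        assert len(cmp.pairwise_p) == 4

    def test_identical_samples_are_not_significant(self):
        x = np.arange(10.0)
        cmp = compare_groups({"a": x, "b": x.copy()}, reference="a")
        assert cmp.pairwise_p["b"] > 0.9

    def test_clear_shift_detected_below_corrected_alpha(self):
        rng = np.random.default_rng(2)
        groups = {
            "ref": rng.normal(0, 1, 30),
            "shifted": rng.normal(3, 1, 30),
            "same": rng.normal(0, 1, 30),
        }
        cmp = compare_groups(groups, reference="ref", alpha=0.05)
        assert cmp.pairwise_p["shifted"] < cmp.corrected_alpha
        assert cmp.kruskal_p < 0.01

    def test_missing_reference_and_tiny_groups_raise(self):
        with pytest.raises(InvalidParameterError):
            compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]}, reference="zzz")
        with pytest.raises(InvalidParameterError):
            compare_groups({"a": [1, 2], "b": [1, 2, 3]}, reference="a")


def test_end_to_end_posterior_recovery():
    """Oocytes simulated 80% posterior recover that share in the descriptor."""
    from stau_rnaloc import NoiseSpec, simulate_rna_spots
    from stau_rnaloc.distribution import oocyte_descriptors

    annot = make_oocyte(100, 50, seed=0)
    vals = []
    for i in range(20):
        spots, _ = simulate_rna_spots(
            annot, 800, frac_posterior=0.8, pole_spread=1.5,
            noise=NoiseSpec(cv=0.2, seed=100 + i),
        )
        vals.append(oocyte_descriptors(spots, annot)["posterior_fraction"])
    assert abs(np.mean(vals) - 0.8) <= 0.05
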