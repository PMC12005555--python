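import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hicpoly.preprocess import (
    ContactMap,
    coarsen_2x,
    compartment_pc1,
    contact_scaling,
    distance_normalize,
    extract_regions,
    load_contact_map,
    normalize_map,
    save_contact_map,
)

from conftest import random_symmetric_positive


class TestContactMapType:
    def test_rejects_asymmetric(self):
        vals = np.array([[1.0, 2.0], [3.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ContactMap(vals)

    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ContactMap(np.array([[1.0, -0.5], [-0.5, 1.0]]))

    def test_rejects_nonsquare(self):
        with pytest.raises(ValueError, match="square"):
            ContactMap(np.ones((2, 3)))


class TestIO:
    def test_text_roundtrip_3x3(self, tmp_path):
        vals = np.array([[4.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 4.0]])
        p = tmp_path / "m.txt"
        np.savetxt(p, vals)
        cmap = load_contact_map(p, format="dense_text")
        assert cmap.m == 3
        np.testing.assert_array_equal(cmap.values, vals)

    def test_negative_entry_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        np.savetxt(p, np.array([[1.0, -2.0], [-2.0, 1.0]]))
        with pytest.raises(ValueError, match="negative"):
            load_contact_map(p)

    def test_nonsquare_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        np.savetxt(p, np.ones((2, 3)))
        with pytest.raises(ValueError, match="square"):
            load_contact_map(p)

    def test_unknown_format(self, tmp_path):
        p = tmp_path / "m.txt"
        np.savetxt(p, np.eye(2))
        with pytest.raises(ValueError, match="format"):
            load_contact_map(p, format="mystery")

    def test_large_asymmetry_rejected(self, tmp_path):
        vals = np.array([[1.0, 2.0], [2.1, 1.0]])
        p = tmp_path / "m.txt"
        np.savetxt(p, vals)
        with pytest.raises(ValueError, match="asymmetry"):
            load_contact_map(p)

    @pytest.mark.parametrize("fmt", ["dense_text", "dense_binary"])
    def test_write_read_bitexact(self, tmp_path, fmt):
        # round-trip oracle: simulated-map-like values must survive exactly
        rng = np.random.default_rng(7)
        vals = rng.integers(0, 1000, size=(16, 16)).astype(float)
        vals = 0.5 * (vals + vals.T)
        cmap = ContactMap(vals, resolution_bp=50_000, chrom="chr9", start_bp=1_000_000)
        p = tmp_path / f"m.{fmt}"
        save_contact_map(cmap, p, format=fmt)
        back = load_contact_map(p, format=fmt)
        np.testing.assert_array_equal(back.values, cmap.values)
        if fmt == "dense_binary":
            assert back.chrom == "chr9"
            assert back.start_bp == 1_000_000
            assert back.resolution_bp == 50_000


class TestExtractRegions:
    def test_512_bins_per_region(self):
        m = 1100
        cmap = ContactMap(random_symmetric_positive(m, seed=3))
        regions = extract_regions(cmap, region_mb=25.6)
        assert len(regions) == 2
        assert all(r.m == 512 for r in regions)

    def test_zero_diagonal_region_discarded(self):
        m = 1200
        vals = random_symmetric_positive(m, seed=4)
        vals[600, 600] = 0.0
        cmap = ContactMap(vals)
        regions = extract_regions(cmap, region_mb=25.6)
        # direct scan oracle: window [512, 1024) contains bin 600
        starts = [(r.start_bp // 50_000) for r in regions]
        assert 512 not in starts
        assert 0 in starts

    def test_single_exact_region(self):
        vals = random_symmetric_positive(512, seed=5)
        cmap = ContactMap(vals)
        regions = extract_regions(cmap)
        assert len(regions) == 1
        np.testing.assert_array_equal(regions[0].values, vals)

    def test_short_chromosome_empty(self):
        cmap = ContactMap(random_symmetric_positive(100, seed=6))
        assert extract_regions(cmap) == []

    def test_count_matches_direct_scan(self):
        m = 2100
        vals = random_symmetric_positive(m, seed=7)
        rng = np.random.default_rng(8)
        zero_bins = rng.choice(m, size=5, replace=False)
        for z in zero_bins:
            vals[z, z] = 0.0
        cmap = ContactMap(vals)
        regions = extract_regions(cmap)
        expected = 0
        for start in range(0, m - 511, 512):
            if np.all(np.diag(vals)[start : start + 512] > 0):
                expected += 1
        assert len(regions) == expected


class TestNormalizeMap:
    def test_first_offdiag_mean_is_point_one(self, raw_map_64):
        out = normalize_map(raw_map_64)
        assert np.diagonal(out.values, 1).mean() == pytest.approx(0.1, abs=1e-12)

    def test_hand_computed_3x3(self):
        cmap = ContactMap(np.array([[4.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 4.0]]))
        out = normalize_map(cmap)
        expected = np.array([[1.0, 0.1, 0.05], [0.1, 1.0, 0.1], [0.05, 0.1, 1.0]])
        np.testing.assert_allclose(out.values, expected)

    def test_unit_diagonal(self, raw_map_64):
        out = normalize_map(raw_map_64)
        assert np.all(np.diag(out.values) == 1.0)

    def test_idempotent(self, raw_map_64):
        once = normalize_map(raw_map_64)
        twice = normalize_map(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_zero_offdiag_errors(self):
        vals = np.diag([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="off-diagonal"):
            normalize_map(ContactMap(vals))

    def test_sets_flag(self, raw_map_64):
        assert normalize_map(raw_map_64).is_normalized


class TestDistanceNormalize:
    def test_toeplitz_becomes_ones(self):
        from scipy.linalg import toeplitz

        vals = toeplitz([1.0, 0.5, 0.25, 0.125])
        out = distance_normalize(ContactMap(vals))
        np.testing.assert_allclose(out.values, np.ones((4, 4)), atol=1e-12)

    def test_hand_computed_3x3(self):
        vals = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        out = distance_normalize(ContactMap(vals))
        expected = np.array([[1.0, 1.25, 1.0], [1.25, 1.0, 0.75], [1.0, 0.75, 1.0]])
        np.testing.assert_allclose(out.values, expected)

    def test_unit_diagonal_means(self, raw_map_64):
        out = distance_normalize(raw_map_64)
        for d in range(64):
            assert np.diagonal(out.values, d).mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_diagonal_maps_to_zero(self):
        vals = np.eye(4)
        out = distance_normalize(ContactMap(vals))
        assert np.all(np.diagonal(out.values, 2) == 0.0)


class TestCompartmentPC1:
    def test_checkerboard_partition(self):
        # two-block plaid: brute-force eigendecomposition oracle
        m = 16
        block = np.array([i < m // 2 for i in range(m)])
        vals = np.where(block[:, None] == block[None, :], 2.0, 0.5)
        vals = vals + np.eye(m)
        nm = distance_normalize(ContactMap(vals))
        pc1 = compartment_pc1(nm)
        signs = np.sign(pc1)
        assert len(set(signs[: m // 2])) == 1
        assert len(set(signs[m // 2 :])) == 1
        assert signs[0] != signs[-1]

    def test_constant_map_degenerate(self):
        nm = distance_normalize(ContactMap(np.ones((8, 8))))
        with pytest.warns(UserWarning, match="degenerate"):
            pc1 = compartment_pc1(nm)
        np.testing.assert_array_equal(pc1, np.zeros(8))

    def test_scale_invariant_direction(self, raw_map_64):
        nm = distance_normalize(raw_map_64)
        p1 = compartment_pc1(nm)
        nm2 = type(nm)(2.0 * nm.values)
        p2 = compartment_pc1(nm2)
        cos = np.dot(p1, p2) / (np.linalg.norm(p1) * np.linalg.norm(p2))
        assert abs(cos) == pytest.approx(1.0, abs=1e-9)

    def test_nonfinite_rejected(self):
        vals = np.ones((4, 4))
        vals[0, 0] = np.nan
        from hicpoly.preprocess import NormalizedMap

        with pytest.raises(ValueError, match="finite"):
            compartment_pc1(NormalizedMap(vals))


class TestCoarsen:
    def test_all_ones(self):
        out = coarsen_2x(ContactMap(np.ones((4, 4))))
        np.testing.assert_array_equal(out.values, 4.0 * np.ones((2, 2)))
        assert out.resolution_bp == 100_000

    def test_mass_conserved(self, raw_map_64):
        out = coarsen_2x(raw_map_64)
        assert out.values.sum() == pytest.approx(raw_map_64.values.sum(), rel=1e-12)

    def test_matches_double_loop(self, raw_map_32):
        out = coarsen_2x(raw_map_32)
        v = raw_map_32.values
        for i in range(16):
            for j in range(16):
                block = v[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].sum()
                assert out.values[i, j] == pytest.approx(block, rel=1e-12)

    def test_odd_m_rejected(self):
        with pytest.raises(ValueError, match="even"):
            coarsen_2x(ContactMap(np.ones((3, 3))))


class TestContactScaling:
    def test_identity_matrix(self):
        curve = contact_scaling(ContactMap(np.eye(5)))
        np.testing.assert_allclose(curve.probabilities, [1, 0, 0, 0, 0])

    def test_toeplitz(self):
        from scipy.linalg import toeplitz

        curve = contact_scaling(ContactMap(toeplitz([1.0, 0.5, 0.25])))
        np.testing.assert_allclose(curve.probabilities, [1.0, 0.5, 0.25])

    def test_matches_double_loop(self, raw_map_32):
        curve = contact_scaling(raw_map_32)
        v = raw_map_32.values
        for d in range(32):
            vals = [v[i, i + d] for i in range(32 - d)]
            assert curve.probabilities[d] == pytest.approx(np.mean(vals), rel=1e-12)


@st.composite
def _positive_symmetric(draw):
    m = draw(st.integers(min_value=3, max_value=12))
    flat = draw(
        hnp.arrays(
            np.float64,
            (m, m),
            elements=st.floats(0.01, 100.0, allow_nan=False),
        )
    )
    return 0.5 * (flat + flat.T)


@given(_positive_symmetric())
@settings(max_examples=40, deadline=None)
def test_property_normalize_idempotent(vals):
    cmap = ContactMap(vals)
    once = normalize_map(cmap)
    twice = normalize_map(once)
    np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


@given(_positive_symmetric())
@settings(max_examples=40, deadline=None)
def test_property_distance_normalize_unit_diag_means(vals):
    out = distance_normalize(ContactMap(vals))
    m = vals.shape[0]
    for d in range(m):
        mean = np.diagonal(out.values, d).mean()
        assert mean == pytest.approx(1.0, abs=1e-9)


@given(_positive_symmetric())
@settings(max_examples=40, deadline=None)
def test_property_coarsen_conserves_mass(vals):
    m = vals.shape[0]
    if m % 2:
        vals = vals[: m - 1, : m - 1]
    if vals.shape[0] < 2:
        return
    out = coarsen_2x(ContactMap(vals))
    assert out.values.sum() == pytest.approx(vals.sum(), rel=1e-12)
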