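"""Wulff construction, facet classification and crystallographic utilities."""

import math
from itertools import product

import numpy as np
import pytest

from nanofacet import crystal
from nanofacet.crystal import (
    BULK,
    EDGE,
    F100,
    F111,
    LatticeSpec,
    MillerPlane,
    WulffSpec,
    atomic_packing_factor,
    build_wulff_nanoparticle,
    classify_atoms,
    equivalent_diameter,
    interplanar_angle,
    rotate_particle,
)


def brute_force_wulff_count(lattice, gamma_ratio, target_diameter):
    """Independent oracle: enumerate every FCC lattice point inside the
    Wulff polyhedron at each candidate scale and pick the atom count nearest
    the target mass (ties toward smaller)."""
    a = lattice.lattice_constant
    n_target = (math.pi / 6.0) * target_diameter**3 / (a**3 / 4.0)
    m = int(math.ceil((0.8 * target_diameter + a) / (a / 2.0)))
    normals_100 = []
    for ax in range(3):
        for s in (1, -1):
            v = [0.0, 0.0, 0.0]
            v[ax] = float(s)
            normals_100.append(v)
    normals_111 = [
        [s1 / math.sqrt(3), s2 / math.sqrt(3), s3 / math.sqrt(3)]
        for s1, s2, s3 in product((1, -1), repeat=3)
    ]
    scales = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            for k in range(-m, m + 1):
                if (i + j + k) % 2:
                    continue
                x = (i * a / 2.0, j * a / 2.0, k * a / 2.0)
                s100 = max(abs(sum(xc * nc for xc, nc in zip(x, n)))
                           for n in normals_100)
                s111 = max(abs(sum(xc * nc for xc, nc in zip(x, n)))
                           for n in normals_111)
                scales.append(max(s100, s111 / gamma_ratio))
    scales.sort()
    best_count, best_gap = None, None
    prev = None
    for idx, s in enumerate(scales):
        count = idx + 1
        if idx + 1 < len(scales) and abs(scales[idx + 1] - s) < 1e-9:
            continue  # not a plateau boundary yet
        gap = abs(count - n_target)
        if best_gap is None or gap < best_gap - 1e-12:
            best_count, best_gap = count, gap
    return best_count


class TestBuildWulff:
    def test_reference_particle_atom_count_and_diameter(self, gold):
        particle = build_wulff_nanoparticle(gold, WulffSpec(0.96, 4.0))
        assert len(particle) == 1925
        assert equivalent_diameter(particle) == pytest.approx(3.96, abs=0.01)

    def test_single_atom_cluster_is_edge_labelled(self, gold):
        # target mass of ~one atom
        d_one = (6.0 * gold.atom_volume / math.pi) ** (1 / 3)
        particle = build_wulff_nanoparticle(gold, WulffSpec(0.96, d_one))
        assert len(particle) == 1
        assert np.allclose(particle.positions, 0.0)
        assert particle.facet_labels[0] == EDGE

    @pytest.mark.parametrize("gamma_ratio", [0.7, 0.96, 1.4])
    def test_matches_brute_force_enumeration_oracle(self, gold, gamma_ratio):
        particle = build_wulff_nanoparticle(gold, WulffSpec(gamma_ratio, 2.0))
        assert len(particle) == brute_force_wulff_count(gold, gamma_ratio, 2.0)

    def test_too_small_target_raises(self, gold):
        with pytest.raises(ValueError, match="target below minimal cluster"):
            build_wulff_nanoparticle(gold, WulffSpec(0.96, 0.05))

    def test_non_fcc_unsupported(self):
        with pytest.raises(ValueError, match="FCC"):
            LatticeSpec(structure="bcc")

    def test_f111_share_non_increasing_in_gamma_ratio(self, gold):
        shares = []
        for gamma in (0.7, 0.96, 1.2, 1.4):
            p = build_wulff_nanoparticle(gold, WulffSpec(gamma, 4.0))
            counts = p.facet_counts()
            surface = counts[F111] + counts[F100] + counts[EDGE]
            shares.append(counts[F111] / surface)
        assert all(a >= b for a, b in zip(shares, shares[1:]))

    def test_octahedral_rotation_symmetry(self, gold):
        particle = build_wulff_nanoparticle(gold, WulffSpec(0.96, 2.0))
        pos = particle.positions
        as_set = {tuple(np.round(p, 6)) for p in pos}
        # generators of the octahedral rotation group
        rot_z = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        rot_diag = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=float)
        for rot in (rot_z, rot_diag):
            rotated = {tuple(np.round(p, 6)) for p in pos @ rot.T}
            assert rotated == as_set

    def test_minimum_interatomic_distance(self, reference_particle, gold):
        from scipy.spatial import cKDTree

        d, _ = cKDTree(reference_particle.positions).query(
            reference_particle.positions, k=2)
        assert d[:, 1].min() >= 0.9 * gold.nearest_neighbor_distance


class TestClassifyAtoms:
    def test_interior_atom_of_fcc_block_is_bulk(self, gold):
        a = gold.lattice_constant
        rng = np.arange(-4, 5)
        i, j, k = np.meshgrid(rng, rng, rng, indexing="ij")
        keep = (i + j + k) % 2 == 0
        pts = np.stack([i[keep], j[keep], k[keep]], 1) * (a / 2)
        particle = crystal.FacetedNanoparticle(
            positions=pts, element="Au",
            facet_labels=np.full(len(pts), EDGE), lattice=gold)
        labels = classify_atoms(particle)
        center = int(np.argmin(np.linalg.norm(pts, axis=1)))
        assert labels[center] == BULK

    @staticmethod
    def _slab_labels(gold, normal):
        """Build a finite slab thick/wide enough that its face centers see
        ideal coordination; return label of an atom in the face center."""
        a = gold.lattice_constant
        rng = np.arange(-6, 7)
        i, j, k = np.meshgrid(rng, rng, rng, indexing="ij")
        keep = (i + j + k) % 2 == 0
        pts = np.stack([i[keep], j[keep], k[keep]], 1) * (a / 2)
        n = np.asarray(normal, float)
        n /= np.linalg.norm(n)
        proj = pts @ n
        slab = pts[(proj <= proj.max() - 2.2 * a)]  # cut the top off
        proj = slab @ n
        particle = crystal.FacetedNanoparticle(
            positions=slab, element="Au",
            facet_labels=np.full(len(slab), EDGE), lattice=gold)
        labels = classify_atoms(particle)
        # top-layer atom nearest the lateral center
        top = np.abs(proj - proj.max()) < 1e-6
        lateral = slab - np.outer(proj, n)
        candidates = np.flatnonzero(top)
        center = candidates[np.argmin(np.linalg.norm(lateral[top], axis=1))]
        # independent O(N^2) neighbor count for that atom
        d = np.linalg.norm(slab - slab[center], axis=1)
        cn = int(((d > 1e-9) & (d < 0.34)).sum())
        return labels[center], cn

    def test_top_layer_of_111_slab(self, gold):
        label, cn = self._slab_labels(gold, (1, 1, 1))
        assert cn == 9
        assert label == F111

    def test_top_layer_of_100_slab(self, gold):
        label, cn = self._slab_labels(gold, (0, 0, 1))
        assert cn == 8
        assert label == F100

    def test_agrees_with_quadratic_neighbor_oracle(self, small_particle):
        pos = small_particle.positions
        n = len(pos)
        cutoff = 0.34
        cn = np.array([
            int(sum(
                0 < np.linalg.norm(pos[j] - pos[i]) < cutoff for j in range(n)
            ))
            for i in range(n)
        ])
        expected = np.full(n, EDGE, dtype="U4")
        expected[cn == 12] = BULK
        expected[cn == 9] = F111
        expected[cn == 8] = F100
        assert (classify_atoms(small_particle) == expected).all()

    def test_cutoff_outside_shells_rejected(self, small_particle):
        with pytest.raises(ValueError, match="ambiguous shell cutoff"):
            classify_atoms(small_particle, neighbor_cutoff=0.5)
        with pytest.raises(ValueError, match="ambiguous shell cutoff"):
            classify_atoms(small_particle, neighbor_cutoff=0.2)


class TestPlaneGeometry:
    def test_packing_factors(self):
        assert atomic_packing_factor(MillerPlane((1, 1, 1))) == pytest.approx(
            0.907, abs=5e-4)
        assert atomic_packing_factor(MillerPlane((1, 0, 0))) == pytest.approx(
            0.785, abs=5e-4)

    def test_packing_111_equals_hexagonal_disc_packing(self):
        assert atomic_packing_factor(MillerPlane((1, 1, 1))) == pytest.approx(
            math.pi / (2 * math.sqrt(3)), abs=1e-12)

    def test_unsupported_plane_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            atomic_packing_factor(MillerPlane((1, 1, 0)))

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 0, 0), (1, 1, 1), 54.7356),
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (1, 1, 0), 45.0),
        ],
    )
    def test_interplanar_angles(self, a, b, expected):
        angle = interplanar_angle(MillerPlane(a), MillerPlane(b))
        assert angle == pytest.approx(expected, abs=1e-3)

    def test_zero_plane_rejected(self):
        with pytest.raises(ValueError):
            MillerPlane((0, 0, 0))


class TestRotation:
    def test_identity_and_full_turn(self, small_particle):
        for theta in (0.0, 360.0):
            rotated = rotate_particle(small_particle, (0, 0, 1), theta)
            np.testing.assert_allclose(
                rotated.positions, small_particle.positions, atol=1e-9)

    def test_distances_preserved(self, small_particle, rng):
        axis = rng.normal(size=3)
        rotated = rotate_particle(small_particle, axis, 37.3)
        d0 = np.linalg.norm(
            small_particle.positions[0] - small_particle.positions, axis=1)
        d1 = np.linalg.norm(rotated.positions[0] - rotated.positions, axis=1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)
        assert (rotated.facet_labels == small_particle.facet_labels).all()

    def test_111_normal_maps_onto_100_normal(self, small_particle):
        n111 = np.array([1.0, 1.0, 1.0]) / math.sqrt(3)
        n100 = np.array([0.0, 0.0, 1.0])
        axis = np.cross(n111, n100)
        theta = interplanar_angle(MillerPlane((1, 1, 1)), MillerPlane((0, 0, 1)))
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec(axis / np.linalg.norm(axis)
                                   * math.radians(theta))
        np.testing.assert_allclose(rot.apply(n111), n100, atol=1e-9)

    def test_zero_axis_rejected(self, small_particle):
        with pytest.raises(ValueError, match="nonzero"):
            rotate_particle(small_particle, (0, 0, 0), 10.0)


class TestEquivalentDiameter:
    def test_one_unit_cell(self, gold):
        a = gold.lattice_constant
        expected = (6 * a**3 / math.pi) ** (1 / 3)
        assert equivalent_diameter(4, gold) == pytest.approx(expected, rel=1e-12)

    def test_empty_particle_rejected(self, gold):
        with pytest.raises(ValueError, match="empty"):
            equivalent_diameter(0, gold)
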