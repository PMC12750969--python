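"""Superimposition: centering, scaling, rotation recovery, metric axioms."""

import numpy as np
import pytest

from vertmorph import (
    centroid_size,
    generalized_procrustes,
    optimal_align,
    procrustes_distance,
)
from vertmorph.synthetic import default_base_shape

from conftest import random_rotation


SQUARE = np.array([[1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [-1.0, -1.0, 0.0]])


class TestCentroidSize:
    def test_analytic_square(self):
        assert centroid_size(SQUARE) == pytest.approx(np.sqrt(8.0))

    def test_translation_invariance(self):
        assert centroid_size(SQUARE + np.array([5.0, 5.0, 5.0])) == pytest.approx(
            np.sqrt(8.0)
        )

    def test_rotation_invariance(self, rng):
        shape = rng.standard_normal((30, 3))
        for _ in range(5):
            rotated = shape @ random_rotation(rng)
            assert centroid_size(rotated) == pytest.approx(
                centroid_size(shape), abs=1e-12
            )

    def test_coincident_landmarks_error(self):
        with pytest.raises(ValueError, match="coincident"):
            centroid_size(np.ones((5, 3)))


class TestOptimalAlign:
    @staticmethod
    def _unit(shape):
        c = shape - shape.mean(axis=0)
        return c / np.sqrt(np.sum(c**2))

    def test_identity_on_self(self, rng):
        shape = self._unit(rng.standard_normal((10, 3)))
        rot, aligned, residual = optimal_align(shape, shape)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert residual < 1e-12

    def test_recovers_90_degree_z_rotation(self, rng):
        shape = self._unit(rng.standard_normal((10, 3)))
        rz = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        rot, _, residual = optimal_align(shape @ rz, shape)
        assert residual < 1e-9
        assert np.trace(rot) == pytest.approx(1.0, abs=1e-9)  # trace of Rz(90 deg)

    def test_recovers_random_rotations(self, rng):
        shape = self._unit(rng.standard_normal((12, 3)))
        for _ in range(100):
            applied = random_rotation(rng)
            rot, _, _ = optimal_align(shape @ applied, shape)
            assert np.linalg.norm(rot - applied.T) < 1e-8

    def test_rotation_is_proper(self, rng):
        # even aligning a mirrored shape must return det(+1)
        shape = self._unit(rng.standard_normal((15, 3)))
        mirrored = shape * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = optimal_align(self._unit(mirrored), shape)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_uncentered_input_rejected(self, rng):
        shape = self._unit(rng.standard_normal((8, 3)))
        with pytest.raises(ValueError, match="centered"):
            optimal_align(shape + 1.0, shape)


class TestGeneralizedProcrustes:
    def test_single_shape_recovery(self, rng):
        base = default_base_shape()
        configs = []
        for _ in range(8):
            scale = float(rng.uniform(0.5, 20.0))
            configs.append(
                scale * base @ random_rotation(rng) + rng.uniform(-10, 10, size=3)
            )
        block = generalized_procrustes(np.stack(configs))
        assert block.converged
        for i in range(8):
            for j in range(i + 1, 8):
                assert procrustes_distance(block.aligned[i], block.aligned[j]) < 1e-9

    def test_alignment_invariants(self, lf_block):
        centroids = lf_block.aligned.mean(axis=1)
        assert np.abs(centroids).max() < 1e-9
        sizes = np.sqrt((lf_block.aligned**2).sum(axis=(1, 2)))
        assert np.abs(sizes - 1.0).max() < 1e-9
        assert np.allclose(lf_block.consensus, lf_block.aligned.mean(axis=0), atol=1e-12)

    def test_two_shape_symmetry(self, rng):
        a = default_base_shape()
        b = a + 0.05 * rng.standard_normal(a.shape)
        block = generalized_procrustes(np.stack([a, b]))
        r0 = np.sqrt(np.sum((block.aligned[0] - block.consensus) ** 2))
        r1 = np.sqrt(np.sum((block.aligned[1] - block.consensus) ** 2))
        assert r0 == pytest.approx(r1, abs=1e-9)

    def test_invariance_to_pre_rotation(self, rng, lf_block):
        sub = lf_block.aligned[:6].copy()
        rotated = np.stack([cfg @ random_rotation(rng) for cfg in sub])
        block_a = generalized_procrustes(sub)
        block_b = generalized_procrustes(rotated)
        # compare via Procrustes distances, which are frame-independent
        for i in range(6):
            for j in range(i + 1, 6):
                da = procrustes_distance(block_a.aligned[i], block_a.aligned[j])
                db = procrustes_distance(block_b.aligned[i], block_b.aligned[j])
                assert da == pytest.approx(db, abs=1e-8)

    def test_consensus_is_fixed_point(self, lf_block):
        # one more explicit iteration against the converged consensus moves it
        # by less than the convergence tolerance
        target = lf_block.consensus / np.sqrt(np.sum(lf_block.consensus**2))
        realigned = np.stack(
            [optimal_align(cfg, target)[1] for cfg in lf_block.aligned]
        )
        new_consensus = realigned.mean(axis=0)
        assert np.linalg.norm(new_consensus - lf_block.consensus) < 1e-7

    def test_requires_two_configurations(self):
        with pytest.raises(ValueError, match="at least 2"):
            generalized_procrustes(default_base_shape()[None])


class TestProcrustesDistance:
    def test_identical_shapes_zero(self):
        base = default_base_shape()
        assert procrustes_distance(base, base) < 1e-12

    def test_symmetry(self, rng, lf_block):
        for _ in range(20):
            i, j = rng.choice(lf_block.n_specimens, size=2, replace=False)
            dij = procrustes_distance(lf_block.aligned[i], lf_block.aligned[j])
            dji = procrustes_distance(lf_block.aligned[j], lf_block.aligned[i])
            assert dij == pytest.approx(dji, abs=1e-12)

    def test_triangle_inequality(self, rng):
        base = default_base_shape()
        shapes = []
        for _ in range(12):
            noisy = base + 0.1 * rng.standard_normal(base.shape)
            c = noisy - noisy.mean(axis=0)
            shapes.append(c / np.sqrt(np.sum(c**2)))
        for _ in range(100):
            a, b, c = rng.choice(12, size=3, replace=False)
            dab = procrustes_distance(shapes[a], shapes[b])
            dbc = procrustes_distance(shapes[b], shapes[c])
            dac = procrustes_distance(shapes[a], shapes[c])
            assert dac <= dab + dbc + 1e-12

    def test_landmark_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            procrustes_distance(default_base_shape(30), default_base_shape(20))
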