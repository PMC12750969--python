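"""Generalized Procrustes superimposition of 3D landmark configurations.

Removes translation (centering), scale (unit centroid size) and orientation
(least-squares rotation, reflections excluded) so that the remaining variation
among configurations is pure shape.  The iterative scheme follows the standard
generalized Procrustes algorithm: all configurations are aligned to a running
consensus, the consensus is recomputed, and the loop repeats until the
consensus stops moving.

Conventions
-----------
* Configurations are ``(k, 3)`` arrays of landmark coordinates, rows in
  homologous order across specimens.
* Aligned shapes are dimensionless: centroid at the origin, centroid size 1.
* Reflections are never admitted as alignments (vertebrae are chirally
  consistent objects); fitted rotations always have determinant +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignedBlock",
    "centroid_size",
    "optimal_align",
    "generalized_procrustes",
    "procrustes_distance",
]


@dataclass
class AlignedBlock:
    """GPA output for one vertebral position.

    Attributes
    ----------
    position : str
        Vertebral position label (``CF`` ... ``LL``), or any block name.
    aligned : ndarray, shape (n, k, 3)
        Superimposed configurations: centered, unit centroid size, rotated
        onto the consensus.
    consensus : ndarray, shape (k, 3)
        Arithmetic mean of the aligned configurations.
    centroid_sizes : ndarray, shape (n,)
        Original centroid sizes (scanner units), recorded before rescaling;
        used downstream as the size covariate in phylogenetic regressions.
    iterations : int
        Number of consensus updates performed.
    converged : bool
        Whether the consensus change fell below ``tol`` within ``max_iter``.
    specimen_ids : list of str
        Row labels for ``aligned``; synthesized as ``"0", "1", ...`` when the
        caller supplies none.
    """

    position: str
    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    specimen_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.specimen_ids:
            self.specimen_ids = [str(i) for i in range(self.aligned.shape[0])]

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def as_matrix(self) -> np.ndarray:
        """Vectorized aligned shapes, shape ``(n, 3k)`` (row-major per landmark)."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid.

    The standard geometric-morphometrics size measure; invariant to
    translation and rotation of the configuration.

    Raises
    ------
    ValueError
        If all landmarks coincide (size would be zero).
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2:
        raise ValueError("configuration must be a (landmarks, dims) matrix")
    centered = config - config.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size <= 0.0 or not np.isfinite(size):
        raise ValueError("degenerate configuration: all landmarks coincident")
    return size


def _center_and_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    size = centroid_size(config)
    centered = config - config.mean(axis=0)
    return centered / size, size


def _optimal_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Sign-corrected Kabsch rotation mapping ``moving`` onto ``target``.

    Returns the proper rotation R (det = +1) minimizing
    ``||moving @ R - target||_F`` over SO(3).
    """
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


def optimal_align(
    moving: np.ndarray,
    target: np.ndarray,
    *,
    atol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Ordinary Procrustes rotation of one centered shape onto another.

    Parameters
    ----------
    moving, target : ndarray, shape (k, 3)
        Centered configurations of unit centroid size.
    atol : float
        Tolerance for the centering / unit-size precondition check.

    Returns
    -------
    rotation : ndarray (3, 3)
        Proper orthonormal matrix, ``det = +1``.
    aligned : ndarray (k, 3)
        ``moving @ rotation``.
    residual : float
        Root summed squared coordinate difference after rotation (minimal
        over all proper rotations).
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape:
        raise ValueError("shape mismatch between moving and target")
    for name, cfg in (("moving", moving), ("target", target)):
        if np.linalg.norm(cfg.mean(axis=0)) > atol:
            raise ValueError(f"{name} configuration is not centered")
    rotation = _optimal_rotation(moving, target)
    aligned = moving @ rotation
    residual = float(np.sqrt(np.sum((aligned - target) ** 2)))
    return rotation, aligned, residual


def generalized_procrustes(
    configs: "np.ndarray | list[np.ndarray]",
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    position: str = "",
    specimen_ids: "list[str] | None" = None,
    tangent_project: bool = False,
) -> AlignedBlock:
    """Iterative generalized Procrustes superimposition.

    All configurations are centered and scaled to unit centroid size, then
    repeatedly rotated onto the current consensus; the consensus is the mean
    of the rotated shapes, renormalized to unit size between iterations.  The
    loop stops when the Frobenius change of the consensus drops below ``tol``.
    The stored consensus is the plain arithmetic mean of the final aligned
    shapes (not renormalized), so it equals ``aligned.mean(axis=0)`` exactly.

    Parameters
    ----------
    configs : sequence of (k, 3) arrays or (n, k, 3) array
        At least two configurations with a common landmark count.
    tol, max_iter : float, int
        Convergence tolerance on the consensus and the iteration cap.  On
        non-convergence the partial result is returned with
        ``converged=False`` rather than raising.
    tangent_project : bool
        If True, orthogonally project the aligned shapes onto the tangent
        space at the consensus (linearization of shape space).  Off by
        default; principal component analyses operate directly on aligned
        coordinates.
    """
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected (n_specimens, n_landmarks, 3) input")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("generalized Procrustes needs at least 2 configurations")

    sizes = np.empty(n)
    scaled = np.empty_like(arr)
    for i in range(n):
        scaled[i], sizes[i] = _center_and_scale(arr[i])

    consensus = scaled[0].copy()  # initial reference: first specimen
    aligned = scaled.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            rot = _optimal_rotation(scaled[i], consensus)
            aligned[i] = scaled[i] @ rot
        new_consensus = aligned.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        delta = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break

    if tangent_project:
        u = consensus.ravel()
        u = u / np.linalg.norm(u)
        flat = aligned.reshape(n, -1)
        coeff = flat @ u
        flat = flat - np.outer(coeff - 1.0, u)  # consensus has unit norm
        aligned = flat.reshape(n, -1, 3)

    return AlignedBlock(
        position=position,
        aligned=aligned,
        consensus=aligned.mean(axis=0),
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        specimen_ids=list(specimen_ids) if specimen_ids else [],
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray, *, atol: float = 1e-6) -> float:
    """Procrustes distance between two centered unit-size configurations.

    Root summed squared coordinate difference after optimally rotating ``a``
    onto ``b``.  Symmetric; zero iff the shapes are identical up to rotation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("landmark count mismatch")
    _, _, residual = optimal_align(a, b, atol=atol)
    return residual
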