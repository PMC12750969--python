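"""Shape-space ordination: per-vertebra PCA and multi-block combination.

A principal component analysis of the vectorized Procrustes-aligned
coordinates summarizes each vertebra's shape variation as PC scores.  For
multi-element analyses, several vertebrae (each superimposed separately) are
vectorized, column-centered, optionally scaled to unit total variance per
block, concatenated, and ordinated in one global PCA — so landmark-rich or
high-variance elements cannot dominate the combined morphospace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpa import AlignedBlock

__all__ = ["ShapeSpace", "MultiBlockSpace", "fit_pca", "project", "reconstruct",
           "combine_blocks"]


@dataclass
class ShapeSpace:
    """PCA basis over vectorized aligned shapes.

    ``scores = (X - mean_vector) @ eigenvectors`` for the training matrix X;
    eigenvalues use the N-1 divisor and are sorted descending.  Eigenvector
    sign is fixed by making each vector's largest-magnitude loading positive,
    so results are deterministic across runs and BLAS backends.
    """

    mean_vector: np.ndarray       # (p,)
    eigenvectors: np.ndarray      # (p, k), orthonormal columns
    eigenvalues: np.ndarray       # (k,), descending
    scores: np.ndarray            # (n, k)
    variance_fraction: np.ndarray  # (k,), sums to 1 (all zero if no variance)
    specimen_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)


def _fix_signs(eigenvectors: np.ndarray, scores: np.ndarray) -> None:
    for j in range(eigenvectors.shape[1]):
        i = int(np.argmax(np.abs(eigenvectors[:, j])))
        if eigenvectors[i, j] < 0:
            eigenvectors[:, j] *= -1.0
            scores[:, j] *= -1.0


def _pca(matrix: np.ndarray, specimen_ids: list[str]) -> ShapeSpace:
    n, p = matrix.shape
    mean = matrix.mean(axis=0)
    centered = matrix - mean
    # SVD route: numerically stable eigendecomposition of the covariance
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n - 1, p)
    s = s[:k]
    eigenvalues = s**2 / (n - 1)
    eigenvectors = vt[:k].T.copy()
    scores = centered @ eigenvectors
    _fix_signs(eigenvectors, scores)
    total = eigenvalues.sum()
    if total > 0:
        variance_fraction = eigenvalues / total
    else:
        variance_fraction = np.zeros_like(eigenvalues)
        scores = np.zeros_like(scores)
    return ShapeSpace(
        mean_vector=mean,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        scores=scores,
        variance_fraction=variance_fraction,
        specimen_ids=list(specimen_ids),
    )


def fit_pca(block: "AlignedBlock | np.ndarray", specimen_ids=None) -> ShapeSpace:
    """PCA of the covariance of vectorized aligned coordinates.

    Retains ``k = min(n_specimens - 1, 3 * n_landmarks)`` components.  With
    identical specimens all eigenvalues (and scores) are zero.
    """
    if isinstance(block, AlignedBlock):
        matrix = block.as_matrix()
        specimen_ids = block.specimen_ids
    else:
        matrix = np.asarray(block, dtype=float)
        if matrix.ndim == 3:
            matrix = matrix.reshape(matrix.shape[0], -1)
        if specimen_ids is None:
            specimen_ids = [str(i) for i in range(matrix.shape[0])]
    if matrix.shape[0] < 3:
        raise ValueError("PCA needs at least 3 specimens")
    return _pca(matrix, specimen_ids)


def project(
    space: ShapeSpace,
    config: np.ndarray,
    *,
    check: bool = True,
    atol: float = 1e-2,
) -> np.ndarray:
    """Score an aligned configuration in an existing shape space.

    The configuration must already be superimposed on the space's consensus
    (centered, unit centroid size, optimally rotated); ``check`` enforces the
    centering and size preconditions to ``atol``.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim == 2:
        if check:
            if np.linalg.norm(config.mean(axis=0)) > atol:
                raise ValueError("configuration is not centered")
            size = np.sqrt(np.sum((config - config.mean(axis=0)) ** 2))
            if abs(size - 1.0) > atol:
                raise ValueError(f"configuration is not unit centroid size ({size:.4f})")
        vec = config.ravel()
    else:
        vec = config
    if vec.shape[0] != space.mean_vector.shape[0]:
        raise ValueError("landmark count mismatch with shape space")
    return (vec - space.mean_vector) @ space.eigenvectors


def reconstruct(space: ShapeSpace, scores: np.ndarray) -> np.ndarray:
    """Inverse transform: scores back to a vectorized configuration."""
    scores = np.asarray(scores, dtype=float)
    return space.mean_vector + scores @ space.eigenvectors[:, : scores.shape[-1]].T


@dataclass
class MultiBlockSpace:
    """Combined shape space over several vertebral blocks.

    ``blocks`` records, per element, the source AlignedBlock and the scale
    factor its centered sub-matrix was divided by (1.0 when scaling is off);
    only specimens present in every block enter the combined analysis, in
    sorted-id order.
    """

    blocks: list[tuple[str, AlignedBlock, float]]
    specimen_ids: list[str]
    space: ShapeSpace
    block_slices: list[slice]
    block_means: list[np.ndarray]

    @property
    def combined_scores(self) -> np.ndarray:
        return self.space.scores

    def project_configs(self, configs: "dict[str, np.ndarray]") -> np.ndarray:
        """Score an external specimen given one superimposed configuration per
        block position (each already aligned to that block's consensus,
        centered, unit centroid size)."""
        parts = []
        for (position, _, factor), mean in zip(self.blocks, self.block_means):
            if position not in configs:
                raise KeyError(f"no configuration supplied for block {position!r}")
            vec = np.asarray(configs[position], dtype=float).ravel()
            if vec.shape[0] != mean.shape[0]:
                raise ValueError(f"landmark count mismatch in block {position!r}")
            parts.append((vec - mean) / factor)
        combined = np.concatenate(parts)
        return (combined - self.space.mean_vector) @ self.space.eigenvectors


def combine_blocks(
    blocks: "list[AlignedBlock]",
    scale_blocks: bool = True,
) -> MultiBlockSpace:
    """Concatenate per-element shape matrices and ordinate them jointly.

    Each block is vectorized and column-centered over the common specimens;
    with ``scale_blocks`` each centered sub-matrix is divided by the square
    root of its total variance so every element contributes unit variance.
    A single global PCA of the concatenation yields the combined scores.
    """
    if not blocks:
        raise ValueError("no blocks supplied")
    common = set(blocks[0].specimen_ids)
    for blk in blocks[1:]:
        common &= set(blk.specimen_ids)
    if not common:
        raise ValueError("blocks share no specimens")
    specimen_ids = sorted(common)

    parts = []
    kept: list[tuple[str, AlignedBlock, float]] = []
    slices: list[slice] = []
    means: list[np.ndarray] = []
    offset = 0
    for blk in blocks:
        rows = [blk.specimen_ids.index(s) for s in specimen_ids]
        sub = blk.as_matrix()[rows]
        means.append(sub.mean(axis=0))
        centered = sub - sub.mean(axis=0)
        factor = 1.0
        if scale_blocks:
            total_var = centered.var(axis=0, ddof=1).sum()
            if total_var > 0:
                factor = float(np.sqrt(total_var))
                centered = centered / factor
        parts.append(centered)
        kept.append((blk.position, blk, factor))
        slices.append(slice(offset, offset + sub.shape[1]))
        offset += sub.shape[1]

    concatenated = np.hstack(parts)
    if concatenated.shape[0] < 3:
        raise ValueError("multi-block PCA needs at least 3 common specimens")
    space = _pca(concatenated, specimen_ids)
    return MultiBlockSpace(
        blocks=kept,
        specimen_ids=specimen_ids,
        space=space,
        block_slices=slices,
        block_means=means,
    )
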