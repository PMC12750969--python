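"""Distance-based PERMANOVA: global and pairwise tests of group separation.

The pseudo-F statistic partitions summed squared inter-point distances into
between- and within-group components,

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    F         = (SS_between / (g - 1)) / (SS_within / (N - g)),

with significance assessed by random relabelling of observations.  Distances
default to Euclidean on vectorized Procrustes-aligned coordinates (the
tangent-space approximation of Procrustes distance); the exact Procrustes
metric is available as a switch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .gpa import procrustes_distance

__all__ = [
    "PermanovaResult",
    "pseudo_f",
    "permanova",
    "pairwise_permanova",
    "distance_matrix",
]

#: Reporting convention: pairwise comparisons with p at or below this are
#: flagged as significant (no further multiplicity correction by default).
REPORT_ALPHA = 0.005


@dataclass
class PermanovaResult:
    comparison: str            # "global" or "levelA vs levelB"
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int
    n_obs: int
    significant: bool = False

    def __post_init__(self) -> None:
        self.significant = self.p_value <= REPORT_ALPHA


def distance_matrix(data: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Square distance matrix from observations.

    ``data`` may be (n, p) vectors or (n, k, 3) aligned shapes.  With
    ``metric="procrustes"`` the exact pairwise Procrustes distance is used
    (requires shape input); otherwise Euclidean on the vectorized rows.
    """
    data = np.asarray(data, dtype=float)
    if metric == "procrustes":
        if data.ndim != 3:
            raise ValueError("procrustes metric requires (n, landmarks, 3) shapes")
        n = data.shape[0]
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = procrustes_distance(data[i], data[j])
        return dist
    if data.ndim == 3:
        data = data.reshape(data.shape[0], -1)
    return squareform(pdist(data, metric=metric))


def _as_distance(data: np.ndarray) -> np.ndarray:
    """Pass through a distance matrix; otherwise compute Euclidean distances."""
    data = np.asarray(data, dtype=float)
    if (
        data.ndim == 2
        and data.shape[0] == data.shape[1]
        and np.allclose(data, data.T)
        and np.allclose(np.diag(data), 0.0)
    ):
        return data
    return distance_matrix(data)


def _ss_parts(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)  # full matrix counts each pair twice
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_total, ss_within


def _f_from_d2(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total, ss_within = _ss_parts(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def _encode(groups) -> tuple[np.ndarray, list]:
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    codes = np.array([levels.index(g) for g in groups])
    return codes, levels


def pseudo_f(dist: np.ndarray, groups) -> float:
    """PERMANOVA pseudo-F from a distance matrix and group labels."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("dist must be square")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("dist must be symmetric with zero diagonal")
    codes, levels = _encode(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes, minlength=len(levels))
    if (counts < 2).any():
        small = [levels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups with fewer than 2 members: {small}")
    return float(_f_from_d2(dist**2, codes, len(levels)))


def permanova(
    data: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    comparison: str = "global",
) -> PermanovaResult:
    """Permutational multivariate ANOVA.

    ``data`` is a distance matrix, a score/coordinate matrix, or aligned
    shapes.  The p-value is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` under
    random relabelling, bit-reproducible given the seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99 for a meaningful p-value")
    dist = _as_distance(data)
    f_obs = pseudo_f(dist, groups)
    codes, levels = _encode(groups)
    d2 = dist**2
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _f_from_d2(d2, perm, len(levels)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(
        comparison=comparison,
        pseudo_F=f_obs,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        n_obs=dist.shape[0],
    )


def pairwise_permanova(
    data: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> list[PermanovaResult]:
    """One PERMANOVA per unordered pair of group levels.

    Each pair's test runs on the subset of observations in those two levels,
    with its own RNG stream derived as ``SeedSequence([seed, pair_index])``
    over the lexicographically ordered pairs — so results are independent of
    which other levels exist yet fully reproducible from one seed.
    """
    dist = _as_distance(data)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    results = []
    for pair_index, (a, b) in enumerate(itertools.combinations(levels, 2)):
        mask = np.isin(groups, [a, b])
        idx = np.flatnonzero(mask)
        sub = dist[np.ix_(idx, idx)]
        pair_seed = int(
            np.random.SeedSequence([int(seed), pair_index]).generate_state(1)[0]
            % (2**31)
        )
        res = permanova(
            sub, groups[idx], n_perm=n_perm, seed=pair_seed,
            comparison=f"{a} vs {b}",
        )
        results.append(res)
    return results
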