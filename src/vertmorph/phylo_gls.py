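"""Phylogenetic generalized least squares for multivariate shape data.

Under Brownian motion on a rooted tree with branch lengths, species trait
values covary in proportion to shared evolutionary history: the expected
covariance of species i and j is the root-to-MRCA path length.  Shape (the
matrix of Procrustes coordinates or PC scores) is regressed on an ecological
factor or on centroid size after whitening both sides by the inverse square
root of that covariance; effect size is R² = SS_effect / SS_total in the
transformed space and significance comes from residual-randomization
permutations (RRPP) of the reduced-model residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PGLSResult",
    "read_newick",
    "bm_covariance",
    "pgls_fit",
    "align_to_tree",
]


@dataclass
class Phylogeny:
    """Rooted, branch-length-bearing tree (thin wrapper over dendropy)."""

    tree: dendropy.Tree

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per taxon."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            leaf.taxon.label: float(leaf.root_distance)
            for leaf in self.tree.leaf_node_iter()
        }

    def prune(self, keep: "list[str]") -> "Phylogeny":
        """Restrict the tree to ``keep`` (error if any taxon is absent)."""
        have = set(self.taxa)
        missing = [s for s in keep if s not in have]
        if missing:
            raise KeyError(f"species not in tree: {missing}")
        pruned = self.tree.clone(depth=1)
        taxa = [t for t in pruned.taxon_namespace if t.label in set(keep)]
        pruned.retain_taxa(taxa)
        return Phylogeny(pruned)

    def write_newick(self, path: "str | Path") -> Path:
        path = Path(path)
        path.write_text(self.tree.as_string(schema="newick"))
        return path


def read_newick(path: "str | Path") -> Phylogeny:
    """Parse a Newick tree; duplicate tips or missing branch lengths raise."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge length is optional
        if edge.length is None:
            raise ValueError(
                "tree has edges without branch lengths; Brownian covariance undefined"
            )
    return Phylogeny(tree)


def bm_covariance(phylogeny: Phylogeny, order: "list[str]") -> np.ndarray:
    """Brownian-motion covariance matrix in a given species order.

    ``C[i, j]`` is the root-to-MRCA shared path length of species i and j;
    the diagonal holds root-to-tip depths.  Symmetric positive semidefinite
    by construction.
    """
    tree = phylogeny.tree
    depths = phylogeny.depths()
    missing = [s for s in order if s not in depths]
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    taxon_of = {t.label: t for t in tree.taxon_namespace if t.label in depths}
    n = len(order)
    cov = np.zeros((n, n))
    for i, a in enumerate(order):
        cov[i, i] = depths[a]
        for j in range(i + 1, n):
            b = order[j]
            patristic = pdm.patristic_distance(taxon_of[a], taxon_of[b])
            shared = 0.5 * (depths[a] + depths[b] - patristic)
            cov[i, j] = cov[j, i] = shared
    return cov


@dataclass
class PGLSResult:
    predictor: str
    r_squared: float
    F: float
    p_value: float
    df_effect: int
    df_residual: int
    n_permutations: int
    seed: int


def _design(x, n: int) -> np.ndarray:
    """Full design [1 | predictor]: indicator contrasts for categories."""
    x = np.asarray(x)
    if x.dtype.kind in "fiu" and x.ndim == 1:
        if np.allclose(x, x[0]):
            raise ValueError("predictor is constant")
        return np.column_stack([np.ones(n), x.astype(float)])
    levels = sorted(set(x.tolist()))
    if len(levels) < 2:
        raise ValueError("predictor is constant")
    cols = [np.ones(n)]
    for level in levels[1:]:  # drop-first coding, full rank with intercept
        cols.append((x == level).astype(float))
    return np.column_stack(cols)


def _inv_sqrt(c: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(c)
    floor = jitter * vals.max()
    if vals.min() < -floor:
        raise np.linalg.LinAlgError("covariance matrix is not PSD")
    vals = np.clip(vals, floor, None)
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def _projector(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def pgls_fit(
    Y: np.ndarray,
    X,
    C: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    predictor: str = "predictor",
) -> PGLSResult:
    """Multivariate PGLS of shape on one predictor with RRPP significance.

    Parameters
    ----------
    Y : (n, p) or (n, k, 3) array
        Species shape data (Procrustes coordinates or PC scores), rows in
        the same species order as ``X`` and ``C``.
    X : array of category labels or continuous values
        Categorical predictors are expanded to full-rank indicator contrasts
        and tested as one overall effect.
    C : (n, n) PSD matrix
        Brownian-motion covariance; rescaled internally to unit determinant
        before inversion (pure numerical conditioning — R² and p are
        invariant to scalar rescaling of C).
    n_perm, seed
        Residual-randomization permutations of the reduced (intercept-only)
        model residuals; p = (1 + #{F* >= F}) / (1 + n_perm).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 3:
        Y = Y.reshape(Y.shape[0], -1)
    n = Y.shape[0]
    C = np.asarray(C, dtype=float)
    if C.shape != (n, n):
        raise ValueError("covariance matrix does not match the number of species")

    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance matrix is singular")
    C = C / np.exp(logdet / n)  # unit determinant
    T = _inv_sqrt(C)

    design_full = T @ _design(X, n)
    design_null = T @ np.ones((n, 1))
    Yt = T @ Y

    rank_full = np.linalg.matrix_rank(design_full)
    df_effect = rank_full - 1
    df_resid = n - rank_full
    if df_effect < 1 or df_resid < 1:
        raise ValueError("insufficient degrees of freedom for the fit")

    p_null = _projector(design_null)
    p_full = _projector(design_full)

    def f_and_r2(y: np.ndarray) -> tuple[float, float]:
        resid_null = y - p_null @ y
        ss_total = float(np.sum(resid_null**2))
        resid_full = y - p_full @ y
        ss_resid = float(np.sum(resid_full**2))
        ss_effect = ss_total - ss_resid
        if ss_total <= 0:
            return 0.0, 0.0
        f = (ss_effect / df_effect) / (ss_resid / df_resid) if ss_resid > 0 else np.inf
        return f, ss_effect / ss_total

    f_obs, r2 = f_and_r2(Yt)

    fitted_null = p_null @ Yt
    resid_null = Yt - fitted_null
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_star, _ = f_and_r2(fitted_null + resid_null[perm])
        if f_star >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)

    return PGLSResult(
        predictor=predictor,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        F=float(f_obs),
        p_value=p,
        df_effect=df_effect,
        df_residual=df_resid,
        n_permutations=n_perm,
        seed=seed,
    )


def align_to_tree(
    species: "list[str]", phylogeny: Phylogeny
) -> tuple[list[str], Phylogeny]:
    """Intersect a species list with tree tips, warning about drops.

    Species absent from the tree are removed with a logged warning (never
    silently); the tree is pruned to the survivors.  Returns the retained
    species (input order) and the pruned phylogeny.
    """
    tips = set(phylogeny.taxa)
    kept = [s for s in species if s in tips]
    dropped = [s for s in species if s not in tips]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} species absent from the tree: {dropped}",
            stacklevel=2,
        )
    if len(kept) < 3:
        raise ValueError("fewer than 3 species shared between data and tree")
    return kept, phylogeny.prune(kept)
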