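"""Canonical variate analysis and ecological classification of fossils.

The extant species' PC scores train a canonical variate analysis (CVA): the
generalized eigenproblem of between-group versus pooled within-group
covariance, solved by whitening.  In the resulting canonical space the pooled
within-group covariance is the identity, so Euclidean distance to a group
mean equals the Mahalanobis distance in PC space.  A fossil configuration is
superimposed on the extant consensus, projected through the retained PC
basis and the canonical vectors, and assigned membership probabilities from
its squared distances to the group means.

Two probability flavours are reported:

* posterior — softmax over groups of ``-d²/2`` with equal priors (the
  headline "probability of membership");
* typicality — per-group chi-square tail probability of d² on r degrees of
  freedom (is the fossil plausible for that group at all?).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .gpa import optimal_align
from .shape_space import ShapeSpace, project

__all__ = [
    "CVAModel",
    "ClassificationReport",
    "FossilPrediction",
    "choose_n_pcs",
    "fit_cva",
    "classify",
    "project_external",
    "membership_probabilities",
]

STRONG_SUPPORT = 0.95  # reporting flag for well-supported predictions


@dataclass
class CVAModel:
    """Fitted canonical variate model over k retained PC scores.

    ``canonical_vectors`` (k × r) maps centered PC scores to canonical
    scores; by construction the pooled within-group covariance of the
    training canonical scores is the identity.
    """

    canonical_vectors: np.ndarray      # (k, r)
    group_means_cv: np.ndarray         # (g, r)
    group_labels: list
    pooled_within_cov: np.ndarray      # (k, k)
    mean_scores: np.ndarray            # (k,) grand mean of training PC scores
    eigenvalues: np.ndarray            # (r,) canonical roots, descending
    training_cv: np.ndarray = field(repr=False, default=None)  # (n, r)
    training_groups: np.ndarray = field(repr=False, default=None)

    @property
    def n_canonical(self) -> int:
        return self.canonical_vectors.shape[1]

    def transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return (scores - self.mean_scores) @ self.canonical_vectors


def choose_n_pcs(
    space: ShapeSpace,
    n_groups: int,
    *,
    cum_var: float = 0.95,
    cap: "int | None" = None,
) -> int:
    """Default PC retention: smallest k reaching ``cum_var`` cumulative
    variance, capped at ``n - n_groups - 1`` so the pooled within-group
    covariance stays invertible."""
    n = space.scores.shape[0]
    hard_cap = n - n_groups - 1 if cap is None else cap
    hard_cap = max(1, min(hard_cap, space.n_components))
    k = int(np.searchsorted(space.cumulative_variance(), cum_var) + 1)
    return max(1, min(k, hard_cap))


def fit_cva(
    scores: np.ndarray, groups, r: "int | None" = None, *,
    allow_singletons: bool = False,
) -> CVAModel:
    """Canonical variate analysis of PC scores against group labels.

    Solves the between/within generalized eigenproblem via within-group
    whitening; retains ``r <= min(k, g - 1)`` canonical axes.  Raises if the
    pooled within-group covariance is singular (too many PCs for the sample).
    ``allow_singletons`` admits one-member groups (they contribute nothing to
    the within-group covariance); leave-one-out refits rely on this.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    n, k = scores.shape
    levels = sorted(set(groups.tolist()))
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = {lv: int((groups == lv).sum()) for lv in levels}
    small = [lv for lv, c in counts.items() if c < 2]
    if small and not allow_singletons:
        raise ValueError(f"groups with fewer than 2 members: {small}")
    if k > n - g:
        raise ValueError(
            f"{k} PCs with {n} specimens in {g} groups leaves a singular "
            f"within-group covariance; lower k to at most {n - g}"
        )

    grand_mean = scores.mean(axis=0)
    within = np.zeros((k, k))
    means = np.empty((g, k))
    for gi, lv in enumerate(levels):
        sub = scores[groups == lv]
        means[gi] = sub.mean(axis=0)
        dev = sub - means[gi]
        within += dev.T @ dev
    within /= n - g

    centered_means = means - grand_mean
    between = np.zeros((k, k))
    for gi, lv in enumerate(levels):
        between += counts[lv] * np.outer(centered_means[gi], centered_means[gi])
    between /= max(g - 1, 1)

    w_vals, w_vecs = np.linalg.eigh(within)
    if w_vals.min() <= 1e-12 * w_vals.max():
        raise ValueError(
            "pooled within-group covariance is numerically singular; lower k"
        )
    w_isqrt = (w_vecs * (1.0 / np.sqrt(w_vals))) @ w_vecs.T

    m = w_isqrt @ between @ w_isqrt
    vals, vecs = np.linalg.eigh(m)
    order = np.argsort(vals)[::-1]
    r_max = min(k, g - 1)
    r = r_max if r is None else min(r, r_max)
    vals = np.clip(vals[order][:r], 0.0, None)
    axes = w_isqrt @ vecs[:, order][:, :r]  # A' W A = I by construction

    # deterministic sign: largest-|loading| entry of each axis positive
    for j in range(axes.shape[1]):
        i = int(np.argmax(np.abs(axes[:, j])))
        if axes[i, j] < 0:
            axes[:, j] *= -1.0

    model = CVAModel(
        canonical_vectors=axes,
        group_means_cv=(means - grand_mean) @ axes,
        group_labels=levels,
        pooled_within_cov=within,
        mean_scores=grand_mean,
        eigenvalues=vals,
    )
    model.training_cv = model.transform(scores)
    model.training_groups = groups
    return model


@dataclass
class ClassificationReport:
    confusion: np.ndarray  # (g, g) counts, rows = true, cols = predicted
    accuracy: float
    mode: str
    group_labels: list

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.confusion))

    @property
    def n_total(self) -> int:
        return int(self.confusion.sum())


def _assign(model: CVAModel, cv_scores: np.ndarray) -> np.ndarray:
    d2 = ((cv_scores[:, None, :] - model.group_means_cv[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def classify(
    scores: np.ndarray,
    groups,
    r: "int | None" = None,
    mode: str = "leave-one-out",
) -> ClassificationReport:
    """Classification accuracy of CVA nearest-group-mean assignment.

    ``mode="resubstitution"`` scores the training data through one fitted
    model; ``mode="leave-one-out"`` refits the model without each specimen
    before assigning it (the headline cross-validated accuracy).
    """
    if mode not in {"resubstitution", "leave-one-out"}:
        raise ValueError(f"unknown mode {mode!r}")
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    true_codes = np.array([levels.index(gr) for gr in groups])
    n = scores.shape[0]

    if mode == "resubstitution":
        model = fit_cva(scores, groups, r=r)
        pred = _assign(model, model.transform(scores))
    else:
        pred = np.empty(n, dtype=int)
        for i in range(n):
            mask = np.arange(n) != i
            sub_model = fit_cva(scores[mask], groups[mask], r=r, allow_singletons=True)
            cv = sub_model.transform(scores[i : i + 1])
            local = _assign(sub_model, cv)[0]
            pred[i] = levels.index(sub_model.group_labels[local])

    g = len(levels)
    confusion = np.zeros((g, g), dtype=int)
    for t, p in zip(true_codes, pred):
        confusion[t, p] += 1
    return ClassificationReport(
        confusion=confusion,
        accuracy=float(np.trace(confusion)) / n,
        mode=mode,
        group_labels=levels,
    )


def project_external(
    model: CVAModel,
    space: ShapeSpace,
    consensus: np.ndarray,
    fossil: np.ndarray,
) -> np.ndarray:
    """Project an external (fossil) configuration into canonical space.

    The configuration is centered, scaled to unit centroid size, optimally
    rotated onto the extant consensus, scored in the retained PC basis, then
    mapped by the canonical vectors.  The fossil must not be part of the
    training sample.
    """
    fossil = np.asarray(fossil, dtype=float)
    consensus = np.asarray(consensus, dtype=float)
    if fossil.shape != consensus.shape:
        raise ValueError(
            f"landmark count mismatch: fossil {fossil.shape}, consensus {consensus.shape}"
        )
    centered = fossil - fossil.mean(axis=0)
    size = np.sqrt(np.sum(centered**2))
    if size <= 0:
        raise ValueError("degenerate fossil configuration")
    unit = centered / size
    target = consensus - consensus.mean(axis=0)
    _, aligned, _ = optimal_align(unit, target / np.sqrt(np.sum(target**2)))
    # re-inflate target scale: PC projection uses the space's own mean shape
    pc = project(space, aligned, check=False)
    k = model.canonical_vectors.shape[0]
    return model.transform(pc[:k])


@dataclass
class FossilPrediction:
    """Mahalanobis membership assessment of one configuration."""

    specimen_id: str
    position: str
    category_set: str
    group_labels: list
    mahalanobis_d2: np.ndarray
    probability: np.ndarray      # softmax posterior, sums to 1
    typicality: np.ndarray       # chi-square tail probabilities
    predicted: object
    strong_support: bool


def membership_probabilities(
    model: CVAModel,
    cv_scores: np.ndarray,
    *,
    specimen_id: str = "",
    position: str = "",
    category_set: str = "speed",
) -> FossilPrediction:
    """Group membership probabilities from canonical-space distances.

    ``d²_g`` is the squared Euclidean distance to group mean g in canonical
    space (= Mahalanobis distance in PC space).  The posterior is
    ``exp(-d²_g / 2) / Σ_h exp(-d²_h / 2)`` with equal priors — invariant to
    adding a constant to every d² — and the chi-square typicality
    ``1 - CDF_{χ²(r)}(d²_g)`` is reported alongside.
    """
    cv_scores = np.asarray(cv_scores, dtype=float).ravel()
    d2 = ((model.group_means_cv - cv_scores) ** 2).sum(axis=1)
    shifted = -(d2 - d2.min()) / 2.0  # stabilized softmax
    weights = np.exp(shifted)
    posterior = weights / weights.sum()
    typicality = chi2.sf(d2, df=model.n_canonical)
    best = int(d2.argmin())
    return FossilPrediction(
        specimen_id=specimen_id,
        position=position,
        category_set=category_set,
        group_labels=list(model.group_labels),
        mahalanobis_d2=d2,
        probability=posterior,
        typicality=typicality,
        predicted=model.group_labels[best],
        strong_support=bool(posterior[best] > STRONG_SUPPORT),
    )
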