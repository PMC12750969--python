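# vertmorph

Ecological inference from vertebral shape, for palaeobiologists and
comparative morphologists.  Isolated vertebrae are among the most common
postcranial fossils, yet most ecomorphological toolchains are built around
skulls and limbs.  `vertmorph` implements a complete 3D geometric-morphometric
pipeline that asks how much locomotor ecology — running speed
(fast / intermediate / slow) and hunting mode (pursuit / ambush / pounce /
occasional) — can be read from single vertebrae, vertebral regions, or
multi-element combinations, and then projects fossil configurations into the
extant shape space to predict their ecology with explicit probabilities.

## What it computes

Starting from Morphologika-format 3D landmark files (30 landmarks per
vertebra after consolidation, at up to 10 homologous presacral positions
CF/CM/CL, TF/TM/TD/TL, LF/LM/LL), a species ecology table, and an optional
Newick phylogeny:

- **Generalized Procrustes analysis (GPA).** Each configuration X_i is
  centered, scaled to unit centroid size CS = √Σ‖x_j − x̄‖², and rotated by
  the proper rotation (det R = +1, no reflections) minimizing ‖X_i R − M‖²
  against the iteratively recomputed consensus M.
- **Shape-space PCA.** Eigendecomposition of the covariance of the
  vectorized aligned coordinates (divisor N − 1); species means are taken
  after superimposition.  Multi-element ("block") analyses vectorize each
  vertebra's aligned shapes separately, center and optionally scale each
  block to unit total variance, concatenate, and run one global PCA, so no
  element dominates the combined morphospace.
- **PERMANOVA.** Pseudo-F = (SS_B/(g−1)) / (SS_W/(N−g)) from the matrix of
  pairwise distances (Euclidean on Procrustes coordinates by default), with
  global and pairwise permutation p-values, seeded and reproducible.
- **Phylogenetic GLS.** Multivariate regression of shape on ecology or
  log centroid size under Brownian motion: both sides are whitened by
  C^{−1/2}, where C_ij is the shared root-to-ancestor branch length, and the
  effect size R² = SS_effect/SS_total is tested by residual-randomization
  permutation (RRPP).
- **CVA + Mahalanobis prediction.** Canonical variate analysis of the
  retained PC scores (between- vs pooled within-group generalized
  eigenproblem); in canonical space the pooled within-group covariance is
  the identity, so squared Euclidean distance d²_g to a group mean is the
  Mahalanobis distance.  A fossil is centered, scaled, rotated onto the
  extant consensus, projected through the PC and canonical bases, and
  assigned posterior membership probabilities
  p_g = exp(−d²_g/2) / Σ_h exp(−d²_h/2) (equal priors), with chi-square
  typicality probabilities reported alongside.
- **Synthetic data.** A generator producing landmark datasets with exactly
  the structure the analysis assumes — Brownian shape evolution on a
  simulated pure-birth phylogeny, additive group effect vectors, digitizing
  noise, arbitrary rigid motions and scale — plus held-out pseudo-fossils of
  known ecology, so the whole pipeline is testable without any downloads.

## Worked example

```python
import numpy as np
from vertmorph import *

truth = make_truth(43, seed=1)                      # 43 species, known ecology
dataset, ecology = simulate_dataset(truth, positions=("LF",))
sub = dataset.at_position("LF")
coords = np.stack([c.coords for c in sub.configurations])
block = generalized_procrustes(coords,
                               specimen_ids=[c.specimen_id for c in sub.configurations])
space = fit_pca(block)
labels = ecology.speed_of(block.specimen_ids)
model = fit_cva(space.scores[:, :choose_n_pcs(space, n_groups=3)], labels)

fossil = make_pseudofossil(truth, "fast", seed=1, position="LF")  # held out
cv = project_external(model, space, block.consensus, fossil.coords)
pred = membership_probabilities(model, cv)
print("PC1+PC2 variance: {:.2f}%".format(100 * space.variance_fraction[:2].sum()))
print("predicted:", pred.predicted)
for label, p in zip(pred.group_labels, pred.probability):
    print(f"  P({label}) = {p:.3f}")
```

prints

```
PC1+PC2 variance: 41.45%
predicted: fast
  P(fast) = 1.000
  P(intermediate) = 0.000
  P(slow) = 0.000
```

i.e. the first two PCs carry 41% of first-lumbar shape variation in this
simulated radiation, and the held-out pseudo-fossil — drawn at the fast
group's mean shape — is recovered as a fast runner with posterior
probability 1.000.

The same analyses are available from the shell:

```sh
vertmorph simulate --n-species 43 --seed 1 --positions LF --out syn
vertmorph cva syn/landmarks.txt syn/ecology.csv --position LF
# -> LF/speed: LOO accuracy 97.67% (42/43) with 23 PCs
vertmorph pgls syn/landmarks.txt syn/ecology.csv syn/tree.nwk --position LF --seed 1
# -> R2=0.469 F=17.631 p=0.001
vertmorph run-all config.yaml      # full pipeline -> CSV tables + manifest
```

## Layout

- `src/vertmorph/io_landmarks.py` — Morphologika I/O, landmark consolidation,
  position sampling, species means, ecology tables
- `src/vertmorph/gpa.py` — centroid size, Procrustes alignment, GPA, shape distance
- `src/vertmorph/shape_space.py` — per-vertebra PCA and multi-block combination
- `src/vertmorph/group_tests.py` — pseudo-F, PERMANOVA, pairwise tests
- `src/vertmorph/phylo_gls.py` — Newick input, Brownian covariance, PGLS/RRPP
- `src/vertmorph/eco_classify.py` — CVA, classification, fossil projection,
  membership probabilities
- `src/vertmorph/synthetic.py` — the simulation generator
- `src/vertmorph/pipeline.py`, `cli.py` — run configuration, orchestration, CLI

See `docs/methods.md` for the statistical details, default parameters and
known limitations.
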