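# conncca

Canonical correlation analysis (CCA) of brain functional connectomes against
behavioural and demographic subject measures (SMs), with permutation
inference that respects twin/sibling family structure.

Large population neuroimaging studies have repeatedly found a single
"positive–negative" mode of covariation linking resting-state functional
connectivity to cognition, behaviour and lifestyle: SMs with desirable
connotations load on one end of the mode and undesirable ones on the other.
`conncca` implements that analysis as a tested, reusable library for
researchers who want to run it on their own parcellated fMRI + phenotype
data, or to study its statistical behaviour under a known ground truth.

## The model

Given a subjects-by-edges connectivity matrix **N₀** (half-vectorized
Fisher-z netmats) and a subjects-by-measures table **S₁**, both views are
staged into d-dimensional score matrices:

* **S₁ → S₂** rank-based inverse normal (Blom) transform per SM;
  **S₂ → S₃** regression of 12 confound regressors (7 base + 5 squared);
  **S₃ → S₄** subjects×subjects covariance estimated pairwise over shared
  observations and completed to the nearest symmetric positive-definite
  matrix; **S₄ → S₅** top-d eigenvector scores.
* **N₀ → N₃** two normalized copies (column-demeaned, and column-mean-scaled
  with low-mean columns dropped), concatenated; **N₃ → N₄** confound
  regression; **N₄ → N₅** rank-d SVD scores.

The CCA finds demixing matrices A, B maximizing corr(U_k, V_k) for
**U = N₅A**, **V = S₅B**, successive mode pairs mutually uncorrelated.
Significance uses restricted permutations: co-twins (MZ, DZ) and siblings
exchange within families, and whole families with identical role signatures
exchange with each other; familywise error is controlled with the
max-statistic (first canonical correlation) null. Per-mode variance
explained in the original matrices is z-scored against the same null. The
primary mode is mapped back to individual SMs (the positive–negative axis)
and edges (top-K edge list, Ward node clusters), and validated with
family-respecting 80–20 train/test splits.

A synthetic cohort generator plants a known cross-view latent mode —
familial score correlations (MZ > DZ > sibling), SM loadings, and a sparse
precision-matrix tilt on connectome edges — so every stage can be tested
against ground truth, including filter-bait pathological SM columns and
heavy-tailed head-motion traces for the QC stage.

## Worked example

```bash
python examples/05_full_analysis.py
```

runs the full pipeline on the desk-scale planted cohort (300 subjects in
families, 50 nodes, 500 permutations) and prints:

```
top modes (r = canonical correlation, p = familywise permutation p):
 mode     r  p_fwe  ve_connectome  z_connectome  ve_sm   z_sm
    1 0.958  0.002          0.176        18.729  0.121 20.604
    2 0.586  0.625          0.005        -0.838  0.019 -0.266
    3 0.543  0.996          0.005        -0.758  0.017 -0.733
    4 0.490  1.000          0.005        -0.718  0.019 -0.290

top-30 edges: 30/30 are planted edges
cross-validation: held-out first-mode r = 0.89 +/- 0.05, all p <= 0.010
```

Mode 1 is the planted mode: its canonical correlation (0.958) towers over
the null (p = 1/(P+1), the smallest value 500 permutations can resolve), it
explains far more variance than any other mode in both views (z ≈ 19–21
against the permutation null, other modes ≈ 0), every one of the 30 edges
carrying planted signal lands in the top-30 edge list, and the mode
generalizes to held-out families. The positive–negative axis orders SMs by
their correlation with the mode's subject weights; the planted loadings
alternate sign, and the axis recovers them with |r| > 0.99.

Other examples cover cohort simulation, motion QC, netmat estimation,
restricted-permutation enumeration, and cross-validation in isolation. A
thin CLI wraps the same pipeline: `conncca run --seed 7 --outdir out/`.

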