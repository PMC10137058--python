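# mirsm

Prediction of small molecule–miRNA associations by truncated-nuclear-norm
matrix completion.

Small molecule (SM) drugs can target dysregulated microRNAs and modulate
their expression, but confirming an SM–miRNA association experimentally is
slow and expensive. Given a binary association matrix **M** (rows = SMs,
columns = miRNAs; 1 = confirmed regulation) together with SM–SM and
miRNA–miRNA similarity matrices, `mirsm` scores every unconfirmed pair so
that laboratory effort can be focused on the most promising candidates.
The intended users are computational biologists running link-prediction
screens on drug–miRNA resources.

## Method

Integrated similarities (weighted averages of the available similarity
sources, Ssm and Sm) and the association matrix are assembled into the
adjacency matrix of a heterogeneous network,

```
H = [ Ssm   M  ]
    [ M^T   Sm ],
```

whose observed entries are the similarity blocks plus the confirmed
associations; zeros of M are treated as missing. Assuming the underlying
matrix is low rank, the missing entries are recovered by minimizing the
**truncated nuclear norm** ‖X‖ᵣ = Σᵢ₌ᵣ₊₁ σᵢ(X) — the sum of all singular
values beyond the r largest — subject to fitting the observed entries
(relaxed into a quadratic penalty with weight α) and the bound
0 ≤ Xᵢⱼ ≤ 1:

```
min_X ‖X‖* − max_{AAᵀ=BBᵀ=I} Tr(A X Bᵀ) + (α/2)‖P_Ω(X) − P_Ω(H)‖²_F ,  0 ≤ X ≤ 1
```

A two-step scheme alternates (1) refreshing A, B as the top-r singular
vectors of the current iterate and (2) solving the remaining convex
subproblem by ADMM (auxiliary variable W clipped into [0,1], nuclear-norm
variable Z updated by singular-value shrinkage D₁∕β, multiplier Y updated
by gradient ascent with step γβ). Defaults are r=1, 3 outer passes, ADMM
cap 300, α=1, β=10, γ=1, ε₁=2×10⁻³, ε₂=10⁻⁵; r=0 disables truncation and
yields a plain bounded nuclear-norm completion as a baseline. The top-right
block of the recovered matrix is the score matrix **M′**.

## Worked example

```python
from mirsm import SyntheticSpec, generate, AssociationCompletion, SolverConfig

bundle, truth = generate(SyntheticSpec(ns=30, nm=24, latent_rank=2,
                                       density=0.1, similarity_noise=0.05, seed=11))
model = AssociationCompletion.from_bundle(bundle, SolverConfig(r=2))
result = model.fit()
print(result.summary())
print(result.ranked_pairs().head(5).to_string(index=False))
```

```
        Association Matrix Completion Results
========================================================
SMs:                       30    miRNAs:              24
Known associations:        65    Unknown pairs:      655
Truncation rank r:          2    Outer passes:         3
alpha: 1        beta: 10       gamma: 1
Inner iterations/pass: [163, 170, 173]
Final d1: 1.734e-03    Final d2: 9.954e-06
Max block asymmetry:   4.090e-13
Mean score (known 1s): 0.8475
Mean score (unknown):  0.5701
========================================================
  sm_id     mirna_id    score  known_flag
SM:0004 hsa-mir-0018 1.000000           1
SM:0008 hsa-mir-0008 1.000000           0
SM:0015 hsa-mir-0008 1.000000           0
SM:0022 hsa-mir-0012 1.000000           0
SM:0010 hsa-mir-0009 0.999999           1
```

The summary reports the problem size, the solver setting, how many ADMM
iterations each outer pass used before the ε₁/ε₂ stop conditions fired, the
final convergence statistics d1/d2, and the worst asymmetry between the two
association blocks of the recovered matrix (a numerical diagnostic — scores
are always read from the top-right block). Known associations score much
higher on average than unknown pairs, and the ranked table surfaces
unconfirmed pairs (known_flag 0) that the completion places among the top
candidates — these are the pairs a screen would take to the bench.

The same pipeline is available from the shell:

```
mirsm simulate --ns 30 --nm 24 --density 0.1 --seed 11 --outdir data/
mirsm predict --associations data/associations.tsv \
    --sm-similarity data/sm_similarity.tsv \
    --mirna-similarity data/mirna_similarity.tsv \
    --rank 2 --outdir out/
mirsm evaluate --associations data/associations.tsv \
    --sm-similarity data/sm_similarity.tsv \
    --mirna-similarity data/mirna_similarity.tsv \
    --scheme five_fold --repeats 5 --seed 0 --outdir cv/
```

All matrices are tab-separated text with identifier headers; every output
directory contains a `run_config.json` recording the resolved settings,
seed and package version.

## Evaluation protocols

`mirsm.evaluation` implements repeated five-fold cross-validation (known
associations partitioned into five near-equal parts, each part in turn
removed and ranked against all unknown pairs), global leave-one-out CV,
miRNA-fixed and SM-fixed local LOOCV (candidate sets restricted to the
held-out pair's column or row), a train/test ranking experiment and a
classification-style experiment with sampled negative sets evaluated at the
thresholds maximizing F1, accuracy and MCC. AUC uses the Mann–Whitney
statistic with half credit for ties.

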