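# Methods

## Model

`mirsm` treats SM–miRNA association prediction as completion of the
adjacency matrix of a heterogeneous network. With ns small molecules and nm
miRNAs, the target is the (ns+nm)×(ns+nm) symmetric matrix
H = [[Ssm, M], [Mᵀ, Sm]], where Ssm and Sm are integrated similarity
matrices (weighted averages of the available sources; all weights default
to 1) and M is the binary association matrix. The modeling assumptions are:

1. **Low rank.** The underlying complete matrix has rank r ≪ ns+nm; the
   truncated nuclear norm ‖X‖ᵣ = Σᵢ>ᵣ σᵢ(X) penalizes only the residual
   spectrum, so the dominant r-dimensional structure is recovered without
   the shrinkage bias of the full nuclear norm.
2. **Observation model.** Both similarity blocks are fully observed.
   Within the association blocks only the 1-entries are observed; zeros are
   the unknowns to be recovered. This is the only consistent choice given
   that the initializer P_Ω(H) must retain the known associations and the
   goal is to score the zero entries.
3. **Bounded scores.** Completed values are constrained to [0,1] and read
   as association scores.

The noisy-data relaxation replaces the hard constraint P_Ω(X)=P_Ω(H) by a
quadratic penalty with weight α, giving

min_X ‖X‖\* − max_{AAᵀ=BBᵀ=I} Tr(AXBᵀ) + (α/2)‖P_Ω(X) − P_Ω(H)‖²_F,
0 ≤ X ≤ 1.

## Algorithm

A two-step outer loop, X₁ = P_Ω(H):

- **Step 1.** SVD of the current iterate; A (B) = the first r left (right)
  singular vectors, transposed, taken from the same decomposition call so
  the per-vector sign ambiguity cancels in AᵀB. Then Tr(AXBᵀ) attains
  Σᵢ≤ᵣ σᵢ(X).
- **Step 2.** ADMM on the convex subproblem with auxiliary variable W
  (Z = W), multiplier Y, penalty β. Per inner iteration:
  W ← clip(T − α/(α+β)·P_Ω(T), 0, 1) with
  T = Y/β + (α/β)P_Ω(H) + AᵀB/β + Z; Z ← D_{1/β}(W − Y/β) where D_τ is
  singular-value soft-thresholding; Y ← Y + γβ(Z − W). Inner variables are
  re-initialized to P_Ω(H) at each outer pass (warm starting across passes
  is available behind a flag for experimentation but off by default).

Stopping uses d1 = ‖Z_{k+1}−Z_k‖_F/‖Z_k‖_F ≤ ε₁ together with
d2 = |d1_{k+1}−d1_k| / max(d1_k, 1) ≤ ε₂, or the iteration cap. The final
W of the last pass is the completed matrix; its top-right block is the
score matrix, and the diagonal blocks are enhanced similarity matrices.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| r | truncation rank (unpenalized spectrum) | 1 | useful range 1–3; larger r buys little accuracy at extra SVD cost. r=0 gives the plain bounded nuclear-norm baseline |
| outer_iterations | two-step passes | 3 | 1–4 suffices in practice; a warning is logged outside that range |
| maxiter | inner ADMM cap | 300 | typical convergence in 50–200 iterations at the default tolerances |
| α | observation-fit weight | 1 | larger α interpolates observed entries more tightly |
| β | ADMM penalty | 10 | also sets the shrinkage threshold 1/β |
| γ | multiplier learning rate | 1 | Y step size is γβ, implemented exactly as written |
| ε₁, ε₂ | stop tolerances | 2×10⁻³, 10⁻⁵ | on d1 and on its change |

## Numerical choices

- d2 is undefined at the first inner iteration; d1₀ is initialized to 1,
  which makes d2 ≈ 1 at k=1, so the loop never stops before iteration 2.
- The d2 denominator is max(d1_k, 1), i.e. effectively absolute once d1
  drops below 1.
- If ‖Z_k‖_F = 0 the relative change d1 degenerates; the absolute norm
  ‖Z_{k+1}‖_F is used and the case is logged.
- Near-ties σ_r ≈ σ_{r+1} (gap < 10⁻¹⁰) make the truncation factors
  ill-determined; the first r columns of the deterministic LAPACK
  decomposition are kept and a warning is logged.
- Matrices are dense throughout; at the intended scales (≤ ~1400²) each
  inner iteration is one dense SVD and the whole solve is seconds to
  minutes on one CPU. The solver contains no randomness.
- Similarity matrices asymmetric beyond 10⁻⁹, or with entries outside
  [0,1], are rejected rather than repaired — such values indicate upstream
  data corruption.
- Solver-induced asymmetry between the two association blocks is recorded
  per outer pass (`CompletionResults.max_asymmetry`); scores are always
  taken from the top-right block, never averaged across blocks.

## Evaluation protocol choices

- AUC is the Mann–Whitney statistic with half credit for ties (equal to
  trapezoidal ROC area with tie-grouped thresholds); the descending-score
  sweep description is tie-ambiguous and this is the standard resolution.
- Five-fold partitions of n items use sizes differing by at most one,
  smaller parts first (664 → 132, 133, 133, 133, 133). The reported SD is
  the population SD over repeat-level AUC means; repeats default to 100
  and are configurable downward for desk-scale runs.
- Predictions are positive at score ≥ threshold; candidate thresholds for
  F1/accuracy/MCC maximization are the distinct observed scores, swept in
  descending order with the first maximizer kept.
- Metrics with zero denominators are reported as 0 and logged.
- In the classification experiment the negative sets are resampled per
  repeat from unknown pairs disjoint from both the training 1s and the
  positive test set; the model is fitted once since scores do not depend
  on the negative sample.

## Synthetic data

The generator emulates the structure the method assumes: nonnegative
latent factors U (ns×k), V (nm×k) drawn uniform on [0,1]; the truth matrix
is U·Vᵀ scaled into [0,1]; M is sampled entry-wise as independent
Bernoulli with probability proportional to the truth, calibrated by a
single global scale so the expected 1-count is density·ns·nm (densities
that would require per-entry probabilities above 1 are rejected).
Similarities are cosine similarities of the factor rows — automatically in
[0,1] for nonnegative factors — plus optional symmetric Gaussian noise,
clipped and with unit diagonal. Defaults: ns=nm=120, k=2, density 0.05,
noise 0.05.

What it does **not** emulate: the marginal distributions of real
similarity measures (Jaccard, maximal-common-subgraph, MeSH-derived), the
heavy-tailed degree distributions of curated association databases, or
batch structure across sources. Passing tests on synthetic data therefore
demonstrate mechanical and statistical correctness of the pipeline, not
expected performance on real resources.

A consequence of the linear Bernoulli sampling law worth stating plainly:
conditional on the truth matrix, entries are independent, so no predictor
can rank held-out 1s against 0s better than the sampling probability
itself. With smooth rank-2 uniform-factor truth this information-theoretic
ceiling is ≈ 0.68 AUC at the default conditions (measured over 8 seeds);
the solver reaches ≈ 0.55–0.59 and approaches the ceiling (0.90–0.92
against ≈ 0.95) when the latent factors are sharpened so the signal is
strong. Holdout-recovery AUCs on the default generator should be read
against that ceiling, not against 1.0.

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses desk-scale sizes chosen so one run completes
in well under a minute on a single CPU: bookkeeping at the published
dataset shapes (831×541 and 39×286), holdout recovery and the holdout
experiments at 120×120 (the generator defaults), five-fold CV at 60×50
with 3 repeats, and the three LOOCV schemes at 20×16.

## Known limitations

- Each ADMM iteration performs a full dense SVD; very large networks would
  need truncated decompositions, which are deliberately out of scope.
- Similarity construction from raw pharmacological/genomic sources is out
  of scope; similarity matrices are consumed as ready-made inputs and must
  be complete.
- SM-fixed local LOOCV is intrinsically hard for SMs with a single known
  association, since removing it leaves the SM with no training signal in
  its row; low AUCs under that scheme reflect the protocol, not a defect.
- The completion produces one score per pair with no uncertainty
  quantification.
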