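# Methods

`phenoinfo` quantifies how much information about a dynamic, per-cell
phenotype (here: a Ca²⁺-like signaling trace) is carried by paired per-cell
mRNA counts, and how that information is distributed across genes — shared,
unique, or synergistic. This note records the models, the estimator
internals, the numerical choices, and what the synthetic data can and cannot
show.

## The estimation problem

The data are two row-aligned matrices for the same cells: transcript counts
`G` (cells × genes, non-negative integers) and a continuous trace `Ca`
(cells × timepoints). The target quantity is the mutual information
`I(G_S; Ca)` in bits for arbitrary gene subsets `S`, without assuming any
parametric joint distribution for the mixed discrete/continuous data. The
timescale separation assumption — transcript abundances are quasi-static
over the minutes-long trace — is what licenses reading the symmetric MI as
the phenotypic information *in* mRNA abundance.

## Neural lower-bound estimator

MI is estimated by maximizing the Donsker–Varadhan (DV) representation of
the KL divergence between the joint distribution and the product of
marginals:

    I(X;Y) ≥ sup_θ  E_P[T_θ(x,y)] − log E_Q[e^{T_θ(x,y)}]

- **Statistic network.** One hidden layer of 600 units (ELU), scalar
  output. 600 units and learning rate 3e-4 are the published hyperparameter
  choices; depth one is the minimal architecture consistent with a single
  stated width.
- **Optimization.** Adam (β₁ 0.9, β₂ 0.999) at 3e-4, minibatch 256 by
  default. Joint-term rows are paired samples; the marginal term permutes
  the y-rows within the batch, resampled every iteration.
- **Gradient bias.** The minibatch gradient of `log E_Q[e^T]` is biased;
  the denominator is replaced by an exponential moving average (decay 0.99)
  of `E_Q[e^T]`, maintained in log space. Training is unstable without it.
- **Units.** Training is in natural log; every recorded and reported
  quantity is converted to bits.
- **Implementation.** Pure NumPy/Numba, float32 forward/backward. The inner
  loop has two interchangeable backends: a fused Numba kernel (default) and
  a NumPy reference; both consume identical pregenerated random streams and
  agree to ~1e-5, so results are reproducible and backend-checkable.
  `MineConfig.backend` selects the path.

## Training-curve bias correction

The recorded DV bound `I_obs(t)` rises toward the achievable bound and then
drifts as the network overfits the finite sample. Both effects are modeled
jointly by nonlinear least squares of

    I_obs(t) = I_true · (1 − a·e^{−b·t}) + c·t

and `I_true` — the drift-free plateau — is the reported estimate. Fitting
details that matter in practice:

- the first 10% of each curve is excluded (`warmup_fraction`): the
  moving-average initialization produces an early negative dip that the
  saturating model cannot represent and that otherwise inflates the plateau;
- the fit is multistart (three initial guesses) because early-dip curves
  have a local minimum at `a → 0`;
- `a` is bounded to [0, 5] and `I_true` to a window around the observed
  curve, which removes a degenerate `(a → ∞, I_true → 0)` mode;
- the convergence diagnostic is the RMS of block-averaged residuals (≈50
  blocks), so it measures systematic misfit, not per-minibatch noise.

A fit is screened out (replicate marked failed) when any of: block residual
RMS exceeds 10% of `|I_true|` (floor 0.05 bits); the fitted rate `b` is not
positive; the fitted transient has not decayed within the training window;
or the bound is still visibly rising over the last tenth of the trajectory.
The last two catch under-trained runs whose plateau would otherwise be an
unconstrained extrapolation. Screened-out runs still expose a training-tail
mean as a *ranking* score, used only where a total order over candidates is
needed (greedy scanning) — never as a reported value.

## Jackknife and replicates

Each replicate applies a first-order sample-size jackknife: the plateau is
estimated on all n cells and on `n_jackknife` random half-size subsamples,
and the corrected value is `2·I(n) − mean I(n/2)` (extrapolation in 1/n;
4 subsamples by default). Empirically, once the curve fit has removed the
optimization transient and drift, the remaining n-dependence is small and
the correction is modest and noise-dominated; it is retained as part of the
standard chain, and its magnitude is visible in the per-replicate
diagnostics. An estimate is the mean of the corrected plateaus over
converged technical replicates (default 3 — independent trainings on the
same data), with their standard deviation as the spread; if every replicate
fails, the result is an explicit failure object, never a silent number.

## Calibration on Gaussian ground truth

For jointly Gaussian (X, Y), `I = ½·log₂(det Σ_x · det Σ_y / det Σ)` in
closed form. The validation suite (`default_gaussian_suite`) holds 12
datasets of n = 5000 paired samples: ten bivariate couplings whose true MI
spans 0–2.8 bits plus two 2+2-dimensional datasets (per-pair ρ 0.5 and
0.8). The published account of this validation states neither dimensions,
sample sizes, nor number of dependence levels, so these defaults are this
package's interpretation of "a range of strengths of dependence" at desk
scale. `validation_config()` pins the calibration budget: 4000 iterations at
batch 128, 3 replicates, one half-sample jackknife piece — sized so the
whole suite runs in roughly ten minutes on one CPU. `scripts/acceptance.py`
reruns exactly this and reports the suite's mean absolute residual and
Pearson correlation against the closed form.

## Entropy measures

- **Spectral entropy.** Per-cell periodograms (raw, boxcar, optional mean
  detrend) are averaged across cells *before* normalization; the DC bin is
  excluded; the remaining power over 0 < f ≤ fs/2 is normalized to sum to 1
  and its Shannon entropy reported in bits. The measure is invariant to
  amplitude scaling and to duplicating cells. A sampling-rate sweep
  resamples the traces by linear interpolation onto a grid of rate fs over
  the same window (recomputing the periodogram under a different nominal fs
  alone would only relabel the axis); entropy plateaus once fs resolves all
  the signal power. The per-cell-entropy-then-average alternative is exposed
  but not the default.
- **Differential entropy of expression.** PCA (full SVD, deterministic up
  to sign) on globally z-scored counts; the retained components get the
  multivariate-Gaussian differential entropy
  `h = (n/2)·log₂(2πe) + ½·log₂ det Σ_PC` in bits — each component is a
  weighted sum over many genes, so normality is a central-limit-style
  approximation. The cumulative-variance vs cumulative-entropy curves make
  the point that variance saturates long before information does.

## Preprocessing contract

Each modality is z-scored with **one global mean and SD over its whole
matrix** — never per column — so a gene with 10× the counts of another
keeps 10× its centered magnitude, and relative amplitudes across timepoints
survive. This unusual choice is a hard contract with a regression test.
Parameters are stored for inversion; preprocessing is idempotent.

## Information decomposition

- **SRI.** `SRI(G_i, G_j | Ca) = I({G_i,G_j};Ca) − I(G_i;Ca) − I(G_j;Ca)`;
  negative = redundant, positive = synergistic. Single-gene constituents are
  estimated once and shared by all pairs, so a pair's SRI is exact
  bookkeeping over three cached estimates; spreads propagate in quadrature
  (an interpretation — the original work does not state one). The matrix
  diagonal is defined as `−I(G_i;Ca)` (duplicate-gene limit) and excluded
  from all summaries.
- **Rank summaries.** Spearman statistics (ties mid-ranked, large-sample
  p-values) relate each gene's phenotype MI to its mean MI-to-other-genes
  and to its mean SRI; the ranking construction for the latter is one of
  several possible readings and is stated in the function docstrings.
- **NRI / redundancy explained.** With `E[I_k]` the mean joint MI of
  sampled size-k sets, `NRI(k) = E[I_k]·n/k` extrapolates to the
  no-redundancy total, and
  `RE(k) = 1 − (NRI(k) − I_full)/(NRI(1) − I_full)` is the fraction of the
  redundancy gap closed by size k; RE(1) = 0 and RE(n) = 1 by construction.
  If `NRI(1) ≤ I_full` there is no redundancy to explain and the curve is
  returned flagged invalid.

## Gene-set search

Greedy maximize/minimize construct upper/lower information-vs-size bounds:
at each step every remaining candidate's joint MI is scanned at reduced
budget (one replicate, no jackknife — still trained to plateau), ties broken
by smallest gene index, and each chosen set re-estimated at full budget.
Random sets are drawn uniformly without replacement and deduplicated per
size (4 samples per size by default), feeding `E[I_k]`. Joint-MI estimates
canonicalize gene order so the same set yields the same estimate on every
path. The lower bound's least-squares slope (linear region = all sizes minus
the last five by default) reads off the average unique information per gene.
Greedy is a heuristic: on small discrete fixtures it is compared against
exhaustive best-subset enumeration in the tests.

## Synthetic data generator

The generator emulates the structure of a paired MERFISH + live-imaging
experiment with a controllable ground truth:

- a per-cell latent state `z ~ N(0, I)` (the "cell state");
- counts: negative binomial via a gamma–Poisson mixture with
  `mean = exp(baseline + loading·z)` and per-gene dispersion — the standard
  heavy-tailed single-cell count model;
- traces: damped oscillation
  `b + A·e^{−d·t}·sin(2πf·t)` sampled every 2.5 s (the cadence implied by
  314 timepoints over a 13-minute acquisition), with log-parameters affine
  in `z` and additive Gaussian noise; phase is locked to stimulus onset;
- synergy: a designated pair's interaction — the **sign** of the centered
  product of their latent contributions — drives one trace parameter. The
  sign (a Rademacher variable) is independent of each factor alone, so the
  genes are individually uninformative but jointly determine the parameter;
  the raw product would leak magnitude information into the marginals;
- seeding: one user seed expands into labeled per-component streams, so
  adding a gene never perturbs any other gene's draws, and identical specs
  are bit-identical.

Default fixture scale is desk-sized (≈1500–2000 cells, tens of genes,
30–100 timepoints) — large enough to constrain the estimator, small enough
that the full test suite runs in minutes. Fixtures that plant *redundancy*
use low count noise (dispersion 50, baseline mean 50): with noisy counts two
identically-loaded genes are complementary measurements of the same latent
and their true SRI is near zero, not negative.

What the generator does **not** emulate: imaging/segmentation noise,
barcode misidentification, spatial structure, cell-cycle covariates,
transcriptional bursting, or mRNA–phenotype feedback. Passing tests
therefore demonstrate that the machinery recovers known information
structure under the stated generative assumptions — not that any particular
biological dataset has that structure.

## Numerical choices and degenerate inputs

float32 arithmetic in training, float64 in all bound/fit computations;
log-domain EMA; stable log-mean-exp. Constant traces (zero off-DC power),
zero-variance modalities, non-positive-definite covariances, misaligned or
duplicated cell ids, and rank-deficient PCA requests are all rejected with
explicit errors. Gene sets are canonicalized; greedy ties break to the
smallest index; Spearman ties are mid-ranked.

## Known limitations

- The DV bound is a lower bound with optimization-limited tightness: at
  high MI (≳2.5 bits) estimates undershoot at the default budget; longer
  training narrows but does not close the gap.
- Fit screening trades yield for honesty: on hard curves some replicates
  are discarded, and an estimate can fail outright rather than report a
  drift-contaminated number.
- The jackknife correction is noise-dominated once the curve fit has done
  its work; it is kept for fidelity to the standard chain, not because it
  measurably improves calibration here.
- Greedy search is not guaranteed optimal; the brute-force comparison is
  only feasible on small fixtures.
- All quantitative statements in the README/tests are about synthetic or
  Gaussian data; the study-scale dataset this pipeline is designed for is
  not publicly available.
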