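# phenoinfo

How much does mRNA abundance matter for a cell's dynamic phenotype?
`phenoinfo` answers this with information theory on *paired* single-cell
data: per-cell transcript counts (tens of genes, MERFISH-style) measured in
the same cells as a continuous signaling readout (hundreds of timepoints of
Ca²⁺ dynamics). Because the signaling response is much faster than changes
in transcript abundance, the mutual information `I(G; Ca)` between counts
and trace can be read as the phenotypic information *contained in* mRNA
levels — the rest is posttranscriptional.

The package is aimed at computational biologists with multimodal
single-cell data who want absolute, assumption-light dependency measures
rather than correlations or cluster overlaps.

## What it computes

**Mutual information, neurally.** For mixed discrete/continuous,
high-dimensional data, `I(X;Y)` is bounded from below via the
Donsker–Varadhan representation,

    I(X;Y) ≥ E_P[T_θ] − log E_Q[e^{T_θ}],

maximized over a statistic network `T_θ` (one hidden layer, 600 units,
Adam at 3e-4) trained on paired rows (P) versus within-batch-shuffled rows
(Q ≈ product of marginals). Three corrections make the raw bound usable:
a fit of the whole training curve to `I_obs(t) = I_true(1 − a·e^{−bt}) + ct`
whose plateau `I_true` removes the overfitting drift, a half-sample
jackknife `2·I(n) − mean I(n/2)`, and technical replicates (mean ±
standard deviation over independent trainings), with convergence screening
on the fit residuals. Everything is reported in bits. The implementation is
NumPy/Numba; no GPU.

**Entropy of each modality.** Spectral entropy
`H = −Σ_{f>0} P(f)·log₂ P(f)` of the ensemble-averaged, normalized
periodogram summarizes the information content of the oscillatory traces;
Gaussian differential entropy `(n/2)log₂(2πe) + ½log₂ det Σ_PC` of the
PCA-transformed counts shows how expression information spreads across
components (and how poorly explained variance proxies it).

**Information decomposition.** Per-gene `I(G_i;Ca)`; gene–gene `I(G_i;G_j)`;
the synergy–redundancy index
`SRI(G_i,G_j|Ca) = I({G_i,G_j};Ca) − I(G_i;Ca) − I(G_j;Ca)`
(negative = redundant, positive = synergistic); annotation-level SRI
summaries; nonredundant information `NRI(k) = E[I_k]·n/k` and the fraction
of redundancy explained by size-k sets,
`RE(k) = 1 − (NRI(k) − I_full)/(NRI(1) − I_full)`.

**Gene-set search.** Greedy most-/least-informative set construction
(upper/lower information-vs-size bounds), uniform random sets, and the
lower bound's slope — the average unique information per gene.

**Synthetic data.** The study-scale dataset this pipeline was designed
around is not publicly available, so the package ships a generator with
known ground truth: negative-binomial counts and damped-oscillation traces
coupled through a shared latent cell state, with plantable redundancy and
XOR-style synergy, plus multivariate-Gaussian suites with closed-form MI
for calibration.

## Worked example

Simulate a 5-gene dataset where genes g000/g001 are identical-loading
readouts of a latent state that drives trace frequency (planted
redundancy), g002 is weakly coupled and the rest are decoys — then run the
full analysis:

```python
import numpy as np
from phenoinfo import MineConfig, PairedSimSpec
from phenoinfo.pipeline import RunConfig, run_full_analysis

gl = np.zeros((5, 2)); gl[0, 0] = 0.9; gl[1, 0] = 0.9; gl[2, 0] = 0.4
tl = np.zeros((2, 4)); tl[0, 1] = 0.7          # latent 0 -> log-frequency
spec = PairedSimSpec(n_cells=1500, n_genes=5, n_timepoints=40, n_latent=2,
                     gene_loading=gl, trace_loading=tl,
                     baseline_log_mean=float(np.log(50)), dispersion=50.0,
                     trace_noise_sd=0.05, seed=7)
cfg = RunConfig(sim_spec=spec,
                mine=MineConfig(hidden_units=64, n_iterations=4000,
                                batch_size=128, n_replicates=2,
                                n_jackknife=0, seed=7),
                output_dir="demo_run", seed=7, max_pc_components=3,
                samples_per_size=2)
print(run_full_analysis(cfg)["summary"])
```

prints (abridged):

```
spectral_entropy_bits        2.597
total_mi_bits                1.391   ± 0.008
mean_per_gene_mi_bits        0.469
gene_gene_spearman_r         0.900
mean_sri_bits               -0.112
sri_spearman_r              -0.800
upper_size_at_half_total_mi  1
```

Reading it: the trace ensemble carries ~2.6 bits of spectral entropy, of
which all five genes jointly recover 1.39 bits. The per-gene average is
0.47 bits, so the sum over genes (≈2.3 bits) far exceeds the joint total —
the signature of redundancy, quantified by the negative mean SRI. Genes
informative about the trace are also informative about each other
(gene–gene Spearman +0.9) and more redundant (SRI Spearman −0.8), and the
greedy upper bound reaches half the total information with a single gene —
exactly the planted structure. Artifacts (per-gene tables, SRI matrix,
search traces, redundancy curve) land in `demo_run/` as TSVs, each stamped
with the config hash and seed.

A CLI wraps the same pipeline: `phenoinfo simulate`, `phenoinfo validate`,
`phenoinfo analyze --counts counts.tsv --traces traces.tsv`, plus
stage-level verbs (`entropy`, `mi`, `sri`, `search`, `redundancy`).

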