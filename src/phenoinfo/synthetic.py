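"""Synthetic data: Gaussian validation suites and paired count/trace datasets.

Two generators live here.

``sample_gaussian_suite`` draws multivariate-Gaussian dataset pairs with a
known closed-form mutual information; these are the calibration ground truth
for the neural MI estimator, the same strategy used to choose its
hyperparameters (an additive-Gaussian model "across a range of strengths of
dependence").

``sample_paired_dataset`` emulates the structure of a paired MERFISH +
live-cell imaging experiment — per-cell transcript counts for tens of genes
alongside a Ca2+-like oscillatory trace — with a controllable latent coupling
between expression and trace shape, so that redundancy and synergy between
genes are known by construction.  The real study's dataset (5,128 cells x 83
genes x 314 timepoints) was never deposited, so this generator is the
package's stand-in study system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._seeds import rng_for

__all__ = [
    "GaussianSuiteSpec",
    "GaussianDataset",
    "PairedSimSpec",
    "gaussian_mi_closed_form",
    "make_cross_covariance",
    "sample_gaussian_suite",
    "default_gaussian_suite",
    "sample_paired_dataset",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Gaussian validation suite
# ---------------------------------------------------------------------------

def make_cross_covariance(dim_x: int, dim_y: int, rho: float) -> np.ndarray:
    """Joint covariance for (X, Y) with unit marginals and pairwise coupling.

    X and Y have identity covariance; component i of X is correlated with
    component i of Y with coefficient ``rho`` (for i < min(dim_x, dim_y)).
    """
    d = dim_x + dim_y
    cov = np.eye(d)
    for i in range(min(dim_x, dim_y)):
        cov[i, dim_x + i] = rho
        cov[dim_x + i, i] = rho
    return cov


def gaussian_mi_closed_form(cov: np.ndarray, dim_x: int) -> float:
    """Closed-form MI in bits between the first ``dim_x`` and remaining dims.

    For a jointly Gaussian (X, Y),
    ``I(X;Y) = 1/2 * log2( det(S_x) * det(S_y) / det(S) )``.

    Raises
    ------
    ValueError
        If ``cov`` is not symmetric positive definite, or ``dim_x`` does not
        split it into two non-empty blocks.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov must be a square matrix")
    if not (0 < dim_x < cov.shape[0]):
        raise ValueError("dim_x must split cov into two non-empty blocks")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("cov must be symmetric")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("cov must be positive definite") from err
    sx = cov[:dim_x, :dim_x]
    sy = cov[dim_x:, dim_x:]
    _, ld_x = np.linalg.slogdet(sx)
    _, ld_y = np.linalg.slogdet(sy)
    _, ld = np.linalg.slogdet(cov)
    mi = 0.5 * (ld_x + ld_y - ld) / LN2
    return max(float(mi), 0.0)


@dataclass(frozen=True)
class GaussianSuiteSpec:
    """A suite of Gaussian dataset pairs spanning a range of dependence.

    Every combination of ``dimension_pairs`` x ``coupling_levels`` yields one
    dataset of ``n_samples`` paired draws.  Positive-definiteness of each
    implied joint covariance is checked at construction.
    """

    dimension_pairs: tuple = ((1, 1),)
    coupling_levels: tuple = (0.0, 0.5, 0.8, 0.9)
    n_samples: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for dx, dy in self.dimension_pairs:
            if dx <= 0 or dy <= 0:
                raise ValueError("dimensions must be positive")
            for rho in self.coupling_levels:
                if not -1.0 < rho < 1.0:
                    raise ValueError(f"coupling level {rho} outside (-1, 1)")
                cov = make_cross_covariance(dx, dy, rho)
                mi = gaussian_mi_closed_form(cov, dx)  # raises if not PD
                if not np.isfinite(mi) or mi < 0:
                    raise ValueError(f"invalid closed-form MI at rho={rho}")

    @property
    def n_datasets(self) -> int:
        return len(self.dimension_pairs) * len(self.coupling_levels)


@dataclass(frozen=True)
class GaussianDataset:
    """One suite member: paired samples plus the closed-form ground truth."""

    x: np.ndarray
    y: np.ndarray
    rho: float
    dim_x: int
    dim_y: int
    true_mi_bits: float


def sample_gaussian_suite(spec: GaussianSuiteSpec) -> list[GaussianDataset]:
    """Draw every dataset of the suite; deterministic under ``spec.seed``."""
    out = []
    for dx, dy in spec.dimension_pairs:
        if spec.n_samples < 10 * (dx + dy):
            warnings.warn(
                f"n_samples={spec.n_samples} < 10x total dimension ({dx + dy}); "
                "the MI estimator will be poorly constrained",
                stacklevel=2,
            )
        for rho in spec.coupling_levels:
            cov = make_cross_covariance(dx, dy, rho)
            true_mi = gaussian_mi_closed_form(cov, dx)
            rng = rng_for(spec.seed, "gaussian", dx, dy, f"{rho:.6f}")
            z = rng.multivariate_normal(
                np.zeros(dx + dy), cov, size=spec.n_samples, method="cholesky"
            )
            out.append(
                GaussianDataset(
                    x=z[:, :dx], y=z[:, dx:], rho=float(rho),
                    dim_x=dx, dim_y=dy, true_mi_bits=true_mi,
                )
            )
    return out


def _rho_for_mi(mi_bits: float) -> float:
    """Bivariate correlation whose Gaussian MI equals ``mi_bits``."""
    return float(np.sqrt(1.0 - 2.0 ** (-2.0 * mi_bits)))


def default_gaussian_suite(n_samples: int = 5000, seed: int = 0) -> list[GaussianDataset]:
    """The default calibration suite: 12 datasets spanning ~0-3 bits.

    Ten bivariate datasets whose closed-form MI is evenly spread over
    0-2.8 bits, plus two 2+2-dimensional datasets (per-pair rho 0.5 and 0.8,
    i.e. 0.83 and 1.47 bits) to exercise the estimator beyond scalars.
    """
    bivariate_mis = (0.0, 0.2, 0.5, 0.8, 1.1, 1.4, 1.7, 2.0, 2.4, 2.8)
    spec1 = GaussianSuiteSpec(
        dimension_pairs=((1, 1),),
        coupling_levels=tuple(_rho_for_mi(m) for m in bivariate_mis),
        n_samples=n_samples,
        seed=seed,
    )
    spec2 = GaussianSuiteSpec(
        dimension_pairs=((2, 2),),
        coupling_levels=(0.5, 0.8),
        n_samples=n_samples,
        seed=seed,
    )
    return sample_gaussian_suite(spec1) + sample_gaussian_suite(spec2)


# ---------------------------------------------------------------------------
# Paired count / trace simulation
# ---------------------------------------------------------------------------

#: order of the modulated damped-oscillation parameters
TRACE_PARAMS = ("amplitude", "frequency", "decay", "baseline")


@dataclass(frozen=True)
class PairedSimSpec:
    """Generative spec for a paired transcript-count / signaling-trace dataset.

    A per-cell latent state ``z ~ N(0, I_{n_latent})`` drives both modalities:

    * counts: gene g is negative binomial with mean
      ``exp(baseline_log_mean[g] + (gene_loading @ z)[g])`` and per-gene
      dispersion (gamma-Poisson mixture);
    * traces: a damped oscillation
      ``b + A * exp(-d t) * sin(2 pi f t)`` sampled at ``1/dt`` Hz with
      additive Gaussian noise, whose log-parameters (A, f, d; b additively)
      are affine in ``z`` through ``trace_loading`` (n_latent x 4, column
      order :data:`TRACE_PARAMS`).

    ``synergy_pairs`` lists gene index pairs whose interaction modulates
    ``synergy_target`` with weight ``synergy_strength``.  The interaction is
    the *sign* of the centered product of the two genes' latent
    contributions: a Rademacher variable independent of each factor alone,
    so each gene is individually uninformative about the driven parameter
    yet the pair determines it (an XOR-like construction; the raw product
    would leak magnitude information marginally).
    """

    n_cells: int = 2000
    n_genes: int = 20
    n_timepoints: int = 100
    n_latent: int = 3
    gene_loading: np.ndarray | None = None  # genes x latent; None -> zeros
    baseline_log_mean: float | np.ndarray = float(np.log(10.0))
    dispersion: float | np.ndarray = 2.0
    trace_loading: np.ndarray | None = None  # latent x 4; None -> zeros
    trace_noise_sd: float = 0.1
    synergy_pairs: tuple = ()
    synergy_target: str = "frequency"
    synergy_strength: float = 1.0
    amplitude: float = 1.0
    frequency_hz: float = 0.02
    decay_rate: float = 0.005
    trace_baseline: float = 0.2
    dt_seconds: float = 2.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cells", "n_genes", "n_timepoints", "n_latent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if np.any(np.asarray(self.dispersion) <= 0):
            raise ValueError("dispersion must be positive")
        if self.trace_noise_sd < 0:
            raise ValueError("trace_noise_sd must be non-negative")
        if self.synergy_target not in TRACE_PARAMS:
            raise ValueError(f"synergy_target must be one of {TRACE_PARAMS}")
        gl = self.resolved_gene_loading()
        if gl.shape != (self.n_genes, self.n_latent):
            raise ValueError("gene_loading must be (n_genes, n_latent)")
        tl = self.resolved_trace_loading()
        if tl.shape != (self.n_latent, 4):
            raise ValueError("trace_loading must be (n_latent, 4)")
        for i, j in self.synergy_pairs:
            if not (0 <= i < self.n_genes and 0 <= j < self.n_genes) or i == j:
                raise ValueError(f"invalid synergy pair ({i}, {j})")

    def resolved_gene_loading(self) -> np.ndarray:
        if self.gene_loading is None:
            return np.zeros((self.n_genes, self.n_latent))
        return np.asarray(self.gene_loading, dtype=float)

    def resolved_trace_loading(self) -> np.ndarray:
        if self.trace_loading is None:
            return np.zeros((self.n_latent, 4))
        return np.asarray(self.trace_loading, dtype=float)


def sample_paired_dataset(spec: PairedSimSpec):
    """Draw a :class:`~phenoinfo.dataset.PairedDataset` plus its ground truth.

    Returns
    -------
    dataset : PairedDataset
        Raw (unnormalized) counts and traces, cells aligned by id.
    truth : dict
        The generating latent state, loadings and per-cell trace parameters,
        for oracle use in tests and validation.
    """
    from .dataset import PairedDataset  # deferred: avoid circular import

    gl = spec.resolved_gene_loading()
    tl = spec.resolved_trace_loading()
    n, g, tp = spec.n_cells, spec.n_genes, spec.n_timepoints

    z = rng_for(spec.seed, "latent").standard_normal((n, spec.n_latent))

    # counts: per-gene stream so adding genes never perturbs other genes
    base = np.broadcast_to(np.asarray(spec.baseline_log_mean, dtype=float), (g,))
    disp = np.broadcast_to(np.asarray(spec.dispersion, dtype=float), (g,))
    counts = np.empty((n, g), dtype=np.int64)
    log_mu = base[None, :] + z @ gl.T
    for gi in range(g):
        rng = rng_for(spec.seed, "counts", gi)
        mu = np.exp(np.clip(log_mu[:, gi], -30, 30))
        lam = rng.gamma(shape=disp[gi], scale=mu / disp[gi])
        counts[:, gi] = rng.poisson(lam)

    # trace parameter modulation: affine in z, plus centered-product synergy
    mod = z @ tl  # cells x 4
    target_col = TRACE_PARAMS.index(spec.synergy_target)
    for i, j in spec.synergy_pairs:
        ui = z @ gl[i]
        uj = z @ gl[j]
        interaction = np.sign((ui - ui.mean()) * (uj - uj.mean()))
        mod[:, target_col] = mod[:, target_col] + spec.synergy_strength * interaction

    amp = spec.amplitude * np.exp(mod[:, 0])
    freq = spec.frequency_hz * np.exp(mod[:, 1])
    decay = spec.decay_rate * np.exp(mod[:, 2])
    basel = spec.trace_baseline + mod[:, 3]

    t = np.arange(tp) * spec.dt_seconds
    clean = (
        basel[:, None]
        + amp[:, None] * np.exp(-decay[:, None] * t[None, :])
        * np.sin(2.0 * np.pi * freq[:, None] * t[None, :])
    )
    noise = rng_for(spec.seed, "trace-noise").standard_normal((n, tp))
    traces = clean + spec.trace_noise_sd * noise

    gene_labels = [f"g{gi:03d}" for gi in range(g)]
    cell_ids = [f"cell{ci:05d}" for ci in range(n)]
    dataset = PairedDataset.from_arrays(
        counts=counts, traces=traces, gene_labels=gene_labels, cell_ids=cell_ids,
        dt_seconds=spec.dt_seconds,
    )
    truth = {
        "latent": z,
        "gene_loading": gl,
        "trace_loading": tl,
        "trace_params": {
            "amplitude": amp, "frequency": freq, "decay": decay, "baseline": basel,
        },
        "spec": spec,
    }
    return dataset, truth
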