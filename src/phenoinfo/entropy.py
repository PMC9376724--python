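"""Entropy measures for the two modalities.

Spectral entropy summarizes the information content of an ensemble of
oscillatory traces: the per-cell periodograms are averaged, the average power
spectral density is normalized to a probability distribution over the
positive frequencies up to fs/2 (the DC bin is excluded), and its Shannon
entropy is

    H = - sum_f P(f) log2 P(f)        [bits]

The measure is scale-invariant (normalization cancels amplitude) and, once
the sampling rate resolves all the power in the signal, insensitive to fs.

Transcript-count information is summarized by the Gaussian differential
entropy of the PCA-transformed data,

    h(n) = (n/2) log2(2 pi e) + (1/2) log2 det Sigma_PC   [bits]

where Sigma_PC is the (diagonal) covariance of the first n principal
components — each component is a weighted sum of many gene counts, so
normality is a central-limit-style approximation.  Contrasting the cumulative
explained variance with this cumulative entropy shows that variance is a poor
proxy for information: most entropy can live in components that explain
little variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from sklearn.decomposition import PCA

__all__ = [
    "SpectralDensity",
    "PCDecomposition",
    "periodogram",
    "spectral_entropy",
    "per_cell_spectral_entropy",
    "spectral_entropy_fs_sweep",
    "pca_decompose",
    "differential_entropy",
    "variance_entropy_curves",
    "pairwise_gene_correlations",
]

LOG2_2PIE = float(np.log2(2.0 * np.pi * np.e))


@dataclass
class SpectralDensity:
    """Normalized ensemble power spectral density over positive frequencies."""

    frequencies: np.ndarray
    power: np.ndarray
    fs: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def is_normalized(self) -> bool:
        return bool(np.isclose(self.power.sum(), 1.0, atol=1e-8))


def periodogram(traces: np.ndarray, fs: float, *, detrend: bool = False) -> SpectralDensity:
    """Ensemble periodogram: mean of raw per-cell periodograms, normalized.

    The per-cell (boxcar, unwindowed) periodograms are averaged across cells
    *before* normalization, then the DC bin is dropped and the remaining
    power over 0 < f <= fs/2 is scaled to sum to one.

    Raises
    ------
    ValueError
        For fewer than 2 timepoints, non-positive fs, or constant traces
        (zero total power off DC — a degenerate spectrum).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    if fs <= 0:
        raise ValueError("fs must be positive")
    f, pxx = sp_signal.periodogram(
        traces, fs=fs, window="boxcar", detrend="constant" if detrend else False, axis=1
    )
    mean_power = pxx.mean(axis=0)
    # drop DC; the entropy sum runs over f = 1 ... fs/2 only
    dc = mean_power[0]
    f, mean_power = f[1:], mean_power[1:]
    total = mean_power.sum()
    if not np.isfinite(total) or total <= 0 or total <= 1e-12 * dc:
        raise ValueError("traces are constant: total off-DC power is zero (degenerate)")
    return SpectralDensity(frequencies=f, power=mean_power / total, fs=fs)


def spectral_entropy(psd: SpectralDensity) -> float:
    """Shannon entropy (bits) of a normalized PSD, with 0 log 0 = 0."""
    if not psd.is_normalized:
        raise ValueError("PSD must be normalized (power summing to 1); see periodogram()")
    p = psd.power[psd.power > 0]
    return float(-(p * np.log2(p)).sum())


def per_cell_spectral_entropy(traces: np.ndarray, fs: float) -> float:
    """Mean over cells of each cell's own spectral entropy.

    The alternative pooling order to :func:`periodogram` +
    :func:`spectral_entropy` (which averages periodograms across the
    ensemble before normalizing): here each cell's periodogram is
    normalized and summarized on its own and the entropies are averaged.
    By Jensen's inequality this is never larger than the ensemble value.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    ents = [spectral_entropy(periodogram(row[None, :], fs=fs)) for row in traces]
    return float(np.mean(ents))


def spectral_entropy_fs_sweep(
    traces: np.ndarray, fs_values, *, native_fs: float
) -> list[float]:
    """Spectral entropy after resampling the traces to each rate in ``fs_values``.

    Traces sampled at ``native_fs`` are linearly interpolated onto a grid of
    rate fs spanning the same duration, and the ensemble spectral entropy is
    computed at each rate.  Beyond the rate that resolves all the signal
    power the entropy plateaus, which is the practical criterion for "fs
    large enough".
    """
    fs_values = list(fs_values)
    if any(b <= a for a, b in zip(fs_values, fs_values[1:])):
        raise ValueError("fs_values must be increasing")
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[1]
    t_native = np.arange(n) / native_fs
    out = []
    for fs in fs_values:
        # preserve the nominal window length n/native_fs so frequency bins nest
        m = max(int(round(n * fs / native_fs)), 2)
        t_new = np.arange(m) / fs  # np.interp holds the last sample beyond t_native[-1]
        res = np.stack([np.interp(t_new, t_native, row) for row in traces])
        out.append(spectral_entropy(periodogram(res, fs=fs)))
    return out


@dataclass
class PCDecomposition:
    """PCA loadings, explained-variance fractions and component covariance."""

    n_components: int
    components: np.ndarray  # n_components x genes, orthonormal rows
    explained_variance_fraction: np.ndarray
    covariance: np.ndarray  # diagonal covariance of the transformed data
    scores: np.ndarray | None = None  # cells x n_components

    def __post_init__(self):
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-6):
            raise ValueError("component loadings must be orthonormal")
        if np.any(np.diff(self.explained_variance_fraction) > 1e-10):
            raise ValueError("explained variance fractions must be non-increasing")


def pca_decompose(expression: np.ndarray, n_components: int) -> PCDecomposition:
    """Standard PCA of a (z-scored) cells x genes matrix; deterministic up to sign."""
    x = np.asarray(expression, dtype=float)
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds min(cells, genes)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    ev = pca.explained_variance_
    if np.any(ev <= 0):
        raise ValueError("requested components beyond the rank of the data")
    return PCDecomposition(
        n_components=n_components,
        components=pca.components_,
        explained_variance_fraction=pca.explained_variance_ratio_,
        covariance=np.diag(ev),
        scores=scores,
    )


def differential_entropy(pc: PCDecomposition) -> float:
    """Gaussian differential entropy (bits) of the retained components.

    ``h = (n/2) log2(2 pi e) + (1/2) log2 det Sigma_PC``; rotation-invariant
    and additive over components when Sigma_PC is diagonal.
    """
    sigma = np.asarray(pc.covariance, dtype=float)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("component covariance must be positive definite")
    n = pc.n_components
    return float(0.5 * n * LOG2_2PIE + 0.5 * logdet / np.log(2.0))


def variance_entropy_curves(expression: np.ndarray) -> pd.DataFrame:
    """Cumulative explained variance vs cumulative differential entropy per k.

    Returns a table over k = 1..n_components with both curves raw and
    normalized by their value at the last k.  The contrast between a
    fast-saturating variance curve and a steadily climbing entropy curve is
    the signature that explained variance under-represents information.
    """
    x = np.asarray(expression, dtype=float)
    n = min(x.shape)
    pc = pca_decompose(x, n)
    ev = np.diag(pc.covariance)
    evr = pc.explained_variance_fraction
    ks = np.arange(1, n + 1)
    cum_var = np.cumsum(evr)
    cum_ent = 0.5 * ks * LOG2_2PIE + 0.5 * np.cumsum(np.log2(ev))
    return pd.DataFrame(
        {
            "k": ks,
            "explained_variance": cum_var,
            "differential_entropy_bits": cum_ent,
            "explained_variance_norm": cum_var / cum_var[-1],
            "differential_entropy_norm": cum_ent / cum_ent[-1],
        }
    )


def pairwise_gene_correlations(expression: np.ndarray | pd.DataFrame):
    """Pearson correlation matrix between genes plus upper-triangle summary.

    Zero-variance genes yield NaN rows/columns and are reported in the
    summary under ``undefined_genes``; the summary means are taken over the
    defined upper-triangle entries only.
    """
    if isinstance(expression, pd.DataFrame):
        labels = list(expression.columns)
        x = expression.to_numpy(dtype=float)
    else:
        x = np.asarray(expression, dtype=float)
        labels = [f"g{i:03d}" for i in range(x.shape[1])]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    undefined = [labels[i] for i in np.nonzero(sd == 0)[0]]
    iu = np.triu_indices(len(labels), k=1)
    upper = corr[iu]
    valid = np.isfinite(upper)
    summary = {
        "mean_r": float(np.mean(upper[valid])) if valid.any() else np.nan,
        "mean_abs_r": float(np.mean(np.abs(upper[valid]))) if valid.any() else np.nan,
        "n_pairs": int(valid.sum()),
        "undefined_genes": undefined,
    }
    return pd.DataFrame(corr, index=labels, columns=labels), summary
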