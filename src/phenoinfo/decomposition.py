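"""Information decomposition over genes.

Per-gene and gene-pair mutual information with the phenotype, the pairwise
synergy-redundancy index

    SRI(G_i, G_j | Ca) = I({G_i, G_j}; Ca) - I(G_i; Ca) - I(G_j; Ca)

(negative = the pair shares information about the phenotype, positive = the
pair is synergistic, zero = unique or uninformative), annotation-level SRI
summaries, the nonredundant-information extrapolation

    NRI(k) = E[I({G_1..G_k}; Ca)] * n / k

with the redundancy-explained fraction

    RE(k) = 1 - (NRI(k) - I(G; Ca)) / (NRI(1) - I(G; Ca)),

and the MI between leading principal components and the phenotype.

All estimates go through the replicated, bias-corrected MINE chain in
:mod:`phenoinfo.mine`; the single-gene constituents of every SRI pair are
computed once and reused, so an SRI value is exact bookkeeping over its three
constituent estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import rng_for
from .dataset import PairedDataset
from .entropy import LOG2_2PIE, pca_decompose
from .mine import MIEstimate, MineConfig, estimate_mi

__all__ = [
    "PerGeneMI",
    "SRIMatrix",
    "RedundancyCurve",
    "set_mi",
    "per_gene_mi",
    "gene_gene_mi",
    "sri_pair",
    "sri_matrix",
    "annotation_sri_summary",
    "redundancy_explained",
    "pc_phenotype_mi",
]


def _require_normalized(dataset: PairedDataset) -> None:
    if dataset.preprocessing_state != "normalized":
        raise ValueError("dataset must be preprocessed (z-scored); call preprocess() first")


def _seeded(config: MineConfig, *labels) -> MineConfig:
    from dataclasses import replace

    return replace(config, seed=int(rng_for(config.seed, *labels).integers(2**31)))


def set_mi(dataset: PairedDataset, genes, config: MineConfig) -> MIEstimate:
    """Joint MI between a set of gene columns and the full trace matrix.

    The gene list is canonicalized (sorted) so that the same set always maps
    to the same input ordering and seed, whatever path requested it.
    """
    _require_normalized(dataset)
    genes = sorted(genes)
    x = dataset.counts[genes].to_numpy(dtype=np.float32)
    y = dataset.traces_array().astype(np.float32)
    cfg = _seeded(config, "set", *sorted(genes))
    return estimate_mi(x, y, cfg, labels=("+".join(map(str, genes)), "trace"))


@dataclass
class PerGeneMI:
    """Per-gene MI estimates and their standard summaries."""

    table: pd.DataFrame  # sorted ascending by MI; columns gene, mi_bits, spread, ...
    estimates: dict  # gene -> MIEstimate
    n_failed: int

    @property
    def mean_mi(self) -> float:
        return float(self.table["mi_bits"].mean())

    def cumulative_descending(self) -> pd.DataFrame:
        """Cumulative sum of per-gene MI, genes sorted most-informative first."""
        desc = self.table.sort_values("mi_bits", ascending=False).reset_index(drop=True)
        desc["cumulative_bits"] = desc["mi_bits"].cumsum()
        return desc


def per_gene_mi(dataset: PairedDataset, config: MineConfig) -> PerGeneMI:
    """I(G_i; Ca) for every gene, sorted from least to greatest.

    Failed genes (no converged replicate) are flagged with NaN and excluded
    from the summaries.
    """
    _require_normalized(dataset)
    y = dataset.traces_array().astype(np.float32)
    rows, estimates = [], {}
    for gene in dataset.gene_labels:
        x = dataset.counts[[gene]].to_numpy(dtype=np.float32)
        est = estimate_mi(x, y, _seeded(config, "gene", gene), labels=(gene, "trace"))
        estimates[gene] = est
        rows.append(
            {
                "gene": gene,
                "mi_bits": est.value if est.ok else np.nan,
                "spread_bits": est.spread,
                "n_converged": est.n_converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("mi_bits", na_position="first").reset_index(drop=True)
    return PerGeneMI(table=table, estimates=estimates, n_failed=int(table["mi_bits"].isna().sum()))


@dataclass
class GeneGeneMI:
    """Pairwise gene-gene MI and its relation to gene-phenotype MI."""

    values: pd.DataFrame  # symmetric gene x gene, NaN diagonal
    mean_to_others: pd.Series
    spearman_r: float
    spearman_p: float
    n_failed: int


def gene_gene_mi(
    dataset: PairedDataset, config: MineConfig, per_gene: PerGeneMI | None = None
) -> GeneGeneMI:
    """I(G_i; G_j) for all gene pairs, plus the Fig-style rank correlation.

    The Spearman correlation relates each gene's mean MI to the other genes
    with its MI to the phenotype ("summary genes" carry both).  Undefined
    (flagged NaN) when fewer than 3 genes have defined values.
    """
    _require_normalized(dataset)
    genes = dataset.gene_labels
    n = len(genes)
    mat = np.full((n, n), np.nan)
    n_failed = 0
    for i in range(n):
        xi = dataset.counts[[genes[i]]].to_numpy(dtype=np.float32)
        for j in range(i + 1, n):
            xj = dataset.counts[[genes[j]]].to_numpy(dtype=np.float32)
            est = estimate_mi(
                xi, xj, _seeded(config, "gg", genes[i], genes[j]), labels=(genes[i], genes[j])
            )
            if est.ok:
                mat[i, j] = mat[j, i] = est.value
            else:
                n_failed += 1
    values = pd.DataFrame(mat, index=genes, columns=genes)
    mean_to_others = values.mean(axis=1, skipna=True)

    r, p = np.nan, np.nan
    if per_gene is None:
        per_gene = per_gene_mi(dataset, config)
    pheno = per_gene.table.set_index("gene")["mi_bits"].reindex(genes)
    ok = mean_to_others.notna() & pheno.notna()
    if ok.sum() >= 3:
        r, p = stats.spearmanr(mean_to_others[ok], pheno[ok])
    return GeneGeneMI(
        values=values,
        mean_to_others=mean_to_others,
        spearman_r=float(r),
        spearman_p=float(p),
        n_failed=n_failed,
    )


@dataclass
class PairSRI:
    """One SRI value and its constituents; spread propagated in quadrature."""

    sri_bits: float | None
    spread_bits: float
    mi_pair: MIEstimate
    mi_i: MIEstimate
    mi_j: MIEstimate


def sri_pair(
    dataset: PairedDataset,
    i: int | str,
    j: int | str,
    config: MineConfig,
    single_cache: dict | None = None,
) -> PairSRI:
    """SRI(G_i, G_j | Ca) in bits with quadrature-propagated spread.

    ``single_cache`` (gene -> MIEstimate) lets callers reuse single-gene
    constituents across many pairs; :func:`sri_matrix` relies on this so all
    pairs share consistent constituents.  The value is withheld (None) if any
    constituent estimate failed.
    """
    genes = dataset.gene_labels
    gi = genes[i] if isinstance(i, (int, np.integer)) else i
    gj = genes[j] if isinstance(j, (int, np.integer)) else j
    if gi == gj:
        raise ValueError("sri_pair requires two distinct genes")
    y = dataset.traces_array().astype(np.float32)

    def single(g):
        if single_cache is not None and g in single_cache:
            return single_cache[g]
        est = estimate_mi(
            dataset.counts[[g]].to_numpy(dtype=np.float32), y,
            _seeded(config, "gene", g), labels=(g, "trace"),
        )
        if single_cache is not None:
            single_cache[g] = est
        return est

    _require_normalized(dataset)
    mi_i, mi_j = single(gi), single(gj)
    mi_pair = set_mi(dataset, [gi, gj], config)
    if not (mi_pair.ok and mi_i.ok and mi_j.ok):
        return PairSRI(None, np.nan, mi_pair, mi_i, mi_j)
    sri = mi_pair.value - mi_i.value - mi_j.value
    spread = float(np.sqrt(mi_pair.spread**2 + mi_i.spread**2 + mi_j.spread**2))
    return PairSRI(float(sri), spread, mi_pair, mi_i, mi_j)


@dataclass
class SRIMatrix:
    """Gene x gene SRI values (bits) conditioned on the phenotype."""

    values: pd.DataFrame  # symmetric; diagonal = -I(G_i;Ca), excluded from summaries
    per_pair_spread: pd.DataFrame
    gene_labels: list
    per_gene_mean: pd.Series = None
    single_gene_mi: pd.Series = None
    n_failed_pairs: int = 0
    spearman_r: float = np.nan
    spearman_p: float = np.nan

    @property
    def mean_sri(self) -> float:
        """Mean SRI over unique off-diagonal pairs."""
        iu = np.triu_indices(len(self.gene_labels), k=1)
        vals = self.values.to_numpy()[iu]
        return float(np.nanmean(vals))

    def offdiagonal_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.gene_labels), k=1)
        vals = self.values.to_numpy()[iu]
        return vals[np.isfinite(vals)]


def sri_matrix(
    dataset: PairedDataset, config: MineConfig, per_gene: PerGeneMI | None = None
) -> SRIMatrix:
    """SRI for every unique gene pair, with per-gene and rank summaries.

    Single-gene constituents are estimated once (or taken from ``per_gene``)
    and shared by all pairs.  The diagonal is set to -I(G_i; Ca) — the
    duplicate-gene limit — and excluded from all summaries.  The Spearman
    statistic correlates each gene's MI to the phenotype with its mean SRI
    over partners (more informative genes tend to be more redundant,
    i.e. the correlation is negative on redundant data).
    """
    _require_normalized(dataset)
    genes = dataset.gene_labels
    n = len(genes)
    if per_gene is None:
        per_gene = per_gene_mi(dataset, config)
    cache = dict(per_gene.estimates)

    vals = np.full((n, n), np.nan)
    spreads = np.full((n, n), np.nan)
    n_failed = 0
    for i in range(n):
        est = cache[genes[i]]
        if est.ok:
            vals[i, i] = -est.value
    for i in range(n):
        for j in range(i + 1, n):
            pair = sri_pair(dataset, genes[i], genes[j], config, single_cache=cache)
            if pair.sri_bits is None:
                n_failed += 1
                continue
            vals[i, j] = vals[j, i] = pair.sri_bits
            spreads[i, j] = spreads[j, i] = pair.spread_bits

    values = pd.DataFrame(vals, index=genes, columns=genes)
    off = values.where(~np.eye(n, dtype=bool))
    per_gene_mean = off.mean(axis=1, skipna=True)
    single = pd.Series({g: (cache[g].value if cache[g].ok else np.nan) for g in genes})

    r, p = np.nan, np.nan
    ok = per_gene_mean.notna() & single.notna()
    if ok.sum() >= 3:
        r, p = stats.spearmanr(single[ok], per_gene_mean[ok])
    return SRIMatrix(
        values=values,
        per_pair_spread=pd.DataFrame(spreads, index=genes, columns=genes),
        gene_labels=list(genes),
        per_gene_mean=per_gene_mean,
        single_gene_mi=single,
        n_failed_pairs=n_failed,
        spearman_r=float(r),
        spearman_p=float(p),
    )


def annotation_sri_summary(sri: SRIMatrix, annotation_map: dict) -> pd.DataFrame:
    """Label x label mean SRI over all gene pairs carrying those labels.

    Every gene must be labeled (use "Other" as a catch-all).  Within-label
    cells average within-label pairs; a label with a single gene has no
    within-label pair and its diagonal cell is NaN.
    """
    genes = sri.gene_labels
    missing = [g for g in genes if g not in annotation_map]
    if missing:
        raise ValueError(f"genes without annotation: {missing}")
    labels = sorted(set(annotation_map[g] for g in genes))
    sums = {(a, b): [] for a in labels for b in labels}
    vals = sri.values.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            v = vals[i, j]
            if not np.isfinite(v):
                continue
            a, b = annotation_map[genes[i]], annotation_map[genes[j]]
            sums[(a, b)].append(v)
            if a != b:
                sums[(b, a)].append(v)
    out = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for a in labels:
        for b in labels:
            vv = sums[(a, b)]
            out.loc[a, b] = np.mean(vv) if vv else np.nan
    return out


@dataclass
class RedundancyCurve:
    """NRI and redundancy-explained as functions of gene-set size."""

    table: pd.DataFrame  # columns k, mean_set_mi, nri, redundancy_explained
    full_mi: float
    n_genes: int
    valid: bool = True
    message: str = ""


def redundancy_explained(
    mean_set_mi_by_k: dict, full_mi: float | None = None, n: int | None = None
) -> RedundancyCurve:
    """Nonredundant information and redundancy explained per set size.

    ``mean_set_mi_by_k`` maps set size k to the mean joint MI of sampled
    size-k gene sets (k=1 must be present — its NRI is the no-redundancy
    extrapolation anchor, equal to the sum of single-gene MIs).  ``full_mi``
    defaults to the k=n entry.  By construction RE(1) = 0 and RE(n) = 1.

    If NRI(1) <= full MI there is no superfluous information to explain and
    RE is undefined; the curve is returned flagged invalid with RE = NaN.
    """
    ks = sorted(mean_set_mi_by_k)
    if 1 not in mean_set_mi_by_k:
        raise ValueError("mean_set_mi_by_k must contain k=1")
    if n is None:
        n = max(ks)
    if full_mi is None:
        if n not in mean_set_mi_by_k:
            raise ValueError("full_mi not given and k=n not in table")
        full_mi = float(mean_set_mi_by_k[n])

    rows = []
    nri1 = mean_set_mi_by_k[1] * n
    valid = nri1 > full_mi
    for k in ks:
        e_ik = float(mean_set_mi_by_k[k])
        nri = e_ik * n / k
        re = 1.0 - (nri - full_mi) / (nri1 - full_mi) if valid else np.nan
        rows.append({"k": k, "mean_set_mi": e_ik, "nri": nri, "redundancy_explained": re})
    return RedundancyCurve(
        table=pd.DataFrame(rows),
        full_mi=float(full_mi),
        n_genes=int(n),
        valid=bool(valid),
        message="" if valid else "NRI(1) <= full MI: no redundancy to explain",
    )


def pc_phenotype_mi(
    dataset: PairedDataset, config: MineConfig, max_components: int
) -> pd.DataFrame:
    """MI between the first k principal components and the traces, k=1..max.

    Returns the raw and max-normalized MI curve alongside the cumulative
    Gaussian differential entropy of the same components (also normalized),
    the pair of curves whose contrast shows that phenotype-relevant
    information concentrates in far fewer components than entropy does.
    """
    _require_normalized(dataset)
    pc = pca_decompose(dataset.counts_array(), max_components)
    y = dataset.traces_array().astype(np.float32)
    ev = np.diag(pc.covariance)
    rows = []
    for k in range(1, max_components + 1):
        x = pc.scores[:, :k].astype(np.float32)
        est = estimate_mi(x, y, _seeded(config, "pc", k), labels=(f"PC1..{k}", "trace"))
        ent = 0.5 * k * LOG2_2PIE + 0.5 * float(np.sum(np.log2(ev[:k])))
        rows.append(
            {
                "k": k,
                "mi_bits": est.value if est.ok else np.nan,
                "spread_bits": est.spread,
                "diff_entropy_bits": ent,
            }
        )
    out = pd.DataFrame(rows)
    for col, norm_col in (
        ("mi_bits", "mi_norm"),
        ("diff_entropy_bits", "diff_entropy_norm"),
    ):
        mx = np.nanmax(np.abs(out[col].to_numpy())) if out[col].notna().any() else np.nan
        out[norm_col] = out[col] / mx if mx and np.isfinite(mx) else np.nan
    return out
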