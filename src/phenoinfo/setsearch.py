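"""Gene-set construction strategies.

How much phenotype information does a set of k genes carry?  Three strategies
trace joint MI against set size:

* ``greedy maximize`` — start from the most informative single gene and at
  every step add the candidate that raises joint MI the most (an upper-bound
  heuristic; greedy is not guaranteed optimal);
* ``greedy minimize`` — the mirror image, always adding the least
  informative candidate, whose approximately linear growth exposes the
  average unique information per gene (its slope);
* ``random`` — uniformly sampled sets per size, whose per-size mean feeds
  the nonredundant-information extrapolation.

Candidate scanning during greedy search runs the estimator at a reduced
budget (one replicate, no jackknife); each chosen set is then re-estimated
at the full budget, and the full candidate-evaluation log is kept for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb

import numpy as np
import pandas as pd

from ._seeds import rng_for
from .dataset import PairedDataset
from .decomposition import set_mi
from .mine import MineConfig

__all__ = ["SetSearchTrace", "greedy_search", "random_sets", "lower_bound_slope", "SlopeFit"]


@dataclass
class SetSearchTrace:
    """Joint-MI-vs-set-size results for one strategy."""

    strategy: str  # "upper" | "lower" | "random"
    order: list  # greedy: genes in addition order; random: empty
    sizes: list
    mi_by_size: list
    spread_by_size: list
    samples: dict = field(default_factory=dict)  # random: size -> list[(genes, mi)]
    candidate_log: pd.DataFrame | None = None

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": self.sizes, "mi_bits": self.mi_by_size, "spread_bits": self.spread_by_size}
        )

    def quartile_summary(self) -> pd.DataFrame:
        """Per-size median and quartiles over the random samples."""
        if self.strategy != "random" or not self.samples:
            raise ValueError("quartile summary is defined for random-set traces")
        rows = []
        for k in sorted(self.samples):
            vals = [mi for _, mi in self.samples[k] if mi is not None]
            if not vals:
                rows.append({"size": k, "q25": np.nan, "median": np.nan, "q75": np.nan})
                continue
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            rows.append({"size": k, "q25": q25, "median": med, "q75": q75})
        return pd.DataFrame(rows)

    def mean_mi_by_size(self) -> dict:
        """size -> mean MI (over samples for random, the single value otherwise)."""
        if self.strategy == "random" and self.samples:
            return {
                k: float(np.mean([mi for _, mi in v if mi is not None]))
                for k, v in self.samples.items()
            }
        return dict(zip(self.sizes, self.mi_by_size))


def _default_scan_config(config: MineConfig) -> MineConfig:
    # single replicate, no jackknife: ~6x cheaper than a full estimate while
    # still training to plateau (shorter runs fail the drift diagnostic)
    return replace(config, n_replicates=1, n_jackknife=0)


def greedy_search(
    dataset: PairedDataset,
    config: MineConfig,
    direction: str = "maximize",
    max_size: int | None = None,
    scan_config: MineConfig | None = None,
) -> SetSearchTrace:
    """Greedy most- (least-) informative gene-set construction.

    At each step every remaining candidate is scored by the joint MI of the
    current set plus that candidate (reduced-budget scan); the argmax
    (argmin) is kept, ties broken by the smallest gene index, and the chosen
    set is re-estimated at the full budget.  A candidate whose scan fit was
    screened out is still ranked by its training-tail fallback score (and
    recorded as unconverged); only candidates with no usable score at all
    are skipped.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    genes = dataset.gene_labels
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    max_size = len(genes) if max_size is None else min(max_size, len(genes))
    scan_config = _default_scan_config(config) if scan_config is None else scan_config

    chosen: list = []
    sizes, mis, spreads = [], [], []
    log_rows = []
    sign = 1.0 if direction == "maximize" else -1.0

    while len(chosen) < max_size:
        remaining = [g for g in genes if g not in chosen]
        best_gene, best_score = None, -np.inf
        for g in remaining:
            est = set_mi(dataset, chosen + [g], scan_config)
            score = est.ranking_score()
            log_rows.append(
                {
                    "size": len(chosen) + 1,
                    "candidate": g,
                    "scan_mi_bits": score,
                    "converged": est.ok,
                }
            )
            if not np.isfinite(score):
                continue
            if sign * score > best_score:
                best_score = sign * score
                best_gene = g
        if best_gene is None:
            break  # every candidate failed at this size
        chosen.append(best_gene)
        full = set_mi(dataset, chosen, config)
        sizes.append(len(chosen))
        mis.append(full.value if full.ok else np.nan)
        spreads.append(full.spread)

    return SetSearchTrace(
        strategy="upper" if direction == "maximize" else "lower",
        order=list(chosen),
        sizes=sizes,
        mi_by_size=mis,
        spread_by_size=spreads,
        candidate_log=pd.DataFrame(log_rows),
    )


def random_sets(
    dataset: PairedDataset,
    config: MineConfig,
    sizes=None,
    samples_per_size: int = 4,
) -> SetSearchTrace:
    """Uniformly sampled gene sets per size; medians/quartiles per size.

    Sets are drawn without replacement within a set and deduplicated per
    size; when a size admits fewer distinct sets than requested (e.g. the
    full set at k = n) only the distinct ones are evaluated.  The per-size
    mean feeds :func:`phenoinfo.decomposition.redundancy_explained`.
    """
    genes = dataset.gene_labels
    n = len(genes)
    sizes = list(range(1, n + 1)) if sizes is None else sorted(sizes)
    if any(k < 1 or k > n for k in sizes):
        raise ValueError("sizes must lie in 1..n_genes")

    rng = rng_for(config.seed, "random-sets")
    samples: dict = {}
    mis, spreads = [], []
    for k in sizes:
        n_draw = min(samples_per_size, comb(n, k))
        seen, drawn = set(), []
        while len(drawn) < n_draw:
            s = tuple(sorted(rng.choice(n, size=k, replace=False)))
            if s in seen:
                continue
            seen.add(s)
            drawn.append([genes[i] for i in s])
        per = []
        for subset in drawn:
            est = set_mi(dataset, subset, config)
            per.append((tuple(subset), est.value if est.ok else None))
        samples[k] = per
        vals = [mi for _, mi in per if mi is not None]
        mis.append(float(np.mean(vals)) if vals else np.nan)
        spreads.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)

    return SetSearchTrace(
        strategy="random", order=[], sizes=sizes, mi_by_size=mis,
        spread_by_size=spreads, samples=samples,
    )


@dataclass
class SlopeFit:
    """Least-squares slope of the lower-bound trace over its linear region."""

    slope_bits_per_gene: float
    intercept_bits: float
    sizes_used: list


def lower_bound_slope(trace: SetSearchTrace, drop_last: int = 5) -> SlopeFit:
    """Average unique information per gene: slope of the minimize trace.

    Fits MI vs size by least squares over the linear region, which defaults
    to all sizes except the last ``drop_last`` (the tail bends upward as the
    most informative genes finally enter).  Requires at least 3 sizes.
    """
    if trace.strategy != "lower":
        raise ValueError("slope is defined for the greedy-minimize (lower) trace")
    sizes = np.asarray(trace.sizes, dtype=float)
    mis = np.asarray(trace.mi_by_size, dtype=float)
    ok = np.isfinite(mis)
    sizes, mis = sizes[ok], mis[ok]
    if len(sizes) < 3:
        raise ValueError("need at least 3 sizes to fit a slope")
    if len(sizes) - drop_last >= 3:
        sizes, mis = sizes[: len(sizes) - drop_last], mis[: len(mis) - drop_last]
    slope, intercept = np.polyfit(sizes, mis, 1)
    return SlopeFit(float(slope), float(intercept), sizes_used=list(sizes.astype(int)))
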