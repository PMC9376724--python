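"""End-to-end analysis orchestration.

``run_full_analysis`` sequences the whole study on a paired dataset (loaded
from tables or simulated on the fly): modality structure (correlations,
variance-vs-entropy curves, spectral entropy), per-gene and gene-gene MI,
the SRI matrix with annotation summary, greedy/random set searches, the
redundancy-explained curve and the PC-vs-phenotype MI curve.

Every artifact is written as a delimited table next to a small JSON sidecar
carrying the config hash and global seed; identical configs reproduce
bit-identical outputs, so any artifact can be regenerated from its embedded
provenance.  Stage failures isolate: downstream stages that need a failed
stage's output are skipped with a recorded reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import load_paired, preprocess
from .decomposition import (
    gene_gene_mi,
    pc_phenotype_mi,
    per_gene_mi,
    redundancy_explained,
    set_mi,
    sri_matrix,
    annotation_sri_summary,
)
from .entropy import (
    pairwise_gene_correlations,
    periodogram,
    spectral_entropy,
    variance_entropy_curves,
)
from .mine import MineConfig
from .setsearch import greedy_search, lower_bound_slope, random_sets
from .synthetic import PairedSimSpec, sample_paired_dataset

logger = logging.getLogger("phenoinfo")

__all__ = ["RunConfig", "run_full_analysis", "ALL_STAGES"]

ALL_STAGES = (
    "structure",
    "per_gene_mi",
    "gene_gene_mi",
    "sri",
    "search",
    "redundancy",
    "pc_mi",
)


@dataclass
class RunConfig:
    """Everything a full run needs; hashable for provenance."""

    counts_path: str | None = None
    traces_path: str | None = None
    annotations_path: str | None = None
    sim_spec: PairedSimSpec | None = None
    mine: MineConfig = field(default_factory=MineConfig)
    stages: tuple = ALL_STAGES
    output_dir: str = "phenoinfo_results"
    seed: int = 0
    fs_hz: float | None = None  # trace sampling rate; default 1/dt from data
    max_pc_components: int = 6
    samples_per_size: int = 4
    search_max_size: int | None = None

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _write_with_meta(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int) -> None:
    df.to_csv(path, sep="\t", index=False)
    meta = {"config_hash": cfg_hash, "seed": seed}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def _resolve_dataset(config: RunConfig):
    if config.sim_spec is not None:
        ds, truth = sample_paired_dataset(config.sim_spec)
        return ds, truth
    if not (config.counts_path and config.traces_path):
        raise ValueError("RunConfig needs either sim_spec or counts_path+traces_path")
    return load_paired(config.counts_path, config.traces_path, config.annotations_path), None


def run_full_analysis(config: RunConfig) -> dict:
    """Run the configured stages and return the results bundle.

    The bundle maps stage names to in-memory results; a ``summary`` entry
    mirrors the headline quantities (total MI, mean per-gene MI, mean SRI,
    set sizes reaching half the total information, spectral entropy) and is
    written to ``summary.json``.  Stage failures are caught and recorded in
    ``bundle["errors"]``; stages depending on a failed stage are skipped.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    seed = config.seed
    bundle: dict = {"config_hash": cfg_hash, "errors": {}}
    summary: dict = {"config_hash": cfg_hash, "seed": seed}

    raw, truth = _resolve_dataset(config)
    bundle["truth"] = truth
    ds = preprocess(raw)
    mine_cfg = dataclasses.replace(config.mine, seed=seed)
    fs = config.fs_hz or (1.0 / raw.dt_seconds if raw.dt_seconds else 1.0)

    def run_stage(name, fn):
        if name not in config.stages:
            return None
        try:
            res = fn()
            bundle[name] = res
            logger.info("stage %s done", name)
            return res
        except Exception as err:  # noqa: BLE001 - stage isolation is the contract
            logger.error("stage %s failed: %s", name, err)
            bundle["errors"][name] = str(err)
            return None

    # --- structure: single-modality measures ------------------------------
    def _structure():
        corr, corr_summary = pairwise_gene_correlations(raw.counts)
        curves = variance_entropy_curves(ds.counts_array())
        h_spec = spectral_entropy(periodogram(raw.traces_array(), fs=fs))
        _write_with_meta(curves, out / "variance_entropy.tsv", cfg_hash, seed)
        corr.to_csv(out / "gene_correlations.tsv", sep="\t")
        summary["spectral_entropy_bits"] = h_spec
        summary["mean_pairwise_r"] = corr_summary["mean_r"]
        return {"correlations": corr, "corr_summary": corr_summary,
                "curves": curves, "spectral_entropy_bits": h_spec}

    run_stage("structure", _structure)

    # --- total MI (needed by several stages) ------------------------------
    total_est = None
    if set(config.stages) & {"per_gene_mi", "sri", "search", "redundancy", "pc_mi"}:
        total_est = set_mi(ds, ds.gene_labels, mine_cfg)
        summary["total_mi_bits"] = total_est.value
        summary["total_mi_spread_bits"] = total_est.spread

    def _per_gene():
        res = per_gene_mi(ds, mine_cfg)
        _write_with_meta(res.table, out / "per_gene_mi.tsv", cfg_hash, seed)
        summary["mean_per_gene_mi_bits"] = res.mean_mi
        return res

    pg = run_stage("per_gene_mi", _per_gene)

    def _gene_gene():
        res = gene_gene_mi(ds, mine_cfg, per_gene=pg)
        res.values.to_csv(out / "gene_gene_mi.tsv", sep="\t")
        summary["gene_gene_spearman_r"] = res.spearman_r
        return res

    run_stage("gene_gene_mi", _gene_gene)

    def _sri():
        res = sri_matrix(ds, mine_cfg, per_gene=pg)
        res.values.to_csv(out / "sri_matrix.tsv", sep="\t")
        summary["mean_sri_bits"] = res.mean_sri
        summary["sri_spearman_r"] = res.spearman_r
        if ds.annotation_map:
            ann = annotation_sri_summary(res, ds.annotation_map)
            ann.to_csv(out / "annotation_sri.tsv", sep="\t")
            bundle["annotation_sri"] = ann
        return res

    run_stage("sri", _sri)

    def _search():
        upper = greedy_search(ds, mine_cfg, "maximize", max_size=config.search_max_size)
        lower = greedy_search(ds, mine_cfg, "minimize", max_size=config.search_max_size)
        rand = random_sets(ds, mine_cfg, samples_per_size=config.samples_per_size)
        for name, tr in (("upper", upper), ("lower", lower), ("random", rand)):
            _write_with_meta(tr.as_table(), out / f"search_{name}.tsv", cfg_hash, seed)
        try:
            slope = lower_bound_slope(lower)
        except ValueError:
            slope = None
        if slope:
            summary["lower_bound_slope_bits_per_gene"] = slope.slope_bits_per_gene
        if total_est and total_est.ok:
            half = 0.5 * total_est.value
            for name, tr in (("upper", upper), ("random", rand)):
                sizes = [s for s, m in zip(tr.sizes, tr.mi_by_size)
                         if m is not None and np.isfinite(m) and m >= half]
                summary[f"{name}_size_at_half_total_mi"] = min(sizes) if sizes else None
        return {"upper": upper, "lower": lower, "random": rand, "slope": slope}

    search_res = run_stage("search", _search)

    def _redundancy():
        if search_res is None:
            raise RuntimeError("skipped: search stage failed or disabled")
        rand = search_res["random"]
        table = rand.mean_mi_by_size()
        full = total_est.value if (total_est and total_est.ok) else None
        curve = redundancy_explained(table, full_mi=full, n=ds.n_genes)
        _write_with_meta(curve.table, out / "redundancy.tsv", cfg_hash, seed)
        return curve

    run_stage("redundancy", _redundancy)

    def _pc_mi():
        kmax = min(config.max_pc_components, ds.n_genes, ds.n_cells)
        res = pc_phenotype_mi(ds, mine_cfg, kmax)
        _write_with_meta(res, out / "pc_mi.tsv", cfg_hash, seed)
        return res

    run_stage("pc_mi", _pc_mi)

    bundle["summary"] = summary
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return bundle
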