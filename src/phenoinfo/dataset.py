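"""Paired single-cell dataset container, I/O and preprocessing.

A :class:`PairedDataset` holds two row-aligned per-cell matrices: transcript
counts (cells x genes, non-negative integers) and a continuous signaling
trace (cells x timepoints), plus optional gene annotations.

Preprocessing is deliberately unusual and is a hard contract here: each
modality is z-scored with ONE global mean and standard deviation computed
over its whole matrix — not per column — preserving relative magnitude
across genes and across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PairedDataset", "load_paired", "preprocess"]


@dataclass
class PairedDataset:
    """Aligned counts and traces with provenance of any normalization."""

    counts: pd.DataFrame  # cells x genes
    traces: pd.DataFrame  # cells x timepoints
    annotation_map: dict | None = None  # gene -> label
    preprocessing_state: str = "raw"  # "raw" | "normalized"
    norm_params: dict = field(default_factory=dict)
    dt_seconds: float | None = None

    def __post_init__(self):
        if not self.counts.index.equals(self.traces.index):
            raise ValueError("counts and traces must share identical cell ids")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated cell ids: {dups}")
        if self.preprocessing_state == "raw":
            arr = self.counts.to_numpy()
            if np.any(arr < 0):
                raise ValueError("raw counts must be non-negative")

    # -- convenience -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.traces.shape[1]

    @property
    def gene_labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.index)

    def counts_array(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def traces_array(self) -> np.ndarray:
        return self.traces.to_numpy(dtype=float)

    def zero_count_genes(self) -> list[str]:
        tot = self.counts.sum(axis=0)
        return list(tot.index[tot == 0])

    @classmethod
    def from_arrays(
        cls,
        counts: np.ndarray,
        traces: np.ndarray,
        gene_labels=None,
        cell_ids=None,
        annotation_map=None,
        dt_seconds=None,
    ) -> "PairedDataset":
        counts = np.asarray(counts)
        traces = np.asarray(traces)
        if counts.shape[0] != traces.shape[0]:
            raise ValueError("counts and traces must have the same number of cells")
        if gene_labels is None:
            gene_labels = [f"g{i:03d}" for i in range(counts.shape[1])]
        if cell_ids is None:
            cell_ids = [f"cell{i:05d}" for i in range(counts.shape[0])]
        return cls(
            counts=pd.DataFrame(counts, index=pd.Index(cell_ids, name="cell_id"),
                                columns=gene_labels),
            traces=pd.DataFrame(traces, index=pd.Index(cell_ids, name="cell_id"),
                                columns=[f"t{j}" for j in range(traces.shape[1])]),
            annotation_map=annotation_map,
            dt_seconds=dt_seconds,
        )

    # -- I/O ---------------------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        """Write counts and traces as TSV tables (header row, cell_id index)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(path / "counts.tsv", sep="\t")
        self.traces.to_csv(path / "traces.tsv", sep="\t")
        if self.annotation_map:
            pd.Series(self.annotation_map, name="annotation").rename_axis("gene").to_csv(
                path / "annotations.tsv", sep="\t"
            )


def load_paired(
    counts_path: str | Path,
    traces_path: str | Path,
    annotations_path: str | Path | None = None,
) -> PairedDataset:
    """Load a paired dataset from delimited tables, aligning rows by cell id.

    Both tables must carry the same set of cell ids (first column); rows may
    appear in any order.  Cells present in only one table, or duplicated ids,
    are rejected with the offending ids listed.  The dataset is returned raw.
    """
    counts = pd.read_csv(counts_path, sep=None, engine="python", index_col=0)
    traces = pd.read_csv(traces_path, sep=None, engine="python", index_col=0)
    for name, df in (("counts", counts), ("traces", traces)):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"{name} table has duplicated cell ids: {dups}")
    only_counts = counts.index.difference(traces.index)
    only_traces = traces.index.difference(counts.index)
    if len(only_counts) or len(only_traces):
        raise ValueError(
            "cell ids not shared by both tables: "
            f"counts-only={list(only_counts)}, traces-only={list(only_traces)}"
        )
    traces = traces.loc[counts.index]

    annotation_map = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep=None, engine="python", index_col=0)
        annotation_map = ann.iloc[:, 0].to_dict()

    ds = PairedDataset(counts=counts, traces=traces, annotation_map=annotation_map)
    zero = ds.zero_count_genes()
    if zero:
        import warnings

        warnings.warn(f"genes with zero total count: {zero}", stacklevel=2)
    return ds


def preprocess(dataset: PairedDataset) -> PairedDataset:
    """Z-score each modality with a single global mean and SD.

    One (mean, sd) pair is computed over the entire counts matrix and one
    over the entire traces matrix; every entry of a modality is transformed
    with the same two numbers, so a gene with 10x the counts of another keeps
    10x its centered magnitude.  The parameters are stored in
    ``norm_params`` for inversion.  Idempotent: a normalized dataset is
    returned unchanged.
    """
    if dataset.preprocessing_state == "normalized":
        return dataset
    out = {}
    frames = {}
    for name, df in (("counts", dataset.counts), ("traces", dataset.traces)):
        arr = df.to_numpy(dtype=float)
        mu = float(arr.mean())
        sd = float(arr.std())
        if sd == 0.0:
            raise ValueError(f"{name} matrix has zero global variance; cannot z-score")
        frames[name] = pd.DataFrame((arr - mu) / sd, index=df.index, columns=df.columns)
        out[name] = {"mean": mu, "sd": sd}
    return replace(
        dataset,
        counts=frames["counts"],
        traces=frames["traces"],
        preprocessing_state="normalized",
        norm_params=out,
    )
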