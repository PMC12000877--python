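"""Reading and writing of the pipeline's on-disk formats.

Counts travel as matrix-market (cells x genes) with sidecar gene/cell
lists, or as a single delimited table; cell metadata (cell_id, theta,
phase) and per-gene degradation rates (gene_id, rate_per_hour) are
tab-delimited tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data import AgeAnnotatedCounts

__all__ = ["write_dataset", "read_dataset", "read_rates", "to_anndata"]


def write_dataset(
    directory,
    data: AgeAnnotatedCounts,
    rates: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
    meta: dict | None = None,
) -> Path:
    """Write counts.mtx + genes/cells tables (and optional rate/truth
    tables and a JSON provenance record) into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "counts.mtx", sparse.coo_matrix(data.counts))
    pd.DataFrame({"gene_id": data.gene_ids}).to_csv(
        directory / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"cell_id": data.cell_ids, "theta": data.theta, "phase": data.phase}
    ).to_csv(directory / "cells.tsv", sep="\t", index=False)
    if rates is not None:
        rates.to_csv(directory / "rates.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    if meta is not None:
        (directory / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
    return directory


def read_dataset(directory) -> AgeAnnotatedCounts:
    directory = Path(directory)
    counts = np.asarray(spio.mmread(directory / "counts.mtx").todense()).astype(np.int64)
    genes = pd.read_csv(directory / "genes.tsv", sep="\t")
    cells = pd.read_csv(directory / "cells.tsv", sep="\t")
    return AgeAnnotatedCounts(
        counts=counts,
        theta=cells["theta"].to_numpy(),
        phase=cells["phase"].to_numpy(dtype=object),
        gene_ids=genes["gene_id"].to_numpy(),
        cell_ids=cells["cell_id"].to_numpy(),
    )


def read_rates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "rate_per_hour"} <= set(df.columns):
        raise ValueError("rates table needs gene_id and rate_per_hour columns")
    return df


def to_anndata(data: AgeAnnotatedCounts):
    """Convert to an AnnData object (cells as obs, genes as var)."""
    import anndata as ad

    return ad.AnnData(
        X=sparse.csr_matrix(data.counts),
        obs=pd.DataFrame(
            {"theta": data.theta, "phase": pd.Categorical(data.phase)},
            index=pd.Index(np.asarray(data.cell_ids).astype(str), name="cell_id"),
        ),
        var=pd.DataFrame(index=pd.Index(data.gene_ids.astype(str), name="gene_id")),
    )
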