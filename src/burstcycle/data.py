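"""The age-annotated count container shared by the pipeline and generators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgeAnnotatedCounts", "PHASES", "phase_of_theta"]

PHASES = ("G1", "S", "G2/M")


def phase_of_theta(theta: np.ndarray, theta_g1: float, theta_s: float) -> np.ndarray:
    """Phase labels implied by the age bins and transition points."""
    theta = np.asarray(theta, dtype=float)
    out = np.where(theta < theta_g1, "G1", np.where(theta < theta_s, "S", "G2/M"))
    return out.astype(object)


@dataclass
class AgeAnnotatedCounts:
    """A cell x gene UMI count matrix with per-cell age bin and phase label.

    ``theta`` lives on the 0.01 grid {0.00, ..., 0.99}; ``phase`` is one of
    "G1", "S", "G2/M".
    """

    counts: np.ndarray
    theta: np.ndarray
    phase: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.theta = np.round(np.asarray(self.theta, dtype=float), 10)
        self.phase = np.asarray(self.phase, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d cell x gene matrix")
        n_cells, n_genes = self.counts.shape
        if self.theta.shape != (n_cells,) or self.phase.shape != (n_cells,):
            raise ValueError("theta/phase must have one entry per cell")
        if self.gene_ids.shape != (n_genes,):
            raise ValueError("gene_ids must have one entry per gene")
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell{i}" for i in range(n_cells)])
        off_grid = np.abs(self.theta * 100 - np.round(self.theta * 100)) > 1e-6
        if np.any(off_grid):
            raise ValueError("theta values must lie on the 0.01 grid")
        self.theta = np.round(self.theta, 2)
        bad = set(np.unique(self.phase)) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def phase_mask(self, phase: str) -> np.ndarray:
        return self.phase == phase

    def gene_index(self, gene_id) -> int:
        idx = np.nonzero(self.gene_ids == gene_id)[0]
        if idx.size == 0:
            raise KeyError(gene_id)
        return int(idx[0])

    def gene_counts(self, gene_id) -> np.ndarray:
        return np.asarray(self.counts[:, self.gene_index(gene_id)])

    def subset_cells(self, mask: np.ndarray) -> "AgeAnnotatedCounts":
        return AgeAnnotatedCounts(
            counts=self.counts[mask],
            theta=self.theta[mask],
            phase=self.phase[mask],
            gene_ids=self.gene_ids,
            cell_ids=np.asarray(self.cell_ids)[mask],
        )

    def subset_genes(self, mask: np.ndarray) -> "AgeAnnotatedCounts":
        return AgeAnnotatedCounts(
            counts=self.counts[:, mask],
            theta=self.theta,
            phase=self.phase,
            gene_ids=self.gene_ids[mask],
            cell_ids=self.cell_ids,
        )
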