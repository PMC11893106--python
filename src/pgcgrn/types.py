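"""Core in-memory containers for the paired snRNA/snATAC multiome pipeline.

A :class:`MultiomeDataset` holds gene x cell and peak x cell count matrices
that share one cell index, plus the fragment table and the cell / gene / peak
metadata needed by downstream QC, linkage and motif analyses.
:class:`GroundTruth` records the structure a synthetic dataset was built
from (planted differential genes/peaks, true peak-gene links, true TF
targets, true ligand-receptor pairs, true sex of every nucleus) so that
recovery can be measured.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

CELL_META_COLUMNS = ["sex", "stage", "replicate", "compartment"]
GENE_META_COLUMNS = ["chrom", "tss", "strand", "is_chrY", "is_mito", "is_marker_of"]
PEAK_META_COLUMNS = ["chrom", "start", "end", "gc_fraction"]
FRAGMENT_COLUMNS = ["cell", "chrom", "start", "end"]


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class MultiomeDataset:
    """Paired RNA + ATAC counts with shared cell index.

    Matrices are feature x cell (genes/peaks in rows, cells in columns).
    Fragment coordinates are 0-based half-open; peak intervals likewise.
    """

    rna_counts: sp.csr_matrix          # gene x cell, non-negative integers
    atac_counts: sp.csr_matrix         # peak x cell, non-negative integers
    fragments: pd.DataFrame            # cell, chrom, start, end
    cell_meta: pd.DataFrame            # index cell_id; sex, stage, replicate, compartment
    gene_meta: pd.DataFrame            # index gene_id; chrom, tss, strand, is_chrY, is_mito, ...
    peak_meta: pd.DataFrame            # index peak_id; chrom, start, end, gc_fraction
    peak_seqs: dict[str, str] | None = None   # peak_id -> uppercase ACGTN sequence

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def peak_ids(self) -> pd.Index:
        return self.peak_meta.index

    @property
    def n_cells(self) -> int:
        return len(self.cell_meta)

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`DatasetError` on violation."""
        n_cells = len(self.cell_meta)
        if self.rna_counts.shape != (len(self.gene_meta), n_cells):
            raise DatasetError(
                f"rna_counts shape {self.rna_counts.shape} does not match "
                f"{len(self.gene_meta)} genes x {n_cells} cells"
            )
        if self.atac_counts.shape != (len(self.peak_meta), n_cells):
            raise DatasetError(
                f"atac_counts shape {self.atac_counts.shape} does not match "
                f"{len(self.peak_meta)} peaks x {n_cells} cells"
            )
        for col in CELL_META_COLUMNS:
            if col not in self.cell_meta.columns:
                raise DatasetError(f"cell_meta missing column {col!r}")
        for col in PEAK_META_COLUMNS[:3]:
            if col not in self.peak_meta.columns:
                raise DatasetError(f"peak_meta missing column {col!r}")
        widths = self.peak_meta["end"].to_numpy() - self.peak_meta["start"].to_numpy()
        if (widths <= 0).any():
            bad = self.peak_meta.index[widths <= 0][0]
            raise DatasetError(f"peak {bad} has non-positive width (intervals are half-open)")
        if self.rna_counts.nnz and self.rna_counts.data.min() < 0:
            raise DatasetError("rna_counts contains negative entries")
        if self.atac_counts.nnz and self.atac_counts.data.min() < 0:
            raise DatasetError("atac_counts contains negative entries")
        # chrY genes must be silent in XX nuclei (true-sex construction; checked
        # against the recorded dataset labels only when no mislabeling column exists).
        if "is_chrY" in self.gene_meta.columns and "true_sex" in self.cell_meta.columns:
            chry = self.gene_meta["is_chrY"].to_numpy(dtype=bool)
            xx = (self.cell_meta["true_sex"] == "XX").to_numpy()
            if chry.any() and xx.any():
                sub = self.rna_counts[chry][:, xx]
                if sub.nnz:
                    raise DatasetError("chrY gene counts are non-zero in XX cells")

    def subset_cells(self, cells: pd.Index | np.ndarray | list) -> "MultiomeDataset":
        """Return a new dataset restricted to ``cells`` (kept in given order)."""
        idx = self.cell_meta.index.get_indexer(pd.Index(cells))
        if (idx < 0).any():
            missing = pd.Index(cells)[idx < 0][:3].tolist()
            raise KeyError(f"unknown cell ids: {missing}")
        keep = set(pd.Index(cells))
        frags = self.fragments[self.fragments["cell"].isin(keep)].reset_index(drop=True)
        return MultiomeDataset(
            rna_counts=self.rna_counts[:, idx].tocsr(),
            atac_counts=self.atac_counts[:, idx].tocsr(),
            fragments=frags,
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta.copy(),
            peak_meta=self.peak_meta.copy(),
            peak_seqs=self.peak_seqs,
        )

    def subset_genes(self, genes: pd.Index | np.ndarray | list) -> "MultiomeDataset":
        """Return a new dataset restricted to ``genes`` (kept in given order)."""
        idx = self.gene_meta.index.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = pd.Index(genes)[idx < 0][:3].tolist()
            raise KeyError(f"unknown gene ids: {missing}")
        return MultiomeDataset(
            rna_counts=self.rna_counts[idx].tocsr(),
            atac_counts=self.atac_counts,
            fragments=self.fragments,
            cell_meta=self.cell_meta,
            gene_meta=self.gene_meta.iloc[idx].copy(),
            peak_meta=self.peak_meta,
            peak_seqs=self.peak_seqs,
        )

    def equals(self, other: "MultiomeDataset") -> bool:
        """Exact equality of matrices, metadata, fragments and sequences."""
        if (self.rna_counts != other.rna_counts).nnz:
            return False
        if (self.atac_counts != other.atac_counts).nnz:
            return False
        if not self.cell_meta.equals(other.cell_meta):
            return False
        if not self.gene_meta.equals(other.gene_meta):
            return False
        if not self.peak_meta.equals(other.peak_meta):
            return False
        if not self.fragments.reset_index(drop=True).equals(
            other.fragments.reset_index(drop=True)
        ):
            return False
        return (self.peak_seqs or {}) == (other.peak_seqs or {})


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset (the recovery oracle)."""

    true_de: pd.DataFrame           # gene, stage, sex_up, logfc
    true_da: pd.DataFrame           # peak, stage, sex_up, logfc
    true_links: pd.DataFrame        # peak, gene
    true_tf_targets: dict[str, set] = field(default_factory=dict)   # motif_id -> gene set
    planted_motif_positions: pd.DataFrame | None = None             # motif_id, peak, offset, strand
    true_lr: pd.DataFrame | None = None   # pair_id, ligand, receptor, sender, receiver, sex
    sex_of_cell: pd.Series | None = None  # cell_id -> {XX, XY}
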