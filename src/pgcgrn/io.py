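"""Reading and writing a multiome dataset in standard text formats.

Layout written by :func:`write_dataset` (all plain text)::

    rna.mtx, genes.tsv, barcodes.tsv     gene x cell MatrixMarket + row/col names
    atac.mtx, peaks.bed, peaks.tsv       peak x cell matrix, BED3+name, full metadata
    fragments.tsv                        cell, chrom, start (0-based), end (exclusive)
    cell_meta.tsv, peaks.fa              per-cell metadata, per-peak sequences
    truth/*.tsv                          planted ground truth (when provided)
    manifest.json                        file list with row counts

The cell order in ``barcodes.tsv`` is authoritative: both matrices and
``cell_meta.tsv`` must follow it, and :func:`read_dataset` refuses to reorder
silently.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .types import DatasetError, GroundTruth, MultiomeDataset

MANIFEST = "manifest.json"

_BOOL_COLS = {"is_chrY", "is_mito", "qc_ok"}
_INT_COLS = {"tss", "start", "end"}


def _write_fasta(path: Path, seqs: dict[str, str], width: int = 60) -> int:
    with open(path, "w") as f:
        for name, seq in seqs.items():
            f.write(f">{name}\n")
            for i in range(0, len(seq), width):
                f.write(seq[i:i + width] + "\n")
    return len(seqs)


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as f:
        for line in f:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_dataset(dataset: MultiomeDataset, truth: GroundTruth | None,
                  directory) -> dict:
    """Write the dataset (and optional ground truth) to ``directory``.

    Returns the manifest. On any failure, files written so far are removed so
    a partially written directory is never left behind.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"files": {}}

    def record(name: str, path: Path, rows: int):
        written.append(path)
        manifest["files"][name] = {"rows": int(rows)}

    try:
        dataset.validate()
        p = directory / "rna.mtx"
        sio.mmwrite(str(p), sp.coo_matrix(dataset.rna_counts), field="integer")
        record("rna.mtx", p, dataset.rna_counts.shape[0])
        p = directory / "atac.mtx"
        sio.mmwrite(str(p), sp.coo_matrix(dataset.atac_counts), field="integer")
        record("atac.mtx", p, dataset.atac_counts.shape[0])

        p = directory / "barcodes.tsv"
        pd.Series(dataset.cell_ids).to_csv(p, sep="\t", index=False, header=False)
        record("barcodes.tsv", p, dataset.n_cells)
        p = directory / "genes.tsv"
        dataset.gene_meta.to_csv(p, sep="\t", float_format="%.17g")
        record("genes.tsv", p, len(dataset.gene_meta))
        p = directory / "cell_meta.tsv"
        dataset.cell_meta.to_csv(p, sep="\t", float_format="%.17g")
        record("cell_meta.tsv", p, len(dataset.cell_meta))

        p = directory / "peaks.bed"
        bed = dataset.peak_meta[["chrom", "start", "end"]].copy()
        bed["name"] = dataset.peak_meta.index
        bed.to_csv(p, sep="\t", index=False, header=False)
        record("peaks.bed", p, len(bed))
        p = directory / "peaks.tsv"
        dataset.peak_meta.to_csv(p, sep="\t", float_format="%.17g")
        record("peaks.tsv", p, len(dataset.peak_meta))

        p = directory / "fragments.tsv"
        dataset.fragments.to_csv(p, sep="\t", index=False)
        record("fragments.tsv", p, len(dataset.fragments))

        if dataset.peak_seqs is not None:
            p = directory / "peaks.fa"
            n = _write_fasta(p, dataset.peak_seqs)
            record("peaks.fa", p, n)

        if truth is not None:
            tdir = directory / "truth"
            tdir.mkdir(exist_ok=True)
            for name, df in [("true_de", truth.true_de), ("true_da", truth.true_da),
                             ("true_links", truth.true_links),
                             ("planted_motif_positions", truth.planted_motif_positions),
                             ("true_lr", truth.true_lr)]:
                if df is None:
                    continue
                p = tdir / f"{name}.tsv"
                df.to_csv(p, sep="\t", index=False, float_format="%.17g")
                record(f"truth/{name}.tsv", p, len(df))
            if truth.sex_of_cell is not None:
                p = tdir / "sex_of_cell.tsv"
                truth.sex_of_cell.rename_axis("cell_id").to_csv(p, sep="\t")
                record("truth/sex_of_cell.tsv", p, len(truth.sex_of_cell))
            if truth.true_tf_targets:
                p = tdir / "true_tf_targets.tsv"
                rows = [(m, g) for m, gs in sorted(truth.true_tf_targets.items())
                        for g in sorted(gs)]
                pd.DataFrame(rows, columns=["motif_id", "gene"]).to_csv(
                    p, sep="\t", index=False)
                record("truth/true_tf_targets.tsv", p, len(rows))

        p = directory / MANIFEST
        with open(p, "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True)
            f.write("\n")
        written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return manifest


def _coerce_meta(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if col in _BOOL_COLS:
            df[col] = df[col].astype(str).map({"True": True, "False": False}) \
                if df[col].dtype == object else df[col].astype(bool)
        elif col in _INT_COLS:
            df[col] = df[col].astype(np.int64)
    return df


def read_dataset(directory) -> MultiomeDataset:
    """Reconstruct a :class:`MultiomeDataset` written by :func:`write_dataset`."""
    directory = Path(directory)
    mpath = directory / MANIFEST
    if not mpath.exists():
        raise DatasetError(f"no {MANIFEST} in {directory}")
    with open(mpath) as f:
        manifest = json.load(f)

    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    cell_meta = pd.read_csv(directory / "cell_meta.tsv", sep="\t", index_col=0,
                            keep_default_na=False, na_values=[],
                            float_precision="round_trip")
    cell_meta = _coerce_meta(cell_meta)
    if list(cell_meta.index) != barcodes:
        raise DatasetError("cell order in cell_meta.tsv does not match barcodes.tsv")
    gene_meta = _coerce_meta(pd.read_csv(directory / "genes.tsv", sep="\t", index_col=0,
                                         keep_default_na=False, na_values=[],
                                         float_precision="round_trip"))
    peak_meta = _coerce_meta(pd.read_csv(directory / "peaks.tsv", sep="\t", index_col=0,
                                         keep_default_na=False, na_values=[],
                                         float_precision="round_trip"))

    rna = sp.csr_matrix(sio.mmread(str(directory / "rna.mtx")), dtype=np.int32)
    atac = sp.csr_matrix(sio.mmread(str(directory / "atac.mtx")), dtype=np.int32)
    if rna.shape[1] != len(barcodes):
        raise DatasetError("rna.mtx column count does not match barcodes.tsv")
    if atac.shape[1] != len(barcodes):
        raise DatasetError("atac.mtx column count does not match barcodes.tsv")

    fragments = pd.read_csv(directory / "fragments.tsv", sep="\t",
                            dtype={"cell": str, "chrom": str,
                                   "start": np.int64, "end": np.int64})

    fasta = directory / "peaks.fa"
    peak_seqs = _read_fasta(fasta) if fasta.exists() else None
    if peak_seqs is None and "gc_fraction" not in peak_meta.columns:
        raise DatasetError("peaks.fa absent and peaks.tsv has no gc_fraction column")
    if peak_seqs is None:
        pass
    elif "gc_fraction" not in peak_meta.columns:
        gc = [(peak_seqs[p].count("G") + peak_seqs[p].count("C")) / len(peak_seqs[p])
              for p in peak_meta.index]
        peak_meta["gc_fraction"] = gc

    ds = MultiomeDataset(rna_counts=rna, atac_counts=atac, fragments=fragments,
                         cell_meta=cell_meta, gene_meta=gene_meta,
                         peak_meta=peak_meta, peak_seqs=peak_seqs)
    ds.validate()
    return ds


def read_gmt(path) -> dict[str, set]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set] = {}
    with open(path) as f:
        for line in f:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_lr_pairs(path) -> pd.DataFrame:
    """Ligand-receptor pair list: pair_id, ligand, receptor (;-separated), pathway_label."""
    df = pd.read_csv(path, sep="\t")
    required = {"pair_id", "ligand", "receptor"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair list must have columns {sorted(required)}")
    if "pathway_label" not in df.columns:
        df["pathway_label"] = ""
    return df
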