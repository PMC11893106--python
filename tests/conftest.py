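import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pgcgrn.simulate import GeneratorConfig, generate_dataset
from pgcgrn.types import MultiomeDataset


def small_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_cells_per_group=60,
        n_genes=300,
        n_peaks=400,
        n_de_genes_per_stage=(4, 8, 12),
        n_da_peaks_per_stage=(6, 12, 24),
        n_links=10,
        sequencing_depth_rna=2000,
        sequencing_depth_atac=800,
        seed=11,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return generate_dataset(small_cfg)


def tiny_dataset(fragments_rows, n_genes=3, n_cells=2, tss=(5000,)):
    """Hand-buildable dataset for QC metric oracles."""
    cell_ids = [f"c{i}" for i in range(n_cells)]
    gene_ids = [f"g{i}" for i in range(n_genes)]
    gene_meta = pd.DataFrame({
        "chrom": "chr1",
        "tss": list(tss) * (n_genes // len(tss)) + list(tss)[: n_genes % len(tss)],
        "strand": "+",
        "is_chrY": False,
        "is_mito": [i == 0 for i in range(n_genes)],
        "is_marker_of": "",
    }, index=pd.Index(gene_ids, name="gene_id"))
    peak_meta = pd.DataFrame({
        "chrom": ["chr1"], "start": [1000], "end": [2000], "gc_fraction": [0.5],
    }, index=pd.Index(["p0"], name="peak_id"))
    frags = pd.DataFrame(fragments_rows, columns=["cell", "chrom", "start", "end"])
    rna = sp.csr_matrix(np.ones((n_genes, n_cells), dtype=np.int32))
    counts = np.zeros((1, n_cells), dtype=np.int32)
    for c in frags["cell"]:
        counts[0, cell_ids.index(c)] += 1
    return MultiomeDataset(
        rna_counts=rna,
        atac_counts=sp.csr_matrix(counts),
        fragments=frags,
        cell_meta=pd.DataFrame({"sex": "XX", "stage": "E11.5", "replicate": "r1",
                                "compartment": "germ"},
                               index=pd.Index(cell_ids, name="cell_id")),
        gene_meta=gene_meta,
        peak_meta=peak_meta,
    )
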