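import numpy as np
import pandas as pd
import pytest

from xcipipe.io import AllelicCountSet, rpkm_for
from xcipipe.simulate import (
    ConditionSpec,
    SimConfig,
    generate_dataset,
    preset_paper_conditions,
)


def make_acs(
    maternal,
    paternal,
    chromosomes=None,
    gene_names=None,
    sex=None,
    conditions=None,
    total=None,
    starts=None,
    exonic_length=1000,
):
    """Hand-build a small AllelicCountSet from plain arrays."""
    maternal = np.atleast_2d(np.asarray(maternal))
    paternal = np.atleast_2d(np.asarray(paternal))
    n_genes, n_cells = maternal.shape
    gene_ids = [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{j}" for j in range(n_cells)]
    if chromosomes is None:
        chromosomes = ["1"] * n_genes
    if gene_names is None:
        gene_names = [f"Gene{i}" for i in range(n_genes)]
    if starts is None:
        starts = [1000 * (i + 1) for i in range(n_genes)]
    if total is None:
        total = maternal + paternal
    genes = pd.DataFrame(
        {
            "gene_name": gene_names,
            "chromosome": chromosomes,
            "start": starts,
            "end": [s + 500 for s in starts],
            "exonic_length": exonic_length,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    cells = pd.DataFrame(
        {
            "condition": conditions if conditions is not None else ["cond"] * n_cells,
            "sex": sex if sex is not None else ["F"] * n_cells,
            "qc_pass": True,
            "library_size": np.asarray(total).sum(axis=0),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    as_df = lambda a: pd.DataFrame(np.asarray(a), index=genes.index, columns=cells.index)
    return AllelicCountSet(as_df(maternal), as_df(paternal), as_df(total), genes, cells)


def uniform_degree_config(n_cells, seed, **overrides):
    """Female cells with XCI degree d ~ Uniform(0, 1).

    Achieved with group weights proportional to the degree-interval lengths
    (1/9, 5/9, 1/3) and spread 1 (full intervals).
    """
    kwargs = dict(
        conditions=[
            ConditionSpec(
                name="mix.F", sex="F",
                weights=(1.0 / 9.0, 5.0 / 9.0, 1.0 / 3.0), spread=1.0,
            )
        ],
        n_cells_per_condition=n_cells,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def preset_data():
    """Moderate preset simulation shared across read-only tests."""
    acs, truth = generate_dataset(preset_paper_conditions(30, seed=11))
    return acs, truth, rpkm_for(acs)
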