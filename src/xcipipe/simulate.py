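"""Synthetic allele-resolved single-cell count data with known ground truth.

The generator emulates single-cell RNA-seq of a hybrid mouse cross
(maternal C57BL/6J x paternal CAST/EiJ): autosomal genes show ~50/50
allelic balance, male cells express only the maternal X, and female cells
span a continuum of X-chromosome inactivation (XCI). Each female cell
carries a latent XCI degree ``d`` in [0, 1] (0 = both X active, 1 = one X
fully silenced) and a chosen inactivated allele; the expected maternal
fraction of an X-linked gene's SNP-informative reads is

    p = 0.5 * (1 - d) + delta * d,   delta = 1 if the paternal X is
                                     inactivated, 0 if the maternal X is

so the activity index recoverable downstream is a_true = 1 / max(p, 1-p).
Escapee genes are pulled back toward balance by a retention factor.
Pluripotency-module genes decay and differentiation-module genes rise
along a pseudotime ``t`` that is noisily coupled to ``d``, so XCI and loss
of pluripotency are globally correlated but asynchronous per cell. Xist is
transcribed from the inactive X and scales with ``d``; Y genes are
male-only. Allelic dropout at low expression is per-allele Bernoulli with
probability exp(-expected_allele_depth / dropout_scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AllelicCountSet

__all__ = [
    "ConditionSpec",
    "SimConfig",
    "SyntheticTruth",
    "SimConfigError",
    "generate_dataset",
    "preset_paper_conditions",
    "DEGREE_INTERVALS",
    "PLURIPOTENCY_GENES",
    "DIFFERENTIATION_GENES",
    "Y_GENES",
    "ESCAPEE_NAMES",
]

# XCI-degree intervals corresponding to the activity-index groups
# (activity a = 2 / (1 + d): a > 1.8 <=> d < 1/9; a <= 1.2 <=> d >= 2/3)
DEGREE_INTERVALS = {
    "uninitiated": (0.0, 1.0 / 9.0),
    "ongoing": (1.0 / 9.0, 2.0 / 3.0),
    "completed": (2.0 / 3.0, 1.0),
}

PLURIPOTENCY_GENES = (
    "Pou5f1", "Sox2", "Nanog", "Klf2", "Esrrb", "Dppa3", "Tcfcp2l1", "Prdm14",
)
DIFFERENTIATION_GENES = ("Otx2", "Fgf5", "Eomes", "Cer1", "Map2", "Nefl", "Nefm", "Isl1")
Y_GENES = ("Ddx3y", "Uty", "Eif2s3y")
ESCAPEE_NAMES = ("Kdm5c", "Kdm6a", "Ddx3x", "2610029G23Rik")

MOUSE_X_LENGTH = 171_031_299  # bp, used only to place synthetic X genes in order


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class ConditionSpec:
    """One simulated condition (culture state) of one sex.

    For female conditions, ``weights`` are the mixture weights over the
    uninitiated/ongoing/completed XCI groups and ``spread`` scales how much
    of each group's degree interval is used (1 = full interval, 0 = its
    midpoint). ``degree`` pins every cell to an exact XCI degree instead
    (useful for controlled experiments). ``maternal_pref`` is the
    probability that the maternal X is the one chosen for inactivation.
    ``stage`` positions male cells (which have no XCI degree) on the
    pseudotime axis.
    """

    name: str
    sex: str = "F"
    weights: tuple[float, float, float] = (1.0, 0.0, 0.0)
    # central fraction of the group's degree interval that cells occupy;
    # 0.5 keeps group membership identifiable under counting noise at
    # a few thousand informative reads per cell
    spread: float = 0.5
    degree: float | None = None
    maternal_pref: float = 0.7
    stage: float = 0.5


@dataclass
class SimConfig:
    conditions: Sequence[ConditionSpec] = field(default_factory=list)
    n_cells_per_condition: int = 50
    n_autosomal_genes: int = 300
    n_x_genes: int = 100
    n_escapees: int = 4
    escapee_retention: float = 0.5
    mean_depth: float = 30.0
    overdispersion: float = 0.0
    dropout_scale: float = 0.0
    pluripotency_module_size: int = 8
    differentiation_module_size: int = 8
    coupling_noise_sd: float = 0.1
    expression_sigma: float = 0.8
    module_noise_sd: float = 0.5
    gene_noise_sd: float = 0.3
    # library_size = panel read sum x this factor: the simulated gene panel
    # stands for ~1/library_scale of the transcriptome, so RPKM values land
    # on the scale where the 5/10/20 RPKM thresholds are discriminating
    library_scale: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise SimConfigError("conditions: must be non-empty")
        if self.n_cells_per_condition < 1:
            raise SimConfigError("n_cells_per_condition: must be a positive integer")
        if self.n_autosomal_genes < 1:
            raise SimConfigError("n_autosomal_genes: must be a positive integer")
        if self.n_x_genes < 1:
            raise SimConfigError("n_x_genes: must be a positive integer")
        if self.n_escapees < 0 or self.n_escapees > self.n_x_genes:
            raise SimConfigError("n_escapees: must satisfy 0 <= n_escapees <= n_x_genes")
        if not 0.0 <= self.escapee_retention <= 1.0:
            raise SimConfigError("escapee_retention: must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise SimConfigError("mean_depth: must be positive")
        if self.overdispersion < 0 or self.overdispersion >= 1:
            raise SimConfigError("overdispersion: must lie in [0, 1)")
        if self.dropout_scale < 0:
            raise SimConfigError("dropout_scale: must be >= 0")
        if self.library_scale < 1:
            raise SimConfigError("library_scale: must be >= 1")
        if self.coupling_noise_sd < 0:
            raise SimConfigError("coupling_noise_sd: must be >= 0")
        module_total = self.pluripotency_module_size + self.differentiation_module_size
        if self.pluripotency_module_size < 0 or self.differentiation_module_size < 0:
            raise SimConfigError("pluripotency_module_size/differentiation_module_size: must be >= 0")
        if module_total > self.n_autosomal_genes:
            raise SimConfigError(
                "n_autosomal_genes: must be >= pluripotency_module_size + differentiation_module_size"
            )
        for cond in self.conditions:
            if cond.sex not in ("F", "M"):
                raise SimConfigError(f"conditions[{cond.name}].sex: must be 'F' or 'M'")
            w = np.asarray(cond.weights, dtype=float)
            if cond.sex == "F" and cond.degree is None:
                if w.shape != (3,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
                    raise SimConfigError(
                        f"conditions[{cond.name}].weights: must be 3 non-negative weights summing to 1"
                    )
            if not 0.0 <= cond.spread <= 1.0:
                raise SimConfigError(f"conditions[{cond.name}].spread: must lie in [0, 1]")
            if cond.degree is not None and not 0.0 <= cond.degree <= 1.0:
                raise SimConfigError(f"conditions[{cond.name}].degree: must lie in [0, 1]")
            if not 0.0 <= cond.maternal_pref <= 1.0:
                raise SimConfigError(f"conditions[{cond.name}].maternal_pref: must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth: per-cell latent state and per-gene roles.

    ``cells`` columns: cell_id (index), sex, condition, true_xci_degree
    (NaN for males, whose single maternal X has no degree), inactivated_allele
    ({maternal, paternal, none}), pseudotime. ``genes`` columns: role,
    is_escapee, base_expression.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame

    def write(self, path) -> None:
        out = self.cells.reset_index()[
            ["cell_id", "sex", "condition", "true_xci_degree", "inactivated_allele", "pseudotime"]
        ]
        out.to_csv(path, sep="\t", index=False)


def _build_gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []

    def add(name, chrom, role, base, is_escapee=False):
        rows.append(dict(gene_name=name, chromosome=chrom, role=role,
                         base_expression=base, is_escapee=is_escapee))

    n_pl, n_df = config.pluripotency_module_size, config.differentiation_module_size
    pl_names = [PLURIPOTENCY_GENES[i] if i < len(PLURIPOTENCY_GENES) else f"Pluri{i + 1}"
                for i in range(n_pl)]
    df_names = [DIFFERENTIATION_GENES[i] if i < len(DIFFERENTIATION_GENES) else f"Diff{i + 1}"
                for i in range(n_df)]
    for name in pl_names:
        add(name, "1", "pluripotency", rng.lognormal(np.log(30.0), 0.4))
    for name in df_names:
        add(name, "1", "differentiation", rng.lognormal(np.log(25.0), 0.4))
    for i in range(config.n_autosomal_genes - n_pl - n_df):
        add(f"Auto{i + 1:04d}", "1", "autosomal",
            rng.lognormal(np.log(5.0), config.expression_sigma))
    for i in range(config.n_x_genes):
        escapee = i < config.n_escapees
        name = (ESCAPEE_NAMES[i] if escapee and i < len(ESCAPEE_NAMES)
                else (f"Esc{i + 1}" if escapee else f"Xlinked{i + 1:04d}"))
        add(name, "X", "x_escapee" if escapee else "x_linked",
            rng.lognormal(np.log(5.0), config.expression_sigma), is_escapee=escapee)
    add("Xist", "X", "xist", 25.0)
    add("Tsix", "X", "tsix", 8.0)
    for name in Y_GENES:
        add(name, "Y", "y_linked", rng.lognormal(np.log(8.0), 0.3))

    genes = pd.DataFrame(rows)
    genes.index = pd.Index([f"G{i + 1:05d}" for i in range(len(genes))], name="gene_id")

    # uniform gene spacing per chromosome; only the order matters downstream
    start = np.zeros(len(genes), dtype=np.int64)
    end = np.zeros(len(genes), dtype=np.int64)
    for chrom, idx in genes.groupby("chromosome", sort=False).groups.items():
        n = len(idx)
        length = MOUSE_X_LENGTH if chrom == "X" else 190_000_000
        spacing = length // (n + 1)
        pos = np.arange(1, n + 1) * spacing
        order = rng.permutation(n)  # genomic order independent of role order
        start[genes.index.get_indexer(idx)] = pos[np.argsort(order)]
        end[genes.index.get_indexer(idx)] = pos[np.argsort(order)] + 5_000
    genes["start"] = start
    genes["end"] = end
    genes["exonic_length"] = np.maximum(
        rng.lognormal(np.log(1_500.0), 0.5, size=len(genes)).astype(np.int64), 200
    )
    return genes


def _draw_cells(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    groups = list(DEGREE_INTERVALS)
    recs = []
    for cond in config.conditions:
        for j in range(config.n_cells_per_condition):
            cell_id = f"{cond.name}_c{j + 1:04d}"
            if cond.sex == "M":
                t = float(np.clip(cond.stage + rng.normal(0.0, 0.1), 0.0, 1.0))
                recs.append(dict(cell_id=cell_id, sex="M", condition=cond.name,
                                 true_xci_degree=np.nan, inactivated_allele="none",
                                 pseudotime=t))
                continue
            if cond.degree is not None:
                d = float(cond.degree)
            else:
                g = groups[rng.choice(3, p=np.asarray(cond.weights, float))]
                lo, hi = DEGREE_INTERVALS[g]
                mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0 * cond.spread
                d = float(rng.uniform(mid - half, mid + half))
            if d > 0:
                allele = "maternal" if rng.random() < cond.maternal_pref else "paternal"
            else:
                allele = "none"
            t = float(np.clip(d + rng.normal(0.0, config.coupling_noise_sd), 0.0, 1.0))
            recs.append(dict(cell_id=cell_id, sex="F", condition=cond.name,
                             true_xci_degree=d, inactivated_allele=allele, pseudotime=t))
    return pd.DataFrame(recs).set_index("cell_id")


def _maternal_prob_matrix(genes: pd.DataFrame, cells: pd.DataFrame,
                          escapee_retention: float) -> np.ndarray:
    """Expected maternal fraction p per gene x cell."""
    n_g, n_c = len(genes), len(cells)
    p = np.full((n_g, n_c), 0.5)
    is_male = (cells["sex"] == "M").to_numpy()
    d = np.nan_to_num(cells["true_xci_degree"].to_numpy(float), nan=0.0)
    delta = (cells["inactivated_allele"] == "paternal").to_numpy(float)
    active = (cells["inactivated_allele"] != "none").to_numpy(float)

    chrom = genes["chromosome"].to_numpy(str)
    role = genes["role"].to_numpy(str)
    x_rows = np.flatnonzero(chrom == "X")
    for gi in x_rows:
        if role[gi] == "xist":
            # Xist is expressed from the inactive X once XCI has begun
            p[gi] = np.where(
                active > 0,
                np.where(cells["inactivated_allele"].to_numpy(str) == "maternal", 1.0, 0.0),
                0.5,
            )
        elif role[gi] == "tsix":
            # Tsix from the active X
            p[gi] = np.where(
                active > 0,
                np.where(cells["inactivated_allele"].to_numpy(str) == "maternal", 0.0, 1.0),
                0.5,
            )
        else:
            d_eff = d * (1.0 - escapee_retention) if genes["is_escapee"].iloc[gi] else d
            p[gi] = 0.5 * (1.0 - d_eff) + delta * d_eff
    # male cells: single maternal X
    p[np.ix_(x_rows, np.flatnonzero(is_male))] = 1.0
    return p


def _modulation_matrix(genes: pd.DataFrame, cells: pd.DataFrame,
                       config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n_g, n_c = len(genes), len(cells)
    t = cells["pseudotime"].to_numpy(float)
    d = np.nan_to_num(cells["true_xci_degree"].to_numpy(float), nan=0.0)
    is_male = (cells["sex"] == "M").to_numpy()
    role = genes["role"].to_numpy(str)

    mod = np.exp(rng.normal(0.0, config.gene_noise_sd, size=(n_g, n_c)))
    pl_factor = np.exp(rng.normal(0.0, config.module_noise_sd, size=n_c))
    df_factor = np.exp(rng.normal(0.0, config.module_noise_sd, size=n_c))

    pl = role == "pluripotency"
    df_ = role == "differentiation"
    mod[pl] *= np.maximum(1.0 - 0.97 * t, 0.02)[None, :] * pl_factor[None, :]
    mod[df_] *= (0.1 + 0.9 * t)[None, :] * df_factor[None, :]
    xist = role == "xist"
    tsix = role == "tsix"
    mod[xist] *= np.where(is_male, 0.0, 0.02 + 0.98 * d)[None, :]
    mod[tsix] *= np.where(is_male, 0.1, 0.05 + 0.6 * d)[None, :]
    y = role == "y_linked"
    mod[y] *= np.where(is_male, 1.0, 0.0)[None, :]
    return mod


def generate_dataset(config: SimConfig) -> tuple[AllelicCountSet, SyntheticTruth]:
    """Simulate an :class:`AllelicCountSet` with ground truth.

    Deterministic given ``config.seed``. SNP-informative totals per gene/cell
    are Poisson around ``mean_depth`` scaled by each gene's base expression
    and its pseudotime modulation; maternal counts are binomial (beta-binomial
    when ``overdispersion`` > 0) at the expected maternal fraction; an equal
    expected number of non-SNP reads tops up the total-count matrix, so
    maternal + paternal <= total always holds.
    """
    rng = np.random.default_rng(config.seed)
    genes = _build_gene_table(config, rng)
    cells = _draw_cells(config, rng)

    base = genes["base_expression"].to_numpy(float)
    mod = _modulation_matrix(genes, cells, config, rng)
    lam = config.mean_depth * (base / base.mean())[:, None] * mod

    n_snp = rng.poisson(lam)
    p = _maternal_prob_matrix(genes, cells, config.escapee_retention)

    if config.overdispersion > 0:
        nu = (1.0 - config.overdispersion) / config.overdispersion
        interior = (p > 0) & (p < 1)
        p_draw = p.copy()
        p_draw[interior] = rng.beta(p[interior] * nu, (1.0 - p[interior]) * nu)
    else:
        p_draw = p
    maternal = rng.binomial(n_snp, p_draw)
    paternal = n_snp - maternal

    if config.dropout_scale > 0:
        lam_m, lam_p = lam * p, lam * (1.0 - p)
        drop_m = rng.random(lam.shape) < np.exp(-lam_m / config.dropout_scale)
        drop_p = rng.random(lam.shape) < np.exp(-lam_p / config.dropout_scale)
        maternal = np.where(drop_m, 0, maternal)
        paternal = np.where(drop_p, 0, paternal)

    total = maternal + paternal + rng.poisson(lam)

    cell_meta = pd.DataFrame(
        {
            "condition": cells["condition"],
            "sex": cells["sex"],
            "qc_pass": True,
            "library_size": (total.sum(axis=0) * config.library_scale).astype(np.int64),
        },
        index=cells.index,
    )
    gene_ann = genes[["gene_name", "chromosome", "start", "end", "exonic_length"]].copy()
    acs = AllelicCountSet(
        maternal=pd.DataFrame(maternal, index=genes.index, columns=cells.index),
        paternal=pd.DataFrame(paternal, index=genes.index, columns=cells.index),
        total=pd.DataFrame(total, index=genes.index, columns=cells.index),
        genes=gene_ann,
        cells=cell_meta,
    )
    truth = SyntheticTruth(
        cells=cells,
        genes=genes[["gene_name", "role", "is_escapee", "base_expression"]].copy(),
    )
    return acs, truth


def preset_paper_conditions(
    n_cells_per_condition: int = 50, seed: int = 0, **overrides
) -> SimConfig:
    """Study-condition preset: five female and four male culture states.

    Female XCI-group mixture weights follow the observed per-condition
    composition: ground-state 2i cells are mostly uninitiated with ~30%
    ongoing and none completed; serum/LIF ES cells are mixed with ~6%
    completed; delayed EpiStem cells are ~25% completed; EpiStem cells are
    all completed; neurons are mostly completed with a small undifferentiated
    tail. Inactivation is biased toward the maternal X (70%).
    """
    female = [
        ("ES2i.F", (0.70, 0.30, 0.00), 0.05),
        ("ES.F", (0.54, 0.40, 0.06), 0.30),
        ("delayed.Epi.F", (0.241, 0.506, 0.253), 0.55),
        ("Epi.F", (0.00, 0.00, 1.00), 0.70),
        ("Neuron.F", (0.103, 0.179, 0.718), 0.95),
    ]
    male = [("ES2i.M", 0.05), ("ES.M", 0.30), ("Epi.M", 0.70), ("Neuron.M", 0.95)]
    conditions = [
        ConditionSpec(name=n, sex="F", weights=w, stage=s) for n, w, s in female
    ] + [ConditionSpec(name=n, sex="M", stage=s) for n, s in male]
    kwargs = dict(
        conditions=conditions,
        n_cells_per_condition=n_cells_per_condition,
        n_x_genes=150,
        n_autosomal_genes=300,
        n_escapees=4,
        escapee_retention=0.5,
        mean_depth=30.0,
        dropout_scale=6.0,
        coupling_noise_sd=0.15,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
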