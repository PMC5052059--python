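"""Per-cell X activity index, XCI-group classification and X-wide profiles.

The activity index "digitalizes" how many X chromosomes are transcribed in
a cell. With f the maternal fraction of SNP-informative X-linked reads,

    a = 1/f        if f >= 0.5
    a = 1/(1 - f)  otherwise

so a = 2 means two fully active X chromosomes and a = 1 means one. Cells
are grouped as uninitiated-XCI (1.8 < a <= 2), ongoing-XCI
(1.2 < a <= 1.8) or completed-XCI (1 <= a <= 1.2). Silencing progression
along the chromosome is profiled as the pooled inactive-X / active-X read
ratio in a sliding window of (by default) 10 consecutive informative
genes; genes still expressed from the otherwise inactive X in
completed-XCI cells are flagged as escapees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AllelicCountSet

__all__ = [
    "XCIStateResult",
    "maternal_fraction",
    "maternal_fraction_per_cell",
    "activity_from_fraction",
    "classify_xci",
    "xci_state_table",
    "window_ratio_profile",
    "detect_escapees",
    "DEFAULT_GROUP_BOUNDS",
    "DEFAULT_EXCLUDE_GENES",
]

# (completed_upper, ongoing_upper) on the activity scale
DEFAULT_GROUP_BOUNDS = (1.2, 1.8)
# Xist/Tsix are transcribed allele-specifically by design (inactive/active X),
# so they are excluded from the activity estimate by default.
DEFAULT_EXCLUDE_GENES = ("Xist", "Tsix")
GROUPS = ("uninitiated", "ongoing", "completed")


@dataclass
class XCIStateResult:
    """Per-cell XCI state plus per-condition summaries.

    ``cells``: one row per female cell — maternal_x_fraction,
    informative_x_reads, activity, xci_group (incl. 'insufficient'),
    inactive_allele, autosomal_maternal_fraction, condition.
    ``condition_summary``: per condition x group — n cells and percentage
    among cells with sufficient evidence.
    ``skew_tests``: per condition — counts of maternal- vs
    paternal-X inactivation among initiated (ongoing + completed) cells and
    a two-sided binomial test against an even 50/50 choice.
    """

    cells: pd.DataFrame
    condition_summary: pd.DataFrame
    skew_tests: pd.DataFrame


def _chromosome_gene_ids(acs: AllelicCountSet, chromosome: str, exclude_genes) -> pd.Index:
    ids = acs.genes_on(chromosome)
    if exclude_genes:
        names = acs.genes.loc[ids, "gene_name"]
        ids = ids[~names.isin(exclude_genes)]
    return ids


def maternal_fraction_per_cell(
    acs: AllelicCountSet,
    chromosome: str = "X",
    exclude_genes=DEFAULT_EXCLUDE_GENES,
) -> pd.DataFrame:
    """Maternal read fraction f and informative read count per cell.

    f = sum(maternal) / (sum(maternal) + sum(paternal)) over the selected
    chromosome's genes; cells with zero informative reads get f = NaN.
    """
    ids = _chromosome_gene_ids(acs, chromosome, exclude_genes)
    if len(ids) == 0:
        raise ValueError(f"no genes selected on chromosome {chromosome!r}")
    mat = acs.maternal.loc[ids].sum(axis=0)
    pat = acs.paternal.loc[ids].sum(axis=0)
    informative = mat + pat
    with np.errstate(invalid="ignore", divide="ignore"):
        f = mat / informative.where(informative > 0)
    return pd.DataFrame({"fraction": f, "informative_reads": informative})


def maternal_fraction(
    acs: AllelicCountSet, cell: str, chromosome: str = "X",
    exclude_genes=DEFAULT_EXCLUDE_GENES,
) -> tuple[float, int]:
    table = maternal_fraction_per_cell(acs, chromosome, exclude_genes)
    row = table.loc[cell]
    return float(row["fraction"]), int(row["informative_reads"])


def activity_from_fraction(f):
    """Convert a maternal expression fraction to the activity index in [1, 2].

    a = 1/f for f >= 0.5, else 1/(1-f); symmetric about f = 0.5 where a = 2.
    Accepts scalars or arrays; NaN propagates (insufficient evidence).
    """
    arr = np.asarray(f, dtype=float)
    valid = np.isnan(arr) | ((arr >= 0.0) & (arr <= 1.0))
    if not valid.all():
        raise ValueError("maternal fraction outside [0, 1]")
    major = np.maximum(arr, 1.0 - arr)
    with np.errstate(invalid="ignore"):
        a = 1.0 / major
    return float(a) if np.isscalar(f) else a


def classify_xci(a, bounds=DEFAULT_GROUP_BOUNDS):
    """Assign the XCI group for an activity index in [1, 2].

    Half-open intervals with the printed boundary convention:
    a = ongoing_upper (1.8) -> ongoing; a = completed_upper (1.2) ->
    completed; uninitiated is (1.8, 2].
    """
    completed_upper, ongoing_upper = bounds
    if not 1.0 < completed_upper < ongoing_upper < 2.0:
        raise ValueError("bounds must satisfy 1 < completed_upper < ongoing_upper < 2")
    arr = np.asarray(a, dtype=float)
    valid = np.isnan(arr) | ((arr >= 1.0) & (arr <= 2.0))
    if not valid.all():
        raise ValueError("activity index outside [1, 2]")
    out = np.where(
        arr > ongoing_upper, "uninitiated",
        np.where(arr > completed_upper, "ongoing", "completed"),
    ).astype(object)
    out[np.isnan(arr)] = "insufficient"
    return str(out.item()) if np.isscalar(a) else out


def xci_state_table(
    acs: AllelicCountSet,
    min_informative_reads: int = 50,
    bounds=DEFAULT_GROUP_BOUNDS,
    exclude_genes=DEFAULT_EXCLUDE_GENES,
) -> XCIStateResult:
    """Per-female-cell XCI state with condition summaries and skew tests.

    Cells with fewer than ``min_informative_reads`` SNP-informative X reads
    are marked 'insufficient' and excluded from group percentages. The
    inactive allele is the lower-expressed one (f > 0.5 -> paternal
    inactive); at exactly f = 0.5 it is 'undetermined'. The
    maternal/paternal inactivation split is tested only among initiated
    (ongoing + completed) cells, where the choice is identifiable.
    """
    female = acs.cells.index[acs.cells["sex"] == "F"].intersection(acs.cell_ids)
    if len(female) == 0:
        raise ValueError("no female cells in the dataset")
    sub = acs.subset_cells(female)

    x = maternal_fraction_per_cell(sub, "X", exclude_genes)
    auto_ids = sub.autosomal_genes()
    auto_mat = sub.maternal.loc[auto_ids].sum(axis=0)
    auto_tot = auto_mat + sub.paternal.loc[auto_ids].sum(axis=0)
    with np.errstate(invalid="ignore"):
        auto_f = auto_mat / auto_tot.where(auto_tot > 0)

    f = x["fraction"]
    activity = pd.Series(activity_from_fraction(f.to_numpy()), index=f.index)
    group = pd.Series(classify_xci(activity.to_numpy(), bounds), index=f.index)
    group[x["informative_reads"] < min_informative_reads] = "insufficient"
    inactive = pd.Series(
        np.select(
            [f > 0.5, f < 0.5], ["paternal", "maternal"], default="undetermined"
        ),
        index=f.index,
    )
    inactive[f.isna()] = "undetermined"

    cells = pd.DataFrame(
        {
            "condition": sub.cells.loc[f.index, "condition"],
            "maternal_x_fraction": f,
            "informative_x_reads": x["informative_reads"].astype(int),
            "activity": activity,
            "xci_group": group,
            "inactive_allele": inactive,
            "autosomal_maternal_fraction": auto_f,
        }
    )
    cells.index.name = "cell_id"

    usable = cells[cells["xci_group"] != "insufficient"]
    summary_rows = []
    for cond, cdf in usable.groupby("condition", sort=False):
        for g in GROUPS:
            n = int((cdf["xci_group"] == g).sum())
            summary_rows.append(
                dict(condition=cond, xci_group=g, n_cells=n,
                     percent=100.0 * n / len(cdf) if len(cdf) else np.nan)
            )
    condition_summary = pd.DataFrame(summary_rows)

    skew_rows = []
    for cond, cdf in usable.groupby("condition", sort=False):
        initiated = cdf[cdf["xci_group"].isin(["ongoing", "completed"])]
        n_mat = int((initiated["inactive_allele"] == "maternal").sum())
        n_pat = int((initiated["inactive_allele"] == "paternal").sum())
        n = n_mat + n_pat
        p = stats.binomtest(n_mat, n, 0.5).pvalue if n > 0 else np.nan
        skew_rows.append(
            dict(condition=cond, n_initiated=len(initiated),
                 n_maternal_inactive=n_mat, n_paternal_inactive=n_pat,
                 maternal_inactive_fraction=n_mat / n if n else np.nan,
                 binomial_p=p)
        )
    skew_tests = pd.DataFrame(skew_rows)
    return XCIStateResult(cells=cells, condition_summary=condition_summary,
                          skew_tests=skew_tests)


def _inactive_active_counts(
    acs: AllelicCountSet, gene_ids: pd.Index, cell_ids: pd.Index,
    inactive_allele: pd.Series,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene pooled inactive-X and active-X read counts over the cells.

    Each cell contributes its maternal counts to the inactive pool when its
    inactive allele is maternal (ties resolved to maternal by convention),
    paternal counts otherwise.
    """
    mat = acs.maternal.loc[gene_ids, cell_ids].to_numpy()
    pat = acs.paternal.loc[gene_ids, cell_ids].to_numpy()
    # undetermined (f == 0.5) falls back to maternal-as-inactive
    mat_inactive = inactive_allele.loc[cell_ids].isin(["maternal", "undetermined"]).to_numpy()
    inactive = np.where(mat_inactive[None, :], mat, pat).sum(axis=1)
    active = np.where(mat_inactive[None, :], pat, mat).sum(axis=1)
    return inactive, active


def window_ratio_profile(
    acs: AllelicCountSet,
    state: XCIStateResult | pd.DataFrame,
    cells_subset=None,
    window_genes: int = 10,
    exclude_genes=DEFAULT_EXCLUDE_GENES,
) -> pd.DataFrame:
    """Sliding-window inactive/active expression ratio along the X.

    X genes are ordered by start coordinate; genes with zero pooled allelic
    reads in the subset are dropped as uninformative. Each window spans
    ``window_genes`` consecutive informative genes (step 1); reads are
    pooled over cells before the ratio, with each cell's inactive allele
    taken from its state-table row. Windows with zero active reads get a
    NaN ratio (undefined).
    """
    cells_df = state.cells if isinstance(state, XCIStateResult) else state
    if cells_subset is None:
        cells_subset = cells_df.index
    cell_ids = pd.Index(cells_subset)
    if len(cell_ids) == 0:
        raise ValueError("cells_subset is empty")

    ids = _chromosome_gene_ids(acs, "X", exclude_genes)
    order = acs.genes.loc[ids, "start"].sort_values().index
    inactive, active = _inactive_active_counts(
        acs, order, cell_ids, cells_df["inactive_allele"]
    )
    informative = (inactive + active) > 0
    order = order[informative]
    inactive, active = inactive[informative], active[informative]

    if len(order) < window_genes:
        warnings.warn(
            f"only {len(order)} informative X genes (< window of {window_genes}); "
            "returning a single whole-chromosome window", stacklevel=2,
        )
        windows = [np.arange(len(order))] if len(order) else []
    else:
        windows = [np.arange(i, i + window_genes)
                   for i in range(len(order) - window_genes + 1)]

    starts = acs.genes.loc[order, "start"].to_numpy()
    ends = acs.genes.loc[order, "end"].to_numpy()
    rows = []
    for w, idx in enumerate(windows):
        i_sum = int(inactive[idx].sum())
        a_sum = int(active[idx].sum())
        rows.append(
            dict(
                window=w,
                midpoint_bp=float((starts[idx[0]] + ends[idx[-1]]) / 2.0),
                n_genes=len(idx),
                gene_ids=",".join(order[idx]),
                inactive_sum=i_sum,
                active_sum=a_sum,
                ratio=i_sum / a_sum if a_sum > 0 else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["window", "midpoint_bp", "n_genes", "gene_ids",
                       "inactive_sum", "active_sum", "ratio"],
    )


def detect_escapees(
    acs: AllelicCountSet,
    state: XCIStateResult | pd.DataFrame,
    completed_cells=None,
    min_ratio: float = 0.1,
    min_cell_fraction: float = 0.25,
    exclude_genes=DEFAULT_EXCLUDE_GENES,
) -> pd.DataFrame:
    """Flag X genes retaining inactive-X expression in completed-XCI cells.

    A gene escapes if its pooled inactive/active read ratio over
    completed-XCI cells is >= ``min_ratio`` and inactive-allele reads are
    seen in >= ``min_cell_fraction`` of the completed cells in which the
    gene is expressed (any allelic read).
    """
    cells_df = state.cells if isinstance(state, XCIStateResult) else state
    if completed_cells is None:
        completed_cells = cells_df.index[cells_df["xci_group"] == "completed"]
    cell_ids = pd.Index(completed_cells)
    if len(cell_ids) == 0:
        raise ValueError("no completed-XCI cells available for escapee detection")

    ids = _chromosome_gene_ids(acs, "X", exclude_genes)
    mat = acs.maternal.loc[ids, cell_ids].to_numpy()
    pat = acs.paternal.loc[ids, cell_ids].to_numpy()
    mat_inactive = cells_df["inactive_allele"].loc[cell_ids].isin(
        ["maternal", "undetermined"]).to_numpy()
    inactive = np.where(mat_inactive[None, :], mat, pat)
    active = np.where(mat_inactive[None, :], pat, mat)

    i_sum = inactive.sum(axis=1)
    a_sum = active.sum(axis=1)
    expressed = (mat + pat) > 0
    n_expressed = expressed.sum(axis=1)
    n_inactive_detected = ((inactive > 0) & expressed).sum(axis=1)
    ratio = np.full(len(ids), np.nan)
    ratio[a_sum > 0] = i_sum[a_sum > 0] / a_sum[a_sum > 0]
    ratio[(a_sum == 0) & (i_sum > 0)] = np.inf  # inactive-only expression
    cell_frac = np.where(n_expressed > 0,
                         n_inactive_detected / np.maximum(n_expressed, 1), 0.0)

    report = pd.DataFrame(
        {
            "gene_name": acs.genes.loc[ids, "gene_name"],
            "inactive_sum": i_sum,
            "active_sum": a_sum,
            "inactive_active_ratio": ratio,
            "n_cells_expressed": n_expressed,
            "inactive_detected_fraction": cell_frac,
        },
        index=ids,
    )
    ratio_ok = np.nan_to_num(ratio, nan=-1.0) >= min_ratio
    report["escapee"] = (n_expressed > 0) & ratio_ok & (cell_frac >= min_cell_fraction)
    report.index.name = "gene_id"
    return report
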