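"""Associating XCI progression with gene expression.

Covers the pluripotency score (mean RPKM of the eight core factors
Pou5f1, Sox2, Nanog, Klf2, Esrrb, Dppa3, Tcfcp2l1 and Prdm14), Spearman
correlations of per-gene expression with the per-cell X activity index,
uninitiated- vs initiated-XCI group expression tests, condition-enriched
marker detection (one-way ANOVA + fold-change rule) and the Xist/Tsix
report. "Adjusted P" is Benjamini-Hochberg throughout.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .state import XCIStateResult

__all__ = [
    "PLURIPOTENCY_SCORE_GENES",
    "pluripotency_score",
    "spearman",
    "correlate_with_activity",
    "group_expression_test",
    "marker_enrichment",
    "xist_tsix_report",
]

PLURIPOTENCY_SCORE_GENES = (
    "Pou5f1", "Sox2", "Nanog", "Klf2", "Esrrb", "Dppa3", "Tcfcp2l1", "Prdm14",
)

# exact permutation null is enumerated up to this sample size (8! = 40320)
_EXACT_PERMUTATION_MAX_N = 8


def _resolve_gene_rows(expr: pd.DataFrame, names, gene_names: pd.Series | None):
    """Map requested gene names to expression rows; returns (ids, missing)."""
    if gene_names is None:
        present = [n for n in names if n in expr.index]
        return present, [n for n in names if n not in expr.index]
    lookup = {}
    for gid, gname in gene_names.items():
        lookup.setdefault(gname, gid)
    ids = [lookup[n] for n in names if n in lookup and lookup[n] in expr.index]
    missing = [n for n in names if n not in lookup or lookup[n] not in expr.index]
    return ids, missing


def pluripotency_score(
    expr: pd.DataFrame,
    gene_set=PLURIPOTENCY_SCORE_GENES,
    gene_names: pd.Series | None = None,
) -> pd.Series:
    """Mean RPKM of the pluripotency gene set per cell.

    ``gene_names`` maps expression-row ids to gene symbols when the matrix
    is id-indexed. Missing genes trigger a warning; all missing is an error.
    """
    ids, missing = _resolve_gene_rows(expr, gene_set, gene_names)
    if not ids:
        raise ValueError(f"none of the score genes present: {list(gene_set)}")
    if missing:
        warnings.warn(f"score genes missing from matrix: {missing}", stacklevel=2)
    score = expr.loc[ids].mean(axis=0)
    score.name = "pluripotency_score"
    return score


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    Two-sided p-value from the exact permutation null for n <= 8, the
    t-approximation otherwise. Returns (nan, nan) for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_PERMUTATION_MAX_N:
        null = np.array([
            np.corrcoef(rx, np.asarray(perm))[0, 1]
            for perm in itertools.permutations(ry)
        ])
        p = float(np.mean(np.abs(null) >= abs(r) - 1e-12))
    else:
        t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def correlate_with_activity(
    expr: pd.DataFrame,
    state: XCIStateResult | pd.DataFrame,
    gene_ids=None,
    min_rpkm_filter: float | dict | None = None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of each gene's expression with the activity index.

    Only female cells with a defined activity are used. ``min_rpkm_filter``
    restricts, per gene, to cells expressing that gene at or above the
    threshold (a scalar applies to all genes; a dict sets per-gene values —
    e.g. the Xist >= 1 RPKM rule). BH adjustment runs across tested genes.
    """
    cells_df = state.cells if isinstance(state, XCIStateResult) else state
    usable = cells_df.index[cells_df["activity"].notna()]
    usable = usable.intersection(expr.columns)
    if gene_ids is None:
        gene_ids = expr.index
    rows = []
    for gid in gene_ids:
        thr = (min_rpkm_filter.get(gid, None) if isinstance(min_rpkm_filter, dict)
               else min_rpkm_filter)
        vals = expr.loc[gid, usable]
        cells = usable if thr is None else usable[vals >= thr]
        if len(cells) < min_cells:
            rows.append(dict(gene_id=gid, r=np.nan, p=np.nan, n=len(cells),
                             cell_filter=thr if thr is not None else np.nan))
            continue
        r, p = spearman(expr.loc[gid, cells], cells_df.loc[cells, "activity"])
        rows.append(dict(gene_id=gid, r=r, p=p, n=len(cells),
                         cell_filter=thr if thr is not None else np.nan))
    table = pd.DataFrame(rows)
    tested = table["p"].notna()
    table["p_adj"] = np.nan
    if tested.any():
        table.loc[tested, "p_adj"] = multipletests(
            table.loc[tested, "p"], method="fdr_bh")[1]
    return table


def group_expression_test(
    values: pd.Series,
    groups: pd.Series,
    uninitiated_label: str = "uninitiated",
    initiated_labels=("ongoing", "completed"),
    alternative: str = "two-sided",
) -> dict:
    """Student's t-test of expression between uninitiated- and initiated-XCI cells.

    ``values`` is a per-cell score or expression vector; ``groups`` the
    per-cell XCI group. ``alternative='greater'`` tests uninitiated-higher.
    """
    common = values.index.intersection(groups.index)
    v, g = values.loc[common], groups.loc[common]
    a = v[g == uninitiated_label].to_numpy(float)
    b = v[g.isin(initiated_labels)].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"both groups need >= 2 cells (uninitiated: {len(a)}, initiated: {len(b)})"
        )
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return dict(t=float(t), p=float(p), n_uninitiated=len(a), n_initiated=len(b),
                mean_uninitiated=float(a.mean()), mean_initiated=float(b.mean()))


def marker_enrichment(
    expr: pd.DataFrame,
    conditions: pd.Series,
    fc_cut: float = 4.0,
    alpha: float = 0.01,
    pseudocount: float = 0.1,
    gene_ids=None,
) -> pd.DataFrame:
    """Condition-enriched genes by ANOVA + all-pairwise fold change.

    A gene is enriched in condition k when (mean_k + eps) > fc_cut *
    (mean_j + eps) for every other condition j (eps = ``pseudocount`` RPKM,
    means on the raw scale) and its one-way ANOVA across conditions — run
    on log2(RPKM + 1) — has BH-adjusted p < alpha. At most one enriched
    condition per gene by construction.
    """
    cond_values = conditions.loc[expr.columns]
    cond_names = list(pd.unique(cond_values))
    if len(cond_names) < 2:
        raise ValueError("marker enrichment needs >= 2 conditions")
    group_cols = {c: expr.columns[(cond_values == c).to_numpy()] for c in cond_names}
    for c, cols in group_cols.items():
        if len(cols) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 cells")
    if gene_ids is None:
        gene_ids = expr.index

    sub = expr.loc[gene_ids]
    log_expr = np.log2(sub + 1.0)
    anova_p = np.full(len(sub), np.nan)
    groups_log = [log_expr[group_cols[c]].to_numpy() for c in cond_names]
    for i in range(len(sub)):
        samples = [g[i] for g in groups_log]
        if np.ptp(np.concatenate(samples)) == 0:
            anova_p[i] = 1.0
            continue
        anova_p[i] = stats.f_oneway(*samples).pvalue
    anova_p = np.nan_to_num(anova_p, nan=1.0)
    p_adj = multipletests(anova_p, method="fdr_bh")[1]

    means = pd.DataFrame(
        {c: sub[group_cols[c]].mean(axis=1) for c in cond_names}
    )
    shifted = means + pseudocount
    rows = []
    for i, gid in enumerate(sub.index):
        m = shifted.iloc[i]
        best = m.idxmax()
        others = m.drop(best)
        fc = float((m[best] / others).min())
        enriched = fc > fc_cut and p_adj[i] < alpha
        rows.append(
            dict(gene_id=gid,
                 enriched_condition=best if enriched else None,
                 fold_change_vs_best_other=fc,
                 anova_p=float(anova_p[i]), anova_p_adj=float(p_adj[i]),
                 **{f"mean_{c}": float(means.iloc[i][c]) for c in cond_names})
        )
    return pd.DataFrame(rows)


def xist_tsix_report(
    expr: pd.DataFrame,
    state: XCIStateResult | pd.DataFrame,
    cell_meta: pd.DataFrame,
    gene_names: pd.Series | None = None,
    xist: str = "Xist",
    tsix: str = "Tsix",
    min_xist_rpkm: float = 1.0,
) -> pd.DataFrame:
    """Per condition x sex: Xist/Tsix coupling and their relation to activity.

    Reports Spearman r (and p) of Xist vs Tsix per condition and sex, the
    Xist-vs-activity and Tsix-vs-activity correlations in female cells with
    Xist >= ``min_xist_rpkm`` RPKM, and the female-vs-male Student's t-test
    of Xist expression per condition pair sharing a base condition name
    (suffix before '.F'/'.M').
    """
    ids, missing = _resolve_gene_rows(expr, [xist, tsix], gene_names)
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    xist_id, tsix_id = ids
    cells_df = state.cells if isinstance(state, XCIStateResult) else state

    rows = []
    for (cond, sex), meta in cell_meta.groupby(["condition", "sex"], sort=False):
        cols = meta.index.intersection(expr.columns)
        if len(cols) < 3:
            continue
        xs = expr.loc[xist_id, cols]
        ts = expr.loc[tsix_id, cols]
        r_xt, p_xt = spearman(xs, ts)
        r_xa = p_xa = r_ta = p_ta = np.nan
        if sex == "F":
            f_cells = cols.intersection(cells_df.index[cells_df["activity"].notna()])
            f_cells = f_cells[expr.loc[xist_id, f_cells] >= min_xist_rpkm]
            if len(f_cells) >= 3:
                r_xa, p_xa = spearman(expr.loc[xist_id, f_cells],
                                      cells_df.loc[f_cells, "activity"])
                r_ta, p_ta = spearman(expr.loc[tsix_id, f_cells],
                                      cells_df.loc[f_cells, "activity"])
        rows.append(dict(condition=cond, sex=sex, n_cells=len(cols),
                         mean_xist=float(xs.mean()), mean_tsix=float(ts.mean()),
                         r_xist_tsix=r_xt, p_xist_tsix=p_xt,
                         r_xist_activity=r_xa, p_xist_activity=p_xa,
                         r_tsix_activity=r_ta, p_tsix_activity=p_ta))
    report = pd.DataFrame(rows)
    if report.empty:
        return report

    # female-vs-male Xist comparison per shared base condition (e.g. ES2i.F / ES2i.M)
    report["base_condition"] = report["condition"].str.replace(r"\.(F|M)$", "", regex=True)
    fvm_p, fvm_t = {}, {}
    for base, grp in report.groupby("base_condition"):
        sexes = set(grp["sex"])
        if {"F", "M"} <= sexes:
            f_cond = grp.loc[grp["sex"] == "F", "condition"].iloc[0]
            m_cond = grp.loc[grp["sex"] == "M", "condition"].iloc[0]
            f_cells = cell_meta.index[cell_meta["condition"] == f_cond].intersection(expr.columns)
            m_cells = cell_meta.index[cell_meta["condition"] == m_cond].intersection(expr.columns)
            f_vals = expr.loc[xist_id, f_cells].to_numpy(float)
            m_vals = expr.loc[xist_id, m_cells].to_numpy(float)
            if np.ptp(np.concatenate([f_vals, m_vals])) == 0:
                # degenerate: identical everywhere (e.g. Xist silent in all)
                fvm_t[base], fvm_p[base] = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(f_vals, m_vals, equal_var=True)
                fvm_t[base], fvm_p[base] = float(t), float(p)
    report["t_female_vs_male_xist"] = report["base_condition"].map(fvm_t)
    report["p_female_vs_male_xist"] = report["base_condition"].map(fvm_p)
    return report
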