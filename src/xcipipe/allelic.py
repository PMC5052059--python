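"""Biallelic/monoallelic expression calling and its link to expression level.

A gene in a cell is called from its SNP-informative read pair
(maternal, paternal): an allele is detected when it has at least
``min_allele_reads`` reads (default 2); both detected -> biallelic,
exactly one -> mono-maternal / mono-paternal, neither -> undetected.
Because allelic dropout is more likely at low expression, the biallelic
fraction of a gene rises with its expression level; the analyses here
quantify that coupling: per-gene allelic profiles across conditions at
RPKM thresholds (5/10/20), a one-sided t-test of whether biallelically
expressed cells show higher RPKM than monoallelic ones, and an exact
binomial sign test of whether up-/down-regulated genes shift their
biallelic fraction between conditions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AllelicCountSet

__all__ = [
    "CALL_CLASSES",
    "call_allelic_state",
    "build_call_matrix",
    "allelic_profile_report",
    "biallelic_vs_mono_expression_test",
    "biallelic_shift_vs_de",
    "exact_sign_test",
]

CALL_CLASSES = ("biallelic", "mono_maternal", "mono_paternal", "undetected")


def call_allelic_state(maternal_reads, paternal_reads, min_allele_reads: int = 2):
    """Classify allelic expression from a read pair (vectorized).

    Returns 'biallelic', 'mono_maternal', 'mono_paternal' or 'undetected'
    (strings; an array of them for array input).
    """
    mat = np.asarray(maternal_reads)
    pat = np.asarray(paternal_reads)
    if (mat < 0).any() or (pat < 0).any():
        raise ValueError("read counts must be non-negative")
    m_det = mat >= min_allele_reads
    p_det = pat >= min_allele_reads
    out = np.where(
        m_det & p_det, "biallelic",
        np.where(m_det, "mono_maternal",
                 np.where(p_det, "mono_paternal", "undetected")),
    )
    if np.isscalar(maternal_reads) and np.isscalar(paternal_reads):
        return str(out.item())
    return out


def build_call_matrix(acs: AllelicCountSet, min_allele_reads: int = 2) -> pd.DataFrame:
    """Genes x cells matrix of allelic calls."""
    calls = call_allelic_state(
        acs.maternal.to_numpy(), acs.paternal.to_numpy(), min_allele_reads
    )
    return pd.DataFrame(calls, index=acs.gene_ids, columns=acs.cell_ids)


def allelic_profile_report(
    calls: pd.DataFrame,
    expr: pd.DataFrame,
    conditions: pd.Series,
    gene_ids=None,
    tau_set=(5, 10, 20),
) -> pd.DataFrame:
    """Per gene x condition x RPKM-threshold allelic composition.

    For each threshold tau, only cells expressing the gene at >= tau RPKM
    are counted; fractions are over cells with a biallelic or monoallelic
    call (undetected cells are tallied separately).
    """
    if gene_ids is None:
        gene_ids = calls.index
    rows = []
    cond_values = conditions.loc[calls.columns]
    for gid in gene_ids:
        g_calls = calls.loc[gid]
        g_expr = expr.loc[gid, calls.columns]
        for cond in cond_values.unique():
            in_cond = cond_values == cond
            for tau in tau_set:
                sel = in_cond & (g_expr >= tau)
                n = int(sel.sum())
                sub = g_calls[sel]
                n_bi = int((sub == "biallelic").sum())
                n_mm = int((sub == "mono_maternal").sum())
                n_mp = int((sub == "mono_paternal").sum())
                n_called = n_bi + n_mm + n_mp
                rows.append(
                    dict(
                        gene_id=gid, condition=cond, tau=tau,
                        n_cells_expressed=n, n_called=n_called,
                        biallelic_fraction=n_bi / n_called if n_called else np.nan,
                        mono_maternal_fraction=n_mm / n_called if n_called else np.nan,
                        mono_paternal_fraction=n_mp / n_called if n_called else np.nan,
                        mean_rpkm=float(g_expr[sel].mean()) if n else np.nan,
                    )
                )
    return pd.DataFrame(rows)


def _biallelic_fraction(g_calls: pd.Series, sel: pd.Series) -> float:
    sub = g_calls[sel]
    called = sub.isin(["biallelic", "mono_maternal", "mono_paternal"])
    n_called = int(called.sum())
    if n_called == 0:
        return np.nan
    return float((sub == "biallelic").sum() / n_called)


def biallelic_vs_mono_expression_test(
    calls: pd.DataFrame,
    expr: pd.DataFrame,
    conditions: pd.Series,
    gene_ids=None,
    tau: float = 20.0,
    min_bi: int = 5,
    min_mono: int = 5,
) -> pd.DataFrame:
    """Does biallelic expression of a gene come with higher expression?

    Per gene x condition, among cells expressing the gene at >= tau RPKM,
    a one-sided two-sample Student's t-test of RPKM in biallelic vs
    monoallelic cells (alternative: biallelic higher). Only combinations
    with >= min_bi biallelic and >= min_mono monoallelic cells qualify;
    p-values are Benjamini-Hochberg adjusted across the table.
    """
    if gene_ids is None:
        gene_ids = calls.index
    cond_values = conditions.loc[calls.columns]
    rows = []
    for gid in gene_ids:
        g_calls = calls.loc[gid]
        g_expr = expr.loc[gid, calls.columns]
        for cond in cond_values.unique():
            sel = (cond_values == cond) & (g_expr >= tau)
            bi = g_expr[sel & (g_calls == "biallelic")]
            mono = g_expr[sel & g_calls.isin(["mono_maternal", "mono_paternal"])]
            if len(bi) < min_bi or len(mono) < min_mono:
                continue
            t, p = stats.ttest_ind(bi, mono, equal_var=True, alternative="greater")
            rows.append(
                dict(gene_id=gid, condition=cond, n_biallelic=len(bi),
                     n_monoallelic=len(mono), mean_rpkm_biallelic=float(bi.mean()),
                     mean_rpkm_monoallelic=float(mono.mean()), t=float(t),
                     p=float(p))
            )
    table = pd.DataFrame(rows)
    if table.empty:
        warnings.warn("no gene/condition pair qualified for the biallelic-vs-mono test",
                      stacklevel=2)
        return table
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def exact_sign_test(n_positive: int, n_negative: int) -> dict[str, float]:
    """Exact binomial sign test against an even split (ties already dropped).

    Returns one-sided (toward an excess of positives) and two-sided
    p-values; both NaN when there are no non-tied observations.
    """
    n = n_positive + n_negative
    if n == 0:
        return {"p_one_sided": np.nan, "p_two_sided": np.nan}
    return {
        "p_one_sided": stats.binomtest(n_positive, n, 0.5, alternative="greater").pvalue,
        "p_two_sided": stats.binomtest(n_positive, n, 0.5, alternative="two-sided").pvalue,
    }


def biallelic_shift_vs_de(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    up_genes,
    down_genes,
    tau: float = 20.0,
    occupancy: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relate differential expression direction to biallelic-fraction shifts.

    ``calls_a``/``calls_b`` and ``expr_a``/``expr_b`` are the call and RPKM
    matrices restricted to the cells of the two compared conditions;
    ``up_genes``/``down_genes`` are externally determined genes up- or
    down-regulated in condition A relative to B. A gene qualifies when it
    is expressed at >= tau RPKM in at least ``occupancy`` of the cells of
    either condition. Per gene, delta_bi = biallelic fraction(A) -
    biallelic fraction(B); each direction group gets an exact binomial sign
    test of whether genes with delta_bi > 0 outnumber those with
    delta_bi < 0 (ties dropped). Returns (per-gene table, per-group tests).
    """
    up_genes, down_genes = list(up_genes), list(down_genes)
    if not up_genes:
        raise ValueError("up_genes is empty")
    if not down_genes:
        raise ValueError("down_genes is empty")

    gene_rows = []
    for direction, genes in (("up", up_genes), ("down", down_genes)):
        for gid in genes:
            if gid not in calls_a.index or gid not in calls_b.index:
                continue
            occ_a = float((expr_a.loc[gid] >= tau).mean())
            occ_b = float((expr_b.loc[gid] >= tau).mean())
            if max(occ_a, occ_b) < occupancy:
                continue
            bi_a = _biallelic_fraction(calls_a.loc[gid], expr_a.loc[gid] >= tau)
            bi_b = _biallelic_fraction(calls_b.loc[gid], expr_b.loc[gid] >= tau)
            if np.isnan(bi_a) or np.isnan(bi_b):
                continue
            gene_rows.append(
                dict(gene_id=gid, direction=direction, occupancy_a=occ_a,
                     occupancy_b=occ_b, biallelic_fraction_a=bi_a,
                     biallelic_fraction_b=bi_b, delta_bi=bi_a - bi_b)
            )
    shift = pd.DataFrame(gene_rows)

    test_rows = []
    for direction in ("up", "down"):
        sub = shift[shift["direction"] == direction] if not shift.empty else shift
        n_pos = int((sub["delta_bi"] > 0).sum()) if not sub.empty else 0
        n_neg = int((sub["delta_bi"] < 0).sum()) if not sub.empty else 0
        n_tie = int((sub["delta_bi"] == 0).sum()) if not sub.empty else 0
        res = exact_sign_test(n_pos, n_neg)
        test_rows.append(
            dict(direction=direction, n_genes=len(sub), n_delta_positive=n_pos,
                 n_delta_negative=n_neg, n_ties=n_tie,
                 median_delta_bi=float(sub["delta_bi"].median()) if len(sub) else np.nan,
                 **res)
        )
    tests = pd.DataFrame(test_rows)
    if shift.empty or (tests[["p_one_sided"]].isna().all().all()):
        warnings.warn("sign test undefined for at least one direction "
                      "(no qualifying genes or all ties)", stacklevel=2)
    return shift, tests
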