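"""Containers and I/O for allele-resolved single-cell count data.

The central container is :class:`AllelicCountSet`: paired maternal/paternal
SNP-informative read-count matrices (genes x cells) plus a total-read matrix,
gene annotation and cell metadata. On disk this is a directory of five TSV
files (``maternal_counts.tsv``, ``paternal_counts.tsv``, ``total_counts.tsv``,
``genes.tsv``, ``cells.tsv``); gene annotation may alternatively come from a
GTF file, in which case the exonic length of a gene is the length of the
union of its exon intervals.

By convention the maternal allele is the C57BL/6J haplotype of the
C57BL/6J (dam) x CAST/EiJ (sire) cross; the ``swap_alleles`` helper flips
the labelling for data phased the other way round.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AllelicCountSet",
    "AllelicDataError",
    "read_allelic_counts",
    "write_allelic_counts",
    "read_gene_annotation",
    "compute_rpkm",
    "qc_filter_cells",
    "infer_sex",
    "swap_alleles",
]

GENE_COLUMNS = ["gene_id", "gene_name", "chromosome", "start", "end", "exonic_length"]
CELL_COLUMNS = ["cell_id", "condition", "sex", "qc_pass", "library_size"]


class AllelicDataError(ValueError):
    """Raised when allelic count inputs violate the container contract."""


@dataclass
class AllelicCountSet:
    """Paired allelic count matrices with gene annotation and cell metadata.

    Attributes
    ----------
    maternal, paternal : pd.DataFrame
        Genes x cells matrices of SNP-informative read counts assigned to
        the maternal (C57BL/6J) and paternal (CAST/EiJ) haplotypes.
    total : pd.DataFrame
        Genes x cells matrix of all mapped reads (SNP-informative or not);
        ``maternal + paternal <= total`` entrywise.
    genes : pd.DataFrame
        Indexed by gene_id with columns gene_name, chromosome, start, end,
        exonic_length (1-based inclusive coordinates).
    cells : pd.DataFrame
        Indexed by cell_id with columns condition, sex ({M, F, unknown}),
        qc_pass, library_size.
    """

    maternal: pd.DataFrame
    paternal: pd.DataFrame
    total: pd.DataFrame
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        for m in (self.maternal, self.paternal, self.total):
            m.index.name = "gene_id"
            m.columns.name = "cell_id"
        self.validate()

    def validate(self) -> None:
        mats = {"maternal": self.maternal, "paternal": self.paternal, "total": self.total}
        shape = self.maternal.shape
        for name, m in mats.items():
            if m.shape != shape:
                raise AllelicDataError(
                    f"{name} matrix shape {m.shape} differs from maternal {shape}"
                )
            if not m.index.equals(self.maternal.index):
                raise AllelicDataError(f"{name} matrix gene order differs from maternal")
            if not m.columns.equals(self.maternal.columns):
                missing = set(self.maternal.columns).symmetric_difference(m.columns)
                raise AllelicDataError(
                    f"{name} matrix cell columns differ from maternal: {sorted(missing)}"
                )
            if (m.to_numpy() < 0).any():
                raise AllelicDataError(f"{name} matrix contains negative counts")
        if self.maternal.index.has_duplicates:
            dups = self.maternal.index[self.maternal.index.duplicated()].unique().tolist()
            raise AllelicDataError(f"duplicated gene ids: {dups}")
        if self.maternal.columns.has_duplicates:
            dups = self.maternal.columns[self.maternal.columns.duplicated()].unique().tolist()
            raise AllelicDataError(f"duplicated cell ids: {dups}")
        missing_genes = self.maternal.index.difference(self.genes.index)
        if len(missing_genes):
            raise AllelicDataError(
                f"genes absent from annotation: {missing_genes.tolist()}"
            )
        missing_cells = self.maternal.columns.difference(self.cells.index)
        if len(missing_cells):
            raise AllelicDataError(
                f"cells absent from metadata: {missing_cells.tolist()}"
            )
        allelic = self.maternal.to_numpy() + self.paternal.to_numpy()
        if (allelic > self.total.to_numpy()).any():
            raise AllelicDataError("maternal + paternal exceeds total for some entries")
        bad = self.genes.loc[self.maternal.index]
        if (bad["start"] > bad["end"]).any():
            raise AllelicDataError("gene annotation with start > end")
        if (bad["exonic_length"] < 1).any():
            raise AllelicDataError("gene annotation with exonic_length < 1")

    @property
    def gene_ids(self) -> pd.Index:
        return self.maternal.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.maternal.columns

    def gene_names(self) -> pd.Series:
        return self.genes.loc[self.gene_ids, "gene_name"]

    def genes_on(self, chromosome: str) -> pd.Index:
        ann = self.genes.loc[self.gene_ids]
        return ann.index[ann["chromosome"].astype(str) == str(chromosome)]

    def autosomal_genes(self) -> pd.Index:
        ann = self.genes.loc[self.gene_ids]
        chrom = ann["chromosome"].astype(str)
        return ann.index[~chrom.isin(["X", "Y", "chrX", "chrY", "MT", "chrM"])]

    def ids_for_names(self, names) -> list[str]:
        """Map gene names to gene ids (first match per name, missing skipped)."""
        lookup = {}
        for gid, gname in self.gene_names().items():
            lookup.setdefault(gname, gid)
        return [lookup[n] for n in names if n in lookup]

    def subset_cells(self, cell_ids) -> "AllelicCountSet":
        cols = pd.Index(cell_ids)
        return AllelicCountSet(
            maternal=self.maternal[cols],
            paternal=self.paternal[cols],
            total=self.total[cols],
            genes=self.genes,
            cells=self.cells.loc[cols],
        )

    def passing_cells(self) -> "AllelicCountSet":
        """Default downstream view: cells with qc_pass == True."""
        keep = self.cells.index[self.cells["qc_pass"].astype(bool)]
        return self.subset_cells(keep)


def _read_matrix(path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise AllelicDataError(f"{what} matrix {path}: duplicated gene ids {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise AllelicDataError(f"{what} matrix {path}: non-numeric entries")
    if not np.allclose(arr, np.round(arr)):
        raise AllelicDataError(f"{what} matrix {path}: non-integer counts")
    return df.astype(np.int64)


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene annotation from TSV or GTF.

    TSV must carry the columns gene_id, gene_name, chromosome, start, end,
    exonic_length. For GTF, exonic_length is computed as the union of the
    exon intervals of each gene (1-based inclusive).
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff", ".gff3"}:
        return _annotation_from_gtf(path)
    ann = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in ann.columns]
    if missing:
        raise AllelicDataError(f"annotation {path} missing columns: {missing}")
    return ann.set_index("gene_id")


def _annotation_from_gtf(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (e.start, e.end) for e in db.region(
                seqid=gene.seqid, start=gene.start, end=gene.end, featuretype="exon"
            ) if e.attributes.get("gene_id", [None])[0] == gene.id
        )
        length = _union_length(exons) if exons else (gene.end - gene.start + 1)
        name = gene.attributes.get("gene_name", [gene.id])[0]
        records.append(
            dict(gene_id=gene.id, gene_name=name, chromosome=gene.seqid,
                 start=gene.start, end=gene.end, exonic_length=length)
        )
    if not records:
        raise AllelicDataError(f"no gene features found in {path}")
    return pd.DataFrame(records).set_index("gene_id")


def _union_length(intervals) -> int:
    total, cur_start, cur_end = 0, None, None
    for s, e in intervals:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def read_allelic_counts(
    maternal_path, paternal_path, total_path, annotation_path, metadata_path
) -> AllelicCountSet:
    """Assemble an :class:`AllelicCountSet` from its on-disk TSV layout.

    All three matrices must share gene rows and cell columns; every gene row
    must be covered by the annotation and every cell column by the metadata.
    Violations raise :class:`AllelicDataError` naming the offending ids.
    """
    maternal = _read_matrix(maternal_path, "maternal")
    paternal = _read_matrix(paternal_path, "paternal")
    total = _read_matrix(total_path, "total")
    for name, m in [("paternal", paternal), ("total", total)]:
        missing = maternal.columns.difference(m.columns)
        if len(missing):
            raise AllelicDataError(f"{name} matrix missing cells: {missing.tolist()}")
        extra = m.columns.difference(maternal.columns)
        if len(extra):
            raise AllelicDataError(f"{name} matrix has extra cells: {extra.tolist()}")
        if not m.index.equals(maternal.index):
            raise AllelicDataError(f"{name} matrix gene rows differ from maternal")
    paternal = paternal[maternal.columns]
    total = total[maternal.columns]

    genes = read_gene_annotation(annotation_path)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "cell_id" not in meta.columns:
        raise AllelicDataError(f"metadata {metadata_path} missing cell_id column")
    meta = meta.set_index("cell_id")
    if "qc_pass" not in meta.columns:
        meta["qc_pass"] = True
    if "library_size" not in meta.columns:
        meta["library_size"] = total.sum(axis=0).reindex(meta.index)
    if "sex" not in meta.columns:
        meta["sex"] = "unknown"
    return AllelicCountSet(maternal, paternal, total, genes, meta)


def write_allelic_counts(acs: AllelicCountSet, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "maternal": out / "maternal_counts.tsv",
        "paternal": out / "paternal_counts.tsv",
        "total": out / "total_counts.tsv",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    acs.maternal.to_csv(paths["maternal"], sep="\t", index_label="gene_id")
    acs.paternal.to_csv(paths["paternal"], sep="\t", index_label="gene_id")
    acs.total.to_csv(paths["total"], sep="\t", index_label="gene_id")
    acs.genes.to_csv(paths["genes"], sep="\t", index_label="gene_id")
    acs.cells.to_csv(paths["cells"], sep="\t", index_label="cell_id")
    return paths


def read_allelic_counts_dir(in_dir) -> AllelicCountSet:
    d = Path(in_dir)
    return read_allelic_counts(
        d / "maternal_counts.tsv", d / "paternal_counts.tsv", d / "total_counts.tsv",
        d / "genes.tsv", d / "cells.tsv",
    )


def swap_alleles(acs: AllelicCountSet) -> AllelicCountSet:
    """Flip the maternal/paternal labelling (for crosses phased the other way)."""
    return AllelicCountSet(
        maternal=acs.paternal.copy(), paternal=acs.maternal.copy(),
        total=acs.total, genes=acs.genes, cells=acs.cells,
    )


def compute_rpkm(total_counts: pd.DataFrame, exonic_length, library_size=None) -> pd.DataFrame:
    """Reads per kilobase of exon model per million mapped reads.

    rpkm[g, c] = counts[g, c] * 1e9 / (exonic_length[g] * library_size[c]).
    If ``library_size`` is None it defaults to the column sums of
    ``total_counts``. Zero library sizes are an error.
    """
    length = pd.Series(exonic_length).reindex(total_counts.index)
    if length.isna().any():
        missing = length.index[length.isna()].tolist()
        raise AllelicDataError(f"exonic_length missing for genes: {missing}")
    if (length < 1).any():
        raise AllelicDataError("exonic_length must be >= 1 bp")
    if library_size is None:
        library_size = total_counts.sum(axis=0)
    library_size = pd.Series(library_size).reindex(total_counts.columns)
    if (library_size <= 0).any():
        bad = library_size.index[library_size <= 0].tolist()
        raise AllelicDataError(f"zero or negative library size for cells: {bad}")
    rpkm = total_counts.to_numpy(dtype=float) * 1e9
    rpkm /= length.to_numpy(dtype=float)[:, None]
    rpkm /= library_size.to_numpy(dtype=float)[None, :]
    return pd.DataFrame(rpkm, index=total_counts.index, columns=total_counts.columns)


def rpkm_for(acs: AllelicCountSet) -> pd.DataFrame:
    lib = acs.cells.loc[acs.cell_ids, "library_size"]
    lib = lib.where(lib > 0, acs.total.sum(axis=0))
    return compute_rpkm(acs.total, acs.genes.loc[acs.gene_ids, "exonic_length"], lib)


def qc_filter_cells(
    acs: AllelicCountSet,
    expr: pd.DataFrame,
    min_genes_detected: int = 2000,
    detection_rpkm: float = 1.0,
    marker_genes: tuple[str, ...] | None = None,
    marker_min_rpkm: float = 1.0,
    marker_conditions: tuple[str, ...] | None = None,
) -> AllelicCountSet:
    """Flag cells failing quality thresholds (``qc_pass=False``).

    A cell passes if it detects at least ``min_genes_detected`` genes at
    ``detection_rpkm``. When ``marker_genes`` is given (e.g. the core
    pluripotency markers Nanog, Sox2, Pou5f1), cells of the conditions in
    ``marker_conditions`` (all conditions if None) must additionally express
    every marker above ``marker_min_rpkm``. Filtering is idempotent: the
    returned set keeps all cells, with failing ones flagged; downstream code
    uses :meth:`AllelicCountSet.passing_cells`.
    """
    expr = expr[acs.cell_ids]
    n_detected = (expr >= detection_rpkm).sum(axis=0)
    ok = n_detected >= int(min_genes_detected)

    if marker_genes:
        ids = acs.ids_for_names(marker_genes)
        if len(ids) < len(marker_genes):
            found = set(acs.gene_names().loc[ids])
            missing = [g for g in marker_genes if g not in found]
            raise AllelicDataError(f"marker genes absent from annotation: {missing}")
        marker_ok = (expr.loc[ids] > marker_min_rpkm).all(axis=0)
        if marker_conditions is not None:
            in_scope = acs.cells.loc[acs.cell_ids, "condition"].isin(marker_conditions)
            marker_ok = marker_ok | ~in_scope
        ok = ok & marker_ok

    cells = acs.cells.copy()
    cells.loc[acs.cell_ids, "qc_pass"] = ok & cells.loc[acs.cell_ids, "qc_pass"].astype(bool)
    n_removed = int((~cells.loc[acs.cell_ids, "qc_pass"]).sum())
    if n_removed == len(acs.cell_ids):
        raise AllelicDataError("QC removed every cell; thresholds too strict for this data")
    if n_removed:
        warnings.warn(f"QC flagged {n_removed} of {len(acs.cell_ids)} cells", stacklevel=2)
    return replace(acs, cells=cells)


def infer_sex(
    acs: AllelicCountSet,
    expr: pd.DataFrame,
    y_genes: tuple[str, ...] | None = None,
    min_y_rpkm: float = 1.0,
    x_fraction_cut: float = 0.95,
    min_informative_reads: int = 20,
) -> pd.DataFrame:
    """Infer cell sex from Y-gene expression and maternal X allelic fraction.

    In a C57BL/6J dam x CAST/EiJ sire cross, male cells carry only the
    maternal X, so a maternal X-read fraction near 1 is male evidence on a
    par with summed Y-gene expression. Returns a copy of the cell metadata
    with columns ``inferred_sex`` and ``sex_conflict``; the declared ``sex``
    column is reported against but never overwritten.
    """
    x_ids = acs.genes_on("X")
    if y_genes is None:
        y_ann = acs.genes.loc[acs.gene_ids]
        y_ids = y_ann.index[y_ann["chromosome"].astype(str).isin(["Y", "chrY"])]
    else:
        y_ids = pd.Index(acs.ids_for_names(y_genes))
    if len(y_ids) == 0 and len(x_ids) == 0:
        raise AllelicDataError("no Y genes annotated and no X allelic reads available")

    mat = acs.maternal.loc[x_ids].sum(axis=0)
    pat = acs.paternal.loc[x_ids].sum(axis=0)
    informative = mat + pat
    with np.errstate(invalid="ignore"):
        frac = mat / informative.replace(0, np.nan)
    y_sum = expr.loc[y_ids, acs.cell_ids].sum(axis=0) if len(y_ids) else pd.Series(0.0, index=acs.cell_ids)

    out = acs.cells.copy()
    inferred = []
    for cell in acs.cell_ids:
        male_y = y_sum[cell] >= min_y_rpkm
        enough = informative[cell] >= min_informative_reads
        male_x = enough and frac[cell] >= x_fraction_cut
        if male_y or male_x:
            inferred.append("M")
        elif len(y_ids) or enough:
            # silent Y genes and/or balanced X reads are female evidence
            inferred.append("F")
        else:
            inferred.append("unknown")
    out.loc[acs.cell_ids, "inferred_sex"] = inferred
    declared = out.loc[acs.cell_ids, "sex"].astype(str)
    conflict = (declared.isin(["M", "F"])) & (out.loc[acs.cell_ids, "inferred_sex"] != "unknown") \
        & (declared != out.loc[acs.cell_ids, "inferred_sex"])
    out.loc[acs.cell_ids, "sex_conflict"] = conflict
    n_conf = int(conflict.sum())
    if n_conf:
        warnings.warn(
            f"inferred sex conflicts with declared sex for {n_conf} cells "
            f"({out.index[conflict].tolist()[:10]}...)", stacklevel=2,
        )
    return out
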