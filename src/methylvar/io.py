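"""Readers and writers: modkit-dialect bedMethyl, BED annotations, covariates.

bedMethyl is the 18-column tab-separated summary modkit emits per sample.
The parser uses columns 1–6 (position/strand/mod code) plus the valid
coverage (column 10) and modified-read count (column 12); all other columns
are carried through on write but ignored on read. Coordinates are 0-based
half-open throughout, the BED convention.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import CELL_TYPES, MethylationCountTable, merge_tables, validate_covariates

logger = logging.getLogger(__name__)

BEDMETHYL_MIN_COLUMNS = 12


class BedMethylParseError(ValueError):
    pass


def _site_id(chrom: str, pos: int, strand: str) -> str:
    return f"{chrom}:{pos}:{strand}"


def read_bedmethyl(path, subject_id: str | None = None, mod_code: str = "m") -> MethylationCountTable:
    """Read one subject's bedMethyl file, retaining calls for ``mod_code`` (5mC = "m").

    Rows for other modification codes (e.g. "h" for 5hmC) are dropped.
    Returns a single-subject MethylationCountTable fragment.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem.split(".")[0]
    rows = []
    site_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < BEDMETHYL_MIN_COLUMNS:
                raise BedMethylParseError(
                    f"{path}:{lineno}: expected ≥{BEDMETHYL_MIN_COLUMNS} tab-separated "
                    f"columns, got {len(parts)}"
                )
            chrom, start = parts[0], parts[1]
            code, strand = parts[3], parts[5]
            if code != mod_code:
                continue
            try:
                pos = int(start)
                n_valid = int(parts[9])
                n_mod = int(parts[11])
            except ValueError as exc:
                raise BedMethylParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if n_valid < 0 or n_mod < 0:
                raise BedMethylParseError(f"{path}:{lineno}: negative count")
            if n_mod > n_valid:
                raise BedMethylParseError(f"{path}:{lineno}: n_mod > n_valid")
            sid = _site_id(chrom, pos, strand)
            rows.append((sid, subject_id, n_mod, n_valid))
            site_rows.append((sid, chrom, pos, strand))
    entries = pd.DataFrame(rows, columns=["site_id", "subject_id", "n_mod", "n_valid"])
    sites = pd.DataFrame(site_rows, columns=["site_id", "chrom", "pos", "strand"]).drop_duplicates(
        "site_id"
    )
    return MethylationCountTable(entries=entries, sites=sites.reset_index(drop=True), subjects=[subject_id])


def write_bedmethyl(table: MethylationCountTable, subject_id: str, path, mod_code: str = "m") -> None:
    """Write one subject's counts as an 18-column modkit-dialect bedMethyl."""
    e = table.entries[table.entries["subject_id"] == subject_id]
    site_info = table.sites.set_index("site_id")
    with open(path, "w") as fh:
        merged = e.join(site_info, on="site_id").sort_values(["chrom", "pos"], kind="mergesort")
        for row in merged.itertuples(index=False):
            n_valid, n_mod = int(row.n_valid), int(row.n_mod)
            frac = 100.0 * n_mod / n_valid if n_valid else 0.0
            n_canon = n_valid - n_mod
            fields = [
                row.chrom, str(int(row.pos)), str(int(row.pos) + 1), mod_code,
                str(min(n_valid, 1000)), row.strand, str(int(row.pos)), str(int(row.pos) + 1),
                "255,0,0", str(n_valid), f"{frac:.2f}", str(n_mod), str(n_canon),
                "0", "0", "0", "0", "0",
            ]
            fh.write("\t".join(fields) + "\n")


def combine_strand_dyads(table: MethylationCountTable) -> MethylationCountTable:
    """Merge opposite-strand CpG records into one site per dyad, summing counts.

    A minus-strand cytosine at position p pairs with the plus-strand
    cytosine at p−1; merged sites take the plus-strand coordinate and an
    unstranded label. Off by default in the readers: whether strand records
    should be collapsed depends on the upstream caller's conventions.
    """
    sites = table.sites.copy()
    dyad_pos = np.where(sites["strand"] == "-", sites["pos"] - 1, sites["pos"])
    sites["dyad_id"] = sites["chrom"].astype(str) + ":" + pd.Series(dyad_pos).astype(str) + ":."
    mapping = sites.set_index("site_id")["dyad_id"]
    e = table.entries.copy()
    e["site_id"] = e["site_id"].map(mapping)
    merged = e.groupby(["site_id", "subject_id"], as_index=False)[["n_mod", "n_valid"]].sum()
    new_sites = (
        pd.DataFrame(
            {"site_id": sites["dyad_id"], "chrom": sites["chrom"], "pos": dyad_pos, "strand": "."}
        )
        .drop_duplicates("site_id")
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return MethylationCountTable(entries=merged, sites=new_sites, subjects=list(table.subjects))


def read_cohort_bedmethyls(paths_by_subject: dict[str, Path], mod_code: str = "m") -> MethylationCountTable:
    frags = [read_bedmethyl(p, subject_id=s, mod_code=mod_code) for s, p in sorted(paths_by_subject.items())]
    return merge_tables(frags)


# ---------------------------------------------------------------------------
# BED / interval annotation

def read_bed(path, name_col: bool = True) -> pd.DataFrame:
    """Read BED4/BED6 into a frame with chrom, start, end[, name[, score, strand]]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if not name_col and "name" in df.columns:
        df = df.drop(columns=["name"])
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _build_trees(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in bed.groupby("chrom"):
        tree = IntervalTree()
        for row in grp.itertuples(index=False):
            if row.end > row.start:
                tree.addi(int(row.start), int(row.end), getattr(row, "name", None))
        trees[str(chrom)] = tree
    return trees


def annotate_sites(
    sites: pd.DataFrame,
    gene_bed: pd.DataFrame,
    feature_beds: dict[str, pd.DataFrame],
    te_bed: pd.DataFrame,
    cpg_bed: pd.DataFrame,
    tss_table: pd.DataFrame,
    promoter_window: int = 2000,
) -> pd.DataFrame:
    """Assign each site exactly one category plus CpG-island/TE context.

    Category precedence when intervals overlap: CDS > UTR > promoter > intron;
    a site inside a panel gene but in no feature interval is an intron, and a
    site on a chromosome absent from the annotation falls back to intron with
    a warning. Promoters are the ``promoter_window`` bases upstream of each
    TSS (strand-aware). The TE name field carries taxonomy as "class/family".
    """
    cds_trees = _build_trees(feature_beds.get("CDS", pd.DataFrame(columns=["chrom", "start", "end"])))
    utr_trees = _build_trees(feature_beds.get("UTR", pd.DataFrame(columns=["chrom", "start", "end"])))
    te_trees = _build_trees(te_bed)
    cpg_trees = _build_trees(cpg_bed)
    gene_trees = _build_trees(gene_bed)

    prom_rows = []
    for row in tss_table.itertuples(index=False):
        if getattr(row, "strand", "+") == "-":
            start, end = int(row.tss) + 1, int(row.tss) + 1 + promoter_window
        else:
            start, end = int(row.tss) - promoter_window, int(row.tss)
        prom_rows.append((row.chrom, max(0, start), max(0, end), row.gene))
    prom_bed = pd.DataFrame(prom_rows, columns=["chrom", "start", "end", "name"])
    prom_trees = _build_trees(prom_bed)

    known_chroms = set(gene_trees) | set(cds_trees) | set(prom_trees)
    gene_starts = gene_bed.set_index("name")[["chrom", "start"]] if len(gene_bed) else None

    out = []
    for row in sites.itertuples(index=False):
        chrom, pos = str(row.chrom), int(row.pos)
        if chrom not in known_chroms:
            logger.warning("site %s on chromosome %s absent from annotation; intron fallback", row.site_id, chrom)
        def hits(trees):
            t = trees.get(chrom)
            return sorted(t[pos]) if t is not None else []

        if hits(cds_trees):
            category = "CDS"
        elif hits(utr_trees):
            category = "UTR"
        elif hits(prom_trees):
            category = "promoter"
        else:
            category = "intron"

        te_hit = hits(te_trees)
        te_present = bool(te_hit)
        te_taxonomy = te_hit[0].data if te_present else None
        cpg_island = bool(hits(cpg_trees))

        gene_hit = hits(gene_trees)
        if gene_hit:
            gene = gene_hit[0].data
        else:
            prom_hit = hits(prom_trees)
            if prom_hit:
                gene = prom_hit[0].data
            elif gene_starts is not None and len(gene_starts):
                same = gene_starts[gene_starts["chrom"] == chrom]
                gene = (same["start"] - pos).abs().idxmin() if len(same) else "NA"
            else:
                gene = "NA"
        out.append((row.site_id, category, cpg_island, te_present, te_taxonomy, gene))
    return pd.DataFrame(
        out, columns=["site_id", "category", "cpg_island", "te_present", "te_taxonomy", "gene"]
    )


# ---------------------------------------------------------------------------
# Cohort assembly

def assemble_dataset(
    table: MethylationCountTable,
    n_top_subjects: int = 100,
    min_cov: int = 10,
    min_subjects: int = 90,
) -> MethylationCountTable:
    """Keep the highest-coverage subjects, then sufficiently covered sites.

    Subjects are ranked by mean n_valid over all their sites (ties broken
    lexicographically by subject_id) and the top ``n_top_subjects`` retained.
    A site survives iff at least ``min_subjects`` of the kept subjects cover
    it with n_valid ≥ ``min_cov``.
    """
    if n_top_subjects > table.n_subjects:
        raise ValueError(
            f"n_top_subjects={n_top_subjects} exceeds available subjects ({table.n_subjects})"
        )
    mean_cov = table.entries.groupby("subject_id")["n_valid"].mean()
    mean_cov = mean_cov.reindex(table.subjects).fillna(0.0)
    ranked = sorted(table.subjects, key=lambda s: (-mean_cov[s], s))
    kept_subjects = sorted(ranked[:n_top_subjects])

    e = table.entries[table.entries["subject_id"].isin(kept_subjects)]
    ok = e[e["n_valid"] >= min_cov].groupby("site_id").size()
    kept_sites = set(ok[ok >= min_subjects].index)
    if not kept_sites:
        raise ValueError("no sites survive filters")
    return table.subset(site_ids=kept_sites, subject_ids=kept_subjects)


# ---------------------------------------------------------------------------
# Covariates and tidy outputs

def read_covariates(path) -> pd.DataFrame:
    cov = pd.read_csv(path)
    if "subject_id" not in cov.columns:
        raise ValueError("covariate CSV needs a subject_id column")
    cov["subject_id"] = cov["subject_id"].astype(str)
    return validate_covariates(cov)


def write_covariates(cov: pd.DataFrame, path) -> None:
    validate_covariates(cov)
    cov[["subject_id"] + CELL_TYPES].to_csv(path, index=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    """Tidy TSV with floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
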