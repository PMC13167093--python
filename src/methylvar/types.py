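"""Core domain containers for per-site, per-subject methylation count data.

The unit of observation is a CpG site measured in one subject: a count of
5mC-supporting reads (``n_mod``) out of the valid coverage (``n_valid``).
Tables are stored long-form in pandas with deterministic site/subject order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES = ["lymphocytes", "monocytes", "eosinophils", "basophils", "neutrophils"]

ANNOTATION_CATEGORIES = ["CDS", "UTR", "promoter", "intron"]


@dataclass(frozen=True)
class GenomicSite:
    """A single CpG position. ``pos`` is the 0-based coordinate of the cytosine."""

    site_id: str
    chrom: str
    pos: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position for site {self.site_id}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r} for site {self.site_id}")


@dataclass
class MethylationCountTable:
    """Long-form site × subject methylated/valid read counts.

    ``entries`` has columns site_id, subject_id, n_mod, n_valid with at most
    one row per (site, subject) pair and 0 ≤ n_mod ≤ n_valid.
    """

    entries: pd.DataFrame
    sites: pd.DataFrame  # site_id, chrom, pos, strand — ordered
    subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        e = self.entries
        required = {"site_id", "subject_id", "n_mod", "n_valid"}
        missing = required - set(e.columns)
        if missing:
            raise ValueError(f"entries missing columns: {sorted(missing)}")
        if len(e):
            if (e["n_mod"] < 0).any() or (e["n_valid"] < 0).any():
                raise ValueError("negative counts in entries")
            if (e["n_mod"] > e["n_valid"]).any():
                raise ValueError("n_mod exceeds n_valid for some entries")
            if e.duplicated(["site_id", "subject_id"]).any():
                raise ValueError("duplicate (site, subject) entries")
        if not self.subjects:
            self.subjects = sorted(e["subject_id"].unique().tolist())

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def fractions(self) -> pd.DataFrame:
        """Per-entry methylation fraction n_mod / n_valid (rows with n_valid>0)."""
        e = self.entries[self.entries["n_valid"] > 0].copy()
        e["fraction"] = e["n_mod"] / e["n_valid"]
        return e

    def fraction_matrix(self) -> pd.DataFrame:
        """Site × subject matrix of methylation fractions (NaN where missing)."""
        f = self.fractions()
        mat = f.pivot(index="site_id", columns="subject_id", values="fraction")
        return mat.reindex(index=self.sites["site_id"], columns=self.subjects)

    def subset(self, site_ids=None, subject_ids=None) -> "MethylationCountTable":
        e = self.entries
        sites = self.sites
        subjects = self.subjects
        if site_ids is not None:
            keep = set(site_ids)
            e = e[e["site_id"].isin(keep)]
            sites = sites[sites["site_id"].isin(keep)]
        if subject_ids is not None:
            keep = set(subject_ids)
            e = e[e["subject_id"].isin(keep)]
            subjects = [s for s in subjects if s in keep]
        return MethylationCountTable(
            entries=e.reset_index(drop=True),
            sites=sites.reset_index(drop=True),
            subjects=subjects,
        )


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check SiteAnnotation invariants and return the frame unchanged.

    Columns: site_id, category, cpg_island, te_present, te_taxonomy, gene,
    and optionally chromatin_state.
    """
    bad = ~ann["category"].isin(ANNOTATION_CATEGORIES)
    if bad.any():
        raise ValueError(f"unknown annotation categories: {ann.loc[bad, 'category'].unique()}")
    has_tax = ann["te_taxonomy"].notna() & (ann["te_taxonomy"] != "")
    if (has_tax != ann["te_present"].astype(bool)).any():
        raise ValueError("te_taxonomy must be non-empty iff te_present")
    return ann


def validate_covariates(cov: pd.DataFrame, tol: float = 0.5) -> pd.DataFrame:
    """Check blood differential percentages: non-negative, summing to 100 ± tol.

    Rows with all cell columns missing are allowed (subject without a count).
    """
    cols = [c for c in CELL_TYPES if c in cov.columns]
    if set(cols) != set(CELL_TYPES):
        raise ValueError(f"covariates need columns {CELL_TYPES}")
    vals = cov[CELL_TYPES]
    present = vals.notna().all(axis=1)
    partial = vals.notna().any(axis=1) & ~present
    if partial.any():
        raise ValueError("subjects with partially missing cell percentages")
    sub = vals[present]
    if len(sub):
        if (sub < 0).any().any():
            raise ValueError("negative cell percentages")
        sums = sub.sum(axis=1)
        off = (sums - 100.0).abs() > tol
        if off.any():
            bad_ids = cov.loc[sub.index[off], "subject_id"].tolist()
            raise ValueError(f"cell percentages do not sum to 100 (±{tol}) for {bad_ids}")
    return cov


def merge_tables(fragments: list[MethylationCountTable]) -> MethylationCountTable:
    """Combine per-subject fragments into one table (union of sites)."""
    if not fragments:
        raise ValueError("no fragments to merge")
    entries = pd.concat([f.entries for f in fragments], ignore_index=True)
    sites = (
        pd.concat([f.sites for f in fragments], ignore_index=True)
        .drop_duplicates("site_id")
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    subjects = sorted({s for f in fragments for s in f.subjects})
    return MethylationCountTable(entries=entries, sites=sites, subjects=subjects)


def site_index(table: MethylationCountTable) -> dict[str, int]:
    return {s: i for i, s in enumerate(table.sites["site_id"])}


def as_float_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite values in numeric input")
    return a
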