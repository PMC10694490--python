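"""Bounded-best-hit recruitment of full-length reference alleles.

To build an ASV-tailored reference tree, candidate full-length 16S alleles
are recruited from a repository using a precomputed ASV × reference
percent-identity table (e.g. vsearch ``usearch_global`` output with
max_accepts ≈ 10 and an 80% identity floor).  The recruitment rules:

1. **Bounded best hits** — per ASV, keep only references tied at that ASV's
   best percent identity.
2. **Support filter** — drop references that are a best hit for fewer than
   two ASVs (keeps the tree from ballooning with one-off references).
3. **Backfill** — any ASV whose best references were all dropped gets one
   back, preferring alleles with no ambiguous bases, then precise taxonomy,
   then length, then lexicographic id.

The search itself is out of scope; this module consumes its tabular output
so the logic stays testable without external binaries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from .errors import FormatError, UsageError

__all__ = [
    "HitTable",
    "RefMeta",
    "RecruitReport",
    "read_hits",
    "read_ref_meta",
    "bounded_best_hits",
    "filter_min_support",
    "backfill",
    "recruit",
]

HIT_COLUMNS = ("asv_id", "ref_id", "pct_id")


@dataclass
class HitTable:
    """Rows of (asv_id, ref_id, pct_id) with unique (asv, ref) pairs."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in HIT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"hit table lacks columns {missing}")
        self.df = self.df[list(HIT_COLUMNS)].copy()
        self.df["pct_id"] = self.df["pct_id"].astype(float)
        if self.df.duplicated(["asv_id", "ref_id"]).any():
            raise FormatError("duplicate (asv_id, ref_id) rows in hit table")
        if ((self.df["pct_id"] < 0) | (self.df["pct_id"] > 100)).any():
            raise FormatError("pct_id outside [0, 100]")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RefMeta:
    """Per-reference metadata used to rank backfill candidates."""

    df: pd.DataFrame  # index ref_id; columns length, n_ambiguous, has_precise_taxonomy

    def __post_init__(self):
        need = {"length", "n_ambiguous", "has_precise_taxonomy"}
        missing = need - set(self.df.columns)
        if missing:
            raise FormatError(f"reference metadata lacks columns {sorted(missing)}")
        if self.df.index.has_duplicates:
            raise FormatError("duplicate ref_id in reference metadata")


@dataclass
class RecruitReport:
    """Per-ASV recruitment outcome plus summary diagnostics."""

    per_asv: dict[str, list[str]]
    uncovered: list[str]
    mean_refs_per_asv: float
    n_refs: int

    def to_dict(self) -> dict:
        return {
            "n_refs": self.n_refs,
            "mean_refs_per_asv": self.mean_refs_per_asv,
            "uncovered_asvs": self.uncovered,
            "per_asv": self.per_asv,
        }


def read_hits(path: str | os.PathLike) -> HitTable:
    """Read a hit table from CSV or TSV (sniffed on the header line)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return HitTable(pd.read_csv(path, sep=sep))


def read_ref_meta(path: str | os.PathLike) -> RefMeta:
    df = pd.read_csv(path)
    if "ref_id" not in df.columns:
        raise FormatError("reference metadata needs a ref_id column")
    df = df.set_index("ref_id")
    if "has_precise_taxonomy" in df.columns:
        df["has_precise_taxonomy"] = df["has_precise_taxonomy"].astype(bool)
    return RefMeta(df)


def bounded_best_hits(hits: HitTable) -> HitTable:
    """Keep, per ASV, only hits tied at that ASV's best percent identity."""
    if not len(hits):
        raise UsageError("empty hit table")
    df = hits.df
    best = df.groupby("asv_id")["pct_id"].transform("max")
    return HitTable(df[df["pct_id"] >= best].reset_index(drop=True))


def filter_min_support(best_hits: HitTable, min_asvs: int = 2) -> set[str]:
    """References that are a best hit for at least ``min_asvs`` ASVs."""
    if min_asvs < 1:
        raise UsageError("min_asvs must be >= 1")
    support = best_hits.df.groupby("ref_id")["asv_id"].nunique()
    return set(support[support >= min_asvs].index)


def _backfill_key(meta: RefMeta, ref: str):
    if ref in meta.df.index:
        row = meta.df.loc[ref]
        return (
            0 if int(row["n_ambiguous"]) == 0 else 1,
            0 if bool(row["has_precise_taxonomy"]) else 1,
            -int(row["length"]),
            ref,
        )
    return (1, 1, 0, ref)  # unknown metadata ranks last


def backfill(
    hits: HitTable,
    meta: RefMeta,
    kept: set[str],
    per_asv: int = 1,
) -> set[str]:
    """Restore references for ASVs whose best hits were all discarded.

    For each such ASV, add ``per_asv`` references from its best-hit set,
    ranked by (no ambiguous bases, precise taxonomy, length, id).  ASVs with
    no hits at all are simply uncovered — no error.
    """
    best = bounded_best_hits(hits)
    kept = set(kept)
    for asv, grp in best.df.groupby("asv_id"):
        refs = sorted(grp["ref_id"])
        if any(r in kept for r in refs):
            continue
        ranked = sorted(refs, key=lambda r: _backfill_key(meta, r))
        kept.update(ranked[:per_asv])
    return kept


def recruit(
    hits: HitTable,
    meta: RefMeta,
    min_pct: float = 80.0,
    min_asvs: int = 2,
    backfill_per_asv: int = 1,
) -> tuple[set[str], RecruitReport]:
    """Full recruitment pipeline: floor → best hits → support → backfill.

    Returns the recruited reference set and a per-ASV coverage report whose
    ``mean_refs_per_asv`` can be checked against the design objective of
    roughly ten alleles per ASV.
    """
    if not len(hits):
        raise UsageError("empty hit table")
    floored = hits.df[hits.df["pct_id"] >= min_pct]
    all_asvs = sorted(hits.df["asv_id"].unique())
    if floored.empty:
        report = RecruitReport({a: [] for a in all_asvs}, all_asvs, 0.0, 0)
        return set(), report
    floored_ht = HitTable(floored.reset_index(drop=True))
    best = bounded_best_hits(floored_ht)
    kept = filter_min_support(best, min_asvs=min_asvs)
    kept = backfill(floored_ht, meta, kept, per_asv=backfill_per_asv)
    # drop any kept ref that is no longer a best hit of anything (safety)
    best_refs = set(best.df["ref_id"])
    kept &= best_refs
    per_asv: dict[str, list[str]] = {}
    for asv in all_asvs:
        mine = best.df[best.df["asv_id"] == asv]["ref_id"]
        per_asv[asv] = sorted(set(mine) & kept)
    uncovered = [a for a in all_asvs if not per_asv[a]]
    covered = [a for a in all_asvs if per_asv[a]]
    mean_refs = (
        float(sum(len(per_asv[a]) for a in covered)) / len(covered) if covered else 0.0
    )
    report = RecruitReport(per_asv, uncovered, mean_refs, len(kept))
    return kept, report
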