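"""Homolog mapping and cross-species / cross-tissue gene-set overlap.

Gene sets from different species are compared in a common homolog
namespace.  The resolution rules: a source gene with no homolog is
dropped; a source gene with several homologs keeps only the target whose
numeric ID suffix is lowest (the lowest-Ensembl-ID convention).  Overlap
tables report intersection and exclusive counts; the cross-comparison
ratio contrasts the total between-tissue (intra-species) overlap with the
total between-species (intra-tissue) overlap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .counts import _read_table, _write_table
from .exceptions import ValidationError

_SUFFIX_RE = re.compile(r"(\d+)$")


class HomologMap:
    """Source -> target homolog pairs; a source may map to 0, 1 or many targets."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy().reset_index(drop=True)
        for col in ("source_id", "target_id"):
            if col not in table.columns:
                raise ValidationError(f"homolog map is missing column '{col}'")
            table[col] = table[col].astype(str)
        if table.duplicated(subset=["source_id", "target_id"]).any():
            dups = table[table.duplicated(subset=["source_id", "target_id"])]
            raise ValidationError(f"duplicate (source, target) pairs: {dups.head(5).to_dict('records')}")
        nums = []
        for tid in table["target_id"]:
            m = _SUFFIX_RE.search(tid)
            if m is None:
                raise ValidationError(f"target ID without a numeric suffix: '{tid}'")
            nums.append(int(m.group(1)))
        table["target_num"] = nums
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sources(self) -> set[str]:
        return set(self.table["source_id"])

    @property
    def targets(self) -> set[str]:
        return set(self.table["target_id"])

    def write_tsv(self, path, comments=None) -> None:
        _write_table(self.table[["source_id", "target_id"]].set_index("source_id"),
                     path, index_label="source_id", comments=comments)

    @classmethod
    def from_tsv(cls, path) -> "HomologMap":
        return cls(_read_table(path, index_col=None))


def resolve_homologs(gene_ids: Iterable[str], homolog_map: HomologMap) -> set[str]:
    """Map source genes to targets: unmapped dropped, multi-mapped keep lowest ID."""
    wanted = set(map(str, gene_ids))
    sub = homolog_map.table[homolog_map.table["source_id"].isin(wanted)]
    if sub.empty:
        return set()
    best = sub.sort_values(["source_id", "target_num", "target_id"]).groupby("source_id").head(1)
    return set(best["target_id"])


@dataclass(frozen=True)
class OverlapResult:
    """Intersection/exclusive counts between two gene sets in one namespace."""

    label_a: str
    label_b: str
    overlap_count: int
    exclusive_a_count: int
    exclusive_b_count: int

    def as_dict(self) -> dict:
        return {
            "label_a": self.label_a, "label_b": self.label_b,
            "overlap": self.overlap_count,
            "exclusive_a": self.exclusive_a_count,
            "exclusive_b": self.exclusive_b_count,
        }


def overlap_sets(set_a: Iterable[str], set_b: Iterable[str],
                 label_a: str = "A", label_b: str = "B") -> OverlapResult:
    a, b = set(set_a), set(set_b)
    return OverlapResult(
        label_a=label_a, label_b=label_b,
        overlap_count=len(a & b),
        exclusive_a_count=len(a - b),
        exclusive_b_count=len(b - a),
    )


def overlap_table(results: Sequence[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def biotype_breakdown(de_results: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Expressed / preserved / degraded counts and percentages per biotype.

    ``de_results`` is one contrast's DE table (indexed by gene, with a
    ``status`` column); every tested gene counts as expressed.  Percentages
    are of the biotype's expressed genes, rounded to one decimal.
    """
    if "status" not in de_results.columns:
        raise ValidationError("de_results must carry a 'status' column")
    if "biotype" not in annotations.columns:
        raise ValidationError("annotations must carry a 'biotype' column")
    genes = de_results.index
    missing = sorted(set(genes) - set(annotations.index))
    if missing:
        raise ValidationError(f"genes without annotation rows: {missing[:10]}")
    biotype = annotations.loc[genes, "biotype"]
    if biotype.isna().any():
        raise ValidationError(
            f"genes without biotype: {list(biotype.index[biotype.isna()])[:10]}"
        )
    frame = pd.DataFrame({"biotype": biotype, "status": de_results["status"]})
    rows = []
    for bt, grp in frame.groupby("biotype", sort=True):
        n_exp = len(grp)
        n_pres = int((grp["status"] == "preserved").sum())
        n_deg = int((grp["status"] == "degraded").sum())
        rows.append({
            "biotype": bt, "n_expressed": n_exp,
            "n_preserved": n_pres, "n_degraded": n_deg,
            "pct_preserved": round(100.0 * n_pres / n_exp, 1),
            "pct_degraded": round(100.0 * n_deg / n_exp, 1),
        })
    return pd.DataFrame(rows).set_index("biotype")


def cross_comparison_ratio(overlaps_by_tissue: Sequence[OverlapResult],
                           overlaps_by_species: Sequence[OverlapResult]) -> float:
    """Total intra-species (between-tissue) overlap over total intra-tissue
    (between-species) overlap."""
    if not overlaps_by_tissue or not overlaps_by_species:
        raise ValidationError("both overlap lists must be non-empty")
    num = sum(r.overlap_count for r in overlaps_by_tissue)
    den = sum(r.overlap_count for r in overlaps_by_species)
    if den == 0:
        raise ValidationError("between-species overlap sum is zero; ratio undefined")
    return num / den
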