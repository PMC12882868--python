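"""Pearson co-expression screening and functional-category counting.

For each candidate regulator, the genes whose expression across the atlas
correlates with it at Pearson r >= 0.85 (the screening threshold used by the
PhytoMine co-expression service) form its co-expression neighborhood. Each
partner is assigned one of three target functional categories — lignin
biosynthesis, lignin-related (phenoloxidases such as laccases and class III
peroxidases, lignin-associated transcription factors), or phenylpropanoid-
related (flavonoid / phenolic-acid metabolism) — from a user-supplied
annotation table; everything else counts as "other". Candidates are
shortlisted when their neighborhood holds at least ``min_targets`` genes
from the three target categories.

The printed co-expression lists for the two strongest published candidates
(queries SvMYB24 and SvMYB74) ship as a packaged fixture and can be loaded
with :func:`load_printed_coexpression`.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TARGET_CATEGORIES = ("lignin_biosynthesis", "lignin_related", "phenylpropanoid_related")
OTHER = "other"

PRINTED_LISTS_RESOURCE = "printed_coexpression.tsv"


@dataclass(frozen=True)
class CoexpressionRecord:
    query_id: str
    partner_id: str
    r: float
    category: str = OTHER
    note: str = ""

    def __post_init__(self) -> None:
        if self.query_id == self.partner_id:
            raise ValueError("a gene is not its own co-expression partner")
        if not (-1.0 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"Pearson r out of range: {self.r}")


@dataclass(frozen=True)
class GeneAnnotation:
    category: str = OTHER
    is_toolbox: bool = False
    is_laccase: bool = False
    is_class3_peroxidase: bool = False
    is_nac: bool = False
    is_hcaldh: bool = False


class CategoryAnnotation:
    """gene id -> (category, note flags); unannotated genes default to other."""

    def __init__(self, entries: Mapping[str, GeneAnnotation] | None = None):
        self._entries = dict(entries or {})
        for g, e in self._entries.items():
            if e.category not in TARGET_CATEGORIES + (OTHER,):
                raise ValueError(f"{g}: unknown category {e.category!r}")

    def __getitem__(self, gene_id: str) -> GeneAnnotation:
        return self._entries.get(gene_id, GeneAnnotation())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CategoryAnnotation":
        """Build from a table with gene_id, category and optional flag columns."""
        flags = ("is_toolbox", "is_laccase", "is_class3_peroxidase", "is_nac", "is_hcaldh")
        entries = {}
        for _, row in df.iterrows():
            kwargs = {f: bool(row[f]) for f in flags if f in df.columns and pd.notna(row[f])}
            entries[str(row["gene_id"])] = GeneAnnotation(
                category=str(row["category"]), **kwargs
            )
        return cls(entries)


@dataclass
class CategoryCounts:
    per_category: dict[str, int]
    total_targets: int
    flags: dict[str, bool] = field(default_factory=dict)


def pearson_rows(query: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Pearson r between one row and each row of ``others`` (vectorized)."""
    q = query - query.mean()
    o = others - others.mean(axis=1, keepdims=True)
    qn = np.sqrt((q**2).sum())
    on = np.sqrt((o**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (o @ q) / (on * qn)
    return r


def coexpressed_set(
    query_id: str,
    atlas: pd.DataFrame,
    r_min: float = 0.85,
    log2p1: bool = False,
) -> list[CoexpressionRecord]:
    """All genes correlating with the query at r >= ``r_min``.

    Correlations are computed on raw abundances by default (``log2p1``
    switches to log2(x+1)). Zero-variance partner rows are skipped with a
    warning; a zero-variance query is an error. Records are sorted by r
    descending, then partner id.
    """
    if query_id not in atlas.index:
        raise KeyError(f"query {query_id!r} absent from matrix")
    if atlas.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation screening")
    values = atlas.to_numpy(dtype=float)
    if log2p1:
        values = np.log2(values + 1.0)
    qpos = atlas.index.get_loc(query_id)
    query = values[qpos]
    if np.std(query) == 0:
        raise ValueError(f"query {query_id!r} has zero variance")
    r = pearson_rows(query, values)
    records = []
    for gene, ri in zip(atlas.index, r):
        if gene == query_id:
            continue
        if np.isnan(ri):
            logger.warning("skipping zero-variance partner row %s", gene)
            continue
        if ri >= r_min:
            records.append(CoexpressionRecord(query_id, gene, float(ri)))
    records.sort(key=lambda rec: (-rec.r, rec.partner_id))
    return records


def count_target_categories(
    records: Sequence[CoexpressionRecord], ann: CategoryAnnotation
) -> tuple[list[CoexpressionRecord], CategoryCounts]:
    """Fill categories from the annotation and count target-category partners.

    The total counts only partners in the three target categories; "other"
    is excluded. Note flags are aggregated over the partner list (any
    toolbox partner, any laccase partner, ...).
    """
    filled = [replace(rec, category=ann[rec.partner_id].category) for rec in records]
    per_category = {c: 0 for c in TARGET_CATEGORIES + (OTHER,)}
    flags = {
        "has_toolbox": False,
        "has_laccase": False,
        "has_class3_peroxidase": False,
        "has_nac": False,
        "has_hcaldh": False,
    }
    for rec in filled:
        per_category[rec.category] += 1
        a = ann[rec.partner_id]
        flags["has_toolbox"] |= a.is_toolbox
        flags["has_laccase"] |= a.is_laccase
        flags["has_class3_peroxidase"] |= a.is_class3_peroxidase
        flags["has_nac"] |= a.is_nac
        flags["has_hcaldh"] |= a.is_hcaldh
    total = sum(per_category[c] for c in TARGET_CATEGORIES)
    return filled, CategoryCounts(per_category=per_category, total_targets=total, flags=flags)


def shortlist_candidates(
    candidates: Sequence[str],
    atlas: pd.DataFrame,
    ann: CategoryAnnotation,
    r_min: float = 0.85,
    min_targets: int = 11,
    log2p1: bool = False,
) -> pd.DataFrame:
    """Rank candidates by their count of target-category co-expressed genes.

    Returns one row per candidate with per-category counts, aggregated note
    flags and ``passed`` = (total targets >= ``min_targets``), sorted by
    total descending then candidate id.
    """
    rows = []
    for cand in candidates:
        records = coexpressed_set(cand, atlas, r_min=r_min, log2p1=log2p1)
        _, counts = count_target_categories(records, ann)
        row = {
            "gene_id": cand,
            "n_coexpressed": len(records),
            "n_targets": counts.total_targets,
            **{c: counts.per_category[c] for c in TARGET_CATEGORIES},
            **counts.flags,
            "passed": counts.total_targets >= min_targets,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["n_targets", "gene_id"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return df


def load_printed_coexpression() -> pd.DataFrame:
    """Packaged fixture of the published co-expression lists.

    Columns: query_name, query_accession, partner_accession, annotation,
    category, note, r — one row per printed partner of SvMYB24 and SvMYB74.
    """
    path = importlib.resources.files("mybfunnel.data").joinpath(PRINTED_LISTS_RESOURCE)
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    df["r"] = df["r"].astype(float)
    return df


def printed_records(query_name: str) -> list[CoexpressionRecord]:
    """The printed partner list of one query as CoexpressionRecord objects."""
    df = load_printed_coexpression()
    sub = df[df["query_name"] == query_name]
    if sub.empty:
        raise KeyError(f"no printed co-expression list for {query_name!r}")
    return [
        CoexpressionRecord(
            query_id=row["query_accession"],
            partner_id=row["partner_accession"],
            r=float(row["r"]),
            category=row["category"],
            note=row["note"],
        )
        for _, row in sub.iterrows()
    ]


def printed_annotation() -> CategoryAnnotation:
    """CategoryAnnotation derived from the packaged printed lists."""
    df = load_printed_coexpression()
    entries: dict[str, GeneAnnotation] = {}
    for _, row in df.iterrows():
        ann_text = row["annotation"].lower()
        note = row["note"].lower()
        entries[row["partner_accession"]] = GeneAnnotation(
            category=row["category"],
            is_toolbox="lignin toolbox" in note,
            is_laccase="laccase" in ann_text,
            is_class3_peroxidase="class iii peroxidase" in ann_text,
            is_nac="nac domain" in ann_text,
            is_hcaldh="hcaldh" in note or "hydroxycinnamaldehyde" in ann_text,
        )
    return CategoryAnnotation(entries)
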