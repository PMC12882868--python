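"""Genomic naming, chromosome distribution and tandem-duplication detection.

Family members are named ``<prefix>1 .. <prefix>N`` following their physical
order in the genome: chromosomes in natural-sort order (chr2 before chr10,
scaffolds after chromosomes), genes by ascending start within a chromosome.
Tandem duplicates are family genes lying within a fixed physical distance of
one another (default 50 kb, measured between the closest gene edges) on the
same chromosome; the relation is chained transitively, so a tandem cluster is
a connected component of the within-50-kb graph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class GeneModel:
    """One gene locus; coordinates are 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"{self.gene_id}: empty chromosome")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class TandemCluster:
    chromosome: str
    members: tuple[str, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a tandem cluster needs >= 2 members")
        if len(self.gaps) != len(self.members) - 1:
            raise ValueError("need one gap per consecutive member pair")


def natural_chromosome_key(name: str) -> tuple:
    """Sort key: chromosomes numerically (chr2 < chr10), scaffolds last."""
    m = re.fullmatch(r"(?:chr|chromosome[_ ]?)(\d+)", name, flags=re.IGNORECASE)
    if m:
        return (0, int(m.group(1)), name)
    # names with trailing digits still sort numerically within their prefix
    m2 = re.fullmatch(r"(\D*?)(\d+)", name)
    if m2:
        return (1, m2.group(1).lower(), int(m2.group(2)), name)
    return (2, name.lower(), 0, name)


def assign_family_names(
    family_ids: Sequence[str],
    models: Iterable[GeneModel],
    prefix: str = "SvMYB",
) -> tuple[dict[str, str], dict[str, int]]:
    """Name family genes by genomic order; also count members per chromosome.

    Returns (gene_id -> name, chromosome -> count). Every family id must have
    a gene model; duplicate ids are rejected.
    """
    by_id: dict[str, GeneModel] = {}
    for m in models:
        if m.gene_id in by_id:
            raise ValueError(f"duplicate gene model for {m.gene_id}")
        by_id[m.gene_id] = m
    if len(set(family_ids)) != len(list(family_ids)):
        raise ValueError("duplicate family ids")
    missing = [g for g in family_ids if g not in by_id]
    if missing:
        raise ValueError(f"family ids without coordinates: {missing}")

    ordered = sorted(
        family_ids,
        key=lambda g: (
            natural_chromosome_key(by_id[g].chromosome),
            by_id[g].start,
            by_id[g].end,
            g,
        ),
    )
    names = {g: f"{prefix}{i}" for i, g in enumerate(ordered, start=1)}
    counts: dict[str, int] = {}
    for g in ordered:
        counts[by_id[g].chromosome] = counts.get(by_id[g].chromosome, 0) + 1
    return names, counts


def edge_gap(a: GeneModel, b: GeneModel) -> int:
    """Distance in bp between the closest edges of two genes (0 if overlapping)."""
    if a.chromosome != b.chromosome:
        raise ValueError("genes on different chromosomes have no gap")
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end)


def detect_tandem_clusters(
    family_models: Iterable[GeneModel],
    max_gap_bp: int = 50_000,
) -> tuple[list[TandemCluster], int, float]:
    """Connected components of the <=``max_gap_bp`` proximity graph.

    Two family genes are linked iff they lie on the same chromosome with an
    inter-gene edge gap of at most ``max_gap_bp`` (inclusive). Returns
    (clusters, number of tandem genes, tandem fraction of the family).
    Because genes within a chromosome are processed in coordinate order,
    chaining A-B and B-C links A and C even when their direct gap exceeds
    the window.
    """
    if max_gap_bp <= 0:
        raise ValueError("max_gap_bp must be positive")
    models = list(family_models)
    seen: dict[str, GeneModel] = {}
    for m in models:
        prev = seen.get(m.gene_id)
        if prev is not None and prev != m:
            raise ValueError(f"conflicting duplicate coordinates for {m.gene_id}")
        seen[m.gene_id] = m
    models = list(seen.values())

    clusters: list[TandemCluster] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom in sorted(by_chrom, key=natural_chromosome_key):
        genes = sorted(by_chrom[chrom], key=lambda m: (m.start, m.end, m.gene_id))
        # union-find over all within-chromosome pairs: the tandem relation is
        # symmetric and chained transitively into connected components
        parent = list(range(len(genes)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if edge_gap(genes[i], genes[j]) <= max_gap_bp:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        components: dict[int, list[GeneModel]] = {}
        for i, g in enumerate(genes):
            components.setdefault(find(i), []).append(g)
        for root in sorted(components, key=lambda r: components[r][0].start):
            group = components[root]
            if len(group) < 2:
                continue
            clusters.append(
                TandemCluster(
                    chromosome=chrom,
                    members=tuple(g.gene_id for g in group),
                    gaps=tuple(edge_gap(a, b) for a, b in zip(group, group[1:])),
                )
            )

    n_tandem = sum(len(c.members) for c in clusters)
    fraction = n_tandem / len(models) if models else 0.0
    return clusters, n_tandem, fraction


def chromosome_distribution_table(counts: dict[str, int]) -> pd.DataFrame:
    chroms = sorted(counts, key=natural_chromosome_key)
    return pd.DataFrame(
        {"chromosome": chroms, "n_family_genes": [counts[c] for c in chroms]}
    )
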