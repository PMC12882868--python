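"""Subgroup classification of family members on a distance tree.

The family's evolutionary structure is summarized by aligning the member
proteins together with reference sequences carrying published subgroup
labels, trimming gappy alignment columns, building a neighbor-joining tree
on p-distances, and transferring to each unlabeled member the majority label
of the smallest sufficiently supported clade that contains it together with
at least one reference.

The multiple alignment is a center-star construction (the sequence with the
highest summed pairwise global-alignment score is the star center; pairwise
alignments against the center are merged under "once a gap, always a gap").
Distances are p-distances: the fraction of mismatching residues over columns
where both sequences are ungapped. The tree is Saitou-Nei neighbor joining
with negative branch lengths clamped to zero; branch support comes from
bootstrap resampling of alignment columns.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .repeat_scan import ProteinRecord

GAP = "-"


@dataclass
class Alignment:
    """A gapped multiple alignment; all rows have equal length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def column_gap_fractions(self) -> np.ndarray:
        mat = np.array([list(s) for s in self.rows.values()])
        return (mat == GAP).mean(axis=0)


@dataclass(frozen=True)
class SubgroupAssignment:
    query_id: str
    subgroup: str
    support: float | None
    clade_size: int


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def build_msa(
    sequences: Sequence[ProteinRecord],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    max_exact_center: int = 80,
) -> Alignment:
    """Center-star multiple alignment.

    The center is the sequence maximizing the summed pairwise global-alignment
    score against all others (ties: first in input order). For inputs larger
    than ``max_exact_center`` the quadratic center search is replaced by
    choosing the longest sequence, which keeps the construction O(n) pairwise
    alignments; the merge step is unchanged.
    """
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    if len({s.id for s in seqs}) != len(seqs):
        raise ValueError("duplicate sequence ids")
    aligner = _make_aligner(match, mismatch, gap)

    if len(seqs) <= max_exact_center:
        totals = np.zeros(len(seqs))
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                s = aligner.score(seqs[i].sequence, seqs[j].sequence)
                totals[i] += s
                totals[j] += s
        center_idx = int(np.argmax(totals))  # argmax takes the first maximum
    else:
        center_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i].sequence), -i))

    center = seqs[center_idx]
    master: list[str] = list(center.sequence)
    rows: dict[str, list[str]] = {center.id: master}

    for rec in seqs:
        if rec.id == center.id:
            continue
        aln = aligner.align(center.sequence, rec.sequence)[0]
        c_aln, s_aln = str(aln[0]), str(aln[1])
        new_row: list[str] = []
        i = 0  # position in master (accumulated center row)
        j = 0  # position in the fresh pairwise alignment
        while i < len(master) or j < len(c_aln):
            mc = master[i] if i < len(master) else None
            cc = c_aln[j] if j < len(c_aln) else None
            if mc == GAP:
                # column inserted by an earlier merge: once a gap, always a gap
                new_row.append(GAP)
                i += 1
            elif cc == GAP or mc is None:
                # the new sequence inserts relative to the center: open a new
                # column in every existing row
                for row in rows.values():
                    row.insert(i, GAP)
                new_row.append(s_aln[j])
                i += 1
                j += 1
            else:
                new_row.append(s_aln[j])
                i += 1
                j += 1
        rows[rec.id] = new_row

    # restore input order
    ordered = {rec.id: "".join(rows[rec.id]) for rec in seqs}
    return Alignment(rows=ordered)


def trim_alignment(
    aln: Alignment, gap_threshold: float = 0.5, min_conserve: float = 0.10
) -> Alignment:
    """Drop columns whose gap fraction exceeds ``gap_threshold``.

    If fewer than ``min_conserve`` of the original columns would survive, the
    ceil(min_conserve * n_columns) columns with the lowest gap fraction are
    retained instead (ties resolved leftmost). Idempotent whenever the floor
    is not triggered.
    """
    if not (0 < gap_threshold <= 1):
        raise ValueError("gap_threshold must be in (0, 1]")
    if not (0 < min_conserve <= 1):
        raise ValueError("min_conserve must be in (0, 1]")
    frac = aln.column_gap_fractions()
    keep = np.nonzero(frac <= gap_threshold)[0]
    floor = int(np.ceil(min_conserve * aln.n_columns))
    if keep.size < floor:
        keep = np.argsort(frac, kind="stable")[:floor]
        keep = np.sort(keep)
    rows = {k: "".join(np.array(list(v))[keep]) for k, v in aln.rows.items()}
    return Alignment(rows=rows)


def _encoded_rows(aln: Alignment) -> tuple[list[str], np.ndarray]:
    ids = aln.ids
    mat = np.array([list(aln.rows[i]) for i in ids])
    codes = np.full(mat.shape, -1, dtype=np.int16)
    residues = np.unique(mat)
    for k, r in enumerate(residues):
        if r != GAP:
            codes[mat == r] = k
    return ids, codes


def p_distance_matrix(
    aln: Alignment, columns: np.ndarray | None = None
) -> DistanceMatrix:
    """Pairwise p-distances (mismatches over shared ungapped columns).

    ``columns`` optionally selects (possibly repeated) column indices, which
    is how bootstrap replicates are scored. A pair with no comparable columns
    is an error.
    """
    ids, codes = _encoded_rows(aln)
    if columns is not None:
        codes = codes[:, columns]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (codes[i] >= 0) & (codes[j] >= 0)
            total = int(valid.sum())
            if total == 0:
                raise ValueError(
                    f"sequences {ids[i]!r} and {ids[j]!r} share no ungapped columns"
                )
            d[i, j] = d[j, i] = float((codes[i][valid] != codes[j][valid]).mean())
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei NJ with negative branch lengths clamped to zero."""
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return nj(dm)


def nj_tree(aln: Alignment) -> TreeNode:
    """Neighbor-joining tree on the alignment's p-distance matrix."""
    if len(aln.rows) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    return neighbor_joining(p_distance_matrix(aln))


def _bipartitions(tree: TreeNode, tip_set: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (unrooted) tree, canonicalized to the
    smaller side (ties: lexicographically smaller side)."""
    splits: set[frozenset[str]] = set()
    n = len(tip_set)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= n - 1:
            continue
        other = tip_set - side
        if len(side) < len(other) or (
            len(side) == len(other) and sorted(side) < sorted(other)
        ):
            splits.add(side)
        else:
            splits.add(frozenset(other))
    return splits


def bootstrap_support(
    aln: Alignment, n_replicates: int, seed: int
) -> TreeNode:
    """Point-estimate NJ tree with bootstrap support on internal nodes.

    Columns are resampled with replacement; each internal split's support is
    the percentage of replicate trees containing that split. Supports are
    stored on ``node.support`` and mirrored into internal node names so they
    survive newick round trips.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(aln)
    tip_set = frozenset(aln.ids)
    rng = np.random.default_rng(seed)
    counts: collections.Counter[frozenset[str]] = collections.Counter()
    n_cols = aln.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, n_cols)
        rep_tree = neighbor_joining(p_distance_matrix(aln, columns=cols))
        counts.update(_bipartitions(rep_tree, tip_set))

    n = len(tip_set)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= n - 1:
            continue
        other = tip_set - side
        canon = side
        if not (
            len(side) < len(other)
            or (len(side) == len(other) and sorted(side) < sorted(other))
        ):
            canon = frozenset(other)
        support = 100.0 * counts[canon] / n_replicates
        node.support = support
        node.name = f"{support:g}"
    return tree


def _node_support(node: TreeNode) -> float | None:
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.name:
        try:
            return float(node.name)
        except ValueError:
            return None
    return None


def _rooted_for_clades(tree: TreeNode) -> TreeNode:
    work = tree.copy()
    try:
        return work.root_at_midpoint()
    except Exception:
        # zero-length or degenerate trees cannot be midpoint rooted; clade
        # queries then operate on the tree as given
        return work


def assign_subgroups(
    tree: TreeNode,
    reference_labels: Mapping[str, str],
    min_support: float = 50.0,
    query_ids: Iterable[str] | None = None,
) -> list[SubgroupAssignment]:
    """Transfer subgroup labels from reference leaves to query leaves.

    For each query, ascend from the leaf on the midpoint-rooted tree until a
    clade is found that contains at least one reference and whose support is
    at least ``min_support`` (nodes without a support value qualify). The
    majority reference label in that clade is assigned; a tied majority or
    the absence of any qualifying clade yields "unclassified".
    """
    if not reference_labels:
        raise ValueError("need at least one labeled reference leaf")
    rooted = _rooted_for_clades(tree)
    tips = {t.name: t for t in rooted.tips()}
    for ref in reference_labels:
        if ref not in tips:
            raise KeyError(f"reference leaf {ref!r} absent from tree")
    if query_ids is None:
        queries = [t for t in tips if t not in reference_labels]
    else:
        queries = list(query_ids)
        missing = [q for q in queries if q not in tips]
        if missing:
            raise KeyError(f"query leaves absent from tree: {missing}")

    out: list[SubgroupAssignment] = []
    for q in queries:
        node = tips[q]
        assigned = SubgroupAssignment(q, "unclassified", None, 0)
        for anc in node.ancestors():
            clade_tips = [t.name for t in anc.tips()]
            labels = [reference_labels[t] for t in clade_tips if t in reference_labels]
            if not labels:
                continue
            sup = _node_support(anc)
            if sup is not None and sup < min_support:
                continue
            tally = collections.Counter(labels).most_common()
            top_label, top_n = tally[0]
            if len(tally) > 1 and tally[1][1] == top_n:
                assigned = SubgroupAssignment(q, "unclassified", sup, len(clade_tips))
            else:
                assigned = SubgroupAssignment(q, top_label, sup, len(clade_tips))
            break
        out.append(assigned)
    return out


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
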