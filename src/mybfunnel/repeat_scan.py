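"""R2R3-MYB family identification by MYB-repeat scanning.

Plant R2R3-MYB transcription factors carry two adjacent ~52-residue MYB
DNA-binding repeats (R2 and R3) near the N terminus, followed by a variable
C-terminal region. Family membership is decided here by scoring every window
of each protein against a position-specific scoring matrix (PSSM) built from
a bundled seed alignment of MYB repeats, resolving the significant windows
into non-overlapping repeat hits, and keeping proteins whose hit architecture
is exactly two N-terminal repeats. Proteins with a single repeat (MYB-related)
or three and more repeats (R1R2R3 / 3R-MYBs) are excluded.

The PSSM is a log-odds model: score(column, residue) =
log2(((count + pseudocount * bg) / (n_rows + pseudocount)) / bg), i.e. the
observed residue frequency with background-proportional pseudocounts relative
to the background frequency, in bits. Unknown residues (X) score 0 in every
column. A window counts as a repeat hit when its summed score reaches a
threshold expressed as a fraction of the maximum achievable window score.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
UNIFORM_BACKGROUND = {a: 1.0 / 20.0 for a in AMINO_ACIDS}

SEED_ALIGNMENT_RESOURCE = "myb_repeat_seed.synthetic.fasta"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; residues are the 20 standard amino acids plus X."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence.upper()) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class RepeatHit:
    """One repeat instance: [start, end) residue window with its bit score."""

    start: int
    end: int
    score: float


class ArchitectureLabel(str, Enum):
    NONE = "NONE"
    ONE_R = "ONE_R"
    R2R3 = "R2R3"
    THREE_R_PLUS = "THREE_R_PLUS"


@dataclass(frozen=True)
class Architecture:
    label: ArchitectureLabel
    hits: tuple[RepeatHit, ...]


@dataclass
class RepeatPSSM:
    """Log-odds scoring matrix for one MYB repeat.

    ``scores`` is a (width x 21) array over AMINO_ACIDS + X in that order;
    the X column is all zeros (ambiguity is scored neutrally).
    """

    width: int
    scores: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("PSSM width must be positive")
        if self.scores.shape != (self.width, 21):
            raise ValueError("scores must have shape (width, 21)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PSSM scores must be finite")

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    def score_window(self, window: str) -> float:
        idx = encode_sequence(window)
        return float(self.scores[np.arange(self.width), idx].sum())


def encode_sequence(seq: str) -> np.ndarray:
    """Map residues to integer codes 0..19, with X (and only X) mapped to 20."""
    return np.array([_AA_INDEX.get(c, 20) for c in seq.upper()], dtype=np.intp)


def load_seed_alignment() -> dict[str, str]:
    """Bundled synthetic seed alignment of MYB repeats (8 rows, 52 columns).

    A constructed stand-in for a curated repeat-family alignment: rows are
    variations around the canonical plant MYB repeat consensus
    (W...W...W tryptophan scaffold with the conserved CGKSCRLRW core).
    """
    text = (
        importlib.resources.files("mybfunnel.data")
        .joinpath(SEED_ALIGNMENT_RESOURCE)
        .read_text()
    )
    rows: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            rows[name] = ""
        else:
            rows[name] += line
    return rows


def build_repeat_pssm(
    seed_alignment: Mapping[str, str] | Sequence[str],
    pseudocount: float = 1.0,
    background: Mapping[str, float] | None = None,
    threshold_fraction: float = 0.45,
) -> RepeatPSSM:
    """Build a log-odds PSSM from an ungapped block of aligned repeats.

    The threshold defaults to ``threshold_fraction`` times the maximum
    achievable window score.
    """
    rows = list(seed_alignment.values()) if isinstance(seed_alignment, Mapping) else list(seed_alignment)
    if not rows:
        raise ValueError("seed alignment is empty")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged seed alignment: rows differ in length")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = dict(background) if background is not None else dict(UNIFORM_BACKGROUND)
    if any(bg.get(a, 0.0) <= 0 for a in AMINO_ACIDS):
        raise ValueError("background must assign positive frequency to all residues")
    total_bg = sum(bg[a] for a in AMINO_ACIDS)
    if not np.isclose(total_bg, 1.0, atol=1e-6):
        raise ValueError(f"background frequencies sum to {total_bg}, expected 1")

    n = len(rows)
    scores = np.zeros((width, 21))
    for j in range(width):
        column = [r[j].upper() for r in rows]
        for a in AMINO_ACIDS:
            count = column.count(a)
            freq = (count + pseudocount * bg[a]) / (n + pseudocount)
            scores[j, _AA_INDEX[a]] = np.log2(freq / bg[a])
    pssm = RepeatPSSM(width=width, scores=scores, threshold=0.0)
    pssm.threshold = threshold_fraction * pssm.max_score
    return pssm


def _window_scores(encoded: np.ndarray, pssm: RepeatPSSM) -> np.ndarray:
    """Scores of all length-``width`` windows, vectorized over start positions."""
    n = encoded.size - pssm.width + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, pssm.width)
    return pssm.scores[np.arange(pssm.width), windows].sum(axis=1)


def scan_repeats(protein: ProteinRecord, pssm: RepeatPSSM) -> list[RepeatHit]:
    """All non-overlapping repeat hits in ``protein``, sorted by start.

    Every window scoring at or above the PSSM threshold is a candidate;
    candidates are resolved greedily in descending score order (ties: the
    leftmost window wins), discarding windows that overlap an accepted hit.
    A sequence shorter than the PSSM width has no windows and yields [].
    """
    encoded = encode_sequence(protein.sequence)
    scores = _window_scores(encoded, pssm)
    starts = np.nonzero(scores >= pssm.threshold)[0]
    if starts.size == 0:
        return []
    # sort by (-score, start): greedy best-first with leftmost tie-break
    order = sorted(starts, key=lambda s: (-scores[s], s))
    accepted: list[int] = []
    for s in order:
        if all(s + pssm.width <= a or s >= a + pssm.width for a in accepted):
            accepted.append(s)
    return [
        RepeatHit(start=int(s), end=int(s + pssm.width), score=float(scores[s]))
        for s in sorted(accepted)
    ]


def classify_architecture(
    hits: Sequence[RepeatHit],
    protein_length: int,
    nterm_limit: int = 200,
    max_inter_repeat_gap: int = 30,
) -> Architecture:
    """Label a hit list as NONE / ONE_R / R2R3 / THREE_R_PLUS.

    R2R3 requires exactly two hits, both starting within the N-terminal
    window, separated by at most ``max_inter_repeat_gap`` residues.
    """
    hits = tuple(hits)
    for a, b in zip(hits, hits[1:]):
        if b.start < a.start:
            raise ValueError("hits must be sorted by start")
        if b.start < a.end:
            raise ValueError("hits must be non-overlapping")
    if len(hits) == 0:
        label = ArchitectureLabel.NONE
    elif len(hits) == 1:
        label = ArchitectureLabel.ONE_R
    elif len(hits) == 2:
        first, second = hits
        gap = second.start - first.end
        nterm_ok = first.start < nterm_limit and second.start < nterm_limit
        if nterm_ok and gap <= max_inter_repeat_gap:
            label = ArchitectureLabel.R2R3
        else:
            # two repeats violating the N-terminal/spacing rule are not a
            # typical R2R3 architecture; excluded like repeat-free proteins
            label = ArchitectureLabel.NONE
    else:
        label = ArchitectureLabel.THREE_R_PLUS
    return Architecture(label=label, hits=hits)


def identify_family(
    proteome: Iterable[ProteinRecord],
    pssm: RepeatPSSM,
    nterm_limit: int = 200,
    max_inter_repeat_gap: int = 30,
) -> pd.DataFrame:
    """Scan a proteome and return the table of R2R3 family members.

    Columns: protein_id, n_hits, hit1_start, hit1_end, hit2_start, hit2_end,
    label. Order follows the input proteome order. Duplicate protein ids are
    an error.
    """
    proteome = list(proteome)
    if not proteome:
        raise ValueError("empty proteome")
    seen: set[str] = set()
    rows = []
    for rec in proteome:
        if rec.id in seen:
            raise ValueError(f"duplicate protein id: {rec.id}")
        seen.add(rec.id)
        hits = scan_repeats(rec, pssm)
        arch = classify_architecture(
            hits, len(rec.sequence), nterm_limit, max_inter_repeat_gap
        )
        if arch.label is ArchitectureLabel.R2R3:
            h1, h2 = arch.hits
            rows.append(
                {
                    "protein_id": rec.id,
                    "n_hits": 2,
                    "hit1_start": h1.start,
                    "hit1_end": h1.end,
                    "hit2_start": h2.start,
                    "hit2_end": h2.end,
                    "label": arch.label.value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "n_hits",
            "hit1_start",
            "hit1_end",
            "hit2_start",
            "hit2_end",
            "label",
        ],
    )
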