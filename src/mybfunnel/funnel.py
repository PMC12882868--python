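"""The candidate funnel: intersect all screening stages into a final verdict.

Stages run in the published order — family membership, atlas co-clustering
with the lignin toolbox, internode-zone profiling, co-expression shortlist,
preferential expression in the lignifying tissue — and a gene is a final
candidate only if it survives every evaluated stage. A gene lacking data at
a stage (e.g. absent from the internode matrix) fails that stage and is
listed in the diagnostics; a stage given ``None`` was not evaluated and does
not constrain the verdict (it is reported as such rather than as a pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .config import PipelineConfig

STAGES = (
    "in_family",
    "atlas_cocluster",
    "internode_pass",
    "shortlist_pass",
    "preferential_pass",
)


@dataclass
class CandidateReport:
    gene_id: str
    family_name: str | None
    subgroup: str | None
    flags: dict[str, bool | None]
    final_candidate: bool

    def __post_init__(self) -> None:
        evaluated = [v for v in self.flags.values() if v is not None]
        if self.final_candidate != all(evaluated):
            raise ValueError("final_candidate must equal the conjunction of evaluated stages")


@dataclass
class FunnelResult:
    reports: list[CandidateReport]
    summary: dict[str, int]
    diagnostics: dict[str, list[str]] = field(default_factory=dict)
    config: PipelineConfig | None = None

    def final_candidates(self) -> list[str]:
        return [r.gene_id for r in self.reports if r.final_candidate]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "family_name": r.family_name or "",
                    "subgroup": r.subgroup or "",
                    **{
                        s: ("NA" if v is None else bool(v))
                        for s, v in r.flags.items()
                    },
                    "final_candidate": r.final_candidate,
                }
            )
        return pd.DataFrame(rows)


def run_funnel(
    family_ids: Iterable[str],
    atlas_candidates: Iterable[str] | None,
    internode_candidates: Iterable[str] | None,
    shortlist_pass: Iterable[str] | None,
    preferential_verdicts: Mapping[str, bool] | None,
    subgroups: Mapping[str, str] | None = None,
    family_names: Mapping[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> FunnelResult:
    """Intersect the per-stage survivor sets over the family gene universe.

    Stage flags are monotone along the pipeline: a gene that failed an
    earlier evaluated stage cannot pass a later one. ``None`` marks a stage
    as not evaluated. The summary reports the survivor count after each
    evaluated stage.
    """
    family_list = list(family_ids)
    family = list(dict.fromkeys(family_list))
    if len(family) != len(family_list):
        raise ValueError("duplicate ids in family table")
    stage_sets: dict[str, set[str] | None] = {
        "atlas_cocluster": None if atlas_candidates is None else set(atlas_candidates),
        "internode_pass": None if internode_candidates is None else set(internode_candidates),
        "shortlist_pass": None if shortlist_pass is None else set(shortlist_pass),
        "preferential_pass": None
        if preferential_verdicts is None
        else {g for g, v in preferential_verdicts.items() if v},
    }

    diagnostics: dict[str, list[str]] = {}
    reports: list[CandidateReport] = []
    surviving = set(family)
    summary = {"in_family": len(family)}
    per_gene_flags: dict[str, dict[str, bool | None]] = {
        g: {"in_family": True} for g in family
    }
    for stage in STAGES[1:]:
        sset = stage_sets[stage]
        if sset is None:
            for g in family:
                per_gene_flags[g][stage] = None
            continue
        missing = sorted(g for g in surviving if g not in sset)
        if missing and stage in ("internode_pass", "preferential_pass"):
            diagnostics.setdefault(f"no_data_or_failed_{stage}", missing)
        surviving = surviving & sset
        for g in family:
            earlier = [v for v in per_gene_flags[g].values() if v is not None]
            per_gene_flags[g][stage] = bool(g in sset and all(earlier))
        summary[stage] = len(surviving)

    for g in family:
        flags = per_gene_flags[g]
        evaluated = [v for v in flags.values() if v is not None]
        reports.append(
            CandidateReport(
                gene_id=g,
                family_name=(family_names or {}).get(g),
                subgroup=(subgroups or {}).get(g),
                flags=flags,
                final_candidate=all(evaluated),
            )
        )
    return FunnelResult(
        reports=reports, summary=summary, diagnostics=diagnostics, config=config
    )
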