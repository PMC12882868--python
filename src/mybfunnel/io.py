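"""Readers, writers, run manifest and the end-to-end pipeline driver.

External formats: FASTA (proteomes), GFF3 (gene models, 1-based inclusive
coordinates; internal bookkeeping stays 1-based since only distances are
computed), TSV (expression matrices with gene ids in the first column and
sample ids in the header; Ct and luciferase tables; annotation tables),
newick (trees) and JSON (truth tables, reports, manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .config import PipelineConfig
from .coexpr import CategoryAnnotation, GeneAnnotation, shortlist_candidates
from .expr_cluster import (
    INTERNODE_ZONES,
    cluster_rows,
    internode_stage,
    select_cocluster_candidates,
    unit_variance_scale,
    validate_expression_matrix,
)
from .funnel import FunnelResult, run_funnel
from .genome_map import GeneModel, chromosome_distribution_table, detect_tandem_clusters, assign_family_names
from .phylo import assign_subgroups, bootstrap_support, build_msa, trim_alignment, write_newick
from .repeat_scan import ProteinRecord, build_repeat_pssm, identify_family, load_seed_alignment
from .synthetic import SyntheticFamilyGenome, SyntheticStudy, TruthEntry, TruthTable
from .validation import preferential_call, relative_expression, transactivation_fold

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record without an id")
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------- GFF3

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Gene records (type == gene) from a GFF3 file; requires ID attributes."""
    models = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise ValueError(f"{path}: missing ##gff-version header")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr_map:
                raise ValueError(f"{path}:{ln}: gene record without ID attribute")
            s, e = int(start), int(end)
            if s == e:
                logger.info("%s:%d: zero-length gene %s accepted as 1 bp", path, ln, attr_map["ID"])
            models.append(
                GeneModel(
                    gene_id=attr_map["ID"],
                    chromosome=chrom,
                    start=s,
                    end=e,
                    strand=strand if strand in "+-" else "+",
                )
            )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chromosome}\tmybfunnel\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )


# ---------------------------------------------------------------- TSV

def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Expression matrix: first column gene ids, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value at row {bad[0]!r}, column {col!r}"
            )
        if converted.isna().any():
            raise ValueError(
                f"{path}: missing value at row {df.index[converted.isna()][0]!r}, column {col!r}"
            )
        df[col] = converted
    validate_expression_matrix(df)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def read_table_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = read_table_tsv(path, ("gene", "tissue", "replicate", "ct"))
    df["ct"] = pd.to_numeric(df["ct"])
    return df


def read_luciferase_table(path: str | Path) -> pd.DataFrame:
    df = read_table_tsv(path, ("effector", "replicate", "fluc", "rluc"))
    df["fluc"] = pd.to_numeric(df["fluc"])
    df["rluc"] = pd.to_numeric(df["rluc"])
    return df


def read_annotation(path: str | Path) -> CategoryAnnotation:
    df = read_table_tsv(path, ("gene_id", "category"))
    return CategoryAnnotation.from_frame(df)


def read_reference_labels(path: str | Path) -> dict[str, str]:
    df = read_table_tsv(path, ("id", "subgroup"))
    return dict(zip(df["id"].astype(str), df["subgroup"].astype(str)))


def read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_id_list(ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in ids:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------- truth JSON

def write_truth(truth: TruthTable, path: str | Path) -> None:
    payload = [
        {
            "entity_id": e.entity_id,
            "roles": list(e.roles),
            "planted_cluster": e.planted_cluster,
            "planted_params": e.planted_params,
        }
        for e in truth.entries.values()
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> TruthTable:
    payload = json.loads(Path(path).read_text())
    truth = TruthTable()
    for e in payload:
        truth.add(
            TruthEntry(
                entity_id=e["entity_id"],
                roles=tuple(e["roles"]),
                planted_cluster=e["planted_cluster"],
                planted_params=e["planted_params"],
            )
        )
    return truth


def write_synthetic_genome(genome: SyntheticFamilyGenome, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": out / "proteome.fasta",
        "gff3": out / "genes.gff3",
        "truth": out / "genome_truth.json",
    }
    write_fasta(genome.proteins, paths["proteome"])
    write_gff3(genome.models, paths["gff3"])
    write_truth(genome.truth, paths["truth"])
    return paths


def write_study(study: SyntheticStudy, out_dir: str | Path, seed: int = 0) -> Path:
    """Write a complete synthetic study plus a ready-to-run config.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_synthetic_genome(study.genome, out)
    write_matrix_tsv(study.expression.atlas, out / "atlas.tsv")
    write_matrix_tsv(study.expression.internode, out / "internode.tsv")
    write_truth(study.expression.truth, out / "expression_truth.json")
    write_id_list(study.toolbox, out / "toolbox.txt")
    rows = []
    for e in study.expression.truth.entries.values():
        g = e.entity_id
        if g in study.annotation:
            a = study.annotation[g]
            rows.append(
                {"gene_id": g, "category": a.category, "is_toolbox": a.is_toolbox}
            )
    pd.DataFrame(rows).to_csv(out / "annotation.tsv", sep="\t", index=False)
    study.validation.ct.to_csv(out / "ct.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    study.validation.luciferase.to_csv(
        out / "luciferase.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    config = {
        "params": {"seed": seed},
        "paths": {
            "proteome": str(out / "proteome.fasta"),
            "gff3": str(out / "genes.gff3"),
            "atlas": str(out / "atlas.tsv"),
            "internode": str(out / "internode.tsv"),
            "toolbox": str(out / "toolbox.txt"),
            "annotation": str(out / "annotation.tsv"),
            "ct": str(out / "ct.tsv"),
            "luciferase": str(out / "luciferase.tsv"),
            "out_dir": str(out / "results"),
        },
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return config_path


# ---------------------------------------------------------------- manifest

@dataclass
class RunManifest:
    inputs: dict[str, dict[str, str]]
    config: dict
    version: str = __version__
    created: str = ""
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "inputs": self.inputs,
                "config": self.config,
                "version": self.version,
                "created": self.created,
                "warnings": self.warnings,
            },
            indent=1,
            sort_keys=True,
        )


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def build_manifest(paths: Mapping[str, str | Path], config: PipelineConfig) -> RunManifest:
    inputs = {
        name: {"path": str(p), "sha256": _checksum(p)}
        for name, p in sorted(paths.items())
        if p is not None and Path(p).exists()
    }
    return RunManifest(
        inputs=inputs,
        config=config.to_dict(),
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


# ---------------------------------------------------------------- pipeline

def load_config(path: str | Path) -> tuple[PipelineConfig, dict]:
    """Read a YAML config file; returns (parameters, input/output paths)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    params = raw.get("params", {})
    paths = raw.get("paths", {})
    config = PipelineConfig.from_dict(params)
    required = ("proteome", "gff3", "atlas", "internode", "toolbox", "out_dir")
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValueError(f"config lacks mandatory paths: {missing}")
    return config, paths


def run_pipeline(config: PipelineConfig, paths: Mapping[str, str | Path]) -> FunnelResult:
    """Execute identify -> map -> (subgroups) -> atlas -> internode ->
    co-expression shortlist -> (validation) -> funnel, writing all reports
    into ``paths['out_dir']``.

    Mandatory paths: proteome, gff3, atlas, internode, toolbox, out_dir.
    Optional: annotation (defaults to toolbox genes as lignin biosynthesis),
    reference_fasta + reference_labels (enables the subgroup stage), ct,
    luciferase (enable the validation stage), prefix (family name prefix).
    """
    out_dir = Path(paths["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = build_manifest(
        {k: v for k, v in paths.items() if k != "out_dir"}, config
    )

    # stage 1: family identification
    proteome = read_fasta(paths["proteome"])
    pssm = build_repeat_pssm(
        load_seed_alignment(), threshold_fraction=config.pssm_threshold_fraction
    )
    family = identify_family(
        proteome, pssm, config.nterm_limit, config.max_inter_repeat_gap
    )
    family_ids = list(family["protein_id"])
    family.to_csv(out_dir / "family.tsv", sep="\t", index=False)

    # stage 2: genomic naming and tandem detection
    models = read_gff3_genes(paths["gff3"])
    model_ids = {m.gene_id for m in models}
    absent = [g for g in family_ids if g not in model_ids]
    if absent:
        raise ValueError(f"family genes without GFF3 gene models: {absent}")
    names, chrom_counts = assign_family_names(
        family_ids, models, prefix=str(paths.get("prefix", "SvMYB"))
    )
    family_models = [m for m in models if m.gene_id in set(family_ids)]
    clusters, n_tandem, tandem_fraction = detect_tandem_clusters(
        family_models, config.tandem_gap_bp
    )
    pd.DataFrame(
        {"gene_id": list(names), "family_name": [names[g] for g in names]}
    ).to_csv(out_dir / "names.tsv", sep="\t", index=False)
    chromosome_distribution_table(chrom_counts).to_csv(
        out_dir / "chromosome_distribution.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "chromosome": c.chromosome,
                "members": ";".join(c.members),
                "gaps_bp": ";".join(str(g) for g in c.gaps),
            }
            for c in clusters
        ]
    ).to_csv(out_dir / "tandem_clusters.tsv", sep="\t", index=False)

    # stage 3 (optional): subgroup classification
    subgroups: dict[str, str] = {}
    if paths.get("reference_fasta") and paths.get("reference_labels"):
        refs = read_fasta(paths["reference_fasta"])
        labels = read_reference_labels(paths["reference_labels"])
        family_seqs = [p for p in proteome if p.id in set(family_ids)]
        aln = trim_alignment(
            build_msa(family_seqs + refs),
            config.gap_threshold,
            config.min_conserve,
        )
        tree = bootstrap_support(aln, config.n_bootstrap, seed=config.seed)
        write_newick(tree, out_dir / "family_tree.nwk")
        assignments = assign_subgroups(tree, labels, config.min_support)
        subgroups = {a.query_id: a.subgroup for a in assignments}
        pd.DataFrame(
            [
                {
                    "gene_id": a.query_id,
                    "subgroup": a.subgroup,
                    "support": a.support,
                    "clade_size": a.clade_size,
                }
                for a in assignments
            ]
        ).to_csv(out_dir / "subgroups.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    # stage 4: atlas co-clustering with the toolbox
    atlas = read_matrix_tsv(paths["atlas"])
    toolbox = read_id_list(paths["toolbox"])
    if not set(atlas.index) & set(family_ids):
        logger.warning("no family gene appears in the atlas matrix")
    scaled = unit_variance_scale(atlas)
    assignment = cluster_rows(
        scaled.data, config.k_atlas, config.distance, config.linkage
    )
    atlas_candidates, atlas_diag = select_cocluster_candidates(
        assignment, toolbox, family_ids
    )
    pd.DataFrame(
        {"gene_id": list(assignment.labels), "cluster": list(assignment.labels.values())}
    ).to_csv(out_dir / "atlas_clusters.tsv", sep="\t", index=False)
    write_id_list(sorted(atlas_candidates), out_dir / "atlas_candidates.txt")

    # stage 5: internode zones
    internode = read_matrix_tsv(paths["internode"])
    internode_candidates = internode_stage(
        internode,
        toolbox,
        mode=config.internode_mode,
        family_ids=family_ids,
        distance=config.distance,
        method=config.linkage,
    )
    write_id_list(sorted(internode_candidates), out_dir / "internode_candidates.txt")

    # stage 6: co-expression shortlist on survivors of both expression stages
    if paths.get("annotation"):
        ann = read_annotation(paths["annotation"])
    else:
        ann = CategoryAnnotation(
            {
                g: GeneAnnotation(category="lignin_biosynthesis", is_toolbox=True)
                for g in toolbox
            }
        )
    survivors = sorted((set(atlas_candidates) & set(internode_candidates)) & set(atlas.index))
    shortlist = shortlist_candidates(
        survivors, atlas, ann, config.r_min, config.min_targets, config.log2p1
    )
    shortlist.to_csv(out_dir / "shortlist.tsv", sep="\t", index=False)
    shortlist_ids = set(shortlist.loc[shortlist["passed"], "gene_id"]) if not shortlist.empty else set()

    # stage 7 (optional): validation statistics
    verdicts: dict[str, bool] | None = None
    if paths.get("ct"):
        ct = read_ct_table(paths["ct"])
        re_table = relative_expression(ct)
        calls = preferential_call(re_table, target_tissue="internode_top", alpha=config.alpha)
        verdicts = {c.gene: c.verdict for c in calls}
        pd.DataFrame(
            [
                {
                    "gene": c.gene,
                    "verdict": c.verdict,
                    "F": c.f_statistic,
                    "anova_p": c.anova_p,
                }
                for c in calls
            ]
        ).to_csv(out_dir / "preferential.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    if paths.get("luciferase"):
        luc = read_luciferase_table(paths["luciferase"])
        transactivation_fold(luc, welch=config.welch).to_csv(
            out_dir / "transactivation.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
        )

    result = run_funnel(
        family_ids,
        atlas_candidates,
        internode_candidates,
        shortlist_ids,
        verdicts,
        subgroups=subgroups or None,
        family_names=names,
        config=config,
    )
    result.diagnostics["atlas"] = [json.dumps(atlas_diag, sort_keys=True)]
    result.to_frame().to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    report = {
        "config": config.to_dict(),
        "summary": result.summary,
        "final_candidates": sorted(result.final_candidates()),
        "diagnostics": result.diagnostics,
        "stage_ids": {
            "family": family_ids,
            "atlas_cocluster": sorted(atlas_candidates),
            "internode_pass": sorted(internode_candidates),
            "shortlist_pass": sorted(shortlist_ids),
            "preferential_pass": sorted(
                [g for g, v in (verdicts or {}).items() if v]
            ),
        },
    }
    (out_dir / "funnel_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    return result
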