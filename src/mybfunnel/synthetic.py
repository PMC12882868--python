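"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study conditions of the screening pipeline:

* a proteome in which a known subset of proteins carries exactly two
  N-terminal MYB repeats (the family), alongside single-repeat, triple-repeat
  and repeat-free decoys, with gene models realizing requested tandem arrays;
* a broad expression atlas (default 39 samples, matching the tissue/condition
  atlas the screen runs on) with k planted co-expression clusters built from
  shared latent factors, one cluster holding the 14-gene lignin toolbox and
  the planted regulators (within-cluster Pearson ~0.9 against a ~0.3
  background), plus a 4-zone internode matrix in which toolbox and regulator
  genes peak in the transitional or maturation zone;
* qPCR Ct and dual-luciferase tables in which planted candidates are
  ``effect_fold`` times more expressed in the top internode and activate the
  reporter ``effect_fold``-fold over the control effector.

Correlation structure uses a per-cluster latent factor: with a global factor
g, cluster factor f_c and noise e (all standard normal),
z = sqrt(r_bg) g + sqrt(r_w - r_bg) f_c + sqrt(1 - r_w) e, so the expected
Pearson correlation is r_w within a cluster and r_bg between clusters.
Abundances are exponentiated (base * 2^(0.5 z)) to give positive TPM-like
values; row-wise scaling and Pearson screening downstream are insensitive to
the per-gene base. Repeat planting samples rows of the same bundled seed
alignment the scanner's PSSM is built from, but through an independent
sampling path with per-position substitution noise, so scanner tests are not
circular at nonzero noise.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpr import CategoryAnnotation, GeneAnnotation
from .genome_map import GeneModel
from .repeat_scan import AMINO_ACIDS, ProteinRecord, load_seed_alignment

ROLES = (
    "r2r3_family",
    "single_repeat",
    "triple_repeat",
    "background",
    "toolbox",
    "planted_regulator",
    "tandem_member",
)

DEFAULT_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 10))
TISSUES = ("young_root", "young_leaf", "internode_bottom", "internode_top")
TARGET_TISSUE = "internode_top"
REFERENCE_GENES = ("CUL", "EF1A")
CONTROL_EFFECTOR = "GUS"


@dataclass(frozen=True)
class TruthEntry:
    entity_id: str
    roles: tuple[str, ...]
    planted_cluster: int | None = None
    planted_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles {sorted(unknown)}")


@dataclass
class TruthTable:
    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def add(self, entry: TruthEntry) -> None:
        if entry.entity_id in self.entries:
            raise ValueError(f"entity {entry.entity_id} recorded twice")
        self.entries[entry.entity_id] = entry

    def ids_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [e.entity_id for e in self.entries.values() if role in e.roles]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "entity_id": e.entity_id,
                    "roles": ";".join(e.roles),
                    "planted_cluster": e.planted_cluster,
                    **{f"param_{k}": v for k, v in sorted(e.planted_params.items())},
                }
                for e in self.entries.values()
            ]
        )


@dataclass
class SyntheticFamilyGenome:
    proteins: list[ProteinRecord]
    models: list[GeneModel]
    truth: TruthTable


@dataclass
class SyntheticExpression:
    atlas: pd.DataFrame
    internode: pd.DataFrame
    truth: TruthTable


@dataclass
class SyntheticValidation:
    ct: pd.DataFrame
    luciferase: pd.DataFrame
    truth: TruthTable


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
    return "".join(out)


def _plant_repeats(
    rng: np.random.Generator,
    n_repeats: int,
    seed_rows: Sequence[str],
    noise: float,
) -> str:
    """A protein carrying ``n_repeats`` noisy seed-alignment repeats up front."""
    width = len(seed_rows[0])
    nterm_pad = int(rng.integers(5, 25))
    parts = [_random_sequence(rng, nterm_pad)]
    for k in range(n_repeats):
        row = seed_rows[rng.integers(0, len(seed_rows))]
        parts.append(_mutate(rng, row, noise))
        if k < n_repeats - 1:
            parts.append(_random_sequence(rng, int(rng.integers(2, 12))))
    parts.append(_random_sequence(rng, int(rng.integers(80, 160))))
    return "".join(parts)


def gen_family_genome(
    n_r2r3: int,
    n_single: int,
    n_triple: int,
    n_background: int,
    tandem_spec: Sequence[tuple[str, int, int]] = (),
    seed: int = 0,
    repeat_noise: float = 0.05,
    chromosomes: Sequence[str] = DEFAULT_CHROMOSOMES,
) -> SyntheticFamilyGenome:
    """Proteome + gene models + truth with planted repeat architectures.

    ``tandem_spec`` lists (chromosome, array_size, intra_gap_bp) tandem
    arrays; array members are drawn from the planted family genes, so the
    summed array sizes may not exceed ``n_r2r3``. Non-tandem genes are placed
    more than 150 kb apart so no accidental tandem pairs arise.
    """
    counts = (n_r2r3, n_single, n_triple, n_background)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    for chrom, size, gap in tandem_spec:
        if chrom not in chromosomes:
            raise ValueError(f"tandem array on undeclared chromosome {chrom!r}")
        if size < 2:
            raise ValueError("tandem arrays need at least 2 members")
        if gap <= 0:
            raise ValueError("intra_gap_bp must be positive")
    if sum(size for _, size, _ in tandem_spec) > n_r2r3:
        raise ValueError("tandem arrays request more members than family genes exist")

    rng = np.random.default_rng(seed)
    seed_rows = list(load_seed_alignment().values())
    truth = TruthTable()
    proteins: list[ProteinRecord] = []
    specs: list[tuple[str, tuple[str, ...], int]] = []  # id, roles, n_repeats
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYNG{counter:04d}"

    for _ in range(n_r2r3):
        specs.append((next_id(), ("r2r3_family",), 2))
    for _ in range(n_single):
        specs.append((next_id(), ("single_repeat",), 1))
    for _ in range(n_triple):
        specs.append((next_id(), ("triple_repeat",), 3))
    for _ in range(n_background):
        specs.append((next_id(), ("background",), 0))

    for gid, roles, n_rep in specs:
        if n_rep == 0:
            seq = _random_sequence(rng, int(rng.integers(150, 400)))
        else:
            seq = _plant_repeats(rng, n_rep, seed_rows, repeat_noise)
        proteins.append(ProteinRecord(id=gid, sequence=seq))

    # genomic placement: tandem arrays consume family genes first
    family_ids = [gid for gid, roles, _ in specs if "r2r3_family" in roles]
    tandem_assignment: list[tuple[str, list[str], int]] = []
    cursor_ids = iter(family_ids)
    tandem_ids: set[str] = set()
    for chrom, size, gap in tandem_spec:
        members = [next(cursor_ids) for _ in range(size)]
        tandem_ids.update(members)
        tandem_assignment.append((chrom, members, gap))

    models: list[GeneModel] = []
    positions: dict[str, int] = {c: 50_000 for c in chromosomes}

    for chrom, members, gap in tandem_assignment:
        for gid in members:
            length = int(rng.integers(1_000, 4_000))
            start = positions[chrom]
            models.append(
                GeneModel(
                    gene_id=gid,
                    chromosome=chrom,
                    start=start,
                    end=start + length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            # next start sits exactly intra_gap_bp beyond this gene's end,
            # so the detector's edge gap recovers the planted value
            positions[chrom] = start + length - 1 + gap
        positions[chrom] += 200_000  # break the chain after the array

    loose = [gid for gid, _, _ in specs if gid not in tandem_ids]
    for gid in loose:
        chrom = chromosomes[int(rng.integers(0, len(chromosomes)))]
        length = int(rng.integers(1_000, 4_000))
        start = positions[chrom]
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=chrom,
                start=start,
                end=start + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
        positions[chrom] = start + length + 200_000

    for gid, roles, n_rep in specs:
        all_roles = roles + (("tandem_member",) if gid in tandem_ids else ())
        truth.add(
            TruthEntry(
                entity_id=gid,
                roles=all_roles,
                planted_params={"n_repeats": n_rep, "repeat_noise": repeat_noise},
            )
        )
    return SyntheticFamilyGenome(proteins=proteins, models=models, truth=truth)


def gen_expression_data(
    genes: Sequence[str],
    n_samples_atlas: int = 39,
    n_zones: int = 4,
    k_planted: int = 5,
    toolbox_ids: Sequence[str] = (),
    regulator_ids: Sequence[str] = (),
    r_within: float = 0.9,
    r_background: float = 0.3,
    seed: int = 0,
    internode_dropout: float = 0.0,
    lignin_related_ids: Sequence[str] = (),
) -> SyntheticExpression:
    """Atlas + internode matrices with one planted lignin-like cluster.

    Cluster 1 holds every toolbox gene, every planted regulator and every
    ``lignin_related_ids`` gene — the latter emulate the annotated laccases,
    class III peroxidases and other lignin-associated genes that co-express
    with the toolbox in real atlases and count as screening targets — plus a
    share of background genes as decoys; the remaining genes are spread over
    clusters 2..k. In the internode matrix, toolbox, regulator and
    lignin-related genes peak in TZ or MZ while all other genes peak in MsZ
    or CEZ; a fraction ``internode_dropout`` of the other genes is left out
    of the internode matrix entirely, mimicking genes not expressed in culms.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    toolbox = list(toolbox_ids)
    regulators = list(regulator_ids)
    lignin_related = list(lignin_related_ids)
    if (
        not set(toolbox) <= set(genes)
        or not set(regulators) <= set(genes)
        or not set(lignin_related) <= set(genes)
    ):
        raise ValueError("toolbox, regulator and lignin-related ids must be drawn from genes")
    if set(toolbox) & set(regulators):
        raise ValueError("regulator ids overlap toolbox roles")
    if set(lignin_related) & (set(toolbox) | set(regulators)):
        raise ValueError("lignin-related ids overlap toolbox/regulator roles")
    if not (0 <= r_background < r_within <= 1):
        raise ValueError("need 0 <= r_background < r_within <= 1")
    if n_samples_atlas < 3:
        raise ValueError("n_samples_atlas must be >= 3")
    if k_planted < 2:
        raise ValueError("k_planted must be >= 2")
    if n_zones != 4:
        raise ValueError("the internode design has exactly 4 zones")
    if not (0 <= internode_dropout < 1):
        raise ValueError("internode_dropout must be in [0, 1)")

    rng = np.random.default_rng(seed)
    cluster_of: dict[str, int] = {}
    for g in toolbox + regulators + lignin_related:
        cluster_of[g] = 1
    others = [g for g in genes if g not in cluster_of]
    for g in others:
        cluster_of[g] = int(rng.integers(1, k_planted + 1))

    n, s = len(genes), n_samples_atlas
    g_factor = rng.standard_normal(s)
    f_factors = rng.standard_normal((k_planted, s))
    eps = rng.standard_normal((n, s))
    z = np.empty((n, s))
    a, b, c = np.sqrt(r_background), np.sqrt(r_within - r_background), np.sqrt(1 - r_within)
    for i, g in enumerate(genes):
        z[i] = a * g_factor + b * f_factors[cluster_of[g] - 1] + c * eps[i]
    base = 2.0 ** rng.uniform(2, 10, size=n)
    atlas = pd.DataFrame(
        base[:, None] * 2.0 ** (0.5 * z),
        index=genes,
        columns=[f"sample_{j+1:02d}" for j in range(s)],
    )

    # internode: scaled-profile shapes with the planted peak zone
    late_shapes = np.array([[-1.0, -0.3, 1.5, 1.0], [-1.0, -0.5, 0.8, 1.6]])
    early_shapes = np.array([[1.5, 0.8, -0.5, -1.0], [0.6, 1.5, -0.5, -1.0]])
    rows = {}
    peak_zone: dict[str, int] = {}
    scw = set(toolbox) | set(regulators) | set(lignin_related)
    kept_others = [g for g in genes if g not in scw and rng.random() >= internode_dropout]
    for g in genes:
        if g in scw:
            shape = late_shapes[int(rng.integers(0, 2))]
        elif g in kept_others:
            shape = early_shapes[int(rng.integers(0, 2))]
        else:
            continue
        profile = shape + rng.normal(0, 0.15, size=4)
        # the noise can swap the two late (or two early) zones but never
        # crosses the early/late divide; truth records the realized peak
        peak_zone[g] = int(profile.argmax()) + 1
        rows[g] = 2.0 ** rng.uniform(2, 10) * 2.0 ** (0.5 * profile)
    internode = pd.DataFrame.from_dict(rows, orient="index")
    internode.columns = ["MsZ", "CEZ", "TZ", "MZ"]

    truth = TruthTable()
    for g in genes:
        if g in toolbox:
            roles: tuple[str, ...] = ("toolbox",)
        elif g in regulators:
            roles = ("planted_regulator",)
        else:
            roles = ("background",)
        params = {"r_within": r_within, "r_background": r_background}
        if g in lignin_related:
            params["category"] = "lignin_related"
        if g in peak_zone:
            params["peak_zone"] = peak_zone[g]
        truth.add(
            TruthEntry(
                entity_id=g,
                roles=roles,
                planted_cluster=cluster_of[g],
                planted_params=params,
            )
        )
    return SyntheticExpression(atlas=atlas, internode=internode, truth=truth)


def annotation_from_truth(truth: TruthTable) -> CategoryAnnotation:
    """Category annotation implied by the planted truth: toolbox genes are
    lignin biosynthesis; genes planted with a lignin_related category keep it."""
    entries = {
        g: GeneAnnotation(category="lignin_biosynthesis", is_toolbox=True)
        for g in truth.ids_with_role("toolbox")
    }
    for e in truth.entries.values():
        cat = e.planted_params.get("category")
        if cat is not None and e.entity_id not in entries:
            entries[e.entity_id] = GeneAnnotation(category=str(cat))
    return CategoryAnnotation(entries)


@dataclass
class SyntheticStudy:
    """A complete planted study: genome, expression, validation, annotation."""

    genome: SyntheticFamilyGenome
    expression: SyntheticExpression
    validation: SyntheticValidation
    toolbox: list[str]
    regulators: list[str]
    annotation: CategoryAnnotation


def standard_study(
    seed: int = 0,
    n_family: int = 12,
    n_regulators: int = 5,
    n_toolbox: int = 14,
    n_lignin_related: int = 40,
    n_background_genes: int = 100,
    n_samples_atlas: int = 39,
    r_within: float = 0.9,
    r_background: float = 0.3,
    effect_fold: float = 8.0,
    n_reps: int = 4,
) -> SyntheticStudy:
    """One coherent synthetic study under the default screening conditions.

    Defaults mirror the screen's real-data shape: a 14-gene lignin toolbox
    and a 39-sample atlas, a family of R2R3 proteins of which
    ``n_regulators`` are planted lignin regulators, a dozen annotated
    lignin-related co-expression partners, and validation fixtures with an
    8-fold top-internode effect.
    """
    genome = gen_family_genome(
        n_family, 8, 3, 30, [("chr1", 3, 20_000)], seed=seed
    )
    family = genome.truth.ids_with_role("r2r3_family")
    regulators = family[:n_regulators]
    toolbox = [f"TBX{i:02d}" for i in range(1, n_toolbox + 1)]
    lignin_related = [f"LIG{i:02d}" for i in range(1, n_lignin_related + 1)]
    background = [f"BGG{i:03d}" for i in range(1, n_background_genes + 1)]
    genes = toolbox + lignin_related + family + background
    expression = gen_expression_data(
        genes,
        n_samples_atlas=n_samples_atlas,
        n_zones=4,
        k_planted=5,
        toolbox_ids=toolbox,
        regulator_ids=regulators,
        r_within=r_within,
        r_background=r_background,
        seed=seed,
        lignin_related_ids=lignin_related,
    )
    validation = gen_validation_fixtures(
        regulators, effect_fold=effect_fold, n_reps=n_reps, seed=seed
    )
    return SyntheticStudy(
        genome=genome,
        expression=expression,
        validation=validation,
        toolbox=toolbox,
        regulators=regulators,
        annotation=annotation_from_truth(expression.truth),
    )


def gen_validation_fixtures(
    candidate_ids: Sequence[str],
    effect_fold: float = 8.0,
    n_reps: int = 4,
    seed: int = 0,
    base_delta_ct: float = 5.0,
    ct_noise: float = 0.15,
) -> SyntheticValidation:
    """Ct and dual-luciferase tables with planted effect sizes.

    Candidates are ``effect_fold`` times more expressed in the top internode
    than in the other three tissues (encoded as a log2(effect_fold) Ct
    shift), and their luciferase effectors activate the reporter
    ``effect_fold``-fold over the GUS control.
    """
    candidates = list(candidate_ids)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if effect_fold <= 0:
        raise ValueError("effect_fold must be positive")
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate ids")

    rng = np.random.default_rng(seed)
    ct_rows = []
    for tissue in TISSUES:
        for rep in range(1, n_reps + 1):
            ref_cts = {}
            for ref in REFERENCE_GENES:
                ref_cts[ref] = 20.0 + rng.normal(0, 0.1)
                ct_rows.append(
                    {"gene": ref, "tissue": tissue, "replicate": rep, "ct": ref_cts[ref]}
                )
            ref_mean = float(np.mean(list(ref_cts.values())))
            for gene in candidates:
                delta = base_delta_ct
                if tissue == TARGET_TISSUE:
                    delta -= float(np.log2(effect_fold))
                ct_rows.append(
                    {
                        "gene": gene,
                        "tissue": tissue,
                        "replicate": rep,
                        "ct": ref_mean + delta + rng.normal(0, ct_noise),
                    }
                )
    ct = pd.DataFrame(ct_rows)

    luc_rows = []
    for effector in [CONTROL_EFFECTOR] + candidates:
        fold = 1.0 if effector == CONTROL_EFFECTOR else effect_fold
        for rep in range(1, n_reps + 1):
            rluc = float(rng.normal(1000, 80))
            rluc = max(rluc, 100.0)
            ratio = fold * float(np.exp(rng.normal(0, 0.08)))
            luc_rows.append(
                {
                    "effector": effector,
                    "replicate": rep,
                    "fluc": ratio * rluc,
                    "rluc": rluc,
                }
            )
    luciferase = pd.DataFrame(luc_rows)

    truth = TruthTable()
    for gene in candidates:
        truth.add(
            TruthEntry(
                entity_id=gene,
                roles=("planted_regulator",),
                planted_params={"effect_fold": effect_fold, "n_reps": n_reps},
            )
        )
    return SyntheticValidation(ct=ct, luciferase=luciferase, truth=truth)
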