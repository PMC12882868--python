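# Methods

This note documents the models, parameter choices and numerical conventions
behind `mybfunnel`, what the synthetic-data generator does and does not
emulate, and the known limitations of each stage.

## Repeat scanning and family membership

The MYB repeat is modeled as an ungapped position-specific scoring matrix
built from a bundled seed alignment (8 rows × 52 columns). The seed
alignment is a *synthetic stand-in* constructed around the canonical plant
MYB repeat consensus (the tryptophan scaffold and the conserved
`CGKSCRLRW` core); it is not a curated database family, and the scanner is
therefore a domain-architecture filter, not a general homology search.
Column scores are log-odds in bits with background-proportional
pseudocounts:

    score(c, a) = log2( ((n_a + κ·π_a) / (N + κ)) / π_a ),

with pseudocount κ = 1 and uniform background π by default. Unknown
residues (X) score 0 everywhere — ambiguity neither helps nor hurts a
window. A window is a repeat hit when its summed score reaches a threshold
expressed as a fraction (default 0.45) of the maximum achievable window
score; overlapping hits are resolved greedily by descending score with a
leftmost tie-break. The fraction, the N-terminal window (200 aa) and the
maximum inter-repeat gap (30 aa) are configuration parameters; the defaults
are wide enough that every seed row passes its own PSSM (self-scores
174–195 bits against a ~89-bit threshold) and strict enough that random
20-letter sequence essentially never scores above threshold (expected
window score is strongly negative). Family membership requires exactly two
hits, both starting inside the N-terminal window, separated by at most the
gap limit; one hit is MYB-related (1R), three or more is a 3R protein, and
two hits violating position/spacing are excluded as atypical.

## Genomic map

Family naming follows physical order: chromosomes in natural sort
(`chr2` < `chr10`; scaffolds after chromosomes), genes by ascending start.
Tandem duplication uses the 50 kb convention, measured between the closest
gene edges (not start-to-start; the overlap case counts as distance 0) and
chained transitively: clusters are connected components of the ≤ 50 kb
proximity graph, computed by union-find over within-chromosome pairs and
verified in tests against an all-pairs transitive-closure oracle.
Intervening non-family genes are allowed — no constraint is placed on what
lies between two family members. Strand is ignored for distances.

## Subgroup classification

The tree stage is deliberately a *distance* method: a center-star multiple
alignment (the center maximizes the summed pairwise global-alignment score;
pairwise alignments against it merge under "once a gap, always a gap"),
column trimming that removes columns with gap fraction > 0.5 while always
retaining at least ⌈10%⌉ of columns (lowest gap fraction first, leftmost on
ties), p-distances (mismatches over shared ungapped columns), and
Saitou–Nei neighbor joining (via scikit-bio) with negative branch lengths
clamped to zero. Bootstrap support resamples alignment columns with
replacement; a split's support is the percentage of replicate trees
containing it. This is **not** a maximum-likelihood reconstruction: no
substitution model, no rate heterogeneity, no alignment uncertainty. It is
sufficient for the downstream contract — transferring subgroup labels — and
that contract is what the tests pin down (consistency on additive
distances, ≥ 90% correct label transfer at 10% mutation from subgroup
ancestors). Label transfer midpoint-roots the tree (no outgroup is
assumed), ascends from each query leaf to the smallest clade containing at
least one reference whose support is ≥ 50% (nodes without a support value
qualify, so unbootstrapped trees remain usable), and assigns the majority
reference label; ties and queries with no qualifying clade are
`unclassified`. For inputs above 80 sequences the quadratic center search
switches to choosing the longest sequence; the merge is unchanged.

## Expression clustering

Rows are standardized to mean 0 and unit sample standard deviation (n−1
convention); constant rows cannot be scaled and are dropped with a warning
and listed in the result. Clustering is agglomerative with correlation
distance (1 − Pearson) and average linkage by default (both configurable to
euclidean/complete/ward); rows are processed in lexicographic id order so
equal-distance ties break deterministically, and cluster labels are
renumbered 1..k by first appearance. The atlas stage cuts at k = 5 and
selects the cluster with the most toolbox genes (ties: higher toolbox
fraction, then smaller cluster, then lower label; a split toolbox is
logged). The internode stage requires exactly the four zone columns MsZ,
CEZ, TZ, MZ and offers two selectors, because heatmap-derived cluster
definitions can be read either way: co-clustering at k = 2 with an
artificial terminal row carrying the mean scaled toolbox profile, or a
direct peak-zone rule (scaled maximum in TZ or MZ). Both are exposed; the
terminal mode is the default. Genes absent from a matrix simply drop out of
that stage and are reported in diagnostics.

## Co-expression screen and shortlist

Correlations are Pearson on raw abundances by default — the public
co-expression services this emulates operate on untransformed values — with
a `log2p1` switch. The inclusion threshold r ≥ 0.85 is inclusive. Partners
are classified by a user-supplied annotation table into lignin
biosynthesis, lignin-related, or phenylpropanoid-related; anything
unannotated is `other` and never counts. The shortlist rule is
`total targets ≥ min_targets` with default 11; the published screen's
printed boundary separates rejected candidates (n < 8) from retained ones
(n ≥ 11), leaving 8–10 ambiguous, so the floor is configurable. The printed
per-query partner lists for the two strongest published candidates ship as
a versioned TSV fixture (`data/printed_coexpression.tsv`); the stronger
query's first printed accession is its own gene identifier, which the
fixture records as the query accession rather than as a partner row.

## Validation statistics

Relative expression is RE = 2^(−ΔCt) with ΔCt = Ct_target − mean(Ct_ref1,
Ct_ref2); averaging reference Cts equals geometric-mean normalization on
the linear scale. Amplification efficiency is fixed at 2 (no efficiency
correction). The preferential-expression verdict is: target tissue has the
strictly highest mean RE *and* every Tukey-HSD-adjusted contrast against the
other tissues is significant at α, after a one-way ANOVA. Note the
calibration consequence: the Tukey conjunction controls error at the
familywise level, so the *verdict's* null false-positive rate is far below
α (measured 0 in 2000 simulated null genes), while the reported omnibus
ANOVA p-value rejects at the nominal α (measured 0.0445 at α = 0.05 over
1000 null genes). Transactivation folds are mean(fLUC/rLUC) of an effector
over the control effector, compared by a two-sided equal-variance t test
(Welch optional); the control against itself is fold 1, p 1 by definition,
and folds above 20× are flagged as strong activation.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with known truth.

*Proteome/genome*: family proteins embed two seed-alignment rows (sampled
through an independent path from the PSSM construction, with per-position
substitution noise, default 5%) starting within the N-terminal window;
decoys carry one, three or zero repeats. Tandem arrays are realized exactly
(next start = previous end + requested gap); all other genes sit > 150 kb
apart so no accidental pairs arise.

*Expression*: correlation structure uses shared latent factors,
z = √r_bg·g + √(r_w − r_bg)·f_c + √(1 − r_w)·ε, giving expected pairwise
Pearson r_w within a cluster and r_bg between clusters (defaults 0.9 and
0.3, with a 39-sample atlas). Values are exponentiated, base·2^(z/2), to be
positive and TPM-like; the mild exponent keeps the raw-scale Pearson
expectation within a few hundredths of the planted Gaussian correlation
(typical realized within-cluster means are 0.88–0.90 for a planted 0.9),
and the per-gene base is irrelevant to both row scaling and Pearson
screening. The planted lignin
cluster holds the 14 toolbox genes, the regulators, and by default 40
additional annotated lignin-related genes — mirroring the scale of the
annotation sets a real screen counts against (toolbox plus laccase,
class III peroxidase, NAC and flavonoid-pathway lists), and giving the
≥ 11-target rule realistic headroom over threshold-crossing noise.
Internode profiles are four-zone shapes peaking late (TZ/MZ) for
toolbox/regulator/lignin-related genes and early (MsZ/CEZ) for everything
else, with Gaussian shape noise; the truth records the realized peak.

*Validation*: Ct tables encode the requested fold as a log2 shift in the
top internode over a ΔCt = 5 baseline with 0.15-cycle noise; luciferase
ratios multiply a ~1.0 control ratio by the fold with 8% lognormal noise.

What this does **not** emulate: sequencing/quantification noise models,
batch effects, missing-not-at-random dropout, heavy-tailed expression
distributions, gapped/degraded protein models, or alignment uncertainty.
Passing tests therefore demonstrate the pipeline's correctness and its
behavior under the stated correlation geometry — not robustness to every
artifact of real RNA-seq data.

## Problem sizes and determinism

Tests and the acceptance script run generator-scale problems: proteomes of
~53 proteins, 200-gene atlases over 39 samples, trees of 8–20 leaves with
20–100 bootstrap replicates, 1000-gene null panels, and 5–10 complete
studies per check. These sizes keep the full suite within a couple of
minutes on one CPU while leaving every statistical check well-powered. All
randomness flows through `numpy.random.default_rng` seeds; identical
arguments and seed give byte-identical written outputs (floats are
serialized with a fixed `%.6g` format).

## Known limitations

- The PSSM has no insert/delete states; severely gapped repeats would be
  missed. Remote domain databases are intentionally not queried.
- The NJ subgroup stage cannot reproduce a published ML tree topology;
  only the label-transfer contract is guaranteed.
- Whether published heatmap clusters were dendrogram cuts or visual reads
  is unknowable from the outside; k per dataset is configuration, not
  inference.
- The co-expression screen requires a manual annotation table; no automatic
  functional annotation is attempted.
- The exact efficiency-correction convention of the upstream qPCR protocol
  is not restated in the source material; 100% efficiency is assumed.
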