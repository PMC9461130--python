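# Methods

This note documents the statistical models, the numerical choices, and what
the synthetic cohorts do and do not emulate.

## Synthetic RIL cohorts

Lines descend from a biparental F1 through G = 6 generations of selfing
(configurable). Meioses are realized at marker loci as a two-state Markov
chain whose switch probability per interval is the Haldane recombination
fraction r(d) = (1 − e^(−2d/100))/2; marginally this is exact for genotypes
observed at markers, and the accumulated recombinant fraction between RIL
genotypes approaches the selfing expansion R = 2r/(1+2r). Residual
heterozygotes after G generations (≈ (1/2)^G per locus, ~1.6% at G = 6) are
resolved to a random homozygote; this inflates apparent adjacent-marker
recombination by roughly the heterozygosity, which the simulator tests
account for (and which vanishes at G = 10). Physical coordinates derive from
cM at a constant 400 kb/cM so that ±200 kb windows are meaningful on the toy
genome. Marker density is a parameter (default one marker per 2 cM on
5 × 100 cM chromosomes); the real population's map density is not needed for
any of the integration logic.

Trait values are sums of planted per-locus allele-substitution effects on
the ±1 genotype coding, an environment mean, and Gaussian noise scaled so
the realized broad-sense heritability matches the requested h² (default
0.55 in the demo). Per-environment effect vectors (+a, −a) plant crossover
QTL-by-environment interactions with no marginal effect. Metabolite/lipid
line effects are drawn from N(0, Ω⁻¹) for a prescribed precision matrix Ω —
the ground truth for GGM recovery — plus planted mQTL effects on the log
scale; replicates add independent noise (sd 0.5), and stored values are
2^x so the analysis exercises its log2-transform path.

The regulatory generator plants, per locus: a causal gene at the window
midpoint with a seed-dominant tissue profile, a 55-DAF-high stage profile,
a differential high/low-oil count pair, a promoter carrying the motif
consensus, and (optionally) a miRNA 50 kb away whose perfect-complement site
sits in the gene's transcript; one shared TF binds every causal promoter and
shares its rising stage profile (pairwise r ≈ 0.99). Decoys are planted both
inside windows (failing the expression filters) and genome-wide (failing the
window test), plus sub-threshold PPI pairs. Every planted relationship is
written once to a JSON ledger.

What the generator does *not* emulate: segregation distortion, population
structure beyond the OC/RC label, mass-spectrometry measurement artifacts,
sequence evolution, or realistic expression noise models. Passing tests
therefore demonstrate that the integration logic recovers structure it is
designed to detect, not that the thresholds are optimal for real soybean
data.

## Association layer

BLUPs come from the balanced random-line model y = env + line + e with
ANOVA method-of-moments components, σ²_g = (MS_line − MS_err)/n_env floored
at zero, and shrinkage k = n_env σ²_g/(n_env σ²_g + σ²_e) applied to centered
line means. With degenerate components (MS_line ≤ MS_err) all BLUPs are 0 and
callers fall back to plain line means.

MCP (γ = 3) and SCAD (a = 3.7) are solved by cyclic coordinate descent on
standardized predictors to max |Δβ| < 1e−8, using the Gram-matrix update so
each coordinate step is O(p). λ runs over a 100-point log-spaced path from
λ_max = max_j |x_j'y|/n down to 0.01 λ_max, with warm starts; cross-validation
is k = 10-fold with seeded fold assignment. λ is chosen by the **one-standard-
error rule** (sparsest λ within 1 SE of the CV minimum). The CV-minimum rule
is available but, combined with post-selection OLS tests, lets chance
selections through far too often under the null (family-wise false-selection
≈ 25–30% in simulation, vs ≤ 10% with the 1-SE rule); the 1-SE rule is the
package's default for that reason. Selection runs per biological replicate
and keeps the intersection across replicates; the union of MCP- and
SCAD-selected variables is refit by OLS with overall F- and per-variable
t-tests at α = 0.05.

Genetic correlations use two-way (line × replicate) mean cross-products:
COV_G = (MCP_line − MCP_err)/r. Non-positive genetic variances flag the
result undefined rather than emitting NaN quietly.

GGM edges: variables are replicate-averaged (one network, not one per
replicate) and standardized; the correlation matrix is shrunk toward the
identity with the Ledoit–Wolf analytic intensity (a fixed intensity,
including 0, can be forced for oracle comparisons); partial correlations come
from the inverted shrunk matrix. P-values use the normal approximation of the
Fisher z-transform with effective df = n − p − 1 floored at 3 — a
deterministic replacement for the empirical-null mixture of the GeneNet-style
estimator; the Bonferroni cut is α/C(p,2) by default and α/119,316 when the
published family size is requested. The family size is a parameter because
the published denominator implies more variables than the described
compound panel; no attempt is made to guess the original feature count.

## Genome layer

Interval mapping: expected ±1 genotypes at pseudomarkers every 1 cM are
conditioned on the flanking markers through the two-state chain with RIL
transfer probabilities R(d); LOD = (n/2) log10(RSS₀/RSS₁) with the OC/RC
covariate in both models (computed via the partial correlation of
residualized phenotype and genotype, which is algebraically identical and
lets one scan be a single matrix operation). Peaks are local maxima ≥ 2.5
separated by ≥ 10 cM **and** topographically prominent: a lower peak is
reported only if the profile dips below its LOD − 1.5 on the path to every
stronger peak, so the shoulders of one broad QTL are not multiply reported.
Support intervals are 1.5-LOD drops, reported with their flanking markers
and bp bounds. Effects are the regression coefficient on the ±1 coding;
r² (%) is the drop in RSS over the total phenotypic sum of squares.

The multilocus scan forward-selects markers by conditional LOD while
LOD ≥ 3.0 and the model holds ≤ n/10 markers, then backward-eliminates at
the same threshold; collinear candidates are skipped. QEI scans compare
y = env + g with y = env + g + g×env on the stacked two-environment data,
LOD_QEI = (N/2) log10(RSS_add/RSS_full), threshold 5.0. This is a standard
G×E interaction regression; it does not reproduce any particular published
software's interaction machinery.

Stable-QTL calling groups records per variable by transitive peak proximity
(≤ 5 cM) and keeps groups spanning ≥ 2 methods and/or ≥ 2 environments.
mQTL clusters merge same-chromosome, same-compound-class records with
overlapping supports (union–find transitive closure) and are retained when
members span ≥ 2 methods; mQTLs are mapped per biological replicate so the
method set is the union over replicates. Co-location pads both intervals by
200 kb and tests closed-interval intersection.

## Regulatory layer

Windows extend from the support interval (not the point peak — the more
inclusive reading; peak-mode is a flag), ±200 kb, closed at both ends,
clamped at position 1. Expression filters: FPKM < 1 in all tissues drops a
gene; missing fraction strictly greater than 20% drops a gene;
"seed-specific" means seed is the arg-max tissue with a ≥ 2× margin over the
runner-up (the margin is configurable — the source rule gives no number);
"55-DAF-high" means FPKM at 55 DAF ≥ 2× the across-stage mean (reading
"one-time higher than average" as one fold above it). Differential
expression between high- and low-oil accessions is a per-gene two-proportion
z-test on library-normalized counts at raw α = 0.05 with no multiplicity
correction — the same binomial null family as MA-plot DE callers, kept
dependency-free and exactly testable against a binomial oracle.

PWM scanning scores windows by Σ log2(p_b/q_b) with a small pseudocount
(0.01 toward the background) and computes p-values exactly by dynamic
programming over the discretized score lattice (0.01-bit bins); window
scores use the same binned lattice, so scan p-values equal exhaustive
enumeration identically. Both strands are scanned; windows containing N are
skipped; the hit threshold is p ≤ 1e−4 per window with no multiple-testing
control, deliberately mirroring common FIMO usage. Promoters are 2 kb
upstream in the demo generator (configurable).

miRNA target scoring slides the mature miRNA over the transcript; per
position the penalty is 0 for Watson–Crick, 0.5 for G:U, 1.0 for a mismatch,
plus 1.0 for a single bulged transcript nucleotide (at most one), all doubled
within miRNA positions 2–13 from the 5′ end; a site is a hit when the total
expectation is ≤ 3.0. This one Allen-style scorer stands in for the consensus
of several published predictors; the "two or more predictors agree" consensus
becomes a single-scheme threshold, which is a documented divergence.
Overlapping hits are resolved greedily by ascending penalty.

GRN assembly gates *every* edge class (TF→gene, miRNA→gene, PPI > 0.40) by
co-expression r > 0.8 (pairwise-complete Pearson, ≥ 3 shared samples)
whenever both endpoints have expression profiles; nodes without profiles
(miRNAs in the demo) pass ungated.

## Network layer

Node types follow a TF > gene precedence when one id appears as both; any
other type collision is an error. Circuits are simple cycles of the
undirected skeleton with lengths 3–5 (direction of regulatory edges is
deliberately ignored: published example cycles traverse both directed and
undirected edges); each cycle is canonicalized to its lexicographically
smallest rotation/reflection. The 3–5 length default matches the reported
sub-network sizes and is a parameter. TF nodes satisfy the "gene" slot in the
3D/4D rules. MCC sums (|C|−1)! over maximal cliques (Bron–Kerbosch with
pivoting); since every edge that is itself a maximal clique contributes 1,
a node whose neighborhood holds no edge scores its degree, matching the
CytoHubba convention. Hubs take the top 10% by count (k = round(0.10 n),
minimum 1) with ties at the cutoff included, ordered (score desc, id asc).

Exports: GraphML (with explicit src/dst attributes so directed-edge
orientation survives the undirected container), Cytoscape SIF (with
companion `.nodes.tsv`/`.edges.tsv` tables so a round-trip is exact), and
JSON. All three round-trip to an identical network.

## Demo cohort and problem sizes

The end-to-end demo uses 398 lines (171 OC / 227 RC), a 5 × 100 cM genome at
2-cM marker spacing, 3 traits in 2 environments (h² = 0.55), 20 metabolites
and 30 lipids with 2 replicates, and five planted relations — one per
chromosome at 50 cM — each coupling a trait QTL (allele effect 1.0), a
compound mQTL at the same position (effect 1.2 on the log scale), a causal
gene at the locus midpoint and a miRNA 50 kb away; a crossover QEI for one
trait sits on a separate chromosome. These effect sizes make each planted
signal individually strong (QTL r² ≈ 20–40%) so that end-to-end recovery
measures the correctness of the integration logic rather than borderline
single-stage power; the power and calibration properties of the individual
stages are measured separately at the weaker effect sizes stated in their
tests (20% variance QTLs, 15% interaction variance, partial correlations of
0.35, partial R² of 0.1). Calibration and power suites use 100 replicates
on this genome; the full demo runs in well under a minute on one CPU.

## Known limitations

* The mapping engines are intentionally simple (no cofactor selection, no
  permutation thresholds, no epistasis scan); the fixed LOD cutoffs are the
  published ones and are not recalibrated per dataset.
* The Fisher-z GGM p-values are approximate for shrunk estimates; the
  shrinkage intensity is not propagated into the null distribution.
* The miRNA scorer has no thermodynamic duplex model and allows at most one
  bulge.
* Interval-mapping shoulder peaks can survive the prominence rule on very
  strong QTLs; downstream stable-QTL and candidate filters absorb most of
  them, but locus counts from single scans should not be over-interpreted.
* With two environments the QEI scan cannot separate scale interactions
  from rank-changing (crossover) interactions; it reports both.
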