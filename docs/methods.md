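# Methods

`cernet` re-implements, as a tested and reusable pipeline, the computational
analysis applied to bulk RNA-seq of partially injured rabbit knee ligaments
(anterior cruciate ligament, ACL, which heals poorly, versus medial
collateral ligament, MCL, which heals well): differential expression
calling, positional classification of lncRNAs, competing-endogenous-RNA
(ceRNA) network inference, hub-gene ranking, term over-representation, and
qPCR quantification. The original deposited sequencing data are not
required; a seeded synthetic-data generator provides inputs with known
ground truth so every stage's recovery behaviour can be measured.

## Synthetic data generator

The generator emulates a 2-tissue (ACL, MCL) x 2-condition (normal,
injured) design on a single synthetic chromosome.

* **Annotation.** Genes (2–4 exons, exons 150–400 bp, introns 0.8–2 kb) are
  spaced at least 12 kb apart so every lncRNA's positional class is
  unambiguous. lncRNA class counts follow largest-remainder rounding of the
  configured fractions, default 40% lincRNA / 8.8% antisense / 48.8%
  intronic / 2.4% sense — the proportions reported for this tissue system.
  Placement is by construction: lincRNAs at least 5 kb from any gene,
  antisense/sense overlapping an exon on the opposite/same strand, intronic
  strictly inside an intron. The generator verifies at build time that the
  classifier reproduces every constructed label.
* **Counts.** Negative binomial with variance m + alpha m^2 (alpha = 0.1 by
  default, the conventional bulk RNA-seq scale); per-feature baselines are
  log-normal around `mean_count` (default 200) and per-sample size factors
  are log-uniform in [0.5, 2] to exercise normalization. Default replication
  is n = 2 per group, matching the emulated sequencing design; statistical
  checks use n = 5 because power at n = 2 is not a meaningful testing
  surface. Three disjoint planted sets (ACL injury response, MCL injury
  response, constitutive tissue difference) receive |log2FC| =
  `planted_log2fc` (default 2) with random sign.
* **Interactions and triplets.** miRNA->target edges are uniform and sparse
  (defaults: 4 mRNA and 2 lncRNA targets per miRNA from a 150-miRNA
  universe). Each planted ceRNA triplet forces its lncRNA and mRNA to share
  exactly `k_shared` (default 8) miRNAs — incidental background overlap is
  pruned — and couples their expression through a shared per-sample latent
  factor (ln-scale sd 1.5, i.e. a log-scale correlation near 0.96) so the
  co-expression filter passes by construction, as the planted-triplet design
  requires. Triplet lncRNA and mRNA are additionally planted as co-directed
  ACL injury responders and their shared miRNAs as opposite-directed,
  mimicking sponge logic.
* **qPCR.** Ct = per-gene baseline + per-sample loading offset
  - log2(relative expression) + Gaussian noise (sd 0.15), three technical
  replicates, a reference gene with no effect. Offsets cancel in dCt and
  baselines in ddCt, so planted folds are recovered exactly in the
  noise-free limit.

What the generator does **not** emulate: read-level artifacts (alignment,
duplication, GC bias), splice isoforms, correlated background co-expression
modules, batch effects, and any sequence realism. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
assumed NB/latent-factor model, not performance on real libraries.

## Normalization

Size factors use the median-of-ratios estimator restricted to features with
all-positive counts, rescaled to geometric mean 1; if no such feature
exists the error is explicit rather than silently switching to a
pseudo-reference. Normalized counts (raw / size factor) feed the DE test and
co-expression; FPKM (c * 1e9 / (length * total)) is exposed for reporting
parity.

## Differential expression

A moment-matched negative-binomial Wald test substitutes for a full
GLM-with-shrinkage engine — the pipeline's substance is the calling rule and
the downstream network logic, not the DE engine, and the divergence is
deliberate. Per feature, a pooled method-of-moments dispersion is computed
within groups on normalized counts and shrunk with weight 0.9 toward a
mean–dispersion trend alpha(m) = a0 + a1/m fitted by least squares across
all features. Two numerical choices matter for calibration: the trend is
fitted on the *unclipped* moment estimates (clipping negative estimates
first biases the trend upward and makes the test conservative), and the
Wald statistic is referred to a standard normal (with thousands of features
the trend is effectively known; per-feature estimates at n = 5 are too noisy
to justify a t reference, which measured type-I error at ~0.02 instead of
the nominal 0.05). Groups with a zero mean receive a +0.5 continuity
correction on both means so fold changes and statistics stay finite;
features constant across all samples yield p = 1.

Calls use the conventional screen: BH FDR < 0.01 (strict) and
max(FC, 1/FC) >= 2, where FC is the ratio of group means (group 1 over
group 2). Measured on synthetic data (2,500 features, n = 5/group,
alpha = 0.1): type-I error 0.045–0.064 across seeds, recall of planted
|log2FC| = 2 features >= 0.99 with 100% direction agreement.

## lncRNA classification

Four positional classes with a fixed precedence: intergenic (no gene-span
overlap) -> lincRNA; contained in a single intron (strand-agnostic) ->
intronic; exonic overlap opposite strand -> antisense; exonic overlap same
strand -> sense. Containment is checked before exonic overlap because it is
the more specific relation; the source analysis names the classes without
defining precedence, so the order is documented and deterministic here. A
transcript overlapping a gene span while matching no rule is classified
sense and logged. Coordinates are handled 1-based inclusive at the GTF
surface with exact integer interval arithmetic.

## ceRNA inference

Every lncRNA–mRNA pair sharing at least one miRNA regulator is scored. A
pair passes when: shared miRNAs k > 5 (strictly); the upper-tail
hypergeometric p-value — universe M = distinct miRNAs in the interaction
table, so the null matches the sampled universe — is < 0.01 and its BH FDR
over the scored pairs is < 0.01; and the partners are co-expressed. The
co-expression metric is unstated in the source analysis; here it is Pearson
r >= 0.7 with two-sided p < 0.05 on log2(x+1) normalized counts, positive
by requirement because ceRNA partners respond in the same direction to
shared miRNA availability (both thresholds configurable). The differential
network retains a triplet (lncRNA, miRNA, mRNA) only when the pair passed,
the miRNA targets both partners, and all three members are differentially
expressed; miRNA DE status is an input like any other feature's (the
emulated study reports no small-RNA sequencing, so miRNA status is taken as
given rather than inferred).

Planted-triplet recovery at the default thresholds, 20 seeds x 10 triplets:
recall 1.0, precision 1.0. Note a real trade-off the generator exposes: the
latent factor that guarantees co-expression also inflates within-group
variance, so a planted triplet member can fail the DE call and drop out of
the differential network even though its pair passes — the integration test
checks consistency (recovered iff all three members called) rather than a
fixed survival rate.

## Hub ranking

Degree and Maximal Clique Centrality, MCC(v) = sum over maximal cliques C
containing v of (|C|-1)!, computed from Bron–Kerbosch-with-pivoting clique
enumeration (networkx). An isolated node scores 1 ({v} is its maximal
clique); on triangle-free graphs MCC reduces to degree. Ranked lists break
score ties by node id so top-k extraction is deterministic, and top-k
returns min(k, n) nodes — a 45-node network queried at k = 50 yields 45.
Input graphs are collapsed to simple undirected graphs (multi-edges merged,
self-loops dropped); enumeration refuses graphs above a configurable
5,000-node ceiling because the worst case is exponential. The pipeline ranks
ceRNA networks by Degree (top 50) and the PPI subgraph induced by a
contrast's DE genes by MCC (top 30), both configurable.

## Enrichment

Classic per-term upper-tail hypergeometric over-representation with BH FDR
across tested terms; the universe defaults to all mRNA features tested for
DE. Graph-aware decorrelation (elim/weight-style term algorithms) is
deliberately not replicated — enrichment here is descriptive, reported as
the top 20 terms per namespace ranked by p-value (ties by term id).

## qPCR quantification

Technical replicates are averaged per (sample, gene) before dCt = Ct(target)
- Ct(reference); ddCt subtracts the arithmetic mean control-group dCt, so
control folds have geometric mean exactly 1; fold = 2^-ddCt. Group
comparisons use Welch's unequal-variance t-test on folds with mean ± SEM
(sd/sqrt(n), ddof = 1) summaries. Averaging replicates before dCt and the
Welch variant are the documented choices where the source analysis is
silent.

## Pipeline and determinism

`run_all` executes normalize -> DE over the four study contrasts (injured
vs normal within each tissue; ACL vs MCL within each condition) -> classify
-> ceRNA -> hub -> enrich -> qPCR, validating every input path before any
stage runs, and writes a manifest of per-stage counts and SHA-256 hashes of
every output. All generator randomness flows from one root seed through
named substreams, outputs carry no timestamps, and floating-point output is
formatted consistently, so identical config + seed gives byte-identical
manifests.

## Problem sizes

Defaults (200 genes, 100 lncRNAs, 150 miRNAs, 10 triplets, n = 2/group) are
chosen so a full run completes in seconds; statistical checks use 2,500
features with n = 5/group for DE calibration and 20 seeds for triplet
recovery. These sizes are the package's own testing conditions and scale up
by configuration.

## Known limitations

The DE test has no per-feature dispersion moderation beyond the trend, no
independent filtering, and supports only two-group contrasts with other
factors fixed. ceRNA candidate FDR is computed over the scored-pair set of
the given interaction table; universes differing from the table's miRNA set
must be handled upstream. Enrichment ignores term–term dependence. The
fallback classification of span-overlapping transcripts that match no rule
is a convention, not biology.
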