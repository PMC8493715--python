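# Methods notes

Statistical and numerical choices behind `gammarep`, with parameter defaults
and known limitations. Module docstrings carry the API-level detail; this
note explains *why* the defaults are what they are.

## Locus model and identity rules

A V sequence's family is the family of its closest exemplar by percent
identity, provided the identity reaches **75%** (the subgroup convention for
immunoglobulin/TCR gene families). Percent identity is defined as
100 × (identical positions) / (length of the shorter sequence), with the
identical positions counted on an end-gap-free global alignment scored
match +1 / mismatch −1 / gap −2; among equal-scoring paths the one with the
most matches is taken, so identity is symmetric and capped at 100. Family
members are numbered distal→proximal with respect to the single TRGC
segment.

The packaged locus annotation reproduces the published chicken TRG map's
counts and statuses: 40 TRGV in families of 6/22/7/5 with 2/8/0/3
pseudogenes, two intact-but-never-expressed genes (TRGV1.2, TRGV2.9), 3
TRGJ, 1 TRGC. Its nucleotide sequences are synthetic placeholders built to
satisfy the map's constraints (within-family identity ≥ 75%, two
germline-identical groups, conserved anchors and RSS motifs); any analysis
needing real germline sequence must supply its own reference bundle
(`load_reference`). Where the map does not pin down *which* family members
are pseudogenes, the fixture's choice is arbitrary but family counts are
exact.

## Annotation

Every read is aligned in both orientations against every non-pseudogene V
and J by Smith–Waterman with **match +5 / mismatch −4 / linear gap −8** (the
scoring used for the locus dot-plot analyses) and a minimum call score of 60
(12 matched bases). Alignment is exhaustive rather than heuristic
(BLAST-style seeding) because TRGV family members differ by a handful of
bases and junction coordinates must be exact. The kernels are numba-compiled
with fixed tie-breaking (diagonal > gap-in-reference > gap-in-query within a
cell; smaller reference start, then smaller query start, then shorter
alignment among equal-scoring local optima) so outputs are bit-reproducible.
Score-only screening selects the best segment; a full traceback is computed
only for the winner. Annotation results are cached by read sequence, so
clonally duplicated reads cost one alignment.

Germline-identical V genes cannot be separated by any aligner and are
reported as grouped calls; only the two groups known to carry signal
(`TRGV2.7/2.18`, `TRGV2.4/2.8/2.14/2.19`) are retained downstream, any other
grouped call is flagged `ambiguous_v_excluded` and dropped from tables (but
kept in the rearrangement file).

The junction (CDR3) is anchor-inclusive: from the first base of the
conserved V cysteine codon through the last base of the conserved J
phenylalanine codon, located by mapping germline anchor coordinates through
the alignments. A junction is *in frame* when its length is divisible by 3;
a frame-0 stop codon (TAA/TAG/TGA) makes it non-productive. Repertoire
tables use the in-frame criterion by default (`filter="in_frame"`), matching
the study filter; `"productive"` additionally removes stop-containing
junctions.

## Usage proportions and the hierarchical bootstrap

Per bird × tissue, a V group's usage is its share of in-frame reads; the
tissue summary is the **unweighted mean over birds** (each bird counts
equally — the bird-as-random-effect logic of a mixed model, without fitting
one). 95% intervals come from a hierarchical bootstrap: resample birds with
replacement (500 replicates by default), average on the **logit scale**, and
back-transform the 2.5/97.5 percentiles. Proportions of exactly 0 or 1 get a
Haldane-style continuity adjustment ((x + 0.5)/(n + 1) using the bird's read
total) before the logit. Between-group contrasts use the bootstrap
distribution of the difference in logit means and are labelled bootstrap
p-values — they are not mixed-model Satterthwaite tests, and when several
bins or genes are tested the p-values should be corrected
(Benjamini–Hochberg via `statsmodels.stats.multitest.multipletests`).

**Limitation — small-cohort coverage.** The percentile bootstrap is
first-order accurate; its interval coverage approaches 95% as the number of
birds grows but falls short in small cohorts. Measured against the
procedure's own estimand (the back-transformed population logit-mean) on
logit-normal birds (σ = 0.4, 5000 reads/bird): ≈ 0.87–0.93 at the study's
8 birds, ≈ 0.91–0.94 at 25, ≈ 0.92–0.96 at 50. The acceptance calibration
therefore runs at 50 birds, where the nominal-coverage claim is the
scientifically meaningful one; intervals reported at n = 8 should be read
as mildly anti-conservative. Note also that the estimand is expit(mean of
logits), not the arithmetic mean proportion — for skewed bird distributions
the two differ (Jensen gap ≈ 0.007 at p = 0.3, σ = 0.4).

## Diversity

Hill numbers (q = 0 richness, q = 1 exponential Shannon, q = 2 inverse
Simpson) are standardised to a common **sample coverage** (Good–Turing)
rather than a common size, using the interpolation/extrapolation framework:
exact combinatorial rarefaction for q = 0, expected-subsample-entropy
rarefaction for q = 1, a single closed form valid on both sides of n for
q = 2, Chao1-anchored extrapolation for q = 0, and for q = 1 a size-weighted
blend H(m) = (n/m)·H_obs + ((m−n)/m)·H_asy anchored on the nearly unbiased
asymptotic entropy estimator (continuous at m = n, converging to exp(H_asy)
for large m; the exact extrapolation variant is a documented choice, as the
framework admits several). When a sample has no singletons it is treated as
complete, and requests beyond n return the observed value, flagged in the
estimate's `method` field; a target coverage that cannot be reached (no
doubletons to drive the extrapolation) is likewise flagged rather than
silently extrapolated.

The default coverage target is **0.1** — unusually low, but it is the
standardisation the study could support across its sample depths, and it is
a config default, not a constant. Interpolation uses log-binomial arithmetic
(`scipy.special.gammaln`) over unique abundance values, so it is stable for
large n.

## Publicity

A clonotype — (V group, junction nucleotide sequence) — is public at 60/80/
100% when present in that fraction of a line's birds, pooling all tissues at
any read frequency. Display bins are half-open and mutually exclusive
(p100 = 1.0; p80 = [0.8, 1.0); p60 = [0.6, 0.8)); cross-line sharing is
cumulative (a clone public at level L in line A counts as shared when it
reaches level ≥ L in line B), reported read-weighted or clone-weighted.
Between-line comparisons first down-sample the larger line to the smaller
line's bird count (default target 5) and use a Mann–Whitney rank test on
per-V public shares.

## RSS scoring

The recombination signal sequence scorer is a position-weight-matrix
log-odds model over the heptamer and nonamer (pseudocount 0.5, uniform
background, unseen-base floor −20, 12/23-nt spacer length-checked but not
scored). Scores are on an arbitrary log-odds scale where the training
consensus attains the maximum; they are **not** RIC scores (trained Bayesian
models on a −1000..0 scale, with functional chicken values around −70..−40),
but externally computed RIC scores can be supplied to the same regression.
The usage~score relation is ordinary least squares of per-V thymic usage on
score (slope, intercept, R², two-sided slope p-value); with realistic
repertoires the association is weak, so the regression is reported, not used
for inference downstream.

## Simulator

The generator is clone-based: per bird, `clones_per_bird` clones draw a V by
the configured usage (default: one dominant gene at 0.35, two elevated
genes, rest uniform — the shape seen in every chicken tissue), a J
uniformly, and a junction built from geometrically trimmed germline ends
(p = 1/3, anchors always preserved) plus Poisson(4) N-insertions; clone
sizes are lognormal (σ = 1); public clones are planted
junction-nucleotide-identical in ceil(penetrance × n_birds) birds with a
weight multiplier. Reads follow the 5'RACE layout (22-nt universal adapter,
8-nt barcode with pairwise Hamming distance ≥ 3, V, junction, J tail, 30 nt
of C) with optional per-base substitution error and reverse-complemented
emission. Every read carries a truth row. Error is **off by default** so
recovery oracles are exact. The simulator is deliberately simple: no indel
sequencing errors, no chimeras or PCR artefacts, no quality-score model, no
convergent recombination model — it validates the pipeline's bookkeeping and
estimators, not sequencer physics.

Problem sizes in the acceptance checks (8 birds × 5 tissues × 5000 reads;
300–600 clones per bird) are this package's own validation choices: large
enough that clone-weight noise keeps designed quantities (dominant usage
0.35, planted 100%-public read share 0.75) inside their tolerance bands with
comfortable margin, small enough to run on one CPU in minutes.

## Reproducibility

All randomness flows through `numpy.random.default_rng` seeds carried in
configs; the pipeline writes a manifest with a SHA-256 checksum of every
output, and identical inputs + config + seed reproduce identical checksums.
Alignment kernels use fixed tie-breaking, so annotation is deterministic
independent of iteration order.
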