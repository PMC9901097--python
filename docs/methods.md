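# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `leafdeo`.

## Study design assumed by the analysis

Three grass species with contrasting photosynthetic subtypes (C3,
Proto-Kranz, C4) are sampled at four segments of the developing leaf (S1,
S3, S5, S7 from base to tip), with three pooled biological replicates per
species × segment. Expression is compared at the orthogroup (OG) level so
that de novo transcriptomes without reference genomes remain comparable:
multicopy OG are quantified as the **sum of raw member-transcript counts**,
which preserves count (negative-binomial) semantics for the downstream
exact test; normalization happens afterwards, per comparison.

## Transcript curation

1. **Top isoform** — per gene, the isoform with maximal mean TPM is kept;
   exact ties resolve to the lexicographically smallest transcript ID.
2. **Redundancy collapse** — greedy longest-first clustering. A candidate
   is absorbed when it is an exact duplicate or substring of a retained
   representative, or when its k-mer containment identity (shared k-mers /
   candidate k-mers, k = 11) reaches the 0.95 threshold. This is a
   desk-scale approximation of reference-based redundancy removal with the
   same threshold semantics: duplicates and near-complete containments are
   removed, sequences differing at ≥ ~1 position per k nucleotides
   (containment ≈ 0.9^k ≪ 0.95 at 10% divergence) are retained. An
   inverted k-mer index keeps this near-linear for realistic inputs.
3. **ORF filter** — all six frames are scanned for complete ORFs (ATG …
   in-frame stop). The span is 0-based half-open on the reported strand
   and **includes the stop codon**, so "≥ 100 nt" means the full ORF
   footprint; codons containing N count as sense codons. The longest ORF
   wins; ties break to the forward strand, then the lower frame, then the
   lower start. 5′-partial (start-less) ORFs are not considered.
4. **Expression filter** — keep features with ≥ 1 cpm in ≥ 3 libraries,
   with cpm computed on **raw** library sizes: the filter precedes
   normalization in the workflow.

Each stage returns a subset of its input and is idempotent. N50 is the
largest length L such that transcripts of length ≥ L contain at least half
of the assembled bases (descending sort and accumulation).

## Differential expression engine

**TMM normalization.** The reference sample is the one whose
75th-percentile count fraction is closest to the sample mean. Per sample,
M (log2 expression ratio versus the reference) and A (average log2
expression) are formed over genes nonzero in both samples; the top and
bottom 30% by M and 5% by A are trimmed (rank-based, ties averaged), and
the remaining M-values are combined with inverse approximate asymptotic
variance weights, (N−y)/(Ny) summed over the two samples. Factors are
rescaled to geometric mean 1. The implementation reproduces the reference
R implementation of TMM to ~1e-12 on integer matrices (cross-checked in
the test suite).

**Dispersion.** Counts are scaled to a common library size. Per feature
and group, the moment identities E[v] = m + φm² and E[m̂²] = m² + v/n give

    raw_i = Σ_g df_g (v_g − m_g)  /  Σ_g df_g (m_g² − v_g/n_g)

(the denominator correction removes the downward bias caused by the noisy
mean estimate). A **common** dispersion pools the same numerators and
denominators across all features — a low-noise, nearly unbiased estimate.
The per-feature value then adapts only upward:

    φ_i = max( common + 0.5 · max(raw_i − common, 0), 1e-4 ).

Rationale: with three replicates per group the per-feature estimate has
~4 degrees of freedom; its downward excursions are dominated by sampling
noise, and feeding them to the exact test inflates the false discovery
rate several-fold, while its upward excursions flag genuinely
hyper-variable features that the test should treat conservatively. In
planted-effect simulations (φ = 0.1, n = 3, 10% of 500 OG at |log2FC| = 2)
this one-sided design attains the power and FDR of the oracle that knows
the true dispersion to within a few percent; symmetric shrinkage designs
we evaluated (toward the median or even toward the truth) did not control
the realized FDR at the nominal level. Degenerate inputs: an all-constant
matrix yields the floor value.

**Exact test.** Counts are equalized to the geometric-mean effective
library size ("pseudo-counts", scale then round half-to-even for
cross-platform determinism). Conditional on the pseudo-count total s, the
group-A total follows the convolution of NB laws, which for proportional
means depends only on the shapes r = n/φ; φ = 0 degenerates to
Binomial(s, n_A/(n_A+n_B)). The two-sided p sums all splits whose
conditional probability is ≤ the observed one (double tail); a relative
tolerance of 1e-10 in log-probability treats numerically equal splits as
ties, and a split at the conditional mode returns exactly 1. Fold changes
are computed from cpm means with a prior count of 0.5 per sample
(direction is B over A). Significance: BH q < α (default 0.01) **and**
|log2FC| strictly > 1 — the strict inequality matters at the boundary.

**Drivers.** DEG: within one species, consecutive segments, TMM computed
on exactly the samples entering the comparison. DEO: between two species
at one matched segment, replicates unpaired, joint TMM over the two
species' samples (a single normalization frame per test). The TF summary
reports (TF among DEO, total DEO, percentage to one decimal, half-to-even).

## Pattern analytics

Profiles are mean TMM-normalized cpm per segment (averaged over
replicates; TMM within species across its 12 samples). z-scores use the
sample standard deviation (n−1); constant profiles map to the zero vector.
A species pair's pattern is **conserved** when Pearson r between
z-profiles is ≥ 0.8 (configurable); constant profiles are conserved with
nothing; an OG is conserved overall when every pair involving the
designated focal species (the C4 species in the standard design) is
conserved. The r-threshold criterion was chosen because it is
reproducible, symmetric in the pair, monotone in profile similarity, and
invariant to per-species affine rescaling of expression level — it
compares the shape of the developmental gradient, not its magnitude.

Pathway DEO tables count significant DEO by direction within a pathway's
tested OG; percentages are 100·count/n rounded half-to-even to one decimal
(computed in exact decimal arithmetic, since binary floats mis-round
values like 46.15). Pathway members absent from the tested set are
excluded with a warning. Heatmap matrices min–max scale each OG row
jointly across all species × segments (constant rows map to 0.5),
mirroring relative-expression displays. Sink/source classification
z-scores each marker profile and labels a segment "sink" when the mean z
of sink markers (cell-cycle, sucrose-synthase-like) exceeds that of source
markers (sucrose transporters, nitrate reductase).

## Enrichment

The GO graph is a DAG (child → parent edge list, multiple parents
allowed), cycle-checked on load, with the true-path rule applied: a
feature annotated to a term annotates all ancestors. Classic enrichment is
the one-sided hypergeometric upper tail of the study/term overlap in the
universe; the universe is the tested (shared-OG) set, not the genome. The
`elim` variant processes terms bottom-up by longest-path depth from the
leaves (deterministic, alphabetical within a level); when a term's p
falls below α its annotated features are removed from all ancestors before
they are tested; global study/universe totals stay fixed, as in the
published algorithm.

PCA operates on log2(cpm+1) of OG expression (features centered, not
scaled — log-cpm is the field convention and unequal feature variances are
informative here) via SVD; variance fractions come from squared singular
values, and each component's sign is fixed so its largest-magnitude
loading is positive. Loading sets take the top and bottom 5% by quantile
with boundary ties included; if ties make the sets overlap, ranks (value,
then feature ID) enforce disjoint sets of at least one feature.

## Synthetic data generator

The generator emulates the study design with planted truth:

* **Structure** — default 500 OG; per-species copy number drawn from
  {1: 0.75, 2: 0.18, 3: 0.07} (configurable over 0–3); 10% of OG are made
  absent in one random species, so ~450 OG are shared; pathway lists are
  drawn from fully shared OG; 6.3% of OG carry a TF flag.
* **Expression** — per-OG baseline log2 relative abundance uniform on
  [0, 8] (about 10–10,000 cpm at the default library sizes, the realistic
  span of an expressed-gene set after cpm filtering). Per-copy offsets
  (±0.5 log2) are drawn **once per OG and shared across species**, so
  species with matching copy numbers are exchangeable — a true
  cross-species null unless an effect is planted.
* **Profiles** — each OG has a class (ascending 0.40, descending 0.25,
  peaked 0.20, flat 0.15 by default) realized as log2 offsets across
  segments with amplitude ±1.5 (an 8-fold base-to-tip span); an optional
  divergence fraction swaps the last species' class to its opposite
  (ascending ↔ descending, peaked ↔ flat) for conservation testing.
* **Effects** — planted (pathway, species, segment, log2FC) entries
  multiply the stated means; the default plants a C4-cycle-style +2 log2FC
  in the C4 species at S5 and S7 on pathway pw01.
* **Counts** — NB(mean = library size × relative abundance, φ) with
  per-transcript φ log-uniform on [0.05, 0.2] (the study does not report
  dispersions; this range spans typical bulk RNA-seq replicates), library
  sizes log-uniform on [0.8M, 1.6M] so normalization matters. φ = 0
  degenerates to Poisson.
* **Nuisance transcripts** — junk transcripts (15% of the pool) have
  target cpm drawn log-uniformly on [0.01, 0.3] and are calibrated exactly
  so their expected cpm stays below 1 in every library (they carry valid
  ORFs, so only the expression filter can remove them); non-coding
  transcripts (8%) are rejection-sampled to contain no ORF ≥ 100 nt;
  truncated isoforms (Poisson rate 0.5 per gene) share the gene's OG and
  have TPM strictly below the top isoform (their count weight scales with
  their length so the TPM ratio equals the drawn fraction < 0.4).
* **Reproducibility** — a single seed is split into four named substreams
  (structure, sequence, expression, counts); identical config + seed gives
  byte-identical outputs.

What the generator does **not** emulate: read-level artifacts (chimeras,
sequencing error, mapping ambiguity), assembly fragmentation,
GC/length-dependent biases, correlated genes (co-expression modules), or
batch effects. Passing recovery tests therefore demonstrates that the
pipeline's inference is correct under its own model assumptions, not that
those assumptions hold for any particular real dataset.

## Problem sizes and determinism

Default simulations use 500 OG (≈ 3,500 transcripts, 36 libraries), the
scale at which every stage exercises its logic while the full test suite
and the acceptance script each run in a few minutes on one CPU; the
statistical behaviour of the engine (calibration, power, FDR) is governed
by per-feature replicate counts and dispersions, not by the number of
features, so conclusions transfer to larger panels. All iteration orders
are sorted, rounding is half-to-even, and the pipeline is deterministic
end-to-end: rerunning with the same seed reproduces every result table
byte for byte (the manifest records the config hash and seed).

## Known limitations

* The redundancy collapse is containment-based; it does not perform full
  banded alignment, so diverged alloalleles below the k-mer containment
  threshold are kept separate by design.
* The exact test treats replicates as unpaired in cross-species
  comparisons; within-species pairing of segment pools is not modeled.
* The one-sided dispersion shrinkage trades a little power (a few percent
  in simulations) for realized FDR control with n = 3; with many
  replicates a symmetric empirical-Bayes scheme would be preferable.
* `elim` is the only topology-aware enrichment variant provided; weight
  and parent-child algorithms are out of scope.
* The conservation call uses 4-point profiles; with so few segments the
  Pearson r of noisy profiles is itself noisy, and rates should be
  interpreted over sets of OG, not per OG.
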