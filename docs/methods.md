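# Methods

This note records the models, conventions and numerical choices behind
`minorintron`, and what the synthetic-data tests do and do not establish.

## Intron extraction and summary statistics

Annotations are read through gffutils; GTF is accepted via its feature model.
Coordinates are 1-based inclusive at the GFF3 boundary and 0-based half-open
internally; everything reported is 1-based inclusive.  One isoform per gene is
kept: the one maximising coding length (sum of CDS segment lengths), ties
broken by lexicographically smaller transcript id — the tie-break is a
determinism choice, nothing more.  CDS features without an mRNA parent are
attached to their gene permissively and logged; CDS segments outside their
contig void the gene (logged).

Introns are the gaps between consecutive CDS segments in transcription order;
transcripts without CDS fall back to exon gaps, and such exon-defined (UTR)
introns carry no phase and are excluded from phase, conservation and all
comparative analyses — they only enter per-genome totals.  Minus-strand
sequence is reverse-complemented, so termini are always sense-strand.  Introns
shorter than 30 nt are discarded (annotation gaps that short are mostly
artifacts, and the scorer's windows would not fit).  Phase is the cumulative
preceding coding length mod 3; relative position is that length divided by the
transcript's coding length; genic intron density is introns × 1000 / coding
length (introns per kbp of coding sequence).

A CT-AC terminus is the exact reverse complement of GT-AG, so a CT-AC fraction
above 1% triggers a wrong-strand warning.

## Minor-intron scoring

The classifier is a deliberately transparent stand-in for SVM-based intron
classifiers: two log-odds features and a monotone percentile calibration.

* **Donor (5′SS)**: the first 8 intronic nt scored as log2 odds of the
  minor-donor PWM against the major-donor PWM.  The window is intron-only
  because the scoring interface guarantees no exonic context; donor
  information for minor introns is concentrated in positions +3..+8
  (the ATCCTT core), so the restriction costs little.
* **Branch point**: a 9-nt PWM scored against background composition at its
  best placement between 40 and 5 nt upstream of the acceptor.  Training
  bootstraps the BPS model from the canonical offset (ending 12 nt before the
  3′ end) and re-estimates once from each reference intron's best window.
* **Calibration**: the combined log-odds is mapped to its percentile (weak
  inequality) in the pooled minor+major reference set, giving a *minor score*
  in [0, 100].  By construction, scoring the reference pool at threshold *t*
  calls ~(100 − t)% of it minor; an intron is minor iff score > threshold
  (default 90; per-species overrides such as 95 are supported).  PWMs use a
  pseudocount (default 0.5); a pseudocount of 0 with an unseen base is a
  training error rather than a silent −inf.

The packaged reference sets (`data/*_ref_synthetic.fa`) are **synthetic**
draws from the package's own motif model (250 per class, 60–119 nt); they make
the default model self-contained and deterministic but are not curated
biological introns — for real surveys, train on a curated reference for the
clade of interest.

**Boundary correction.**  If an intron's termini are non-canonical (5′ not in
{GT, GC, AT} or 3′ not in {AG, AC}), candidate shifts of up to ±10 nt slide
both boundaries together (length preserved); a shift is accepted when the
candidate donor's raw minor log-odds (vs background) reaches the 95th
percentile of the minor reference's donor scores — a deliberately conservative
"strong donor" cutoff, configurable because no published criterion exists.
Best-scoring candidate wins; ties go to the smallest shift.  Canonical introns
are never touched.

## Species curation

Presence: corrected-call fraction ≤ 0.25, ≥ 3 minor calls, ≥ 2 of the four
minor snRNAs (an snRNA is present given ≥ 1 covariance-model hit at
E ≤ 0.01 in the consumed table).  Absence: either (≤ 3 minor calls and < 2
snRNAs) or (≤ 5 minor calls, < 2 snRNAs, < 5 uncorrected AT-AC calls, and
RefSeq provenance or BUSCO ≥ B_Q1 − 1.5·B_IQR for the species' clade).
Clade quartiles use linear interpolation (type 7) — the most common default,
stated here because quartile conventions differ.  A would-be absent species
with minor-intron density ≥ 1% is demoted to uncertain: with massive total
intron loss, a handful of false positives can masquerade as an outstandingly
high minor intron density.  The first absence clause counts **all** minor
calls, corrected or not; the presence and absence clauses are disjoint by the
snRNA conditions, so no evidence vector can satisfy both (fuzz-tested).

## Orthology and conservation

Reciprocal best hits are computed per species pair from 12-column tabular hits
at E ≤ 1e-10; best = maximum bitscore, ties to the smaller subject id.
Maximal cliques of the RBH graph (networkx) are ortholog clusters; for
three-species reconstructions a cluster must span all three species with one
gene each — the estimator needs a state in every species.  Restricting the
search to a gene subset (e.g. minor intron-containing genes) provably yields
the matching subgraph of a full run and is available as an option.  A toy
k-mer-containment scorer stands in for the external similarity search in
synthetic end-to-end tests only.

Intron positions map into protein alignments by residue: a phase-0 intron
after *k* coding nt sits at the codon boundary following residue k/3; phase
1/2 introns sit inside residue ⌊k/3⌋ + 1.  Two introns are the same site iff
same alignment column **and** same phase — an intron at the same column but a
different phase interrupts different codon positions and is treated as a
distinct site.  Local alignment quality requires, for each sequence pair, the
10 columns ending at the site and the 10 following it to be gap-free with
≥ 40% identity, each side tested separately (the strictest reading of an
"ungapped window" requirement; both window length and identity are
configurable).  Intron sliding is not modelled: a slid intron is counted as a
loss.

State calling uses two regimes: ordinary conservation counts call minor at
score > 90; conversion analyses demand major ≤ 60 and exclude any site
containing a borderline score in (60, 90], so borderline minors cannot
masquerade as conversions.  Cross-alignment intron clusters (connected
components of the intron-sharing graph, with hub species linking alignments
transitively) feed the non-canonical termini tallies; a cluster contributes
only if it carries at least two introns of the focal type, suppressing lone
false positives.

## Ancestral reconstruction

For sister species α, β with outgroup γ, introns of one type shared by any two
species are ancestral to the α/β split (parallel gain assumed negligible —
well supported for minor introns).  Retention in β is P̂_β = N_αβγ/N_αγ, and
solving N_αβγ = N_Ω·P̂_α·P̂_β·P̂_γ gives N̂_Ω = N_αβ·N_αγ·N_βγ/N_αβγ².  The
estimator runs separately for minor and major introns among sites passing the
quality filter; the ancestral minor density is the minor share in percent.
Estimates stay real-valued internally and are rounded to integers for
reporting; the reported density is computed from the rounded counts, matching
how such chains are conventionally printed.  Densities are normalised to a
reference species' minor density in the same aligned genes (the aligned gene
set differs per species combination, so the raw percentage is not comparable
across combinations), and combinations are aggregated as an unweighted mean ±
SEM (sample sd, n − 1); combinations with N_αβγ = 0 are dropped — the
estimator is undefined there, and treating them as zero density would bias the
mean.  Monte-Carlo tests show the estimator's mean relative error is within
2% at 5000 ancestral introns per type and retention in [0.6, 0.95] (200
replicates).

The loss decomposition conditions on introns present as the focal type in
both the sister and the outgroup and splits the focal species' fates into
retained / converted / deleted.  Conversion estimates are conservative: a
conversion followed by deletion is indistinguishable from plain deletion.

## Statistical battery

* Fisher 2×2: exact hypergeometric, minimum-likelihood two-sided, summed in
  log space relative to the largest retained term so p-values of order 1e-70
  stay finite; verified against exact-rational enumeration of the full support
  for every table with total ≤ 100.  A tie tolerance of 1e-9 in log space
  absorbs floating-point ties across the support.
* Binomial: the standard two-tailed exact test (minimum-likelihood), verified
  against direct pmf enumeration for all n ≤ 50.
* The 5′ bias battery flags a species only when the binomial test (5′-half
  occupancy of minor introns), the Mann–Whitney U test (minor vs major
  positions; exact below n = 21, asymptotic above) and the median direction
  all agree at α.  Batch mode reports uncorrected flags and flags recomputed
  from Benjamini–Hochberg-adjusted p-values, since conclusions can differ
  between the two.  Null calibration is assessed on the component tests: the
  conjunction flag's null rate is necessarily far below α (it is an
  intersection of correlated significance events plus a direction), so the
  meaningful calibration check is that each component rejects at ~α and the
  conjunction at ≤ α.
* Phase-0 comparisons between species use Boschloo's exact unconditional test
  (scipy), with a Fisher fallback flagged in the output for degenerate tables.
* MIG vs non-MIG comparisons (genic density, coding length) use two-sided
  Mann–Whitney U per species, excluding species with fewer than ten minor
  introns; an optional age-category column stratifies the comparisons with BH
  correction across all tests.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure the analyses assume, with
one shared seeded RNG per call and byte-identical reruns:

* **Toy genomes**: alternating-strand single-isoform genes, exon lengths
  36–120 nt (multiples of 3), intron lengths 60–119 nt, donor/branch-point/
  acceptor sequences drawn from per-type position frequency matrices (default:
  realistic entropic motifs around the GTATCCTT / TTCCTTAAC minor consensus
  and GTAAGT major consensus; consensus-exact variants for separability
  fixtures).  Each intron's type is an independent Bernoulli(minor_fraction)
  draw.  A wrong-strand fraction mis-labels the annotation strand while
  leaving sequence and coordinates intact.
* **Three-taxon evolution**: independent per-lineage, per-type retention;
  conversion applies only to minor introns that survive in a lineage —
  conversion is a fate of a present intron, not a loss — and converted introns
  are present-as-major, never minor.  No parallel gain.
* **Junction counts**: intron–exon junctions Poisson(depth × retention),
  exon–exon Poisson(depth × (1 − retention)) — the simplest model whose
  expected splicing efficiency equals 1 − retention.
* **Expression matrices**: per-gene log-normal baselines with multiplicative
  noise (2^N(0, 0.25)); proliferation-index genes multiplied by the effect
  size in the designated proliferating cell type's samples; effect size 1 is
  the null.

These fixtures deliberately omit sequence evolution (substitutions, indels),
read-level noise, alignment error, annotation incompleteness, paralogy and
rate heterogeneity across genes.  Passing tests therefore establish that the
estimators and decision rules are implemented correctly and behave as derived
under their own assumptions — not that those assumptions hold in any real
genome; real-data conclusions inherit the caveats of the upstream annotation,
alignment and search tools.

Problem sizes in the test suite (e.g. 5000 ancestral introns per type × 200
replicates for estimator recovery, 1000 simulated species for null
calibration, 2000 ancestral minors for the loss decomposition) were chosen so
Monte-Carlo error is small relative to the tolerances being checked while the
whole suite stays desk-scale.

## Known limitations

* The classifier is behaviourally, not numerically, equivalent to SVM-based
  intron classifiers: threshold semantics, correction flags and percentile
  scores match in kind, but scores are not interchangeable with other tools'.
* The percentile calibration depends on the composition of the reference
  pool; the packaged synthetic references are balanced (50/50), which is
  conservative at the default threshold.
* Exact unconditional (Boschloo) comparisons and Mann–Whitney asymptotics
  follow scipy's implementations, including their edge-case behaviour.
* One printed literature value is not exactly reproducible from its own
  printed 2×2 counts: the corrected clade-enrichment table [[11, 279],
  [0, 1288]] has an exact two-sided p of 6.90e-9 (enumeration-verified); the
  published 6.81e-9 corresponds to a background total of ~1290, so the
  original test evidently used slightly different margins than the printed
  per-clade rows.
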