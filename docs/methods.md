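# Methods

`aquadetect` implements the computational core of a common workflow in
bacterial taxonomy and freshwater microbial ecology: deciding, from shotgun
metagenome read mapping, whether a newly described species is present in an
environmental sample, and deciding, from whole-genome comparisons, whether
two strains belong to the same species. Everything is testable offline
because a synthetic-community module generates genomes, divergent
relatives, shared repeats and labelled reads with the statistical structure
the analyses assume.

## Detection model

### Coverage breadth and depth

Reads are placed on a concatenated reference containing all candidate
type-strain genomes, with ribosomal-operon-like repeats masked (they are
near-identical across species and attract cross-mapping). For each genome:

* **breadth** = percentage of unmasked positions with depth ≥ 1
  (configurable via `min_depth_for_breadth`);
* **depth** = mean mapped-read bases per unmasked position;
* **mapped-read %** = mapped reads / total reads of the metagenome, the
  relative-abundance proxy.

The identity filter on read placements defaults to 95%, mirroring the
species demarcation threshold: reads from a different species (ANI ≤ 95%)
should mostly fail it. Identity is matches/aligned-length over an ungapped
extension (internal mapper) or `(aligned_length − NM)/aligned_length`
(SAM import), applied post hoc, the way such filters are realized on top of
standard mappers.

### The breadth-threshold curve

Under Poisson (Lander–Waterman) coverage a genome truly present at mean
depth *d* reaches an expected breadth of `100·(1 − e^(−d))`; reads
cross-mapped from a relative instead plateau at the conserved (core)
fraction of the genome regardless of depth. The detection rule exploits
this difference:

1. breadth > 50% → detected (primary rule, strict inequality);
2. otherwise, detected iff breadth ≥ a floor **and** breadth strictly
   exceeds `threshold(d) = a·b^d + c` with `a < 0`, `0 < b < 1`,
   `0 < c ≤ 100`.

The default (published) curve is `−255.58 · 0.358^d + 75.27`; its asymptote
`c = 75.27` reflects the core-genome fraction of the calibration strains.
The curve can be re-calibrated on any deeply covered genome set:
`subsample_series` stepwise-reduces the mapped reads (nested subsamples, so
each series is monotone by construction; independent redraws behind a
flag), `fit_saturation` fits the exponential by bounded nonlinear least
squares (SciPy trust-region reflective; multi-start with
`c₀ ∈ {max breadth, 75, 95}`, `b₀ ∈ {0.2, 0.358, 0.6}`,
`a₀ = min breadth − c₀`; tolerances 1e−12, ≤ 5000 evaluations), and
`select_min_asymptote` keeps the most conservative curve (smallest *c*,
ties by genome id).

The secondary branch needs a guard against vacuous detections at very low
breadth, where the curve is far below zero. The source wording for this
guard is ambiguous ("breadth … is at least tenfold"), so both readings are
implemented: the default is a breadth floor of 10 percentage points
(`floor_pct`); a minimum mean-depth condition is available instead via
`min_depth`. Neither reading is asserted as the original intent.

Default subsampling fractions are
{0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0}; the original step sizes are
not published, and these span two orders of magnitude of depth, which is
what the fit needs.

## Species demarcation

* **ANI** (`fragment_ani`): fragment-based (ANIb convention) — 1020 bp
  consecutive query fragments, placed on the subject by exact 15-mer
  seeding and ungapped full-fragment scoring over candidate diagonals, kept
  at ≥ 70% identity over ≥ 70% coverage; ANI = mean kept-fragment identity
  averaged over both directions. This is a gene-free reimplementation of
  the gene-based gANI services; on real genomes the two differ by a few
  tenths of a point.
* **dDDH** (`gbdp_d4`): GBDP-style d4 distance, `1 − Σidentities/ΣHSP
  length` over seeded ungapped HSPs (identity ≥ 50%, coverage ≥ 0.7),
  symmetrized. The d4→DDH% transform is a logistic
  `100/(1 + exp(−5 + 83.05·d4))` shipped as configuration data
  (`taxonomy.DDH_LOGISTIC`). Its constants are this package's own
  calibration: anchored so d4 = 0.05 — the divergence at the 95%-ANI
  species boundary — maps to exactly 70% DDH (the DDH species threshold),
  with d4 = 0 mapping to ≈ 99.3%. It preserves the decision boundary and
  monotone ordering, which is what the demarcation rule consumes; it is
  *not* a reproduction of any web service's regression, and absolute DDH
  percentages away from the boundary should not be compared against such
  services.
* **16S identity**: Biopython global alignment, identity over aligned
  columns after trimming terminal-gap columns (so a shorter exact substring
  scores 100%), matching the align-then-trim convention for marker genes.
* **Rule**: same species ⇔ ANI ≥ 95 **and** dDDH ≥ 70 (inclusive). 16S ≥
  98.7% is recorded as "inconclusive — genome indices required": in this
  genus distinct species share 99.3–100% 16S identity, so 16S can exclude
  but never establish conspecificity.

## Phylogenetics

* **K2P distance** with pairwise deletion: sites where either row is not an
  unambiguous A/C/G/T are dropped (gaps, N and ambiguity codes alike);
  `d = −½ln(1−2P−Q) − ¼ln(1−2Q)`. Gamma rate-heterogeneity correction uses
  the standard one-parameter form; no shape value is published for the
  original setting, so the shape is an explicit argument. Saturated pairs
  raise an error naming the pair rather than returning infinity. A minimum
  of 50 comparable sites is required (configurable).
* **Neighbour joining** (Saitou–Nei), implemented in-package because tie
  breaking and negative-branch handling are part of the contract: minimal-Q
  pair with ties by lowest node-creation index; negative intermediate
  branch lengths clamped to zero with the remainder moved to the sibling
  edge; unrooted trifurcating root. On additive matrices the algorithm is
  exact (verified against random trees and against scikit-bio's NJ).
* **Bootstrap**: column resampling with replacement; support = % of
  successful replicates containing each internal bipartition of the
  full-data tree; saturated replicates are dropped and counted (warning
  above 5%). For an alignment of identical sequences every branch length is
  zero — a star in the metric sense — though the arbitrary zero-length
  topology produced by deterministic tie-breaking is retained.
* **Midpoint rooting**: longest tip-to-tip path (ties: lexicographically
  smallest tip pair), root inserted at its midpoint; all pairwise tip path
  lengths are preserved.
* **Core genes**: greedy centroid clustering of proteins (longest-first,
  best centroid hit ≥ 70% global identity, BLOSUM62 scoring), core =
  present in 100% of genomes; per-family center-star alignment of one
  representative per genome, concatenated in stable family order. The
  center-star aligner is a deliberately simple progressive aligner, not a
  general MSA tool.
* **Conserved-block filter**: a simplified Gblocks-like column filter —
  columns with gap fraction > 0.5 removed, surviving runs shorter than 10
  columns removed. No attempt at option parity with Gblocks.

## Synthetic data

The generator defines the conditions under which the pipeline is tested:

* genomes are i.i.d. base sequences at a set G+C fraction (default 0.42,
  typical of the relevant genus branch);
* relatives are made by per-site substitution, uniform over the three
  alternative bases (no transition/transversion bias — the simplest null;
  K2P remains well-defined on such data), so expected identity is
  100·(1−r)%;
* a shared repeat (rRNA-operon analogue) can be planted into every genome,
  recorded in masked intervals;
* reads follow Lander–Waterman: origins ∝ abundance·length, uniform starts
  over full-length positions, either strand, i.i.d. substitution errors;
  default read length 150 bp (2×150 bp sequencing is the norm for the
  relevant genome projects; the original read QC is unpublished). No
  indels, chimeras, GC-biased coverage or paired-end structure — the 95%
  identity filter here is a substitution-identity notion, and those
  features are out of scope.

Truth labels ride in read ids (`…|genome|contig|start|strand`) and survive
FASTA/FASTQ/SAM round-trips. Consequently, passing tests demonstrate
correctness of the *method* under its own model assumptions; they do not
demonstrate robustness to indels, mapping bias, conserved-region mosaicism
or uneven real-world coverage.

## Numerical and design choices

* Coordinates are 0-based half-open internally; SAM ingestion converts from
  1-based. Reverse-strand placements are reported in forward coordinates.
* Mapper seeds: exact 31-mers, one per read end, both strands; candidate
  loci capped at 64; ties broken by lowest global reference coordinate.
  Adequate for ≥ 95% identity at 150 bp; `k` is configurable.
* A fully masked genome reports breadth 0 with a warning, never a division
  error.
* Flat saturation series and non-convergent fits raise a diagnostic-carrying
  error rather than returning a degenerate model.
* `ThresholdModel` serializes to JSON with the constants bit-exact.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical genomes,
  reads and TSV outputs.

## Problem sizes used in the test suite

Unit and property tests run on deliberately small instances chosen to keep
statistical bounds tight while staying quick: 200 kb genomes for the
coverage-law checks (3 pp tolerance vs the Poisson expectation), 500 kb
genomes for ANI recovery (0.5 pp tolerance), 100 seeds for the NJ
exactness and noisy-calibration recoveries, and ~60 kb genomes for the
end-to-end detection audit. These sizes are the package's own choice of
smallest-instance-with-adequate-power.

## Known limitations

* The internal mapper is ungapped and single-hit; it is not a replacement
  for a production aligner on real data (use SAM import for that).
* Fragment ANI assumes collinear, substitution-divergent genomes when run
  on synthetic data; rearranged real genomes rely on per-fragment seeding
  and may lose a few fragments at breakpoints.
* dDDH percentages are calibrated to the decision boundary, not to any
  external service (see above).
* The center-star aligner and the block filter are simplified stand-ins
  adequate for the pipeline's own outputs, not general-purpose tools.
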