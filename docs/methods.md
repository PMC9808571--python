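# Methods

## Cleavage-site model

A PIWI protein loaded with a guide piRNA recognises a precursor transcript
through base pairing. Guide positions are numbered g1…g21 from the guide's
5′ end; with t1 the 1-based target coordinate opposite g1, guide position
*i* is compared with target position t1 − (*i* − 1). A candidate cleavage
site requires perfect Watson–Crick pairing (A:U, G:C) across the seed
g2–g7, and at least `min_pairs` (default 10) further pairs within g8–g21.
g1 is never evaluated: PIWI proteins bind the guide's first nucleotide in a
protein pocket, and the criteria are phrased over g2–g7 and g8–g21 only.

PIWI slicing cuts the phosphodiester bond between the target nucleotides
opposite g10 and g11 — i.e. between positions t1 − 10 and t1 − 9 — the
canonical slicing geometry of Argonaute-family nucleases. The responder
piRNA's 5′ end is therefore t1 − 9, which places the guide's g1–g10 exactly
over the responder's first ten nucleotides (the ping-pong 10-nt 5′
overlap). A site counts as *verified* only when an observed piRNA 5′ end
from the target locus equals t1 − 9 exactly; no positional tolerance is
allowed, because the overlap signature is defined at single-nucleotide
resolution.

Design choices where the procedure was genuinely open:

* **Wobble policy.** Pairing is Watson–Crick only by default. An optional
  flag admits G:U wobble within g8–g21 (never in the seed, where the
  criterion is stated as complete complementarity). The default is the
  conservative reading; the flag exists because PIWI targeting tolerates
  wobble in vitro.
* **Guide species.** Guides are deduplicated by exact sequence before
  counting, with read counts summed; "n guides" in edge summaries counts
  distinct sequences. No minimum guide abundance is imposed by default
  (`min_guide_rpm = 0`, configurable).
* **Observed 5′ ends** are pooled across genotypes, and any piRNA with a
  positive read count contributes its 5′ position; a minimum-support
  threshold is deliberately not imposed (permissive default, configurable
  upstream by filtering the count table).
* Overlapping sites are all reported: every passing anchor t1 is an
  independent prediction.

Scanning is vectorised: the reversed complement of a guide's first 21 nt is
compared against all length-21 windows of the target at once, so the
exhaustive per-anchor scan is O(21·L) per guide with numpy throughput. A
literal per-position brute force serves as the test oracle.

## Promoter occupancy

Distances are measured from a gene's TSS (1-based; interval start + 1 on
the + strand, interval end on the − strand) to the nearest peak summit on
the same chromosome, as absolute values — reported distances are
non-negative and strand does not flip the sign. Summits come from the
narrowPeak offset column where available; summit-less (SEACR-style) BED
intervals use the interval midpoint, floor((start + end)/2). The midpoint
rule is this package's choice — summit reduction for such peaks has no
standard — and is isolated in the reader so it can be swapped.

The ±500 bp window is inclusive (distance ≤ 500 passes), matching the
plain-language reading of "within". The replicate consensus for calling a
promoter bound:

* **TCFL5** — a within-window peak in both CUT&RUN replicates (evidence
  `cutrun_both`), or in at least one CUT&RUN replicate together with
  within-window peaks in ≥ 2 of 3 ChIP-seq replicates
  (`cutrun_plus_chip`).
* **A-MYB** — identical, with the single ChIP-seq replicate standing in
  for the 2-of-3 requirement.

ChIP replicate agreement is evaluated per replicate against the window
(peaks need not overlap each other), and ChIP-only evidence never suffices.
Rule (i) takes precedence for the evidence label when both apply. The rule
is property-tested against exhaustive enumeration of all 2²×2³ (TCFL5) and
2²×2 (A-MYB) replicate patterns.

## Quantification and dependence classes

rpm = reads × 10⁶ / genome-mapping reads; RPKM = reads × 10⁹ /
(genome-mapping reads × feature length in nt). Absolute abundance uses the
ERCC spike-in proportionality with 623,291,645 spike molecules per library:
molecules/cell = reads × 623,291,645 / (cells × spike reads). Small-RNA
absolute quantification reuses the same proportionality with the spike
molecule count supplied in configuration.

Fold-changes are (mutant + pc)/(wild-type + pc) on rpm values with a
pseudocount pc = 0.1 rpm by default; with both terms zero and pc = 0 the
ratio is undefined and recorded absent (such genes are never classified).
Classes, with threshold *T* = 2:

* `TCFL5_dependent`: TCFL5-bound ∧ fc_precursor < 1/T ∧ fc_piRNA < 1/T.
* `AMYB_dependent`: A-MYB-bound ∧ 1/T ≤ fc_precursor ≤ T. "Essentially
  unchanged" is operationalised as within twofold (|log₂ fc| ≤ 1); no
  number is standard, so T is exposed in configuration.
* `AMYB_dependent_biogenesis_defect`: A-MYB-dependent as above, with
  fc_piRNA ≤ 1/T — transcription persists while piRNA output collapses,
  the signature of a missing initiator.
* `unassigned` otherwise; `TCFL5_dependent` wins when both definitions
  hold.

The initiator→responder network runs TCFL5-dependent guides against the
biogenesis-defect precursors (forward) and A-MYB-dependent guides against
TCFL5-dependent precursors (reverse) — the same code path with swapped
class arguments. Genes appearing in both classes are excluded from both
sides and logged; self-edges are dropped.

## Exact statistics

Fisher's exact test is two-sided by the sum-of-small-p convention: sum the
hypergeometric probabilities of all tables with the observed margins whose
probability does not exceed the observed table's. This is the convention of
R's `fisher.test` (the environment in which such analyses are typically
run) and is what reproduces the worked 2×2 example (p = 0.0278 → printed
0.028). The implementation compares exact integer numerators over the
common denominator C(N, row1), so probability ties are exact rather than
subject to a floating-point tolerance; the test suite checks it against an
independent rational-arithmetic enumeration for every table with N ≤ 30.
The hypergeometric pmf is computed in log space (gammaln) and normalises to
1 within 10⁻¹².

χ² enrichment is Pearson's statistic on the implied 2×2 with 1 df and no
continuity correction; a zero expected cell is a hard error that advises
the exact test. Spearman's ρ is the Pearson correlation of average ranks
(ties averaged) and is undefined (recorded absent) for constant vectors.
Box summaries use type-7 (linear-interpolation) quartiles — no quantile
method is standard for these plots, and type-7 is the default of the
mainstream statistical environments — with outliers strictly beyond
Q1/Q3 ∓/± 1.5 × IQR and whiskers at the most extreme non-outliers. Raw
p-values are reported throughout; no multiple-testing correction is
applied anywhere.

## Synthetic cohort

The generator produces the study's statistical skeleton at desk scale, from
one seeded `numpy` generator (byte-reproducible outputs):

* 100 pachytene piRNA genes with 800-nt precursors of uniform-random
  sequence, 14 piRNA-biogenesis genes, 40 background genes, laid out on
  four chromosomes 60 kb apart.
* 25 piRNAs per locus, lengths 26–30 nt, 5′ positions uniform; per-locus
  abundance log-normal (median 2,000 reads, σ = 1 — heavy-tailed, as locus
  abundances are, without claiming distributional fidelity); read counts
  Poisson around expectation, or the expectation itself in
  `count_noise="none"` mode for parameter-recovery checks.
* Dependence classes planted as 30/25/10/35 (TCFL5-dependent /
  A-MYB-dependent / biogenesis-defect / unassigned), with fold-changes
  drawn inside each class's defining region with a margin from the twofold
  boundary (e.g. 0.20–0.35 for dependent precursors, 0.80–1.20 for
  "unchanged"), so classification is exact on noise-free expectations and
  robust at the simulated depths under Poisson noise. Conservation labels
  correlate with class (TCFL5-dependent loci murine/mouse-only;
  A-MYB-dependent mostly eutherian), mirroring the young-vs-old gene
  structure the statistics probe. rpm totals are emitted equal across
  genotypes: piRNA loci are a minority of genome-mapping reads, so library
  depth is treated as fold-change-neutral.
* Peaks are placed at drawn summit distances realising each consensus
  pattern (both-CUT&RUN; one CUT&RUN + 2/3 ChIP; one replicate absent;
  unbound variants including all-far peaks), cycling through the variants
  so every branch of the rule is exercised; biogenesis promoters get
  TCFL5 summits centred on the TSS.
* Cleavage planting: 10 forward edges (TCFL5-dependent →
  biogenesis-defect loci) and 5 reverse edges with full 14-pair
  complements, plus decoys with nine g8–g21 pairs and with broken seeds.
  Each planting reserves its guide and target windows; unpaired positions
  receive the guide's own base, which pairs under neither the
  Watson–Crick nor the wobble policy. The responder piRNA (5′ end t1 − 9)
  and the guide are added to the read sets with guaranteed support.
* **Scrub pass.** Uniform background sequence still yields chance
  pass-and-verify sites at these scales (≈10⁻⁷ per guide–anchor pair,
  ~10⁸ pairs). After planting, the generator scans every non-self
  guide-gene → target-gene combination and breaks each accidental hit with
  a single seed-opposite substitution outside all reserved windows,
  iterating to convergence. Planted windows are reserved and untouchable,
  so the cohort's verified sites are exactly the planted truth for any
  downstream class assignment. This is sanitisation of chance hits, not
  derivation of truth from the predictor.

What the simulation does *not* emulate: genome alignment artifacts,
multimapping, PCR duplicates, sequence composition bias, piRNA 5′/3′-end
heterogeneity around a shared cleavage site, and dispersion beyond Poisson.
Passing the recovery tests therefore demonstrates correctness of the
pipeline's logic under its stated assumptions, not performance on real
libraries, where near-threshold pairing and end heterogeneity will blur the
planted/decoy distinction.

## Problem sizes and numerics

Default analysis scales — 100 loci × 800 nt precursors, ~2,500 piRNA
species, an exhaustive exact-test sweep at N ≤ 30, 200 random
oracle-comparison instances — were chosen as the smallest sizes that
exercise every code path and statistical regime at comfortable margins.
Degenerate inputs are handled explicitly: empty observed-end sets never
verify; genes without a same-chromosome peak are unbound with distance
absent; all-zero contingency tables return p = 1 by convention (logged);
constant vectors make ρ absent; distance ties break toward the leftmost
summit, and peak-file ordering never affects results.
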