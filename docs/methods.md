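# Methods

## Physical model of the simulator

A library is a population of `n_molecules` full-length copies of the
reference. Each molecule receives double-strand sonication cuts drawn as a
Poisson process with rate `1/mean_fragment_len`, the simplest model giving
approximately exponential fragment lengths; chromatin structure and
sequence-dependent shearing bias are not modeled, so the background 5′
counts are Poisson across positions. A fraction `imprint_fraction` of
molecules carries the nick: their nicked strand is additionally severed at
the exact nick coordinate (so a 5′ end exists there in every imprinted
molecule), and with probability `opposite_break_prob` the intact strand
breaks once at a position drawn uniformly inside a `weakened_window`-wide
zone centered on the nick — left of, across, or right of it. Window
placement and width are configuration knobs.

Each strand is then fragmented by the union of the shared cuts and its
strand-specific breaks; every internal 5′ end emits one read of
`read_length` nt, truncated at the fragment's other end. Two deliberate
departures from a literal protocol:

* **Molecule termini are not sequenced.** The ends of a full-length genome
  copy have no analogue at an interior locus of a real chromosome; emitting
  reads from them would stack artifactual strand-exclusive spikes at
  coordinates 0 and L.
* **No aligner is run.** Reads carry their true coordinates; a read whose
  interval lies inside a *repeat block* (a maximal stretch of the
  construction whose sequence occurs more than once in the genome) is
  assigned MAPQ 0, all others MAPQ 60. This reproduces the
  "no unique mapper inside duplicated cassettes" behaviour
  deterministically. The rule is exact for the default 130-nt reads; reads
  longer than the shortest overlap between adjacent repeat blocks could in
  principle be misclassified.

Defaults and why: `n_molecules` 200,000 and `imprint_fraction` 0.3 define
the study conditions used throughout the tests (the imprinted fraction in a
real culture is not a measured constant; 0.3 is a plausible steady-state
value and is configurable). `mean_fragment_len` 300 nt matches the
100–500 bp range ChIP sonication targets. `weakened_window` 20 nt is the
width of the preferential-breakage zone; `opposite_break_prob` 0.8 reflects
that a single-strand region abutting a persistent free end is mechanically
fragile and breaks in most molecules — it scales the height, not the
width, of the opposite-strand zone. `read_length` 130 nt matches the
single-end sequencing mode the analysis is designed for.

## Reference anatomy

Donor-less genomes are `flank | H2 (135 nt) | allele | H1 (59 nt) | flank`
with the ground-truth nick at the allele/H1 junction (the coordinate of the
5′ end created on the Watson strand). The M and P alleles differ in length
by 3 nt, so the junction — and hence the nick — moves by exactly 3 nt
between alleles while the left anatomy is identical. `h90` genomes carry
three cassettes (mat1: H2-allele-H1; mat2P and mat3M: H3-H2-allele-H1) with
verbatim-shared boxes, creating the multi-mapping ambiguity of the real
locus. Box and allele sequences are synthetic random sequences of the
correct lengths; flanks and spacers are random with a builder seed.
Intervals are 0-based half-open everywhere in the API; the TSV report is
1-based.

## 5′ counts

Forward reads count at their leftmost aligned base; reverse reads at their
rightmost aligned base (`end − 1`), which is the biological 5′ terminus.
Duplicate reads are retained on purpose: the signature *is* a pileup of
identical 5′ ends, and deduplication would erase it. The optional MAPQ
filter (default threshold 10 when enabled) is off by default for donor-less
genomes, which contain no repeats. All statistics run on raw integer
counts; counts-per-million normalization exists only for track export and
is rejected by the fitting and screening functions.

## Null model and p-values

Per-position counts of one strand over the fit region (≥ 1000 positions,
zeros included — excluding them would bias the mean upward) are fitted with
a negative binomial by profile maximum likelihood: the mean MLE is the
sample mean for any r, so the optimization is one-dimensional in log r,
initialized at the moment estimate. If the sample variance does not exceed
the mean (or the fitted r exceeds 1e8) the model is the Poisson limit,
recorded as such.

Window sums over w positions are tested against NB(w·r, p) (or
Poisson(w·μ)), i.e. neighboring positions are treated as independent; no
dependence model is asserted by the data, and positive autocorrelation
would make the reported p-values anti-conservative — a known limitation.

Tail probabilities are computed in log space. Where the direct survival
function is representable (> 1e-280) its log is used; deeper in the tail
the pmf terms are summed with `logsumexp` in geometric blocks with a
geometric-series bound on the remainder, so −log10(p) values in the
thousands are exact rather than saturating. This matters because at
realistic simulation depths the signal windows sit far below the smallest
positive double: clamping them to a common floor would create ties across
window sizes and scramble the best-window geometry. The *linear-scale*
p-value accessors floor at 1e-300 simply to return a positive float.

## Scan and caller

The scan is start-registered: a window is `(start, size)` covering
`[start, start+size)`, so offsets to an anchor are unambiguous (0 when the
window covers the anchor, positive/negative when it lies right/left of it).
Ties in −log10(p) are broken toward smaller size, then smaller start. Base
10 is used for all log-p reporting.

The genome screen Bonferroni-corrects over N = 2 × genome length tests
(every position on each strand) at `alpha` (default 0.05); significant
positions within 50 nt merge into regions. A region is *symmetric* when the
opposite strand holds an overlapping/nearby significant region whose
per-position peak is at least 0.25 of its own peak — the signature of
collapsed repeats, which inflate both strands comparably. The factor-4
margin separates that class cleanly from the nick, whose opposite-strand
zone is ~weakened_window-fold weaker per position than the spike; a very
narrow weakened zone (≲ 5 nt) would blur this distinction.

A nick call requires: a strand-exclusive spike region; a scan of the
opposite strand (±1 kb, sizes 1–40) against a null refitted locally on
±5 kb — matching the practice of judging the locus against its local
background — whose best window (a) has size in [2, 40], (b) is Bonferroni
significant across the scan's cells at `alpha`, and (c) overlaps the spike
± its own size ("facing" the break). The nicked strand is the spike strand.

## What the simulations do and do not show

Passing parameter recovery here demonstrates that the statistics and
geometry of the method are implemented correctly: the one-nucleotide
optimum on the nicked strand, the opposite-strand optimum tracking the
weakened-zone width (17–23 nt around the configured 20), the 3-nt allele
offset, clean negative controls, and conservative tail calibration. The
generator does not emulate base-call errors, PCR duplication, adapter
chemistry, chromatin-dependent shearing bias, mappability structure of a
real genome, or overdispersion from biological replicates — so real
libraries need the NB null precisely because their background is *not*
Poisson, and genome-wide artifact classes (mitochondrial homologies,
collapsed repeats) are only represented by their in-silico analogues.

## Problem sizes

Tests run the full study conditions (200,000 molecules over an ~11-kb
genome, ~15 M reads per library) for the headline geometry, and 20,000–
30,000 molecules for unit-level checks; these sizes give the same
qualitative behaviour with per-position background means of ~100 instead
of ~670. All simulations, tests and the acceptance script are seeded;
identical seeds give byte-identical outputs.
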