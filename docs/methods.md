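# Methods

## Expected-current profiles

A nanopore's mean ionic current is, to first order, a function of the k
bases in the pore (k = 6 for R9.4 chemistry). Published pore-model tables
map each k-mer to its expected mean current in pA. For a tandem repeat the
construction is circular: tiling a unit of length L makes every circular
permutation of the unit occupy the pore in turn, so the expected profile is
periodic with period L and one period determines the whole trace. We
therefore define `profile(m)[j]` as the level of the k-window starting at
position j of the infinite repetition of m, for j = 0 … L−1, and build
longer traces by tiling that period. Two consequences we rely on: the
profile of rotation i of m is the circular shift by i of the profile of m,
and homopolymer profiles are constant.

Raw ADC signal converts to pA as `current = (range / digitisation) × (raw +
offset)`; no further normalisation is applied. Dwell time, noise and event
segmentation are deliberately not modelled — the screen works on expected
mean levels only.

## Confusability statistics and the all-pairs screen

Pairs of units are compared by (i) Pearson correlation, (ii) mean-centered
Euclidean distance — each profile centered by its own mean before taking
the norm of the difference, so a constant current offset between units is
ignored — and (iii) absolute mean current difference. Statistics are
computed on one-period (length-k) profiles: the screen enumerates all 4^k
units *as written*, so rotations are distinct motifs and phase is already
encoded in the enumeration; a fixed small vector length also pins the scale
of the distance threshold (≈5 pA), which grows with vector length.
Correlation is undefined when either profile is constant; such pairs are
flagged (NaN), counted among the comparisons, and never pass the screen —
they are also not telomere-like, so nothing of interest is lost.

The screen over all C(4^k, 2) unordered pairs (8,386,560 for k = 6) is
vectorised: profiles are assembled into a matrix, centered and normalised
rows give the full correlation matrix by one matmul, and centered squared
norms give the distance matrix. Default thresholds are r ≥ 0.99 and
d ≤ 5 pA. Output ordering is deterministic: descending r, ascending d,
then lexicographic by pair. Exhaustive double-loop oracles at k = 2–4
verify both the passing set and the comparison count in the test suite.

## Read scanning, error proportion and triage

Counting is greedy, left-to-right, exact-substring matching on the literal
basecalled sequence; one counted unit is `unit_copies` (default 3)
consecutive copies of a motif. Both strands' motif sets are scanned
literally rather than reverse-complementing the read, because the errors
are strand-specific properties of the basecalls. Different motifs are
counted independently (no cross-motif exclusion), `N` never matches, and a
tract in shifted phase still matches after its first partial period — no
rotation canonicalisation is applied. The per-read error proportion is
artefact units over all units, undefined (reported as missing) when a read
carries none. Triage selects reads with ≥ 10 total units; with 6-base
motifs and 3-copy units a read needs ≥ 180 bp of repeat to qualify, which
makes spurious selection of random sequence vanishingly rare (a specific
18-mer at ~4⁻¹⁸ per position).

Co-occurrence over a read set uses a stricter presence rule — ≥ 4
consecutive copies (`cooccur_copies`) — with off-diagonal cells counting
reads containing runs of both motifs and diagonal cells counting reads in
which that motif is the only one of the set present, however many tracts of
it occur.

Repeat-region finding reports maximal runs (≥ 100 bp by default) that are
substrings of the tiled motif at any phase, 0-based half-open. The scanner
tries every phase at a candidate start and advances by a single base when
no qualifying run is found, because matches shorter than one unit are
phase-ambiguous and a maximal run may begin inside them; emitted runs of at
least one unit cannot be extended by a run starting within them (two phases
agreeing on ≥ L consecutive bases coincide), so the scanner skips them
whole.

## Read selection, coverage and pool handling

Terminal windows are `[0, w)` and `[len − w, len)` per chromosome
(default w = 10 kb; chromosomes shorter than w collapse to one
whole-chromosome region). Extraction takes primary alignments only
(secondary/supplementary records would double-count reads at paralogous
subtelomeres) that overlap a window by ≥ 1 bp — an explicit choice, since
"maps within 10 kb" could also be read as containment — with a mapq filter
defaulting to 0 and an optional autosome+X restriction. Arm coverage
counts distinct primary reads per arm at nested 10 kb / 100 kb / 1000 kb
windows, so counts are monotone in window size by construction. Pool
partitioning follows the per-read triage flag; recombination replaces the
selected reads' sequences and preserves the identifier set exactly.

## Ground-truth construction

A telomeric read's unalignable portion — the miscalled tract — appears as
a clip on the telomere-facing end of its anchor alignment (left for p-arm,
right for q-arm; the arm comes from the unique terminal window the
alignment overlaps). The tract length is estimated as that clip length
(default), or alternatively as the number of bases of the telomere-facing
soft-clipped sequence covered by telomeric/artefact motif copies; the two
agree exactly on clean synthetic tracts and the choice is exposed because
neither estimator is canonical. The truth sequence is the aligned
reference interval extended toward the chromosome end by the estimate,
truncated at the chromosome boundary — reference bases are never
fabricated; an explicit `pad_motif` opt-in exists for synthetic
experiments. Truth is always reported on the reference forward strand with
the read's orientation flagged. Signal pairing is emitted as read-id +
truth FASTA + manifest; conversion into any basecaller's training
container, and the training itself, are out of scope.

## Synthetic data generator

The generator emulates the structure of telomeric reads as basecalled: a
mappable subtelomeric anchor (default 2 kb) plus a telomeric tract (default
1–6 kb, mean 3 kb) in which artefact motifs replace telomeric units.
Genomes carry `(CCCTAA)`-type tracts at chromosome starts and
`(TTAGGG)`-type tracts at ends (default 3 kb arms, 50 kb random cores, core
bases adjacent to a tract adjusted so tract boundaries are sharp and
recoverable). p-arm reads are CCCTAA-strand (artefacts CTTCTT/CCCTGG, one
motif per block); q-arm reads are TTAGGG-strand (artefact TTAAAA). Default
artefact proportions are 0.9 on the CCCTAA strand and 0.3 on the TTAGGG
strand, echoing the strand asymmetry of real datasets; both are free
parameters.

Artefact injection is block-wise: a Binomial(units, p) number of motif
copies is laid out as contiguous blocks (mean ≈ 30 copies) rather than
scattered singles, for two reasons. First, real miscalled tracts are
block-like. Second, greedy 3-copy unit counting of an i.i.d. per-copy
mixture is a strongly biased estimator of p (short runs lose their
remainders to the floor; simulation gives a measured proportion of ~0.89
at p = 0.7), whereas block placement aligned to the 3-copy counting grid
makes the measured proportion an essentially unbiased readout of p — the
generator's injected fraction is recovered within ±0.005 at the default
test scale (500 reads, ≥ 3 kb tracts). Tract lengths are likewise rounded
to whole counted units so a minimal 180 bp tract always yields its 10
units.

What the generator does *not* emulate: per-base error profiles of real
basecallers (a uniform substitution knob exists, default off), raw-signal
simulation, alignment noise beyond exact anchor placement, subtelomeric
paralogy, and chimeric reads. Passing tests therefore demonstrate the
correctness of the counting, screening, selection and truth logic under
controlled conditions — not the end-to-end error rates of any particular
real dataset or basecaller.

## Numerical and design notes

* The synthetic pore model draws k-mer levels from a seeded
  position-weighted base-contribution model (central positions dominate)
  plus small per-k-mer noise, in a plausible 60–130 pA band. This gives
  realistic correlation structure (pairs differing at peripheral positions
  correlate highly) so the screen has non-trivial passing sets under
  synthetic models; it claims no physical realism and carries none of the
  published table's values. Checks that depend on the published R9.4
  table's actual numbers require that table at
  `data/r9.4_180mv_450bps_6mer.model` (see README).
* Screen memory at k = 6 is three 4096² float64 matrices (~400 MB peak);
  larger k would need chunking, which is not implemented.
* Problem sizes in the test and acceptance runs (300–1000 reads, 40–50 kb
  chromosomes, 80-read truth round trips) are chosen as the smallest sizes
  at which the binomial tolerances quoted above are comfortably
  discriminating.
* Threshold comparisons are inclusive (r ≥ 0.99, d ≤ 5, total ≥ 10) and
  applied to full-precision values, never to rounded output.
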