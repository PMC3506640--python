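# Methods

This note documents the models, algorithms and numerical choices behind
`barcodegap`, and what the synthetic data generators do and do not emulate.

## Scope and data flow

The package evaluates candidate DNA barcodes for Bacteria — the cpn60
universal target (UT; chaperonin nucleotides 274–828 on the *E. coli*
numbering, amplified by the degenerate primers H279/H280) and the classic
16S rRNA variable-region amplicons (V1–V3, V2–V4, V3–V5, V6, V6-alternate)
— and assesses *de novo* OTU assembly of barcode amplicon reads. The two
pipelines are:

1. **Barcode evaluation**: annotated genomes → marker extraction by
   annotation keyword → primer-site delineation of the barcode region →
   multiple alignment (consumed from an external aligner, or the built-in
   star fallback at fixture scale) → pairwise distances → intra/inter
   partition → barcode gap, distance histograms, window diversity profile.
2. **Assembly assessment**: amplicon reads → greedy overlap-consensus
   assembly swept over (ml, mi) → reference matching → per-OTU
   sensitivity/specificity/residual error → primer trimming, 100%
   collapsing, chimera flagging.

## Marker extraction

Genome annotations are inconsistent for the chaperonin gene, so extraction
is keyword-driven. Matching is case-insensitive on whole tokens — "groEL"
matches "chaperonin GroEL" but not "groES" — because substring matching is
ambiguous inside compound names (e.g. "groESL operon"). Multi-word terms
match as consecutive token runs. The shipped cpn60 keyword set (cpn60,
groEL, groL, hsp60, "60 kDa chaperonin", "chaperonin 60", "chaperonin
GroEL", "heat shock protein 60", mopA, …) is a deliberate superset
judgement call, user-extensible, since no published enumeration is
complete. All annotated paralogs are extracted and numbered in genome
order; minus-strand features are reverse-complemented to the gene sense
strand. GenBank coordinates are 1-based inclusive on input, 0-based
half-open internally, 1-based inclusive in reports.

## Barcode delineation

Primer matching is degenerate-aware Hamming matching: IUPAC codes expand
per the standard code and inosine matches any base (H279/H280 contain
inosine at several positions). Default tolerance is 3 mismatches per
primer — the tolerance is inherently a judgement call because annealing
sites are usually curated by eye — and it is configurable. The barcode
region is the amplicon *interior*: the sequence strictly between the two
annealing footprints, primers excluded. That convention matches both the
~556 bp average UT length and the fact that primer footprints are trimmed
from assembled consensuses before comparison. Sequences missing either
site are reported and skipped rather than guessed at. On gapped input,
matching runs on the degapped sequence.

## Distances and the barcode gap

Distances are substitutions/site under three closed-form models:

* **F84** (default, the model behind DNADIST): with transition proportion
  P, transversion proportion Q, frequencies π, R = πA+πG, Y = πC+πT,
  a = πAπG/R + πCπT/Y, b = πAπG + πCπT, c = RY,

      d = −2a·ln(1 − P/2a − (a−b)Q/2ac) + 2(a−b−c)·ln(1 − Q/2c)

* **K2P**: d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)
* **JC**: d = −¾·ln(1 − 4p/3), p = P+Q.

Choices pinned by tests: base frequencies are empirical *per pair*
(pooled over the two sequences, comparable sites only); sites with a gap
or any non-ACGT symbol in either sequence are deleted pairwise. The
implementation is checked to 1e−9 against `ape::dist.dna` on frozen
fixtures and to 1e−6 against an independently coded oracle on 100 random
pairs. At equal frequencies F84 reduces exactly to K2P.

Saturated pairs (non-positive logarithm argument) get distance +inf; they
are excluded from medians but counted and reported separately. Pairs of
sequences with the same species label — including paralogs within one
genome — are intra-specific. The **barcode gap** is the median
inter-specific minus the median intra-specific distance; medians rather
than means because the intra-specific distributions are heavily skewed
(divergent paralogs produce a long right tail), and the tests assert the
median's robustness to such outliers. Histograms are left-closed
right-open bins of width 0.01 (configurable), normalized per relation to
100% over all finite distances; a display cap truncates the view only,
never the normalization.

## Window diversity profile

For each 120 bp window along a reference sequence (default: the longest
degapped sequence; step 1 column, both configurable), every covering
sequence is compared with its nearest neighbour *from another genome*
(same-genome paralogs excluded; conspecific genomes allowed) over the
window's columns; identity is matches/window-length with gaps counted as
mismatches, and the window reports the median of the per-sequence best
identities at its midpoint. Nearest neighbours are recomputed per window —
only that reading produces the 100% plateaus expected in conserved
regions. Windows are emitted only when at least 95% of sequences span
them fully, suppressing edge effects from target length variation.
Insertion columns relative to the reference are not windowed. No smoothing
is applied.

## Synthetic data generators

All generators are deterministic given their seed.

**Template panel** (default n = 20, length 555 ± one codon, identity
envelope 56–96%): a random ancestor is mutated along a star tree with
per-leaf divergence fractions spaced so that realized pairwise identities
fill the interior of the envelope (about 0.58–0.87 at the defaults);
violating pairs are rejection-adjusted, with an error after bounded
retries for infeasible bounds. ±1-codon indels reproduce the 552–558 bp
length class. Identity is measured as matches over global-alignment
columns. The closest default pair is kept near 87%, a deliberate margin
below the standard 92% merge threshold: a pairwise greedy merger cannot
hold apart templates more similar than its merge identity (see below), so
the near-threshold discrimination case (a 96% pair, mirroring the closest
real clone pair) is exercised as its own two-template scenario with
mi > 96 rather than folded into the default panel.

**Reads**: each template's amplicon is its primer-flanked sequence
(degenerate primer positions instantiated concretely, seeded). Reads
alternate between the 5′ end (forward) and the 3′ end (reverse
complement), emulating sequencing from both amplicon ends; lengths are
truncated-normal (median 394 bp, sd = 0.15 × median, bounds [80, amplicon
length]) — the median is the pinned statistic, the shape is a modelling
choice. Optional substitution errors (per-base rate) and homopolymer ±1
wobble (per run ≥ 3) emulate pyrosequencing noise coarsely; there is no
flowgram-level model, no chimera simulation, and quality strings are
placeholders. Truth labels are complete and exclusive.

**Genome fixtures**: star gene trees place species ancestors (b−a)/2 from
the root and genomes a/2 from their species ancestor, under a Jukes–Cantor
substitution process, so expected pairwise distances are a within and b
between species and the expected barcode gap is b−a. The cpn60-like gene
diverges uniformly along its length; the 16S-like gene alternates
conserved (rate ×0.05) and variable (rate ×2) blocks, giving the two
targets their characteristic window profiles. Primer footprints are held
invariant so in-silico PCR succeeds on every genome — the biological
premise of universal primers. Optional extra cpn60 paralogs diverge by a
designed amount (default 0.4) from the genome's first copy, populating the
intra-specific right tail. Genomes are emitted as genuine GenBank flat
files (with decoy groES annotations as keyword true-negatives) so the
parser is exercised end to end. What passing tests on these fixtures do
*not* show: robustness to real annotation noise, alignment error on
structurally variable rRNA, or non-neutral sequence evolution.

## Assembler

A minimal greedy overlap-consensus assembler, deliberately small:

* Overlaps are semiglobal alignments with free end gaps (match +1,
  mismatch −1, gap −2), both orientations; identity is matches over
  aligned overlap columns, internal gaps count as mismatches.
* An overlap qualifies when identity ≥ mi and length ≥ ml. Merging is
  globally best-first (identity, then overlap length, then lexicographic
  ids), fully deterministic.
* After each merge the consensus is recomputed by per-column majority vote
  over base counts; ties break in fixed order A<C<G<T (never IUPAC codes,
  which would break downstream identity arithmetic); columns where gap
  evidence outvotes every base are dropped. Coverage is tracked for
  diagnostics only; there is no quality weighting.
* Contigs with ≥ 2 members are OTUs; unmerged reads are singletons; every
  input read lands in exactly one OTU or the singleton list.

Known structural limitation: because merging is pairwise with no read
re-placement, two templates whose mutual identity exceeds mi inevitably
collapse into one OTU once each is fully assembled. Production assemblers
escape this through read-level placement heuristics; here the behaviour is
documented and the close-pair case is tested at mi above the pair's
identity.

Performance: at small input sizes (≤ ~220 reads) every pair is scored
with the exact unbanded program — the reference semantics. Larger runs
use a k-mer-seeded candidate search (k = 16, stride-4 sampled index,
full-stride queries after merges), a gapless-diagonal fast path for exact
overlaps, and a banded (±32) alignment fallback for borderline
candidates; with clean reads this is exact in practice, and the fast and
exact modes are asserted to agree on shared fixtures. The alignment
kernel is a numba-compiled dynamic program.

## Evaluation

Reference matching replaces a BLAST-style search with exhaustive
semiglobal alignment of each query against every reference (both
orientations), which is exact at desk scale: best identity wins, ties go
to the lexicographically smallest reference id, matches below a 55% floor
(configurable) are discarded, and a match must cover at least half of the
shorter sequence so incidental end-overlaps never qualify.

Confusion counts follow reference concordance. For a target OTU whose
consensus matches reference R: TP = its reads matching R; FP = its reads
matching anything else; FN = reads in *other* OTUs matching R; TN = reads
in other OTUs that match their own OTU's consensus reference when that
reference differs from R. Reads that sit in another OTU and match neither
that OTU's reference nor R are counted in no class (they are that other
OTU's false positives); consequently TP+FP+TN+FN equals the number of
evaluated reads only in assemblies without such doubly-misplaced reads.
Singletons are excluded throughout and reported as percent data loss.
Unmatched reads or consensuses are excluded and reported. Sp = TN/(TN+FP),
Sn = TP/(TP+FN), E = √((1−Sp)² + (1−Sn)²), total error = ΣE. Degenerate
denominators (e.g. a single-OTU assembly, TN+FP = 0) define the ratio as
1.0 with a flag — the graceful limit for an uninformative comparison.

Cleanup: primer footprints matching within 5 bp of a consensus end
(either orientation, ≤ 3 mismatches) are trimmed; OTUs whose trimmed
consensus is identical to or an exact substring of another's are merged
(longer consensus kept, members unioned); an OTU is chimeric when its
5′-150 bp and 3′-150 bp segments best-match different references
(consensuses under 300 bp are not evaluable and flagged, never deleted).
Chimera removal deletes the OTU and reports its reads as unassembled; they
are not re-assigned. The sweep driver tabulates total error, OTU count
and singleton percentage for every (ml, mi) at all three stages.

## Problem sizes

Default test and acceptance runs use: the 20-template panel with 172
reads/template (3,440 reads) for the headline assembly; 16 or fewer
reads/template on 6-template panels for exact-mode assembler tests; 5×3
genome fixtures for gap recovery; 12 reads/template for the
8-point ml sweep. These sizes give stable statistics while keeping every
assembly deterministic and exhaustively checkable.

## Known limitations

* The assembler is a stand-in: published error magnitudes from a
  production assembler (flowgram-aware, cDNA-mode) are not expected to be
  reproduced numerically, only the qualitative trade-off structure.
* The star-alignment fallback is for near-equal-length, low-indel
  fixtures; real second-round alignments should come from a dedicated MSA
  tool.
* Saturated distances are reported as +inf rather than the large finite
  values some distance programs emit; reports flag them explicitly.
* The identity measured between highly divergent templates (≳40%
  divergence) is alignment-dependent; the generator's envelope check uses
  global edit-distance alignment identity.
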