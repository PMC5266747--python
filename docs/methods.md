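# Methods

## Model

The screen treats AG glycosylation as predictable from primary sequence
via two signals: compositional bias toward Pro/Ala/Ser/Thr (PAST) and the
local arrangement of those residues into the six AG glycomodules (AP, PA,
SP, PS, TP, PT), whose prolines are the hydroxylation/glycosylation sites.
A sub-sequence is considered effectively glycosylatable — an *AGP-like
sequence* — when at least three glycomodules occur with at most ten
residues between consecutive modules. Everything downstream (the seven
screening variables, the thresholds, the subfamily labels) is built on
those two primitives. The method does not model glycan chemistry, the
Hyp-contiguity rule at single-residue resolution, or the contextual
Pro-hydroxylation motifs described elsewhere in the literature; it is a
sequence-arrangement screen.

## Counting conventions

**Glycomodule scan.** Greedy, left-to-right, non-overlapping: at each
position, if the dipeptide is a glycomodule and does not overlap the
previously accepted hit, accept it and jump two residues. Ties ("APA")
resolve to the leftmost module. This convention is fixed by the AtAGP1
worked example: the printed 82-mer counts 21 modules under it (36 under
overlapping counting), giving the published index 21/82 → 0.26. Greedy
leftmost placement of unit-length-2 intervals is maximum-cardinality and
lexicographically earliest among maximum placements, which is what the
test-suite oracle verifies by dynamic programming and, on short strings,
exhaustive enumeration.

**Region extraction.** Consecutive accepted modules chain while the count
of residues strictly between them is ≤ 10 (`max_gap`); maximal chains with
≥ 3 modules (`min_modules`) become regions running from the first module's
start to the last module's end, so regions begin and end on glycomodules.
Multiple regions are concatenated, in order and without separators, into
the representative AGP-like sequence.

**The X-Pro composition table** deliberately uses a different convention:
every position where a non-Pro residue precedes a Pro is counted, overlaps
allowed, for all 19 X-Pro types. It is a descriptive statistic about Pro
context, not a glycosylation call, and the two conventions coexist on
purpose.

**Rounding.** All comparisons use unrounded values; report output rounds
to two decimals, half away from zero.

## Screening parameters

| parameter | default | rationale |
|---|---|---|
| signal-peptide D-score cutoff | 0.34 | the predictor's sensitive mode; a decision column, when present, wins over the score |
| BLAST e-value cutoff | 1e-3 | loose enough to catch divergent chimeric homologs |
| AG-peptide length window | 55 ≤ Length_T < 90 | AG-peptides are short classical AGPs; below 55 the signal-peptide branch excludes the record (it can still enter via homology) |
| PAST_T% split | 42 | separates PAST-rich (Group 2) from PAST-poor (Group 3) long proteins |
| Group 1 minima | GlycoIndex 0.15, PAST_P% 60 | |
| Group 2 minima | 0.15, 55, GlycoNo_P ≥ 5 | |
| Group 3 minima | 0.20, 60, GlycoNo_P ≥ 5 | PAST-poor proteins need a denser module signal |
| homology minima | 0.13, 45 | chimeric AGPs carry shorter, sparser AGP-like regions |
| max gap / min modules | 10 / 3 | the definition of effective glycosylation |

All minima are inclusive (≥). Raising any minimum can only shrink the
candidate set; the extensin/PRP removal predicates do not depend on the
minima, so monotonicity holds end-to-end (tested on a 4×4 grid).

## Extensin and PRP removal

The source method names the confounders (Ser-Pro₂₋₄ extensin repeats;
PVKCYT-style PRP repeats) but not a counting rule, so the rule here is the
package's own and fully configurable:

* **extensin**: ≥ 2 Ser-Proₙ motifs with n ≥ `ext_min_pro_run` (default 3)
  *and* more than half of the region-forming glycomodules lie inside those
  motifs — i.e. the AGP-like signal is an artifact of the repeats. A
  candidate with enough motifs whose modules are mostly *outside* them is
  kept and flagged as an AGP-extensin hybrid (HAE).
* **PRP**: ≥ 2 occurrences of any configured repeat (defaults PVKCYT,
  PPVYK, PPVEK) and GlycoIndex < 0.20.

The Pro-run floor is 3 rather than 2 because Ser-Pro₂ strings occur inside
genuine classical AGP backbones (AtAGP1's own AGP-like sequence contains
two), and a floor of 2 would mislabel such proteins as hybrids; runs of
3–4 are the canonical extensin arabinosylation motif.

## Subfamily classification

Precedence: (1) a recognized conserved-domain name maps to FLA
(fasciclin), PAG (plastocyanin/phytocyanin/Cu-bind) or XYLP
(nsLTP/AAI/xylogen); any other domain counts as *other chimeric* only when
≥ 30 of its residues fall outside the AGP-like regions (a "domain" engulfed
by the AGP-like sequence is not a chimeric scaffold); (2) no domain and
Length_T < 90 → AG-peptide; (3) a basic-residue-rich region inside the
span of the AGP-like regions → Lys-rich classical (KC); (4) the HAE flag;
(5) PAST_T% ≥ 42 → classical (C), else non-classical (NC). The
domain-name vocabulary is a shipped, editable mapping; unknown names are
recorded verbatim. NC is kept as a distinct label for
signal-peptide-branch, domain-free, PAST-poor candidates rather than being
folded into *other chimeric*.

## Basic-region detection

The literature reports Lys-rich region lengths (5–22) and compositions but
no detection algorithm, so this one is the package's design: maximal
windows of length ≥ 5 that start and end on K/H/R and have basic fraction
≥ 0.6, merged when overlapping (only while the union keeps the fraction),
then extended outward over flanking **non-PAST** residues while the
fraction holds. The extension step reflects that these regions interrupt a
PAST-rich backbone: the trailing Asn of LeAGP1's KGKVKGKKGKKHN belongs to
the interruption, and the rule recovers that printed region exactly, as
well as AtAGP19's KHKRKHKHKRHHH (K=5, H=6, R=2). Labels are by strict
plurality of K/H/R with pair labels on exact two-way ties; under that rule
AtAGP19's region is His-rich even though the subfamily is historically
called "Lys-rich" — the screen keeps the historical KC subfamily name
while the region label reports the actual plurality. Loosening the
fraction threshold never loses a region, though its boundaries may shift
(the extension can absorb different flanking residues), so the persistence
property is overlap, not containment.

## Synthetic proteomes

The generator emulates the *screening-relevant* structure of a proteome,
not its biology: planted AGP cores are built module-by-module with
controlled module counts, gap sizes and PAST filler rates, so the target
glycomodule index and PAST_P% are set independently; signal peptides exist
only as report rows; BLAST hits and domain hits are emitted for the
chimeric constructs; negative controls defeat exactly one clause each
(all gaps > 10; only 2 modules; proline-free filler so PAST_P% = 200 ×
GlycoIndex falls below every PAST_P% minimum while the index passes).
Background proteins are i.i.d. residues with PAST at 10% or 25%. Gap
fillers never contain Pro (no accidental modules) nor K/H/R (no
accidental basic regions), and zero-gap junctions after an SP module avoid
a following Pro (no accidental extensin motifs), so construct self-checks
against the scanning engine hold exactly. Every truth record's expected
outcome is the screening logic's own verdict on the construct, frozen at
generation time.

Consequences for interpretation: passing the planted-truth recovery test
shows the pipeline implements its own rules consistently and that the
thresholds separate the planted parameter ranges; it does **not** estimate
sensitivity or specificity on real proteomes, where signal-peptide calls
are noisy, domains are not clean intervals, and AGP-like regions grade
into background composition. The default proteome is 1000 proteins (100
planted, 30 targeted negatives, 870 background), a size chosen so the full
suite runs in seconds while every construct class appears many times.

## Numerical and degenerate-input choices

* A protein without an AGP-like sequence gets GlycoIndex 0 with an
  explicit flag; every threshold then fails, rather than propagating an
  undefined value.
* Ambiguity codes (X, B, Z, U, J, O) stay in sequences, count toward
  lengths, and never count as PAST or as module members.
* Intervals in external reports are stored 1-based inclusive as printed;
  all internal arithmetic is 0-based half-open, converted at the boundary.
* Pearson correlation is the default for the variable matrix (Spearman
  available); records without an AGP-like sequence are excluded with a
  logged count.
* Report rounding is half away from zero via decimal arithmetic, so
  printed values are platform-independent.

## Known limitations

* The screen consumes external predictor *reports*; one documented dialect
  each (plus a two-column id/yes-no fallback for the signal-peptide gate).
  It never runs SignalP, BLAST, or CD-search itself.
* GPI-anchor and transmembrane annotations are recorded when supplied but
  never used as filters.
* Records are screened as given; isoform suffixes are not collapsed per
  gene.
* The descriptive tables reproduce formulas, not published datasets; the
  reference composition/correlation values can only be recomputed when the
  corresponding sequence sets are supplied by the user.
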