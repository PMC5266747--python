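# finding-agp

Screening of **arabinogalactan proteins (AGPs)** in annotated proteomes from
their amino-acid sequence alone.

AGPs are plant cell-wall glycoproteins whose backbones are decorated with
arabinose/galactose-rich glycans at hydroxyproline residues. Because their
protein sequences are poorly conserved, homology searches miss most family
members; what *is* conserved is a compositional signature: backbones rich in
Pro, Ala, Ser and Thr (PAST) in which these residues are arranged as the six
**AG glycomodules** Ala-Pro, Pro-Ala, Ser-Pro, Pro-Ser, Thr-Pro and Pro-Thr.
This package finds those signatures, extracts the putatively glycosylated
sub-sequences, and screens whole proteomes for AGP candidates — classical
AGPs, AG-peptides, Lys-rich classical AGPs, AGP-extensin hybrids, and
chimeric AGPs (fasciclin-, phytocyanin- and xylogen-like) — for anyone doing
cell-wall or HRGP (hydroxyproline-rich glycoprotein) family annotation.

## The method

For each protein the engine computes seven variables:

| variable | meaning |
|---|---|
| Length_T | whole-sequence length |
| PAST_T%  | % of P/A/S/T in the whole sequence |
| GlycoNo_T | glycomodules in the whole sequence |
| Length_P | length of the representative AGP-like sequence |
| PAST_P%  | % of P/A/S/T in the AGP-like sequence |
| GlycoNo_P | glycomodules in the AGP-like sequence |
| GlycoIndex | GlycoNo_P / Length_P |

Glycomodules are counted by a greedy, left-to-right, **non-overlapping**
scan. An **AGP-like sequence** is a maximal stretch of ≥ 3 glycomodules with
≤ 10 residues between consecutive modules; multiple stretches are
concatenated into the representative AGP-like sequence. On the canonical
AtAGP1 AGP-like sequence (82 residues) the scan finds 21 modules, so
GlycoIndex = 21/82 ≈ 0.26.

Screening runs two branches and merges them:

1. **Signal-peptide branch** — proteins with a predicted signal peptide
   (SignalP-style report, D-score cutoff 0.34) are split into Group 1
   (55 ≤ Length_T < 90, the AG-peptides), Group 2 (Length_T ≥ 90 and
   PAST_T% ≥ 42) and Group 3 (Length_T ≥ 90, PAST_T% < 42), with minima
   GlycoIndex ≥ 0.15 / PAST_P% ≥ 60, ≥ 0.15 / ≥ 55 / GlycoNo_P ≥ 5 and
   ≥ 0.20 / ≥ 60 / GlycoNo_P ≥ 5 respectively.
2. **Homology branch** — proteins hit by BLASTP against known AGP seeds
   (e ≤ 1e-3) pass at GlycoIndex ≥ 0.13 and PAST_P% ≥ 45, regardless of a
   signal peptide (this is how chimeric AGPs without one are recovered).

BLAST-hit proteins are removed from the signal-peptide branch so no protein
is reported twice. Extensin artifacts (Ser-Pro₂₋₄ repeat proteins) and
PRP-like repeat proteins are then removed, and survivors are classified into
subfamilies (Pep, C, KC, HAE, FLA, PAG, XYLP, other chimeric, NC) using
conserved-domain annotations and short basic-residue-rich (Lys/His/Arg)
region detection.

## Worked example

```bash
$ printf '>AtAGP1_core\nSPAPAPSNVGGRRISPAPSPKKMTAPAPAPEVSPSPSPAAALTPESSASPPSPPLADSPTADSPALSPSAISDSPTEAPGPA\n' > atagp1.fasta
$ finding-agp variables atagp1.fasta
id	Length_T	PAST_T%	GlycoNo_T	Length_P	PAST_P%	GlycoNo_P	GlycoIndex
AtAGP1_core	82	73.17	21	82	73.17	21	0.26
```

The 82-residue backbone carries 21 non-overlapping glycomodules forming a
single AGP-like region that spans the whole string (Length_P = 82), so the
glycomodule index prints as 0.26 and 73.17% of the region is P/A/S/T — the
profile of a classical AGP backbone.

A full pipeline run on a synthetic proteome (1000 proteins with planted
AGPs, extensins, PRPs and background; ground truth written alongside):

```bash
$ finding-agp simulate --seed 1 --out-dir sim
wrote 1000 proteins (1000 planned) to sim
$ finding-agp screen --fasta sim/proteome.fasta --signalp sim/signalp.txt \
    --blast sim/blast.tsv --domains sim/domains.tsv \
    --out-table sim/candidates.tsv --out-fasta sim/candidates.fasta
...
removed_ext	5
removed_prp	5
final_candidates	90
wrote 90 candidates to sim/candidates.tsv
```

The 90 candidates are exactly the 90 planted AGPs that exceed the
thresholds (`sim/truth.tsv` lists the expected outcome per protein); the
five planted extensins and five PRP-like proteins are caught and removed.
Each output row carries the branch, group, subfamily and the seven
variables, e.g.

```
id        branch    group  subfamily  Length_T  PAST_T%  GlycoNo_T  Length_P  PAST_P%  GlycoNo_P  GlycoIndex  agp_like_sequence
fla_0000  homology  none   FLA        250       34.00    20         95        66.32    20         0.21        PSPSGAPEGPS...
```

— a chimeric protein with low whole-sequence PAST% (34%) that the classical
PAST-bias filter would miss, recovered through its PAST-rich AGP-like
region.

Other subcommands: `finding-agp stats` (amino-acid composition, X-Pro
dipeptide counts, the 7-variable correlation matrix, threshold-efficiency
grids), `finding-agp lysrich` (basic-residue-rich region reports).

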