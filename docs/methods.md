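# Methods

## The problem and the model

Shotgun proteomics experiments occasionally match spectra to peptides that
cannot come from any annotated protein but do map to three-frame
translations of annotated 5′ untranslated regions. This package implements
the discovery side of that analysis — building the translated-UTR search
space, filtering peptide-spectrum matches (PSMs) strictly enough for novel
sequence discovery, assembling peptides into region calls — and the
characterisation side: start-codon inference, Kozak-context classes,
clade-binned reading-frame conservation and allele-frequency-stratified
NS/Syn selection tests.

The underlying biological model is ribosome scanning with imperfect start
recognition: upstream initiation at an ATG or a near-cognate codon (one base
from ATG) produces either an N-terminally extended protein (in-frame,
no intervening stop: a 5′ extension), a short independent product that
terminates before the annotated start (uORF), or an out-of-frame product
that invades the CDS (uoORF). These three conditions — derived from the
frame relative to the CDS and the position of the bounding stop codon — are
mutually exclusive and exhaustive for any ORF overlapping a 5′UTR, and the
test suite enumerates all frame × stop-placement combinations to check that.

## Database construction

- UTRs shorter than 20 nt are skipped (the same minimum is used for
  GC-content): shorter sequences cannot contain a detectable peptide and
  destabilise composition statistics.
- Three-frame fragments shorter than 7 residues are dropped
  (`min_orf_aa = 7`), the minimum legal peptide length — nothing shorter can
  ever be observed.
- CDS upstream extensions are fused to the first 60 CDS codons
  (`cds_prefix_aa = 60`). Any legal junction peptide is at most 40 residues,
  so a 60-codon prefix guarantees that every UTR–CDS junction peptide occurs
  in exactly one novel entry while keeping entries small.
- Decoys are pseudo-reversed per tryptic segment: within each segment ending
  in K/R the preceding residues are reversed and the K/R stays in place.
  This preserves the tryptic peptide mass distribution, which is the point
  of keeping tryptic residues; a whole-protein variant (`decoy_mode =
  "whole"`) is provided because the alternative reading of "reversed with
  tryptic residues maintained" is also defensible.
- Codons containing N translate to X and never count as start or stop —
  a deliberately conservative treatment of ambiguity. In-frame TGA is always
  a stop (no selenocysteine recoding).

## PSM acceptance

The operating point is a posterior error probability ceiling of 2×10⁻⁴,
*inclusive* (a documented choice; the looser screening point 10⁻³ is kept
available for the monotonicity checks). Peptides must be fully tryptic
(N-terminus at the protein start or after K/R, C-terminus K/R or the protein
end, the K/R–P bond uncleavable by default) with at most two missed
cleavages, 7–40 residues. Peptide-to-protein matching treats I and L as
equivalent, the standard for shotgun data; both the P rule and I/L
equivalence are config switches. Modification annotations in peptide strings
are stripped on ingest since they do not affect mapping.

The novel-class FDR is the decoy/target ratio over accepted novel PSMs
(peptide-level: over distinct peptide strings). Decoys pass through the same
acceptance rules, flagged.

A region whose entire peptide support begins directly after an in-frame stop
codon, with no ATG/near-cognate codon at or upstream of the 5′-most peptide
inside its ORF, cannot be translated by any scanning mechanism; such regions
are excluded and reported as inferred false positives. Regions whose
candidate list is merely empty (a start presumably in an unannotated exon)
are kept with status NOT_FOUND — the two situations are deliberately
distinguished.

## Start-codon inference

Candidates are in-frame ATG or near-cognate codons inside the annotated
5′UTR, at or upstream of the 5′-most peptide, with no intervening in-frame
stop. A peptide may retain its initiator residue, hence "at". Selection
rules:

- any ATG wins, irrespective of conservation or Kozak strength; among
  several ATGs the most 3′ one is chosen, because a further-upstream ATG
  would imply an unobserved longer product;
- near-cognates are ranked by conservation depth, then Kozak rank
  (strong = 2, moderate = 1, weak = 0), then distance to the peptides, with
  the most 3′ offset as the final (never-needed, offsets are unique)
  tie-break. The order conservation > Kozak > distance follows the order in
  which those criteria are customarily applied when curating such regions.

Kozak strength uses positions −3 and +4 only: strong when −3 ∈ {A, G} and
+4 = G, moderate when exactly one holds, weak otherwise; missing context
bases never match. Candidate enumeration never extends beyond the annotated
UTR.

## Conservation binning

Alignments are consumed as per-region aligned FASTA (human row first); a MAF
block reader is provided for Cactus-style exports. Per species, the human
codons are projected onto the species row: any gap run (either row) whose
length is not a multiple of 3 is a frameshift; gap-free species codons that
are stops (where the human codon is not) are counted; single-base codon
differences are tallied synonymous/non-synonymous. "Largely free of stops
and frameshifts" is operationalised as exactly zero per species, with
tolerance expressed at the clade level instead: a clade qualifies when at
least `min_clade_fraction` (default 0.5) of its alignable species conserve
the frame, the start codon (identical codon; relaxable per region, since a
start may sit in an unannotated exon — and automatically relaxed when no
start was found) and, for uORFs/uoORFs only, the stop codon (any stop). The
region's bin is the deepest clade such that every clade from chimpanzee
outward to it qualifies; clades with no alignable species do not break the
chain but cannot be the final bin. Bins cap at tetrapods; deeper homology
search is out of scope. The species→clade map is an input, not a constant,
because clade membership depends on which species the alignment resource
contains.

## Selection statistics

- GC-content is computed over A/C/G/T only (N excluded from both numerator
  and denominator), requiring ≥ 20 bases.
- The reference 5′UTR per gene: the unique APPRIS-principal transcript; among
  several principals the MANE Select member, else the longest UTR; genes
  whose chosen UTR is < 20 nt are dropped.
- Variant effects are computed in the *region's own frame*, not the
  annotated CDS frame, since most regions are unannotated or annotated in a
  different frame. Indels with length difference not divisible by 3 are
  frameshifts; in-frame indels are protein-altering (NONSYN) unless they
  create a stop. SNVs in a start codon are NONSYN (no separate start-loss
  class). High impact = frameshift or stop-gain. Stop-gains and stop-losses
  count as non-synonymous in the NS/Syn ratios; frameshifts do not enter the
  ratio.
- Rare/common split at allele frequency 0.005 (rare strictly below).
  Multi-allelic VCF records are split on ingest with per-alternate AF.
- The "conserved" stratum is bins primates/mammals/tetrapods (at least all
  primates including Strepsirrhini); everything shallower is non-conserved.
- The Fisher exact test is two-sided with the "sum of tables at most as
  probable as observed" rule (scipy's convention); the test suite checks it
  against exhaustive rational-arithmetic enumeration. An all-zero (or
  single-margin-zero) table returns p = 1.0 with a warning.

## Synthetic data: what it emulates, and what it does not

The generator plants, per gene: a region type with a true start codon, a
Kozak class realised in the −3/+4 context bases, tryptic peptides (9-mers
ending in R, preceded by an R codon; extensions get one junction peptide
with the annotated Met internal), a bounding upstream stop, a conservation
depth realised in per-region alignments (2 species per clade by default;
species deeper than the planted clade receive a broken start plus an
in-frame stop or a 1-nt gap, alternating), and germline SNVs/indels with AF
split 50/50 rare/common. GC composition is planted exactly (a shuffled
fixed-composition sequence) at a 69.4% UTR default versus 52.3% in coding
sequence — emulating the elevated GC of upstream-translated exons. Candidate
scan windows are cleared of competing start-set codons so that planted-start
recovery is well-defined; an optional decoy near-cognate with broken
conservation exercises the conservation tie-break. Stop-adjacency trap genes
plant a peptide directly after a stop with a non-start first codon. True and
canonical PSMs draw PEP ~ U(0, 10⁻⁴); noise PSMs (for FDR calibration) draw
uniformly over target and decoy novel entries with PEP ~ U(0,
`noise_pep_max`) — the null calibration set uses `noise_pep_max = 0.001` so
the noise spans the analysis' two operating points. Upstream-region PSMs are
emitted cell-line-enriched (60% vs 15% for canonical PSMs) to emulate the
cell-line bias of upstream translation. Everything is reproducible: one
`numpy` child generator per gene, derived from the spec seed.

What the generator does **not** emulate: real spectra or retention times,
correlated PEP structure, alignment errors, paralogy (each gene is a single
transcript on its own contig), population-genetic allele-frequency spectra
(AF is uniform within each class), or annotation errors. Passing the
recovery tests therefore demonstrates the correctness of the pipeline's
logic under its stated assumptions, not its performance on real
noisy search-engine output.

Problem sizes used by the test suite and the acceptance script — 30-gene
recovery studies, 5 000 noise PSMs for FDR calibration, 200 regions × 10
variants × 100 replicates for the selection tests — were chosen as the
smallest sizes at which the stochastic checks have clear statistical power
(binomial/KS tolerances well away from their thresholds).

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; GTF I/O converts from
  1-based inclusive. Stop codons annotated via `stop_codon` features are
  merged into the CDS.
- Deduplication keeps the lexicographically smallest source id as the
  survivor accession, making database construction order-independent and
  byte-reproducible.
- Ambiguous multi-gene peptides are discarded, not fractionally assigned;
  peptides also present in the known proteome carry no novel evidence and
  are dropped.
- A gene with several regions gets suffixed region ids (`GENE.1`, `GENE.2`),
  supporting gene-level reporting when one gene hosts two regions.
- `novel_fdr` errors on zero target PSMs and warns (returning 0) on zero
  decoys; `gc_content` returns None below the length minimum; empty
  candidate lists yield NOT_FOUND start calls.

## Known limitations

- The pipeline starts from a PSM table; spectrum searching and rescoring are
  out of scope by design.
- Conservation input is limited to supplied alignments — no homology search
  beyond them, so bins cannot exceed tetrapods.
- Sample-wise region counts are not strictly monotone in the PEP ceiling:
  extra borderline noise peptides can trigger stop-adjacency exclusions of
  otherwise-called regions. Accepted-PSM counts are monotone, and planted
  regions persist across the operating points; the tests check exactly
  those properties.
- Trans-splicing, ribosomal slippage and selenocysteine recoding are not
  modelled.
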