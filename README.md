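# uptrans

Proteogenomic discovery and characterisation of translated 5′-UTR regions
(TURs): segments of annotated 5′ untranslated regions with peptide-level
evidence of translation. The package is aimed at proteogenomics and gene
annotation researchers who want a tested, reusable implementation of the
full analysis path — from a genome + GTF to region calls with inferred start
codons, Kozak context classes, clade-binned conservation and
purifying-selection statistics — exercisable end to end on synthetic genomes
with planted ground truth.

## What it computes

1. **Search database** (`upstream_db`): every annotated 5′UTR (≥ 20 nt) is
   translated in three frames and split at stop codons; each CDS is extended
   upstream in frame to the nearest stop and fused to a 60-codon CDS prefix
   so junction-spanning peptides map. After exact-sequence deduplication the
   novel entries are concatenated with the known proteome, per-class decoys
   (reversed with tryptic K/R residues kept in place) and contaminants.
2. **PSM filtering** (`psm_filter`): posterior error probability ≤ 2×10⁻⁴
   (inclusive), peptide length 7–40, fully tryptic termini with ≤ 2 missed
   cleavages (K/R, not before P), I/L-equivalent matching. The novel-class
   FDR is estimated as decoy/target counts at PSM and peptide level.
3. **Region calling** (`region_caller`): unambiguous novel peptides are
   placed on transcripts and grouped per (transcript, frame, ORF); a region
   needs ≥ 2 PSMs. Types are mutually exclusive:
   - **5′ extension** — in frame with the CDS, no intervening stop;
   - **uORF** — the ORF's stop codon precedes the annotated start;
   - **uoORF** — out of frame, terminating inside the CDS.
   Regions whose entire support sits directly after an in-frame stop with no
   possible start codon are excluded as inferred false positives.
4. **Start codons** (`start_codon`): candidates are ATG or the nine
   near-cognate codons (one base from ATG), in frame, inside the annotated
   5′UTR, upstream of all peptides, with no intervening stop. An ATG always
   wins; near-cognates rank by conservation depth, then Kozak strength
   (strong: −3 ∈ {A,G} and +4 = G; moderate: exactly one; weak: neither),
   then proximity to the peptides.
5. **Conservation** (`conservation`): per-region orthologous alignments are
   scored per species (in-frame stops, frame-disrupting gaps, start/stop
   codon conservation) and binned into the nested clade ladder
   human → chimpanzee → chimp+gorilla → apes → monkeys → primates →
   mammals → tetrapods.
6. **Selection statistics** (`selection_stats`): GC-content with the
   MANE/APPRIS reference-UTR rules, self-computed variant effects in the
   region's own reading frame, non-synonymous/synonymous (NS/Syn) count
   tables split at allele frequency 0.005 (rare < 0.005 ≤ common) with a
   two-sided Fisher exact test, high-impact (frameshift/stop-gain) counts,
   and PSM-based expression and sample-class summaries.
7. **Synthetic data** (`synthetic_data`): generates genome, annotation, PSM
   table, alignments and VCF with planted region types, start codons, Kozak
   classes, conservation depths, stop-adjacency traps and selection regimes,
   plus a `truth.json` for exact recovery checks.

## Worked example

```python
from uptrans import PlantSpec, generate, run_pipeline

spec = PlantSpec.default(n_extension=3, n_uorf=2, n_uoorf=2, n_none=3,
                         n_traps=1, seed=5)
generate(spec, "demo_data")
result = run_pipeline("demo_data")
for c in result.calls:
    print(c.region_id, c.region_type, c.start_codon, c.kozak, c.conservation_bin)
print(result.rejects[["gene_id", "reason"]])
```

prints

```
G0001 EXTENSION AGG MODERATE PRIMATES
G0002 EXTENSION ATA STRONG MONKEYS
G0003 EXTENSION ATG STRONG CHIMP
G0004 UORF AAG STRONG TETRAPODS
G0005 UORF ATA STRONG CHIMP
G0006 UOORF TTG WEAK APES
G0007 UOORF GTG STRONG TETRAPODS
  gene_id                        reason
0   G0008  stop_adjacent_false_positive
```

Seven upstream regions are recovered with their planted type, start codon,
Kozak class and conservation bin; the eighth gene is a planted
stop-adjacency trap — its only peptide sits directly downstream of an
in-frame stop with no possible start codon, so the region is excluded as an
inferred false positive.

The same steps are available as a CLI: `uptrans simulate`, `uptrans
build-db`, `uptrans filter-psms`, `uptrans run`.

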