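"""Characterisation statistics for translated upstream regions.

Covers GC-content with the reference-transcript selection rules (MANE Select
when it is APPRIS principal, else the longest principal 5'UTR), frame-aware
variant-effect classification in the region's own reading frame, rare/common
NS/Syn tables split at allele frequency 0.005 with a Fisher exact test, and
PSM-based expression / tissue-class / Kozak-strength summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import pysam

from .annotation_io import GenomeSequence, TranscriptModel, revcomp
from .upstream_db import STOP_CODONS, translate_nt

log = logging.getLogger(__name__)

SYN, NONSYN = "SYN", "NONSYN"
STOP_GAINED, STOP_LOST, FRAMESHIFT = "STOP_GAINED", "STOP_LOST", "FRAMESHIFT"
HIGH_IMPACT = {STOP_GAINED, FRAMESHIFT}

RARE, COMMON = "RARE", "COMMON"

# bins counted as conserved for the selection contrast: at least all primates
# (including Strepsirrhini) or deeper
CONSERVED_BINS = {"PRIMATES", "MAMMALS", "TETRAPODS"}

MIN_UTR_NT = 20


@dataclass
class VariantRecord:
    contig: str
    pos: int          # 0-based
    ref: str
    alt: str
    allele_frequency: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError("allele frequency outside [0, 1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def read_vcf(path: str | Path, af_key: str = "AF") -> list[VariantRecord]:
    """Read variants; multi-allelic records are split, AF taken per alt."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            afs = rec.info.get(af_key)
            if afs is None:
                raise ValueError(f"variant at {rec.chrom}:{rec.pos} lacks INFO/{af_key}")
            if not isinstance(afs, tuple):
                afs = (afs,)
            for alt, af in zip(rec.alts or (), afs):
                out.append(VariantRecord(rec.chrom, rec.start, rec.ref, alt, float(af)))
    return out


def gc_content(seq: str, min_len: int = MIN_UTR_NT) -> float | None:
    """Percentage of G+C over unambiguous bases; None (logged) below min_len.

    N bases are excluded from both numerator and denominator, so the value is
    invariant under reverse complement.
    """
    if len(seq) < min_len:
        log.info("sequence of length %d below the %d-base minimum; skipped", len(seq), min_len)
        return None
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return None
    return 100.0 * gc / acgt


def select_reference_utr(
    gene_models: dict[str, list[TranscriptModel]],
    genome: GenomeSequence,
    min_utr_nt: int = MIN_UTR_NT,
) -> dict[str, TranscriptModel]:
    """One reference 5'UTR per gene.

    A unique APPRIS-principal transcript wins; among several principals the
    MANE Select member wins, else the longest 5'UTR.  Genes whose chosen UTR
    is shorter than ``min_utr_nt`` are dropped.  Genes with no principal
    transcript fall back to the longest UTR (warned).
    """
    chosen: dict[str, TranscriptModel] = {}
    for gene, models in gene_models.items():
        principals = [m for m in models if "APPRIS_PRINCIPAL" in m.tags]
        if not principals:
            log.warning("gene %s has no APPRIS principal transcript; using longest UTR", gene)
            pool = models
        elif len(principals) == 1:
            pool = principals
        else:
            mane = [m for m in principals if "MANE_SELECT" in m.tags]
            pool = mane if mane else principals
        best = max(pool, key=lambda m: (m.utr5_len, m.transcript_id))
        if best.utr5_len < min_utr_nt:
            log.info("gene %s reference UTR shorter than %d nt; dropped", gene, min_utr_nt)
            continue
        chosen[gene] = best
    return chosen


def variant_effect_in_frame(region_nt: str, pos: int, ref: str, alt: str) -> str:
    """Effect of a variant on the region translated in its own frame.

    ``region_nt`` starts at a codon boundary of the region's reading frame
    and ``pos`` is the 0-based offset of the variant within it.  Indels whose
    length difference is not a multiple of 3 are frameshifts; in-frame indels
    are protein-altering (NONSYN) unless they create a stop.  SNVs compare
    the affected codon before and after.
    """
    if not 0 <= pos < len(region_nt):
        raise ValueError("variant outside region")
    if region_nt[pos : pos + len(ref)] != ref:
        raise ValueError(f"reference mismatch at region offset {pos}")
    if len(ref) != len(alt):
        if abs(len(ref) - len(alt)) % 3:
            return FRAMESHIFT
        mutated = region_nt[:pos] + alt + region_nt[pos + len(ref):]
        old_aa = translate_nt(region_nt)
        new_aa = translate_nt(mutated)
        if "*" in new_aa and "*" not in old_aa:
            return STOP_GAINED
        return NONSYN
    # SNV (or MNV treated codon-wise): compare the affected codons
    codon_i = pos // 3
    codon_start = 3 * codon_i
    old_codon = region_nt[codon_start : codon_start + 3]
    mutated = region_nt[:pos] + alt + region_nt[pos + len(ref):]
    new_codon = mutated[codon_start : codon_start + 3]
    if len(old_codon) < 3:
        return NONSYN  # partial terminal codon: conservative call
    old_is_stop = old_codon in STOP_CODONS
    new_is_stop = new_codon in STOP_CODONS
    if new_is_stop and not old_is_stop:
        return STOP_GAINED
    if old_is_stop and not new_is_stop:
        return STOP_LOST
    if translate_nt(old_codon) == translate_nt(new_codon):
        return SYN
    return NONSYN


def variants_to_regions(
    variants: list[VariantRecord],
    regions: dict[str, tuple[TranscriptModel, tuple[int, int]]],
    genome: GenomeSequence,
) -> pd.DataFrame:
    """Project genomic variants into region coordinates.

    ``regions`` maps region_id -> (model, transcript-coordinate span whose
    start is codon-aligned to the region frame).  Alleles on '-' strand
    transcripts are reverse-complemented.  Returns columns region_id, pos
    (offset within the region), ref, alt, af.
    """
    rows = []
    for region_id, (model, (start, end)) in regions.items():
        region_nt = model.transcript_slice(genome, start, end)
        for v in variants:
            if v.contig != model.contig:
                continue
            try:
                t_off = model.genomic_to_transcript(v.pos)
            except ValueError:
                continue
            if model.strand == "-":
                # anchor at the last genomic base of the ref allele
                try:
                    t_off = model.genomic_to_transcript(v.pos + len(v.ref) - 1)
                except ValueError:
                    continue
            if not start <= t_off < end:
                continue
            ref = revcomp(v.ref) if model.strand == "-" else v.ref
            alt = revcomp(v.alt) if model.strand == "-" else v.alt
            pos = t_off - start
            if region_nt[pos : pos + len(ref)] != ref:
                log.warning("allele mismatch for %s at %s:%d; skipped", region_id, v.contig, v.pos)
                continue
            rows.append(
                {"region_id": region_id, "pos": pos, "ref": ref, "alt": alt,
                 "af": v.allele_frequency}
            )
    return pd.DataFrame(rows, columns=["region_id", "pos", "ref", "alt", "af"])


def ns_syn_table(
    variant_df: pd.DataFrame,
    region_seqs: dict[str, str],
    region_bins: dict[str, str] | None = None,
    af_cutoff: float = 0.005,
) -> pd.DataFrame:
    """NS/Syn counts and ratios per stratum x allele-frequency class.

    Strata: ALL regions; CONSERVED_GE_PRIMATES (clade bin primates or
    deeper); NONCONSERVED (the rest).  RARE is AF < cutoff, COMMON is AF >=
    cutoff.  Frameshifts and stop-gains are tallied as high_impact;
    stop-gains and stop-losses count as non-synonymous.  Ratio is NaN when
    there are no synonymous variants.
    """
    region_bins = region_bins or {}
    effects = []
    for row in variant_df.itertuples(index=False):
        seq = region_seqs[row.region_id]
        effect = variant_effect_in_frame(seq, int(row.pos), row.ref, row.alt)
        bin_ = region_bins.get(row.region_id)
        stratum_conserved = bin_ in CONSERVED_BINS if bin_ is not None else None
        effects.append(
            {"region_id": row.region_id, "effect": effect,
             "af_class": COMMON if row.af >= af_cutoff else RARE,
             "conserved": stratum_conserved}
        )
    eff = pd.DataFrame(effects, columns=["region_id", "effect", "af_class", "conserved"])

    def tally(sub: pd.DataFrame, stratum: str, af_class: str) -> dict:
        sub = sub[sub["af_class"] == af_class]
        nonsyn = int(sub["effect"].isin([NONSYN, STOP_GAINED, STOP_LOST]).sum())
        syn = int((sub["effect"] == SYN).sum())
        high = int(sub["effect"].isin(HIGH_IMPACT).sum())
        return {
            "stratum": stratum, "af_class": af_class, "nonsyn": nonsyn, "syn": syn,
            "high_impact": high, "ratio": nonsyn / syn if syn else float("nan"),
        }

    rows = []
    for stratum, sub in (
        ("ALL", eff),
        ("CONSERVED_GE_PRIMATES", eff[eff["conserved"] == True]),   # noqa: E712
        ("NONCONSERVED", eff[eff["conserved"] == False]),           # noqa: E712
    ):
        for af_class in (RARE, COMMON):
            rows.append(tally(sub, stratum, af_class))
    return pd.DataFrame(rows)


def fisher_2x2(ns_rare: int, syn_rare: int, ns_common: int, syn_common: int) -> float:
    """Two-sided Fisher exact p for the NS/Syn x rare/common contingency.

    Uses the exact hypergeometric "sum of tables at most as probable as the
    observed one" rule.  An all-zero margin returns 1.0 with a warning.
    """
    table = np.array([[ns_rare, syn_rare], [ns_common, syn_common]])
    if (table < 0).any():
        raise ValueError("negative count")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        warnings.warn("degenerate 2x2 margin; Fisher p = 1.0 by convention")
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def expression_summary(
    psm_df: pd.DataFrame,
    calls_df: pd.DataFrame,
) -> dict[str, object]:
    """PSM-based expression summaries.

    ``psm_df`` columns: gene_id, is_tur (bool: maps to an upstream region
    rather than the annotated protein), sample_class.  ``calls_df`` columns:
    gene_id, region_type, kozak, conservation_bin.  Returns mean PSM/gene
    for the detected-gene background and the upstream-region gene groups,
    cell-line shares split by conservation, and the percent-of-gene-PSMs per
    Kozak stratum for 5' extensions.
    """
    per_gene = psm_df.groupby("gene_id").size()
    tur_genes = set(calls_df["gene_id"])
    ext_genes = set(calls_df.loc[calls_df["region_type"] == "EXTENSION", "gene_id"])
    uorf_genes = tur_genes - ext_genes

    def mean_psm(genes: set[str]) -> float:
        vals = per_gene.reindex(sorted(genes)).dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    conserved_genes = set(
        calls_df.loc[calls_df["conservation_bin"].isin(CONSERVED_BINS), "gene_id"]
    )

    def cellline_share(sub: pd.DataFrame) -> float:
        return 100.0 * (sub["sample_class"] == "cell_line").mean() if len(sub) else float("nan")

    tur = psm_df[psm_df["is_tur"]]
    canon = psm_df[~psm_df["is_tur"]]
    shares = {
        "tur_cell_line_pct": cellline_share(tur),
        "canonical_cell_line_pct": cellline_share(canon),
        "tur_conserved_cell_line_pct": cellline_share(tur[tur["gene_id"].isin(conserved_genes)]),
        "tur_nonconserved_cell_line_pct": cellline_share(tur[~tur["gene_id"].isin(conserved_genes)]),
        "canonical_conserved_cell_line_pct": cellline_share(canon[canon["gene_id"].isin(conserved_genes & tur_genes)]),
        "canonical_nonconserved_cell_line_pct": cellline_share(
            canon[canon["gene_id"].isin(tur_genes - conserved_genes)]
        ),
    }

    kozak_rows = []
    ext_calls = calls_df[calls_df["region_type"] == "EXTENSION"]
    for kozak, sub in ext_calls.groupby("kozak"):
        genes = set(sub["gene_id"])
        gene_psms = psm_df[psm_df["gene_id"].isin(genes)]
        n_tur = int(gene_psms["is_tur"].sum())
        n_all = len(gene_psms)
        kozak_rows.append(
            {"kozak": kozak, "n_regions": len(sub),
             "tur_psm_per_region": n_tur / len(sub) if len(sub) else float("nan"),
             "pct_of_gene_psms": 100.0 * n_tur / n_all if n_all else float("nan")}
        )
    return {
        "mean_psm_all_genes": mean_psm(set(per_gene.index)),
        "mean_psm_tur_genes": mean_psm(tur_genes),
        "mean_psm_extension_genes": mean_psm(ext_genes),
        "mean_psm_uorf_uoorf_genes": mean_psm(uorf_genes),
        "sample_class_shares": shares,
        "kozak_strata": pd.DataFrame(kozak_rows, columns=["kozak", "n_regions", "tur_psm_per_region", "pct_of_gene_psms"]),
    }
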