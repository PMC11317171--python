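"""End-to-end orchestration of the upstream-translation discovery pipeline.

Chains the stage modules over a data directory laid out the way the
synthetic generator writes it: genome.fa, annot.gtf, tags.tsv, psms.tsv and
optionally alignments/ + clades.tsv and variants.vcf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import conservation as cons
from .annotation_io import GenomeSequence, load_annotation
from .config import PipelineConfig
from .psm_filter import filter_psms, novel_fdr, read_psm_table
from .region_caller import TurCall, call_regions, crosstab, map_peptides
from .selection_stats import (
    expression_summary,
    fisher_2x2,
    ns_syn_table,
    read_vcf,
    variants_to_regions,
)
from .start_codon import FOUND, enumerate_candidates, select_start
from .upstream_db import build_database

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    calls: list[TurCall]
    rejects: pd.DataFrame
    excluded_peptides: pd.DataFrame
    fdr: dict[str, float] | None
    crosstab: pd.DataFrame | None
    selection: pd.DataFrame | None
    fisher_p_conserved: float | None
    expression: dict | None
    models: dict = field(default_factory=dict)


def annotate_starts_and_conservation(
    calls: list[TurCall],
    models: dict,
    genome: GenomeSequence,
    blocks: dict[str, cons.AlignmentBlock] | None,
    config: PipelineConfig,
) -> None:
    """Fill start-codon and clade-bin fields of each call, in place."""
    blocks = blocks or {}
    for call in calls:
        model = models[call.transcript_id]
        seq = model.spliced_sequence(genome)
        block = blocks.get(call.region_id)
        depth_fn = None
        if block is not None:
            f = config.conservation.min_clade_fraction
            depth_fn = lambda off, b=block, w=call.nt_span[0], f=f: cons.codon_depth(b, off - w, f)
        first_pep = min(p.nt_start for p in call.peptides)
        candidates = enumerate_candidates(
            seq, call.nt_span[0], first_pep, model.utr5_len, depth_fn
        )
        start = select_start(candidates, call.region_id)
        call.start_codon = start.codon
        call.start_offset = start.offset
        call.start_status = start.status
        call.kozak = start.kozak
        if block is None:
            continue
        start_off_in_region = (
            start.offset - call.nt_span[0] if start.status == FOUND else 0
        )
        verdicts = [
            cons.species_verdict(block, sp, call.region_type, start_off_in_region)
            for sp in block.rows
            if sp != block.human
        ]
        call.conservation_bin = cons.assign_bin(
            verdicts,
            block.species_clade,
            call.region_type,
            config.conservation.min_clade_fraction,
            require_start=config.conservation.require_start_conserved and start.status == FOUND,
        )


def run_pipeline(data_dir: str | Path, config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    d = Path(data_dir)
    genome = GenomeSequence.from_fasta(d / "genome.fa")
    models_list = load_annotation(d / "annot.gtf", d / "tags.tsv" if (d / "tags.tsv").exists() else None)
    models = {m.transcript_id: m for m in models_list}
    database = build_database(models_list, genome, config=config.db)

    psms = read_psm_table(d / "psms.tsv")
    accepted = filter_psms(psms, database, config.filter)
    try:
        fdr = novel_fdr(accepted)
    except ValueError:
        fdr = None
    loci, excluded = map_peptides(accepted, database, models, config.filter.il_equivalent)
    calls, rejects = call_regions(loci, models, genome)

    blocks = None
    if (d / "clades.tsv").exists() and (d / "alignments").is_dir():
        clades = cons.load_clades(d / "clades.tsv")
        blocks = cons.load_alignments(d / "alignments", clades)
    annotate_starts_and_conservation(calls, models, genome, blocks, config)

    xtab = crosstab(calls) if calls and all(c.conservation_bin for c in calls) else None

    selection = fisher_p = None
    if (d / "variants.vcf").exists() and calls:
        variants = read_vcf(d / "variants.vcf")
        regions = {c.region_id: (models[c.transcript_id], c.nt_span) for c in calls}
        vdf = variants_to_regions(variants, regions, genome)
        region_seqs = {
            c.region_id: models[c.transcript_id].transcript_slice(genome, *c.nt_span)
            for c in calls
        }
        bins = {c.region_id: c.conservation_bin for c in calls if c.conservation_bin}
        selection = ns_syn_table(vdf, region_seqs, bins, config.af_cutoff)
        cons_rows = selection[selection["stratum"] == "CONSERVED_GE_PRIMATES"].set_index("af_class")
        if len(cons_rows) == 2:
            fisher_p = fisher_2x2(
                int(cons_rows.loc["RARE", "nonsyn"]), int(cons_rows.loc["RARE", "syn"]),
                int(cons_rows.loc["COMMON", "nonsyn"]), int(cons_rows.loc["COMMON", "syn"]),
            )

    expression = None
    if calls:
        tur_peptides = {p.peptide for c in calls for p in c.peptides}
        rows = []
        for psm in accepted:
            if psm.is_decoy:
                continue
            if psm.is_novel:
                if psm.peptide not in tur_peptides:
                    continue
                orf = database.novel_orfs.get(psm.accession)
                gene = orf.gene_id if orf else None
                is_tur = True
            else:
                tid = psm.accession.split("|", 1)[1]
                gene = models[tid].gene_id if tid in models else None
                is_tur = False
            if gene is not None:
                rows.append({"gene_id": gene, "is_tur": is_tur, "sample_class": psm.sample_class})
        psm_df = pd.DataFrame(rows, columns=["gene_id", "is_tur", "sample_class"])
        calls_df = pd.DataFrame(
            [
                {"gene_id": c.gene_id, "region_type": c.region_type,
                 "kozak": c.kozak, "conservation_bin": c.conservation_bin}
                for c in calls
            ]
        )
        expression = expression_summary(psm_df, calls_df)

    return PipelineResult(
        calls=calls,
        rejects=rejects,
        excluded_peptides=excluded,
        fdr=fdr,
        crosstab=xtab,
        selection=selection,
        fisher_p_conserved=fisher_p,
        expression=expression,
        models=models,
    )
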