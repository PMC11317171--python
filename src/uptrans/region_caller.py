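"""Aggregation of accepted novel peptides into translated-upstream-region calls.

A region call is one contiguous upstream ORF on one transcript, supported by
at least two PSMs.  Calls are classified as 5' extension (in frame with the
annotated CDS, no intervening stop), uORF (the ORF's stop codon precedes the
annotated start) or uoORF (out of frame, stop inside the CDS).  Regions whose
entire peptide support sits directly downstream of an in-frame stop with no
possible start codon are excluded as inferred false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import GenomeSequence, TranscriptModel
from .conservation import CLADES
from .psm_filter import PsmRecord, find_peptide, stop_adjacent_flag
from .start_codon import START_SET
from .upstream_db import STOP_CODONS, SearchDatabase

log = logging.getLogger(__name__)

EXTENSION = "EXTENSION"
UORF = "UORF"
UOORF = "UOORF"


@dataclass
class PeptideLocus:
    """One unambiguous novel peptide placed on a transcript."""

    peptide: str
    gene_id: str
    transcript_id: str
    nt_start: int            # transcript coordinates of the peptide's first base
    nt_end: int
    frame_vs_cds: int        # (nt_start - cds_start) mod 3
    psm_count: int
    best_pep: float
    sample_classes: list[str]
    accessions: list[str]


@dataclass
class TurCall:
    """An accepted translated upstream region."""

    region_id: str
    gene_id: str
    transcript_id: str
    region_type: str
    peptides: list[PeptideLocus]
    psm_count: int
    nt_span: tuple[int, int]     # upstream-region window in transcript coords
    frame_vs_cds: int
    multi_peptide: bool
    cds_start: int
    # filled in by the start_codon / conservation modules
    start_codon: str | None = None
    start_offset: int | None = None
    start_status: str | None = None
    kozak: str | None = None
    conservation_bin: str | None = None
    extra: dict = field(default_factory=dict)


def map_peptides(
    accepted: list[PsmRecord],
    database: SearchDatabase,
    models: dict[str, TranscriptModel],
    il_equivalent: bool = True,
) -> tuple[list[PeptideLocus], pd.DataFrame]:
    """Place every accepted target-novel peptide on a transcript.

    Peptides that also occur in a known (target_known) protein carry no novel
    evidence and are dropped; peptides occurring in more than one gene are
    ambiguous and excluded from region support.  Returns the loci and a table
    of excluded peptides with reasons.
    """
    novel_psms = [p for p in accepted if p.is_novel and not p.is_decoy]
    by_peptide: dict[str, list[PsmRecord]] = {}
    for psm in novel_psms:
        by_peptide.setdefault(psm.peptide, []).append(psm)

    known_proteins = [prot for _, prot, cls in database.entries if cls == "target_known"]
    loci: list[PeptideLocus] = []
    excluded: list[dict] = []
    for peptide in sorted(by_peptide):
        psms = by_peptide[peptide]
        if any(find_peptide(peptide, prot, il_equivalent) for prot in known_proteins):
            excluded.append({"peptide": peptide, "reason": "in_known_proteome"})
            continue
        placements: dict[tuple[str, int], dict] = {}
        genes: set[str] = set()
        for acc, orf in database.novel_orfs.items():
            for occ in find_peptide(peptide, orf.protein, il_equivalent):
                for prov in orf.provenance:
                    genes.add(prov.gene_id)
                    p_start = prov.nt_start + 3 * occ
                    key = (prov.transcript_id, p_start)
                    placements.setdefault(
                        key,
                        {
                            "transcript_id": prov.transcript_id,
                            "gene_id": prov.gene_id,
                            "nt_start": p_start,
                            "nt_end": p_start + 3 * len(peptide),
                            "accession": acc,
                        },
                    )
        if not placements:
            raise ValueError(f"accepted novel peptide {peptide} is unmappable")
        if len(genes) > 1:
            excluded.append({"peptide": peptide, "reason": "multi_gene_ambiguous"})
            log.info("peptide %s maps to %d genes; excluded", peptide, len(genes))
            continue
        # prefer the APPRIS-principal transcript, then the smallest id / 5'-most site
        def rank(item: dict) -> tuple:
            model = models.get(item["transcript_id"])
            principal = model is not None and "APPRIS_PRINCIPAL" in model.tags
            return (not principal, item["transcript_id"], item["nt_start"])

        chosen = min(placements.values(), key=rank)
        model = models[chosen["transcript_id"]]
        loci.append(
            PeptideLocus(
                peptide=peptide,
                gene_id=chosen["gene_id"],
                transcript_id=chosen["transcript_id"],
                nt_start=chosen["nt_start"],
                nt_end=chosen["nt_end"],
                frame_vs_cds=(chosen["nt_start"] - model.cds_start_tx) % 3,
                psm_count=len(psms),
                best_pep=min(p.pep for p in psms),
                sample_classes=[p.sample_class for p in psms],
                accessions=sorted({chosen["accession"]} | {p.accession for p in psms}),
            )
        )
    return loci, pd.DataFrame(excluded, columns=["peptide", "reason"])


def _orf_window(seq: str, nt_start: int, cds_start: int, frame: int):
    """Bounding in-frame stops around a peptide start.

    Returns (orf_start, stop_start, stop_end); stop_start/stop_end are None
    when the frame runs to the transcript 3' end without a stop.
    """
    pos = nt_start
    while pos >= 3:
        if seq[pos - 3 : pos] in STOP_CODONS:
            break
        pos -= 3
    orf_start = pos
    pos = nt_start
    stop_start = stop_end = None
    while pos + 3 <= len(seq):
        if seq[pos : pos + 3] in STOP_CODONS:
            stop_start, stop_end = pos, pos + 3
            break
        pos += 3
    return orf_start, stop_start, stop_end


def classify_region(
    frame_vs_cds: int, cds_start: int, stop_start: int | None, stop_end: int | None
) -> str:
    """Mutually exclusive and exhaustive type assignment for an upstream ORF.

    The ORF's stop ending at or before the annotated start makes a uORF in
    any frame; an in-frame stop-free run into the CDS is a 5' extension; an
    out-of-frame ORF whose stop lies (or would lie) 3' of the annotated start
    is a uoORF.
    """
    if stop_end is not None and stop_end <= cds_start:
        return UORF
    if frame_vs_cds == 0:
        return EXTENSION
    return UOORF


def call_regions(
    loci: list[PeptideLocus],
    models: dict[str, TranscriptModel],
    genome: GenomeSequence,
    min_psms: int = 2,
) -> tuple[list[TurCall], pd.DataFrame]:
    """Group peptide loci into upstream-region calls.

    One call per (transcript, frame, contiguous ORF) with total PSM support
    of at least ``min_psms``.  Every unambiguous peptide ends up in exactly
    one call or one row of the rejects table.
    """
    groups: dict[tuple[str, int, int], list[PeptideLocus]] = {}
    group_meta: dict[tuple[str, int, int], tuple] = {}
    rejects: list[dict] = []
    for locus in loci:
        model = models[locus.transcript_id]
        seq = model.spliced_sequence(genome)
        cds_start = model.cds_start_tx
        if locus.nt_start >= cds_start:
            rejects.append(
                {"gene_id": locus.gene_id, "peptides": locus.peptide,
                 "psm_count": locus.psm_count, "reason": "not_upstream"}
            )
            continue
        orf_start, stop_start, stop_end = _orf_window(seq, locus.nt_start, cds_start, locus.frame_vs_cds)
        key = (locus.transcript_id, locus.frame_vs_cds, orf_start)
        groups.setdefault(key, []).append(locus)
        group_meta[key] = (seq, cds_start, orf_start, stop_start, stop_end, model)

    calls: list[TurCall] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda l: l.nt_start)
        seq, cds_start, orf_start, stop_start, stop_end, model = group_meta[key]
        tid, frame, _ = key
        psm_count = sum(l.psm_count for l in members)
        gene_id = members[0].gene_id
        region_type = classify_region(frame, cds_start, stop_start, stop_end)
        if psm_count < min_psms:
            rejects.append(
                {"gene_id": gene_id, "peptides": ";".join(l.peptide for l in members),
                 "psm_count": psm_count, "reason": "insufficient_psms"}
            )
            continue
        first_pep = members[0].nt_start
        if stop_adjacent_flag(first_pep, seq):
            has_start = any(
                seq[p : p + 3] in START_SET for p in range(orf_start, first_pep + 1, 3)
            )
            if not has_start:
                rejects.append(
                    {"gene_id": gene_id, "peptides": ";".join(l.peptide for l in members),
                     "psm_count": psm_count, "reason": "stop_adjacent_false_positive"}
                )
                continue
        if region_type == EXTENSION:
            span = (orf_start, cds_start)
        else:
            end = stop_end if stop_end is not None else len(seq) - (len(seq) - orf_start) % 3
            span = (orf_start, end)
        calls.append(
            TurCall(
                region_id="",  # assigned below, per gene
                gene_id=gene_id,
                transcript_id=tid,
                region_type=region_type,
                peptides=members,
                psm_count=psm_count,
                nt_span=span,
                frame_vs_cds=frame,
                multi_peptide=len(members) > 1,
                cds_start=cds_start,
            )
        )

    by_gene: dict[str, list[TurCall]] = {}
    for call in calls:
        by_gene.setdefault(call.gene_id, []).append(call)
    for gene, gene_calls in by_gene.items():
        gene_calls.sort(key=lambda c: (c.transcript_id, c.nt_span[0]))
        for i, call in enumerate(gene_calls, start=1):
            call.region_id = gene if len(gene_calls) == 1 else f"{gene}.{i}"
    calls.sort(key=lambda c: c.region_id)
    reject_df = pd.DataFrame(rejects, columns=["gene_id", "peptides", "psm_count", "reason"])
    return calls, reject_df


# -- conservation x type x start cross-tabulation ---------------------------

CROSSTAB_COLUMNS = ["All", "5' ext", "uORF/uoORF", "ATG"]


def crosstab(calls: list[TurCall]) -> pd.DataFrame:
    """Clade bin x region type x ATG summary (Table-1 layout).

    Rows follow the clade order human -> tetrapods plus a Total row; every
    call must already carry a conservation bin.
    """
    counts = pd.DataFrame(0, index=list(CLADES), columns=CROSSTAB_COLUMNS)
    for call in calls:
        if call.conservation_bin is None:
            raise ValueError(f"call {call.region_id} lacks a conservation bin")
        counts.loc[call.conservation_bin, "All"] += 1
        col = "5' ext" if call.region_type == EXTENSION else "uORF/uoORF"
        counts.loc[call.conservation_bin, col] += 1
        if call.start_codon == "ATG":
            counts.loc[call.conservation_bin, "ATG"] += 1
    counts.loc["Total"] = counts.sum()
    return counts


def crosstab_shares(counts: pd.DataFrame) -> dict[str, float]:
    """Named percentage summaries of a Table-1-format cross-tab."""
    body = counts.drop(index="Total") if "Total" in counts.index else counts
    total = body["All"].sum()
    pct = lambda x: 100.0 * x / total if total else 0.0
    shallow = ["HUMAN", "CHIMP", "CHIMP_GORILLA"]
    return {
        "at_least_mammals": pct(body.loc[["MAMMALS", "TETRAPODS"], "All"].sum()),
        "primates_only": pct(body.loc["PRIMATES", "All"]),
        "not_all_primates": pct(body.loc[shallow + ["APES", "MONKEYS"], "All"].sum()),
        "not_beyond_gorilla": pct(body.loc[shallow, "All"].sum()),
        "atg_and_at_least_mammals": pct(body.loc[["MAMMALS", "TETRAPODS"], "ATG"].sum()),
    }
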