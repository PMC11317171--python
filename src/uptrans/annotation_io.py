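"""Genome and transcript-annotation input.

Builds strand-aware transcript models from an Ensembl-dialect GTF plus a
transcript-tag table (APPRIS principal/alternative/minor, MANE Select), and
extracts spliced 5'UTR and CDS sequences with exact coordinate bookkeeping.

All internal coordinates are 0-based half-open; GTF I/O converts from the
1-based inclusive convention.  Transcript offsets run 5'->3' in transcript
orientation, so offset 0 on a '-' strand transcript is the highest genomic
exon base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import gffutils
from pyfaidx import Fasta

log = logging.getLogger(__name__)

VALID_TAGS = {"APPRIS_PRINCIPAL", "APPRIS_ALTERNATIVE", "APPRIS_MINOR", "MANE_SELECT"}

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (uppercase A/C/G/T/N)."""
    return seq.translate(_RC)[::-1]


@dataclass
class GenomeSequence:
    """In-memory genome: contig name -> uppercase nucleotide string."""

    contigs: dict[str, str]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs.get(contig)
        if seq is None:
            raise KeyError(f"unknown contig {contig!r}")
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"coordinates [{start}, {end}) outside contig {contig} of length {len(seq)}"
            )
        return seq[start:end]


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    exons and cds are lists of (start, end) genomic intervals, 0-based
    half-open, in ascending genomic order.  On the '-' strand transcript
    order is descending genomic order; all transcript-offset arithmetic
    accounts for that.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"malformed strand {self.strand!r} for {self.transcript_id}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)

    # -- coordinate maps -------------------------------------------------

    @cached_property
    def _tx_positions(self) -> list[int]:
        """Genomic position of every transcript base, in transcript order."""
        pos: list[int] = []
        for s, e in self.exons:
            pos.extend(range(s, e))
        if self.strand == "-":
            pos.reverse()
        return pos

    @cached_property
    def _g2t(self) -> dict[int, int]:
        return {g: i for i, g in enumerate(self._tx_positions)}

    @property
    def tx_length(self) -> int:
        return len(self._tx_positions)

    def genomic_to_transcript(self, genomic_pos: int) -> int:
        off = self._g2t.get(genomic_pos)
        if off is None:
            raise ValueError(
                f"position {genomic_pos} is not exonic in {self.transcript_id}"
            )
        return off

    def transcript_to_genomic(self, offset: int) -> int:
        if not 0 <= offset < self.tx_length:
            raise ValueError(f"offset {offset} out of range for {self.transcript_id}")
        return self._tx_positions[offset]

    # -- CDS / UTR anatomy ------------------------------------------------

    @cached_property
    def cds_start_tx(self) -> int:
        """Transcript offset of the first CDS base (5'UTR length)."""
        first = self.cds[-1][1] - 1 if self.strand == "-" else self.cds[0][0]
        return self.genomic_to_transcript(first)

    @cached_property
    def cds_end_tx(self) -> int:
        """Transcript offset one past the last CDS base."""
        last = self.cds[0][0] if self.strand == "-" else self.cds[-1][1] - 1
        return self.genomic_to_transcript(last) + 1

    @property
    def utr5_len(self) -> int:
        return self.cds_start_tx

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)

    def validate(self) -> None:
        exon_bases = set()
        for s, e in self.exons:
            exon_bases.update(range(s, e))
        for s, e in self.cds:
            if not set(range(s, e)) <= exon_bases:
                raise ValueError(f"CDS outside exons in {self.transcript_id}")
        if self.cds_len < 3:
            raise ValueError(f"spliced CDS shorter than one codon in {self.transcript_id}")

    # -- sequence extraction ----------------------------------------------

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        parts = [genome.fetch(self.contig, s, e) for s, e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def transcript_slice(self, genome: GenomeSequence, start: int, end: int) -> str:
        return self.spliced_sequence(genome)[start:end]


def five_prime_utr_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced, strand-corrected 5'UTR sequence in transcript orientation.

    May be the empty string when the CDS starts at the transcript 5' end.
    """
    return model.spliced_sequence(genome)[: model.utr5_len]


def cds_sequence(model: TranscriptModel, genome: GenomeSequence) -> str:
    return model.spliced_sequence(genome)[model.cds_start_tx : model.cds_end_tx]


def load_tags(tags_path: str | Path) -> dict[str, set[str]]:
    """transcript_id<TAB>tag table -> transcript_id -> set of tags."""
    tags: dict[str, set[str]] = {}
    with open(tags_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tid, tag = line.split("\t")[:2]
            if tag not in VALID_TAGS:
                raise ValueError(f"unknown transcript tag {tag!r}")
            tags.setdefault(tid, set()).add(tag)
    return tags


def load_annotation(
    gtf_path: str | Path, tags_path: str | Path | None = None
) -> list[TranscriptModel]:
    """Read a GTF and build one TranscriptModel per coding transcript.

    Transcripts without CDS features are skipped (count logged).  A CDS
    feature falling outside its transcript's exons rejects the transcript.
    stop_codon features, when present, are merged into the CDS so the CDS
    includes the stop codon.  Transcripts lacking an APPRIS tag default to
    APPRIS_MINOR.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tags = load_tags(tags_path) if tags_path else {}

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for ftype, store in (("exon", exons), ("CDS", cds), ("stop_codon", cds)):
        for feat in db.features_of_type(ftype):
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes.get("gene_id", [tid])[0]
            store.setdefault(tid, []).append((feat.start - 1, feat.end))
            meta.setdefault(tid, (gid, feat.seqid, feat.strand))

    models: list[TranscriptModel] = []
    n_noncoding = n_rejected = 0
    for tid, ex in exons.items():
        if tid not in cds:
            n_noncoding += 1
            continue
        gid, contig, strand = meta[tid]
        transcript_tags = set(tags.get(tid, set()))
        if not transcript_tags & {"APPRIS_PRINCIPAL", "APPRIS_ALTERNATIVE", "APPRIS_MINOR"}:
            transcript_tags.add("APPRIS_MINOR")
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            contig=contig,
            strand=strand,
            exons=ex,
            cds=_merge_intervals(cds[tid]),
            tags=transcript_tags,
        )
        try:
            model.validate()
        except ValueError as err:
            log.warning("rejecting transcript %s: %s", tid, err)
            n_rejected += 1
            continue
        models.append(model)
    if n_noncoding:
        log.info("skipped %d transcripts without CDS", n_noncoding)
    if n_rejected:
        log.info("rejected %d malformed transcripts", n_rejected)
    models.sort(key=lambda m: m.transcript_id)
    return models


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
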