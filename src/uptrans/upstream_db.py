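"""Target+decoy protein search-database construction.

The database concatenates (i) 3-frame translations of every annotated 5'UTR,
split at stop codons, (ii) in-frame upstream extensions of each CDS walked
back to the nearest stop and fused to a CDS prefix so junction-spanning
peptides map, (iii) the known proteome, (iv) decoys for both novel and known
classes with tryptic residues kept in place, and (v) optional contaminants.

Accession grammar (fixed so downstream filtering never needs a lookup table):
``novel|...``, ``sp|...``, ``decoy_novel|...``, ``decoy_sp|...``, ``cont|...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .annotation_io import GenomeSequence, TranscriptModel, cds_sequence, five_prime_utr_sequence
from .config import DbConfig

log = logging.getLogger(__name__)

UTR3FRAME = "UTR3FRAME"
CDS_EXTENSION = "CDS_EXTENSION"

STOP_CODONS = {"TAA", "TAG", "TGA"}


def translate_nt(seq: str) -> str:
    """Translate a nucleotide string; trailing partial codon is dropped.

    Codons containing N translate to 'X' and never count as stops.
    """
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


@dataclass
class Provenance:
    transcript_id: str
    nt_start: int   # transcript-coordinate start of the translated span
    nt_end: int
    gene_id: str


@dataclass
class CandidateOrf:
    """One predicted upstream translation product."""

    orf_id: str
    gene_id: str
    transcript_id: str
    category: str                 # UTR3FRAME or CDS_EXTENSION
    frame: int                    # vs UTR start (UTR3FRAME); 0 vs CDS (CDS_EXTENSION)
    protein: str
    nt_span: tuple[int, int]      # transcript coordinates of the translated span
    boundary_flag: bool = False   # crosses the UTR-CDS junction
    provenance: list[Provenance] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.protein or "*" in self.protein:
            raise ValueError(f"invalid ORF protein for {self.orf_id}")
        if not self.provenance:
            self.provenance = [
                Provenance(self.transcript_id, *self.nt_span, self.gene_id)
            ]


@dataclass
class SearchDatabase:
    """Concatenated target+decoy database.

    entries: accession -> (protein, class); novel_orfs keeps the accession ->
    CandidateOrf link needed to place peptides back on transcripts.
    """

    entries: list[tuple[str, str, str]] = field(default_factory=list)
    novel_orfs: dict[str, CandidateOrf] = field(default_factory=dict)

    def check_invariants(self) -> None:
        counts: dict[str, int] = {}
        seen = set()
        for acc, _, cls in self.entries:
            if acc in seen:
                raise ValueError(f"duplicate accession {acc}")
            seen.add(acc)
            counts[cls] = counts.get(cls, 0) + 1
        for cls in ("target_known", "target_novel"):
            if counts.get(cls, 0) != counts.get(cls.replace("target", "decoy"), 0):
                raise ValueError(f"decoy count does not match targets for {cls}")

    def protein(self, accession: str) -> str:
        for acc, prot, _ in self.entries:
            if acc == accession:
                return prot
        raise KeyError(accession)

    def as_dict(self) -> dict[str, str]:
        return {acc: prot for acc, prot, _ in self.entries}


def accession_class(accession: str) -> tuple[bool, bool]:
    """(is_decoy, is_novel) from the accession prefix."""
    prefix = accession.split("|", 1)[0]
    return prefix.startswith("decoy"), prefix.endswith("novel")


def translate_three_frames(
    utr_seq: str,
    transcript_id: str = "",
    gene_id: str = "",
    min_orf_aa: int = 7,
) -> list[CandidateOrf]:
    """Split each of the 3 forward-frame translations of a 5'UTR at stops.

    Every stop-free fragment of at least ``min_orf_aa`` residues becomes a
    CandidateOrf carrying its transcript-coordinate nucleotide span.
    """
    orfs: list[CandidateOrf] = []
    for frame in range(3):
        protein = translate_nt(utr_seq[frame:])
        start_aa = 0
        for chunk in protein.split("*"):
            if len(chunk) >= min_orf_aa:
                nt_start = frame + 3 * start_aa
                nt_end = nt_start + 3 * len(chunk)
                orfs.append(
                    CandidateOrf(
                        orf_id=f"{transcript_id}:f{frame}:{nt_start}",
                        gene_id=gene_id,
                        transcript_id=transcript_id,
                        category=UTR3FRAME,
                        frame=frame,
                        protein=chunk,
                        nt_span=(nt_start, nt_end),
                    )
                )
            start_aa += len(chunk) + 1  # +1 for the stop codon
    return orfs


def extend_cds_upstream(
    model: TranscriptModel,
    genome: GenomeSequence,
    cds_prefix_aa: int = 60,
) -> CandidateOrf | None:
    """Walk upstream from the CDS start, in frame, to the nearest stop.

    Returns the extension residues fused to the first ``cds_prefix_aa``
    codons of the annotated CDS (so junction peptides are findable), or
    None when a stop sits immediately upstream or the UTR is shorter than
    one codon.
    """
    utr = five_prime_utr_sequence(model, genome)
    if len(utr) < 3:
        return None
    ext_codons: list[str] = []
    pos = len(utr)
    while pos >= 3:
        codon = utr[pos - 3 : pos]
        if codon in STOP_CODONS:
            break
        ext_codons.append(codon)
        pos -= 3
    if not ext_codons:
        return None
    ext_nt = "".join(reversed(ext_codons))
    ext_aa = translate_nt(ext_nt)
    cds_nt = cds_sequence(model, genome)
    prefix_aa = translate_nt(cds_nt[: 3 * cds_prefix_aa]).rstrip("*")
    protein = ext_aa + prefix_aa
    nt_start = len(utr) - len(ext_nt)
    nt_end = len(utr) + 3 * len(prefix_aa)
    return CandidateOrf(
        orf_id=f"{model.transcript_id}:ext",
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        category=CDS_EXTENSION,
        frame=0,
        protein=protein,
        nt_span=(nt_start, nt_end),
        boundary_flag=True,
    )


def deduplicate(orfs: list[CandidateOrf]) -> list[CandidateOrf]:
    """Collapse exact amino-acid duplicates, keeping all provenance.

    The survivor is the entry with the lexicographically smallest orf_id, so
    the output is independent of the input order.
    """
    by_protein: dict[str, list[CandidateOrf]] = {}
    for orf in orfs:
        by_protein.setdefault(orf.protein, []).append(orf)
    out: list[CandidateOrf] = []
    for group in by_protein.values():
        group.sort(key=lambda o: o.orf_id)
        survivor = group[0]
        survivor.provenance = [p for o in group for p in o.provenance]
        survivor.provenance.sort(key=lambda p: (p.transcript_id, p.nt_start))
        out.append(survivor)
    out.sort(key=lambda o: o.orf_id)
    return out


def make_decoy(protein: str, mode: str = "segment") -> str:
    """Reverse a protein while keeping tryptic residues in place.

    ``segment`` mode reverses the residues preceding the terminal K/R within
    each tryptic segment (a terminal segment without K/R is wholly reversed),
    so decoy tryptic peptides keep the target peptide mass distribution.
    ``whole`` mode reverses the full protein then restores each K/R position.
    """
    if not protein:
        raise ValueError("empty protein")
    if mode == "whole":
        # reverse non-K/R residues across the whole protein, K/R stay in place
        non_kr = [aa for aa in protein[::-1] if aa not in "KR"]
        it = iter(non_kr)
        return "".join(aa if aa in "KR" else next(it) for aa in protein)
    segments: list[str] = []
    start = 0
    for i, aa in enumerate(protein):
        if aa in "KR":
            segments.append(protein[start : i + 1])
            start = i + 1
    if start < len(protein):
        segments.append(protein[start:])
    out: list[str] = []
    for seg in segments:
        if seg and seg[-1] in "KR":
            out.append(seg[:-1][::-1] + seg[-1])
        else:
            out.append(seg[::-1])
    return "".join(out)


def build_database(
    models: list[TranscriptModel],
    genome: GenomeSequence,
    known_fasta: str | Path | None = None,
    contaminants_fasta: str | Path | None = None,
    config: DbConfig | None = None,
) -> SearchDatabase:
    """Assemble the full target+decoy database.

    When ``known_fasta`` is None the known proteome is derived from the
    annotated CDS translations of the supplied models (one entry per
    transcript).  Building twice from the same inputs is byte-identical.
    """
    config = config or DbConfig()
    novel: list[CandidateOrf] = []
    n_short_utr = 0
    for model in sorted(models, key=lambda m: m.transcript_id):
        utr = five_prime_utr_sequence(model, genome)
        if len(utr) < config.min_utr_nt:
            n_short_utr += 1
            continue
        novel.extend(
            translate_three_frames(
                utr, model.transcript_id, model.gene_id, config.min_orf_aa
            )
        )
        ext = extend_cds_upstream(model, genome, config.cds_prefix_aa)
        if ext is not None:
            novel.append(ext)
    if n_short_utr:
        log.info("skipped %d transcripts with 5'UTR < %d nt", n_short_utr, config.min_utr_nt)
    novel = deduplicate(novel)

    if known_fasta is not None:
        known = [
            (rec.id, str(rec.seq).rstrip("*"))
            for rec in SeqIO.parse(str(known_fasta), "fasta")
        ]
    else:
        known = [
            (m.transcript_id, translate_nt(cds_sequence(m, genome)).rstrip("*"))
            for m in sorted(models, key=lambda m: m.transcript_id)
        ]
    contaminants = (
        [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(contaminants_fasta), "fasta")]
        if contaminants_fasta is not None
        else []
    )

    db = SearchDatabase()
    for orf in novel:
        db.entries.append((f"novel|{orf.orf_id}", orf.protein, "target_novel"))
        db.novel_orfs[f"novel|{orf.orf_id}"] = orf
    for acc, prot in known:
        db.entries.append((f"sp|{acc}", prot, "target_known"))
    for orf in novel:
        db.entries.append(
            (f"decoy_novel|{orf.orf_id}", make_decoy(orf.protein, config.decoy_mode), "decoy_novel")
        )
    for acc, prot in known:
        db.entries.append(
            (f"decoy_sp|{acc}", make_decoy(prot, config.decoy_mode), "decoy_known")
        )
    for acc, prot in contaminants:
        db.entries.append((f"cont|{acc}", prot, "contaminant"))
    db.check_invariants()
    return db


def write_fasta(db: SearchDatabase, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for acc, prot, _ in db.entries:
            fh.write(f">{acc}\n")
            for i in range(0, len(prot), width):
                fh.write(prot[i : i + width] + "\n")
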