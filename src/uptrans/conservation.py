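"""Cross-species reading-frame conservation of upstream regions.

Inputs are per-region orthologous alignments (aligned FASTA, human row
first) plus a species -> clade map over the nested clade ladder
human -> chimpanzee -> chimp+gorilla -> apes -> monkeys -> primates ->
mammals -> tetrapods.  A species conserves a region when its row carries no
in-frame stop codons and no frame-disrupting gap runs, and (by default) an
identical start codon; for uORFs/uoORFs the stop codon must be conserved
too.  The region's bin is the deepest clade for which every clade up to it
has at least a configurable fraction of alignable species conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

from .upstream_db import STOP_CODONS, translate_nt

log = logging.getLogger(__name__)

CLADES = (
    "HUMAN",
    "CHIMP",
    "CHIMP_GORILLA",
    "APES",
    "MONKEYS",
    "PRIMATES",
    "MAMMALS",
    "TETRAPODS",
)
CLADE_DEPTH = {c: i for i, c in enumerate(CLADES)}


@dataclass
class AlignmentBlock:
    """Orthologous multi-species alignment of one upstream region.

    rows maps species to aligned nucleotide strings ('-' for gaps), all the
    same length; the human row is ungapped-length-identical to the region.
    """

    region_id: str
    rows: dict[str, str]            # insertion-ordered; human first
    human: str                      # species name of the human row
    species_clade: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment for {self.region_id}")
        for sp, clade in self.species_clade.items():
            if clade not in CLADE_DEPTH:
                raise ValueError(f"unknown clade {clade!r} for species {sp}")

    @property
    def human_row(self) -> str:
        return self.rows[self.human]

    def human_ungapped(self) -> str:
        return self.human_row.replace("-", "")


@dataclass
class SpeciesVerdict:
    species: str
    frame_conserved: bool
    stop_count: int
    frameshift_count: int
    start_conserved: bool
    stop_codon_conserved: bool
    syn_count: int
    nonsyn_count: int
    alignable: bool = True


def load_clades(path: str | Path) -> dict[str, str]:
    """species<TAB>clade table."""
    clades: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sp, clade = line.split("\t")[:2]
            if clade not in CLADE_DEPTH:
                raise ValueError(f"unknown clade {clade!r}")
            clades[sp] = clade
    return clades


def load_alignment(path: str | Path, species_clade: dict[str, str]) -> AlignmentBlock:
    """Read one region's aligned FASTA; the first record is the human row."""
    aln = AlignIO.read(str(path), "fasta")
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    human = aln[0].id
    return AlignmentBlock(
        region_id=Path(path).stem, rows=rows, human=human, species_clade=species_clade
    )


def load_alignments(directory: str | Path, species_clade: dict[str, str]) -> dict[str, AlignmentBlock]:
    blocks = {}
    for path in sorted(Path(directory).glob("*.fa")):
        block = load_alignment(path, species_clade)
        blocks[block.region_id] = block
    return blocks


def read_maf_blocks(path: str | Path, species_clade: dict[str, str]) -> list[AlignmentBlock]:
    """Slice a MAF file into per-block AlignmentBlocks (human = first row).

    Convenience reader for Cactus-style MAF exports; each MAF block becomes
    one region-level alignment keyed by the human source coordinates.
    """
    blocks = []
    for i, aln in enumerate(AlignIO.parse(str(path), "maf")):
        rows = {}
        for rec in aln:
            species = rec.id.split(".")[0]
            rows[species] = str(rec.seq).upper()
        human = next(iter(rows))
        first = aln[0]
        region_id = f"{first.id}:{first.annotations.get('start', i)}"
        blocks.append(
            AlignmentBlock(region_id=region_id, rows=rows, human=human, species_clade=species_clade)
        )
    return blocks


def _gap_runs(row: str, columns: range) -> list[int]:
    runs, run = [], 0
    for i in columns:
        if row[i] == "-":
            run += 1
        elif run:
            runs.append(run)
            run = 0
    if run:
        runs.append(run)
    return runs


def species_verdict(
    block: AlignmentBlock,
    species: str,
    region_type: str = "EXTENSION",
    start_offset: int = 0,
) -> SpeciesVerdict:
    """Assess one species' conservation of the human reading frame.

    Human codons are projected onto the species row.  Frameshifts are gap
    runs (in either row) whose length is not a multiple of 3; stops are
    counted in gap-free species codons aligned to human codons.  The start
    codon (human codon at ``start_offset``, region coordinates) must match
    exactly; for uORF/uoORF regions the terminal stop codon must also be a
    stop in the species.  Substitutions are tallied syn/nonsyn per aligned
    codon with exactly one base difference.
    """
    if species not in block.rows:
        raise KeyError(f"species {species} absent from block {block.region_id}")
    human_row = block.human_row
    sp_row = block.rows[species]
    if set(sp_row) <= {"-"}:
        return SpeciesVerdict(species, False, 0, 0, False, False, 0, 0, alignable=False)

    # map human (ungapped) region offsets -> alignment columns
    col_of: list[int] = [i for i, c in enumerate(human_row) if c != "-"]
    n_region = len(col_of)

    fs = sum(1 for run in _gap_runs(human_row, range(len(human_row))) if run % 3)
    fs += sum(1 for run in _gap_runs(sp_row, range(len(sp_row))) if run % 3)

    stop_count = 0
    syn = nonsyn = 0
    start_conserved = False
    stop_codon_conserved = region_type not in ("UORF", "UOORF")
    for codon_start in range(0, n_region - 2, 3):
        cols = [col_of[codon_start + k] for k in range(3)]
        h_codon = "".join(human_row[c] for c in cols)
        s_codon = "".join(sp_row[c] for c in cols)
        if "-" in s_codon:
            continue
        if s_codon in STOP_CODONS and h_codon not in STOP_CODONS:
            stop_count += 1
        if codon_start == start_offset:
            start_conserved = s_codon == h_codon
        if region_type in ("UORF", "UOORF") and h_codon in STOP_CODONS and codon_start >= n_region - 3:
            stop_codon_conserved = s_codon in STOP_CODONS
        diffs = sum(1 for a, b in zip(h_codon, s_codon) if a != b)
        if diffs == 1 and "N" not in h_codon and "N" not in s_codon:
            if translate_nt(h_codon) == translate_nt(s_codon):
                syn += 1
            else:
                nonsyn += 1
    frame_conserved = stop_count == 0 and fs == 0
    return SpeciesVerdict(
        species=species,
        frame_conserved=frame_conserved,
        stop_count=stop_count,
        frameshift_count=fs,
        start_conserved=start_conserved,
        stop_codon_conserved=stop_codon_conserved,
        syn_count=syn,
        nonsyn_count=nonsyn,
    )


def assign_bin(
    verdicts: list[SpeciesVerdict],
    species_clade: dict[str, str],
    region_type: str = "EXTENSION",
    min_fraction: float = 0.5,
    require_start: bool = True,
) -> str:
    """Deepest clade conserved under the fraction rule.

    Walking outward from chimpanzee, every clade up to the assigned bin must
    have at least ``min_fraction`` of its alignable species conserving the
    frame (and start / stop codon per the region-type rules).  Clades with no
    alignable species do not break the chain but cannot be the final bin.
    HUMAN when no clade qualifies.
    """

    def conserved(v: SpeciesVerdict) -> bool:
        ok = v.frame_conserved
        if require_start:
            ok = ok and v.start_conserved
        if region_type in ("UORF", "UOORF"):
            ok = ok and v.stop_codon_conserved
        return ok

    by_clade: dict[str, list[SpeciesVerdict]] = {}
    for v in verdicts:
        clade = species_clade.get(v.species)
        if clade is None:
            raise KeyError(f"species {v.species} has no clade assignment")
        by_clade.setdefault(clade, []).append(v)

    best = "HUMAN"
    for clade in CLADES[1:]:
        members = [v for v in by_clade.get(clade, []) if v.alignable]
        if not members:
            continue  # vacuous: chain unbroken, but cannot be the bin
        frac = sum(1 for v in members if conserved(v)) / len(members)
        if frac >= min_fraction:
            best = clade
        else:
            break
    return best


def codon_depth(
    block: AlignmentBlock, offset: int, min_fraction: float = 0.5
) -> int:
    """Clade depth to which the codon at region ``offset`` is conserved.

    Used to annotate start-codon candidates: the deepest clade (nested walk)
    in which at least ``min_fraction`` of alignable species carry the
    identical codon.
    """
    human_row = block.human_row
    col_of = [i for i, c in enumerate(human_row) if c != "-"]
    if offset + 3 > len(col_of):
        return 0
    cols = [col_of[offset + k] for k in range(3)]
    h_codon = "".join(human_row[c] for c in cols)

    by_clade: dict[str, list[bool]] = {}
    for sp, row in block.rows.items():
        if sp == block.human:
            continue
        clade = block.species_clade.get(sp)
        if clade is None:
            continue
        if set(row) <= {"-"}:
            continue
        s_codon = "".join(row[c] for c in cols)
        by_clade.setdefault(clade, []).append(s_codon == h_codon)

    depth = 0
    for clade in CLADES[1:]:
        members = by_clade.get(clade)
        if not members:
            continue
        if sum(members) / len(members) >= min_fraction:
            depth = CLADE_DEPTH[clade]
        else:
            break
    return depth


def conservation_summary(bins: list[str]) -> dict[str, float]:
    """Percentage shares over the clade groupings used in reporting."""
    n = len(bins)
    pct = lambda k: 100.0 * k / n if n else 0.0
    count = lambda *names: sum(1 for b in bins if b in names)
    return {
        "n": n,
        "at_least_mammals": pct(count("MAMMALS", "TETRAPODS")),
        "primates_only": pct(count("PRIMATES")),
        "not_all_primates": pct(count("HUMAN", "CHIMP", "CHIMP_GORILLA", "APES", "MONKEYS")),
        "not_beyond_gorilla": pct(count("HUMAN", "CHIMP", "CHIMP_GORILLA")),
        "human_only": pct(count("HUMAN")),
    }
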