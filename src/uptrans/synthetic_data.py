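"""Synthetic toy datasets with planted ground truth.

Generates a complete input bundle -- genome FASTA, GTF annotation, transcript
tags, a Percolator-like PSM table, per-region orthologous alignments, a
species->clade map, a germline VCF and a truth.json -- so that every pipeline
stage is testable without downloads.

The generator emulates the statistical structure the analysis assumes:
GC-rich 5'UTRs (default target 69.4% vs ~52% in coding sequence), upstream
regions initiated at ATG or near-cognate codons with a planted Kozak class,
clade-nested conservation decay (species deeper than the planted clade get
stop codons or frameshifts), allele-frequency-split NS/Syn variant sets with
an optional purifying-selection thinning of common non-synonymous variants,
and cell-line-enriched upstream-region PSMs.  Everything is reproducible:
the same spec and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyteomics import parser as pyt_parser

from .annotation_io import GenomeSequence, TranscriptModel, revcomp
from .conservation import CLADES, CLADE_DEPTH
from .config import DbConfig
from .start_codon import START_SET
from .upstream_db import STOP_CODONS, build_database, translate_nt
from .psm_filter import find_peptide

log = logging.getLogger(__name__)

EXTENSION, UORF, UOORF, NONE = "EXTENSION", "UORF", "UOORF", "NONE"

_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
SAFE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS and c not in START_SET]
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _c in SAFE_CODONS:
    _CODONS_FOR_AA.setdefault(translate_nt(_c), []).append(_c)
# residues usable inside planted peptides: encodable without start/stop codons
# and free of cleavage-relevant residues (K/R internal, P at boundaries)
PEPTIDE_ALPHABET = sorted(set(_CODONS_FOR_AA) - set("KRPX"))

_SPACER_FOR_BASE = {"A": "ACC", "G": "GGC", "C": "CCC", "T": "TCC"}
_DECOY_FOR_BASE = {"A": "ACG", "G": "GTG", "C": "CTG", "T": "TTG"}
_PLUS4 = {"G": "GGC", "H": "CAC"}
_BREAK_BASE = {"A": "G", "G": "A", "C": "A", "T": "A"}


class InconsistentSpecError(ValueError):
    """Raised when a gene plan cannot be realised (e.g. window too long)."""


@dataclass
class GenePlant:
    """Plan for one synthetic gene."""

    gene_id: str
    region_type: str = NONE                  # EXTENSION / UORF / UOORF / NONE
    strand: str = "+"
    true_start_codon: str = "ATG"
    kozak_class: str = "STRONG"              # STRONG / MODERATE / WEAK
    conservation_depth: str = "MAMMALS"      # clade bin name
    utr_gc: float = 0.694
    cds_gc: float = 0.523
    utr_len: int = 300
    cds_len: int = 240                       # incl. ATG and stop; multiple of 3
    n_true_peptides: int = 2
    n_true_psms: int = 4                     # total over the gene's peptides
    n_canonical_psms: int = 40
    n_variants: int = 8
    trap: bool = False                       # stop-adjacent false-positive peptides
    plant_decoy_start: bool = False          # non-conserved near-cognate upstream of the start

    def validate(self) -> None:
        if self.region_type not in (EXTENSION, UORF, UOORF, NONE):
            raise InconsistentSpecError(f"unknown region type {self.region_type}")
        if self.cds_len % 3 or self.cds_len < 60:
            raise InconsistentSpecError("cds_len must be a multiple of 3 and >= 60")
        if self.region_type != NONE:
            if self.true_start_codon not in START_SET:
                raise InconsistentSpecError(f"{self.true_start_codon} is not ATG or near-cognate")
            if self.conservation_depth not in CLADE_DEPTH:
                raise InconsistentSpecError(f"unknown clade {self.conservation_depth}")
            if self.utr_len < 210:
                raise InconsistentSpecError("utr_len too short to host a planted region")
            if self.plant_decoy_start and self.true_start_codon != "ATG" \
                    and self.conservation_depth == "HUMAN":
                raise InconsistentSpecError(
                    "a decoy near-cognate cannot be disambiguated from a human-only start"
                )
        if self.trap and self.region_type != NONE:
            raise InconsistentSpecError("trap genes must have region_type NONE")
        if self.trap and self.utr_len < 120:
            raise InconsistentSpecError("utr_len too short for a trap")


@dataclass
class PlantSpec:
    """Full dataset plan: genes plus dataset-wide nuisance parameters."""

    genes: list[GenePlant]
    seed: int = 0
    species_per_clade: int = 2
    # sample-class emission rates [tissue, cell_line, biopsy]
    canonical_class_rates: tuple[float, float, float] = (0.80, 0.15, 0.05)
    tur_class_rates: tuple[float, float, float] = (0.30, 0.60, 0.10)
    selection_regime: str = "NEUTRAL"        # NEUTRAL or PURIFYING
    ns_thinning: float = 0.5                 # keep prob. of common NS variants (PURIFYING)
    indel_prob: float = 0.1                  # fraction of variants planted as 2-nt deletions
    n_noise_psms: int = 0                    # random PSMs over target+decoy novel entries
    noise_pep_max: float = 1.0               # noise PEPs ~ Uniform(0, noise_pep_max)
    true_pep_max: float = 1e-4               # true/canonical PEPs ~ Uniform(0, this)

    def validate(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise InconsistentSpecError("duplicate gene ids")
        for gene in self.genes:
            gene.validate()
        if self.selection_regime not in ("NEUTRAL", "PURIFYING"):
            raise InconsistentSpecError(f"unknown regime {self.selection_regime}")

    @classmethod
    def default(
        cls,
        n_extension: int = 10,
        n_uorf: int = 5,
        n_uoorf: int = 5,
        n_none: int = 10,
        n_traps: int = 2,
        seed: int = 0,
        **kwargs,
    ) -> "PlantSpec":
        """A mixed study-condition spec; traps are carved out of the NONE genes."""
        rng = np.random.default_rng(seed)
        start_pool = ["ATG", "CTG", "GTG", "ACG", "ATT", "TTG", "AAG", "AGG", "ATA"]
        kozak_pool = ["STRONG", "MODERATE", "WEAK"]
        depth_pool = list(CLADES)
        genes: list[GenePlant] = []
        idx = 0

        def add(region_type: str, trap: bool = False) -> None:
            nonlocal idx
            idx += 1
            if region_type == NONE:
                genes.append(
                    GenePlant(
                        gene_id=f"G{idx:04d}", region_type=NONE, trap=trap,
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
                return
            depth = depth_pool[int(rng.integers(len(depth_pool)))]
            start = start_pool[int(rng.integers(len(start_pool)))]
            genes.append(
                GenePlant(
                    gene_id=f"G{idx:04d}",
                    region_type=region_type,
                    strand="+" if rng.random() < 0.5 else "-",
                    true_start_codon=start,
                    kozak_class=kozak_pool[int(rng.integers(3))],
                    conservation_depth=depth,
                    plant_decoy_start=bool(rng.random() < 0.5)
                    and not (start != "ATG" and depth == "HUMAN"),
                )
            )

        for _ in range(n_extension):
            add(EXTENSION)
        for _ in range(n_uorf):
            add(UORF)
        for _ in range(n_uoorf):
            add(UOORF)
        for i in range(n_none):
            add(NONE, trap=i < n_traps)
        return cls(genes=genes, seed=seed, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlantSpec":
        raw = yaml.safe_load(Path(path).read_text())
        genes = [GenePlant(**g) for g in raw.pop("genes")]
        return cls(genes=genes, **raw)


# ---------------------------------------------------------------------------
# sequence construction helpers


def _biased_seq(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """Sequence with an exact (rounded) GC composition, shuffled."""
    n_gc = int(round(n * gc))
    bases = [("G", "C")[int(rng.integers(2))] for _ in range(n_gc)]
    bases += [("A", "T")[int(rng.integers(2))] for _ in range(n - n_gc)]
    rng.shuffle(bases)
    return bases


def _rand_base(rng: np.random.Generator, gc: float) -> str:
    if rng.random() < gc:
        return ("G", "C")[int(rng.integers(2))]
    return ("A", "T")[int(rng.integers(2))]


def _encode_peptide(rng: np.random.Generator, peptide: str) -> str:
    nt = []
    for aa in peptide:
        if aa == "M":
            nt.append("ATG")  # the only Met codon; placed outside candidate scan windows
            continue
        options = _CODONS_FOR_AA[aa]
        nt.append(options[int(rng.integers(len(options)))])
    return "".join(nt)


def _random_peptide(rng: np.random.Generator, length: int, first: str | None = None) -> str:
    body_len = length - 1 - (1 if first else 0)
    body = "".join(
        PEPTIDE_ALPHABET[int(rng.integers(len(PEPTIDE_ALPHABET)))] for _ in range(body_len)
    )
    return (first or "") + body + "R"


@dataclass
class _Plant:
    """Book-keeping for one planted gene, in transcript coordinates."""

    win_start: int = -1
    win_end: int = -1
    frame: int = -1                 # vs CDS
    start_offset: int = -1
    peptide_positions: list[tuple[str, int]] = field(default_factory=list)
    trap_peptides: list[tuple[str, int]] = field(default_factory=list)


def _repair(
    t: list[str],
    fixed: set[int],
    rng: np.random.Generator,
    gc: float,
    no_stop: list[int],
    no_start: list[int],
    no_proline: list[int],
    max_iter: int = 500,
) -> None:
    """Resample free bases until no forbidden codon remains.

    no_stop / no_start / no_proline are codon start positions.  Raises
    InconsistentSpecError when a violating codon has no free base.
    """
    for _ in range(max_iter):
        violations = []
        for p in no_stop:
            if "".join(t[p : p + 3]) in STOP_CODONS:
                violations.append(p)
        for p in no_start:
            if "".join(t[p : p + 3]) in START_SET:
                violations.append(p)
        for p in no_proline:
            if translate_nt("".join(t[p : p + 3])) == "P":
                violations.append(p)
        if not violations:
            return
        for p in violations:
            free = [i for i in (p, p + 1, p + 2) if i not in fixed]
            if not free:
                raise InconsistentSpecError(f"unsatisfiable constraint at codon {p}")
            for i in free:
                t[i] = _rand_base(rng, gc)
    raise InconsistentSpecError("constraint repair did not converge")


def _build_gene(
    plan: GenePlant, rng: np.random.Generator, used_peptides: set[str]
) -> tuple[list[str], _Plant]:
    """Build the transcript-space sequence (UTR+CDS+trailer) with plants."""
    utr_len, cds_len = plan.utr_len, plan.cds_len
    cds_start = utr_len
    t = _biased_seq(rng, utr_len, plan.utr_gc)
    cds = ["A", "T", "G"]
    while len(cds) < cds_len - 3:
        codon = [_rand_base(rng, plan.cds_gc) for _ in range(3)]
        if "".join(codon) in STOP_CODONS:
            continue
        cds.extend(codon)
    cds.extend(["T", "A", "A"])
    t += cds
    t += [_rand_base(rng, 0.5) for _ in range(30)]  # 3' trailer

    fixed: set[int] = set(range(cds_start, cds_start + 3))  # annotated ATG
    fixed |= set(range(cds_start + cds_len - 3, cds_start + cds_len))  # CDS stop
    plant = _Plant()
    no_stop: list[int] = list(range(cds_start, cds_start + cds_len - 3, 3))
    no_start: list[int] = []
    no_proline: list[int] = []

    def set_codon(pos: int, codon: str) -> None:
        t[pos : pos + 3] = list(codon)
        fixed.update((pos, pos + 1, pos + 2))

    def new_peptide(length: int = 9, first: str | None = None) -> str:
        for _ in range(100):
            pep = _random_peptide(rng, length, first)
            if pep not in used_peptides:
                used_peptides.add(pep)
                return pep
        raise InconsistentSpecError("could not draw a fresh peptide")

    def plant_peptide(pos: int, pep: str, cleave_before: bool = True) -> None:
        if cleave_before:
            set_codon(pos - 3, "CGT")
        for i, aa in enumerate(pep):
            set_codon(pos + 3 * i, _encode_peptide(rng, aa))
        no_proline.append(pos + 3 * len(pep))

    if plan.region_type != NONE:
        f = {EXTENSION: 0}.get(plan.region_type)
        if f is None:
            f = int(rng.integers(3)) if plan.region_type == UORF else int(rng.integers(1, 3))
        if plan.region_type == EXTENSION:
            win_start, win_end = cds_start - 90, cds_start
            stop_scan_end = cds_start
        elif plan.region_type == UORF:
            # deepest frame-f codon boundary whose stop still ends before the CDS
            win_end = {0: cds_start - 3, 1: cds_start - 5, 2: cds_start - 4}[f]
            win_start = win_end - 81
            stop_scan_end = win_end - 3
            set_codon(win_end - 3, "TGA")
        else:  # UOORF
            stop_pos = cds_start + 27 + f
            win_end = stop_pos + 3
            win_start = cds_start - 72 + f
            stop_scan_end = stop_pos
            set_codon(stop_pos, "TGA")
        if win_start - 3 <= 0:
            raise InconsistentSpecError("window does not fit in the UTR")
        set_codon(win_start - 3, "TAG")  # bounding upstream stop
        s = win_start + 3
        minus3 = {"STRONG": "A", "MODERATE": "A", "WEAK": "C"}[plan.kozak_class]
        plus4 = {"STRONG": "G", "MODERATE": "H", "WEAK": "H"}[plan.kozak_class]
        if plan.plant_decoy_start:
            set_codon(win_start, _DECOY_FOR_BASE[minus3])
        else:
            set_codon(win_start, _SPACER_FOR_BASE[minus3])
        set_codon(s, plan.true_start_codon)
        set_codon(s + 3, _PLUS4[plus4])
        p1 = s + 9
        pep1 = new_peptide()
        plant_peptide(p1, pep1)
        plant.peptide_positions.append((pep1, p1))
        if plan.n_true_peptides >= 2:
            if plan.region_type == EXTENSION:
                # junction peptide: spans the UTR-CDS boundary, the annotated
                # initiator Met internal at the position of the CDS start
                jp = cds_start - 12
                pep2 = new_peptide(9)
                pep2 = pep2[:4] + "M" + pep2[5:]
                used_peptides.add(pep2)
                plant_peptide(jp, pep2)
                plant.peptide_positions.append((pep2, jp))
            else:
                p2 = p1 + 30
                pep2 = new_peptide()
                plant_peptide(p2, pep2)
                plant.peptide_positions.append((pep2, p2))
        plant.win_start, plant.win_end = win_start, win_end
        plant.frame = (win_start - cds_start) % 3
        plant.start_offset = s
        no_stop.extend(range(win_start, stop_scan_end, 3))
        first_pep = plant.peptide_positions[0][1]
        skip = {s} | ({win_start} if plan.plant_decoy_start else set())
        no_start.extend(p for p in range(win_start, first_pep + 1, 3) if p not in skip)

    if plan.trap:
        # a false-positive-like peptide directly after an in-frame stop, with
        # no possible start codon upstream of it
        ws = (utr_len // 2) - ((utr_len // 2) % 3)
        set_codon(ws, "TAG")
        pep = new_peptide(9, first="G")
        tp = ws + 3
        plant_peptide(tp, pep, cleave_before=False)
        plant.trap_peptides.append((pep, tp))

    _repair(t, fixed, rng, plan.utr_gc, no_stop, no_start, no_proline)
    return t, plant


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class _GeneBuild:
    plan: GenePlant
    transcript_id: str
    contig: str
    contig_seq: str
    model: TranscriptModel
    t_seq: str
    plant: _Plant


def _assemble_gene(plan: GenePlant, idx: int, rng: np.random.Generator,
                   used_peptides: set[str]) -> _GeneBuild:
    t_list, plant = _build_gene(plan, rng, used_peptides)
    t = "".join(t_list)
    utr_len = plan.utr_len
    e1 = utr_len // 2
    if plant.win_start >= 0 and plant.win_start - 3 <= e1:
        raise InconsistentSpecError("planted window straddles the intron")
    flank, intron_len = 20, 50
    intron = "".join(_rand_base(rng, 0.45) for _ in range(intron_len))
    plus_contig = (
        "".join(_rand_base(rng, 0.45) for _ in range(flank))
        + t[:e1] + intron + t[e1:]
        + "".join(_rand_base(rng, 0.45) for _ in range(flank))
    )
    ex1 = (flank, flank + e1)
    ex2 = (flank + e1 + intron_len, flank + e1 + intron_len + (len(t) - e1))
    cds_g = (ex2[0] + (utr_len - e1), ex2[0] + (utr_len - e1) + plan.cds_len)
    contig = f"chr_{plan.gene_id}"
    if plan.strand == "-":
        L = len(plus_contig)
        flip = lambda iv: (L - iv[1], L - iv[0])
        contig_seq = revcomp(plus_contig)
        exons = sorted([flip(ex1), flip(ex2)])
        cds = [flip(cds_g)]
    else:
        contig_seq = plus_contig
        exons = [ex1, ex2]
        cds = [cds_g]
    tid = f"T{idx:04d}"
    model = TranscriptModel(
        transcript_id=tid, gene_id=plan.gene_id, contig=contig, strand=plan.strand,
        exons=exons, cds=cds, tags={"APPRIS_PRINCIPAL", "MANE_SELECT"},
    )
    return _GeneBuild(plan, tid, contig, contig_seq, model, t, plant)


# ---------------------------------------------------------------------------
# alignments


def species_table(species_per_clade: int = 2) -> dict[str, str]:
    """Default species -> clade map: N species per clade, chimp..tetrapods."""
    return {
        f"{clade.lower()}_{i + 1}": clade
        for clade in CLADES[1:]
        for i in range(species_per_clade)
    }


def _synonymous_sub(rng: np.random.Generator, codon: str) -> str | None:
    options = [
        c for c in _ALL_CODONS
        if c != codon and c not in STOP_CODONS
        and sum(a != b for a, b in zip(c, codon)) == 1
        and translate_nt(c) == translate_nt(codon)
    ]
    if not options:
        return None
    return options[int(rng.integers(len(options)))]


def _alignment_rows(
    build: _GeneBuild, species_clade: dict[str, str], rng: np.random.Generator
) -> dict[str, str]:
    plan, plant = build.plan, build.plant
    w = build.t_seq[plant.win_start : plant.win_end]
    n_codons = len(w) // 3
    start_idx = (plant.start_offset - plant.win_start) // 3
    depth = CLADE_DEPTH[plan.conservation_depth]
    rows = {"human": w}
    for sp_i, (species, clade) in enumerate(sorted(species_clade.items())):
        row = list(w)
        if plan.plant_decoy_start:
            row[0] = _BREAK_BASE[row[0]]  # decoy codon never conserved
        if CLADE_DEPTH[clade] <= depth:
            # conserved: optionally one synonymous substitution
            for _ in range(6):
                j = int(rng.integers(n_codons))
                if j in (0, start_idx) or j == n_codons - 1:
                    continue
                sub = _synonymous_sub(rng, w[3 * j : 3 * j + 3])
                if sub:
                    row[3 * j : 3 * j + 3] = list(sub)
                    break
        else:
            # broken: start codon lost plus a stop or a frameshift
            row[3 * start_idx] = _BREAK_BASE[row[3 * start_idx]]
            j = start_idx + 2 if start_idx + 2 < n_codons - 1 else max(1, n_codons - 2)
            if sp_i % 2 == 0:
                row[3 * j : 3 * j + 3] = list("TGA")
            else:
                row[3 * j] = "-"
        rows[species] = "".join(row)
    return rows


# ---------------------------------------------------------------------------
# variants


def plant_region_variants(
    region_seqs: dict[str, str],
    rng: np.random.Generator,
    n_per_region: int = 8,
    regime: str = "NEUTRAL",
    ns_thinning: float = 0.5,
    indel_prob: float = 0.0,
    af_cutoff: float = 0.005,
) -> pd.DataFrame:
    """Spray variants over regions; thin common non-synonymous ones under
    PURIFYING.  Returns region_id, pos, ref, alt, af (region coordinates)."""
    rows = []
    for region_id in sorted(region_seqs):
        seq = region_seqs[region_id]
        for _ in range(n_per_region):
            if rng.random() < indel_prob and len(seq) > 9:
                pos = int(rng.integers(0, len(seq) - 3))
                ref, alt = seq[pos : pos + 3], seq[pos]
                effect = "FRAMESHIFT"
            else:
                pos = int(rng.integers(len(seq)))
                ref = seq[pos]
                alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
                codon_start = 3 * (pos // 3)
                old = seq[codon_start : codon_start + 3]
                new = old[: pos - codon_start] + alt + old[pos - codon_start + 1 :]
                if len(old) < 3:
                    effect = "NONSYN"
                elif translate_nt(old) == translate_nt(new):
                    effect = "SYN"
                else:
                    effect = "NONSYN"
            common = rng.random() < 0.5
            if (
                regime == "PURIFYING"
                and common
                and effect != "SYN"
                and rng.random() > ns_thinning
            ):
                continue
            af = (
                float(rng.uniform(af_cutoff, 0.5))
                if common
                else float(rng.uniform(1e-4, af_cutoff * 0.98))
            )
            rows.append({"region_id": region_id, "pos": pos, "ref": ref, "alt": alt, "af": af})
    return pd.DataFrame(rows, columns=["region_id", "pos", "ref", "alt", "af"])


def _variants_to_vcf_rows(
    variant_df: pd.DataFrame, builds: dict[str, _GeneBuild]
) -> list[tuple[str, int, str, str, float]]:
    rows = []
    for r in variant_df.itertuples(index=False):
        build = builds[r.region_id]
        model = build.model
        t_pos = build.plant.win_start + int(r.pos)
        g_positions = [model.transcript_to_genomic(t_pos + k) for k in range(len(r.ref))]
        if len(g_positions) > 1:
            step = g_positions[1] - g_positions[0]
            if any(b - a != step for a, b in zip(g_positions, g_positions[1:])):
                continue  # crosses a splice junction; unrepresentable as one record
        if model.strand == "-":
            pos = min(g_positions)
            ref, alt = revcomp(r.ref), revcomp(r.alt)
        else:
            pos = g_positions[0]
            ref, alt = r.ref, r.alt
        rows.append((model.contig, pos, ref, alt, float(r.af)))
    rows.sort(key=lambda x: (x[0], x[1]))
    return rows


# ---------------------------------------------------------------------------
# file emission


def _write_gtf(builds: list[_GeneBuild], path: Path) -> None:
    with open(path, "w") as fh:
        for b in builds:
            attrs = f'gene_id "{b.plan.gene_id}"; transcript_id "{b.transcript_id}";'
            lines = [("gene", min(s for s, _ in b.model.exons), max(e for _, e in b.model.exons)),
                     ("transcript", min(s for s, _ in b.model.exons), max(e for _, e in b.model.exons))]
            for s, e in b.model.exons:
                lines.append(("exon", s, e))
            for s, e in b.model.cds:
                lines.append(("CDS", s, e))
            for feature, s, e in lines:
                fh.write(
                    "\t".join(
                        [b.contig, "uptrans_sim", feature, str(s + 1), str(e), ".",
                         b.plan.strand, "0" if feature == "CDS" else ".", attrs]
                    )
                    + "\n"
                )


def _write_fasta(seqs: dict[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_vcf(rows: list[tuple[str, int, str, str, float]], contigs: dict[str, int], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        for name in sorted(contigs):
            fh.write(f"##contig=<ID={name},length={contigs[name]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, ref, alt, af in rows:
            fh.write(f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\tAF={af:.6f}\n")


def _tryptic_peptides(protein: str) -> list[str]:
    peps = pyt_parser.cleave(protein, "trypsin", missed_cleavages=0)
    return sorted(p for p in peps if 7 <= len(p) <= 40)


def _draw_class(rng: np.random.Generator, rates: tuple[float, float, float]) -> str:
    r = rng.random()
    if r < rates[0]:
        return "tissue"
    if r < rates[0] + rates[1]:
        return "cell_line"
    return "biopsy"


def generate(spec: PlantSpec, out_dir: str | Path) -> dict:
    """Write the full synthetic bundle and return its truth record."""
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(exist_ok=True)

    used_peptides: set[str] = set()
    builds: list[_GeneBuild] = []
    for idx, plan in enumerate(spec.genes, start=1):
        rng = np.random.default_rng([spec.seed % (2**31), idx])
        builds.append(_assemble_gene(plan, idx, rng, used_peptides))

    genome = GenomeSequence({b.contig: b.contig_seq for b in builds})
    models = [b.model for b in builds]
    _write_fasta({b.contig: b.contig_seq for b in builds}, out / "genome.fa")
    _write_gtf(builds, out / "annot.gtf")
    with open(out / "tags.tsv", "w") as fh:
        for b in builds:
            fh.write(f"{b.transcript_id}\tAPPRIS_PRINCIPAL\n")
            fh.write(f"{b.transcript_id}\tMANE_SELECT\n")

    database = build_database(models, genome, config=DbConfig())
    novel_entries = [(acc, prot) for acc, prot, cls in database.entries if cls == "target_novel"]
    decoy_entries = [(acc, prot) for acc, prot, cls in database.entries if cls == "decoy_novel"]

    def accession_for(peptide: str, gene_id: str) -> str:
        for acc, prot in novel_entries:
            orf = database.novel_orfs[acc]
            if any(p.gene_id == gene_id for p in orf.provenance) and find_peptide(peptide, prot):
                return acc
        raise InconsistentSpecError(f"planted peptide {peptide} absent from the database")

    # --- PSM table ---------------------------------------------------------
    psm_rows: list[dict] = []
    truth_genes: list[dict] = []
    noise_truth: list[dict] = []
    counter = 0

    def emit(peptide: str, pep: float, acc: str, sclass: str) -> str:
        nonlocal counter
        counter += 1
        pid = f"psm{counter:06d}"
        psm_rows.append(
            {"psm_id": pid, "peptide": peptide, "pep": f"{pep:.3e}", "accession": acc,
             "sample_id": f"S_{sclass}", "sample_class": sclass}
        )
        return pid

    for idx, b in enumerate(builds, start=1):
        rng = np.random.default_rng([spec.seed % (2**31), idx, 7])
        plan, plant = b.plan, b.plant
        gene_truth: dict = {
            "gene_id": plan.gene_id,
            "transcript_id": b.transcript_id,
            "strand": plan.strand,
            "region_type": plan.region_type,
            "trap": plan.trap,
            "utr_gc_target": plan.utr_gc,
        }
        if plan.region_type != NONE:
            gene_truth.update(
                start_codon=plan.true_start_codon,
                start_offset=plant.start_offset,
                kozak=plan.kozak_class,
                conservation_bin=plan.conservation_depth,
                window=[plant.win_start, plant.win_end],
                frame_vs_cds=plant.frame,
                peptides=[p for p, _ in plant.peptide_positions],
                decoy_start_planted=plan.plant_decoy_start,
            )
            positions = plant.peptide_positions
            n_psms = max(2, plan.n_true_psms)
            psm_alloc = [1] * len(positions)
            for k in range(n_psms - len(positions)):
                psm_alloc[k % len(positions)] += 1
            psm_ids = []
            for (peptide, _), n in zip(positions, psm_alloc):
                acc = accession_for(peptide, plan.gene_id)
                for _ in range(n):
                    psm_ids.append(
                        emit(peptide, float(rng.uniform(0, spec.true_pep_max)), acc,
                             _draw_class(rng, spec.tur_class_rates))
                    )
            gene_truth["true_psm_ids"] = psm_ids
        if plan.trap:
            trap_ids = []
            for peptide, _ in plant.trap_peptides:
                acc = accession_for(peptide, plan.gene_id)
                for _ in range(2):
                    trap_ids.append(
                        emit(peptide, float(rng.uniform(0, spec.true_pep_max)), acc,
                             _draw_class(rng, spec.tur_class_rates))
                    )
            gene_truth["trap_peptides"] = [p for p, _ in plant.trap_peptides]
            gene_truth["trap_psm_ids"] = trap_ids
        # canonical PSMs from the annotated protein
        known_prot = translate_nt(
            b.t_seq[plan.utr_len : plan.utr_len + plan.cds_len]
        ).rstrip("*")
        pool = _tryptic_peptides(known_prot)
        for _ in range(plan.n_canonical_psms if pool else 0):
            peptide = pool[int(rng.integers(len(pool)))]
            emit(peptide, float(rng.uniform(0, spec.true_pep_max)), f"sp|{b.transcript_id}",
                 _draw_class(rng, spec.canonical_class_rates))
        truth_genes.append(gene_truth)

    # noise PSMs over target+decoy novel entries, PEP ~ U(0, noise_pep_max)
    rng_noise = np.random.default_rng([spec.seed % (2**31), 999983])
    pep_cache: dict[str, list[str]] = {}
    for _ in range(spec.n_noise_psms):
        for _attempt in range(50):
            is_decoy = bool(rng_noise.random() < 0.5)
            entries = decoy_entries if is_decoy else novel_entries
            acc, prot = entries[int(rng_noise.integers(len(entries)))]
            if acc not in pep_cache:
                pep_cache[acc] = _tryptic_peptides(prot)
            if pep_cache[acc]:
                break
        else:
            raise InconsistentSpecError("no tryptic peptides available for noise")
        peptide = pep_cache[acc][int(rng_noise.integers(len(pep_cache[acc])))]
        pid = emit(peptide, float(rng_noise.uniform(0, spec.noise_pep_max)), acc,
                   _draw_class(rng_noise, spec.canonical_class_rates))
        noise_truth.append({"psm_id": pid, "is_decoy": is_decoy})

    pd.DataFrame(psm_rows).to_csv(out / "psms.tsv", sep="\t", index=False)

    # --- alignments & clades ----------------------------------------------
    clades = species_table(spec.species_per_clade)
    with open(out / "clades.tsv", "w") as fh:
        for sp in sorted(clades):
            fh.write(f"{sp}\t{clades[sp]}\n")
    for idx, b in enumerate(builds, start=1):
        if b.plan.region_type == NONE:
            continue
        rng = np.random.default_rng([spec.seed % (2**31), idx, 11])
        rows = _alignment_rows(b, clades, rng)
        _write_fasta(rows, out / "alignments" / f"{b.plan.gene_id}.fa")

    # --- variants -----------------------------------------------------------
    region_builds = {b.plan.gene_id: b for b in builds if b.plan.region_type != NONE}
    region_seqs = {
        gid: b.t_seq[b.plant.win_start : b.plant.win_end] for gid, b in region_builds.items()
    }
    rng_var = np.random.default_rng([spec.seed % (2**31), 424243])
    variant_df = plant_region_variants(
        region_seqs, rng_var,
        n_per_region=max((b.plan.n_variants for b in builds), default=0),
        regime=spec.selection_regime, ns_thinning=spec.ns_thinning,
        indel_prob=spec.indel_prob,
    )
    vcf_rows = _variants_to_vcf_rows(variant_df, region_builds)
    _write_vcf(vcf_rows, {b.contig: len(b.contig_seq) for b in builds}, out / "variants.vcf")

    truth = {
        "seed": spec.seed,
        "selection_regime": spec.selection_regime,
        "ns_thinning": spec.ns_thinning,
        "genes": truth_genes,
        "noise_psms": noise_truth,
        "n_variants_written": len(vcf_rows),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth


def dataset_digest(out_dir: str | Path) -> str:
    """SHA-256 over every generated file (for determinism checks)."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).rglob("*")):
        if path.is_file() and path.suffix != ".fai":
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# printed-table fixture


def table1_fixture() -> pd.DataFrame:
    """The published conservation x type x ATG cross-tab of the 192 regions.

    Rows are last-common-ancestor clade bins; columns are All regions,
    5' extensions, uORF/uoORF, and regions with ATG starts.  The Total row is
    computed, not stored.
    """
    data = {
        "HUMAN": (23, 15, 8, 5),
        "CHIMP": (14, 14, 0, 3),
        "CHIMP_GORILLA": (19, 16, 3, 6),
        "APES": (22, 18, 4, 3),
        "MONKEYS": (45, 41, 4, 8),
        "PRIMATES": (27, 26, 1, 1),
        "MAMMALS": (38, 37, 1, 6),
        "TETRAPODS": (4, 4, 0, 3),
    }
    df = pd.DataFrame.from_dict(
        data, orient="index", columns=["All", "5' ext", "uORF/uoORF", "ATG"]
    )
    df.loc["Total"] = df.sum()
    return df
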