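"""Post-rescoring PSM acceptance rules.

Applies the strict acceptance rules used for novel-region discovery: an
inclusive posterior-error-probability ceiling (default 2e-4), peptide length
7-40, fully tryptic termini with at most two missed cleavages, and
novel-class target/decoy FDR accounting.  Decoy PSMs are retained (flagged)
through filtering so that FDR can be computed on the accepted set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import FilterConfig
from .upstream_db import STOP_CODONS, SearchDatabase, accession_class

log = logging.getLogger(__name__)

SAMPLE_CLASSES = {"tissue", "cell_line", "biopsy"}

_MOD_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)|[^A-Za-z]")


def strip_modifications(peptide: str) -> str:
    """Remove modification notation (e.g. oxidised Met brackets); uppercase."""
    return _MOD_RE.sub("", peptide).upper()


@dataclass
class PsmRecord:
    psm_id: str
    peptide: str
    pep: float
    accession: str
    sample_id: str
    sample_class: str
    is_decoy: bool
    is_novel: bool

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z]+", self.peptide):
            raise ValueError(f"malformed peptide {self.peptide!r}")
        if not 0.0 <= self.pep <= 1.0:
            raise ValueError(f"PEP out of range: {self.pep}")


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Read the tab-delimited PSM table (Percolator-output-like).

    Columns: psm_id, peptide, pep, accession, sample_id, sample_class.
    Decoy/novel status is inferred from the accession prefix.
    """
    df = pd.read_csv(path, sep="\t", dtype={"psm_id": str, "sample_id": str})
    records = []
    for row in df.itertuples(index=False):
        is_decoy, is_novel = accession_class(row.accession)
        records.append(
            PsmRecord(
                psm_id=row.psm_id,
                peptide=strip_modifications(row.peptide),
                pep=float(row.pep),
                accession=row.accession,
                sample_id=row.sample_id,
                sample_class=row.sample_class,
                is_decoy=is_decoy,
                is_novel=is_novel,
            )
        )
    return records


def _il(seq: str) -> str:
    return seq.replace("I", "L")


def find_peptide(peptide: str, protein: str, il_equivalent: bool = True) -> list[int]:
    """All start offsets of the peptide in the protein (I/L-aware)."""
    hay = _il(protein) if il_equivalent else protein
    needle = _il(peptide) if il_equivalent else peptide
    hits, start = [], 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def legal_tryptic(
    peptide: str, protein: str, config: FilterConfig | None = None
) -> tuple[bool, int]:
    """Is the peptide fully tryptic within the protein, and how many missed
    cleavages does it carry?

    Legal iff at some occurrence the N-terminus is the protein start or is
    preceded by K/R (with the K/R-P bond uncleavable when configured), the
    C-terminus is K/R (not before P) or the protein end, and the internal
    missed-cleavage count is within the configured maximum.  Raises if the
    peptide does not occur in the protein at all.
    """
    config = config or FilterConfig()
    occurrences = find_peptide(peptide, protein, config.il_equivalent)
    if not occurrences:
        raise ValueError("peptide does not occur in protein")

    def cleaves(res: str, nxt: str | None) -> bool:
        if res not in "KR":
            return False
        return not (config.no_cleave_before_p and nxt == "P")

    best: tuple[bool, int] = (False, 0)
    for start in occurrences:
        end = start + len(peptide)
        nterm_ok = start == 0 or cleaves(protein[start - 1], peptide[0])
        cterm_ok = end == len(protein) or cleaves(
            peptide[-1], protein[end] if end < len(protein) else None
        )
        missed = sum(
            1
            for i in range(len(peptide) - 1)
            if cleaves(peptide[i], peptide[i + 1])
        )
        if nterm_ok and cterm_ok and missed <= config.max_missed_cleavages:
            return True, missed
        best = (False, missed)
    return best


def filter_psms(
    psms: list[PsmRecord],
    database: SearchDatabase,
    config: FilterConfig | None = None,
) -> list[PsmRecord]:
    """Keep PSMs with PEP <= pep_max (inclusive), legal length and tryptic
    termini.  Decoy PSMs pass through the same rules, flagged, so the
    accepted set supports target/decoy FDR estimation."""
    config = config or FilterConfig()
    proteins = database.as_dict()
    accepted = []
    for psm in psms:
        if psm.pep > config.pep_max:
            continue
        if not config.min_len <= len(psm.peptide) <= config.max_len:
            continue
        protein = proteins.get(psm.accession)
        if protein is None:
            log.warning("PSM %s references unknown accession %s", psm.psm_id, psm.accession)
            continue
        try:
            ok, _ = legal_tryptic(psm.peptide, protein, config)
        except ValueError:
            log.warning("PSM %s peptide absent from its protein", psm.psm_id)
            continue
        if ok:
            accepted.append(psm)
    return accepted


def novel_fdr(accepted: list[PsmRecord]) -> dict[str, float]:
    """Novel-class FDR from target/decoy counts, as percentages.

    psm_fdr = 100 * (#decoy-novel PSMs) / (#target-novel PSMs); the peptide
    level is the same ratio over distinct peptide strings.
    """
    tgt = [p for p in accepted if p.is_novel and not p.is_decoy]
    dec = [p for p in accepted if p.is_novel and p.is_decoy]
    if not tgt:
        raise ValueError("no target novel PSMs in the accepted set")
    if not dec:
        log.warning("no decoy novel PSMs: FDR reported as 0")
    psm_fdr = 100.0 * len(dec) / len(tgt)
    tgt_peps = {p.peptide for p in tgt}
    dec_peps = {p.peptide for p in dec}
    peptide_fdr = 100.0 * len(dec_peps) / len(tgt_peps)
    return {"psm_fdr": psm_fdr, "peptide_fdr": peptide_fdr}


def stop_adjacent_flag(peptide_nt_start: int, transcript_seq: str) -> bool:
    """Is the in-frame codon immediately 5' of the peptide's first codon a
    stop?  A peptide at the transcript 5' edge has no upstream codon and is
    not flagged."""
    if peptide_nt_start < 3:
        return False
    return transcript_seq[peptide_nt_start - 3 : peptide_nt_start] in STOP_CODONS
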