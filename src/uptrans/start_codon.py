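"""Translation-initiation-site inference for upstream regions.

Candidate starts are ATG or one of the nine near-cognate codons (one base
away from ATG), in frame, within the annotated 5'UTR, upstream of all the
peptide evidence and with no intervening in-frame stop.  An ATG always wins
(the one nearest the peptides); near-cognates are ranked by cross-species
conservation, then Kozak strength, then distance to the peptide evidence.

Kozak context strength uses only positions -3 (A/G favourable) and +4 (G
favourable): strong = both, moderate = exactly one, weak = neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

NEAR_COGNATES = ("CTG", "GTG", "TTG", "AAG", "ACG", "AGG", "ATA", "ATC", "ATT")
START_SET = {"ATG", *NEAR_COGNATES}

STRONG, MODERATE, WEAK = "STRONG", "MODERATE", "WEAK"
_KOZAK_RANK = {STRONG: 2, MODERATE: 1, WEAK: 0}

FOUND, NOT_FOUND = "FOUND", "NOT_FOUND"

# which codon position differs from ATG
POSITION_OF_DIFFERENCE = {
    "CTG": 1, "GTG": 1, "TTG": 1,
    "AAG": 2, "ACG": 2, "AGG": 2,
    "ATA": 3, "ATC": 3, "ATT": 3,
}


@dataclass
class StartCandidate:
    codon: str
    offset: int                  # transcript nt position of the codon's first base
    is_atg: bool
    is_near_cognate: bool
    kozak: str
    conserved_depth: int         # clade index; 0 = human only / unknown
    dist_to_first_peptide: int
    in_annotated_exon: bool = True


@dataclass
class StartCall:
    region_id: str
    codon: str | None
    offset: int | None
    kozak: str | None
    status: str


def kozak_strength(minus3: str | None, plus4: str | None) -> str:
    """Strength from the -3 and +4 context bases; missing bases never match."""
    m3 = minus3 in ("A", "G")
    p4 = plus4 == "G"
    if m3 and p4:
        return STRONG
    if m3 or p4:
        return MODERATE
    return WEAK


def kozak_at(seq: str, offset: int) -> str:
    """Kozak strength of the codon starting at ``offset`` of ``seq``."""
    minus3 = seq[offset - 3] if offset >= 3 else None
    plus4 = seq[offset + 3] if offset + 3 < len(seq) else None
    return kozak_strength(minus3, plus4)


def enumerate_candidates(
    transcript_seq: str,
    orf_start: int,
    first_peptide_start: int,
    utr_len: int,
    conserved_depth_fn=None,
) -> list[StartCandidate]:
    """All in-frame start candidates between the ORF 5' end and the peptide
    evidence.

    The scan runs over codon positions orf_start .. first_peptide_start
    (inclusive: a peptide may retain its initiator residue), restricted to
    codons fully within the annotated 5'UTR.  ``conserved_depth_fn`` maps a
    transcript offset to a clade depth when alignments are available.
    """
    candidates: list[StartCandidate] = []
    for pos in range(orf_start, first_peptide_start + 1, 3):
        if pos + 3 > utr_len:
            break
        codon = transcript_seq[pos : pos + 3]
        if codon not in START_SET:
            continue
        depth = conserved_depth_fn(pos) if conserved_depth_fn is not None else 0
        candidates.append(
            StartCandidate(
                codon=codon,
                offset=pos,
                is_atg=codon == "ATG",
                is_near_cognate=codon != "ATG",
                kozak=kozak_at(transcript_seq, pos),
                conserved_depth=depth,
                dist_to_first_peptide=first_peptide_start - pos,
            )
        )
    return candidates


def select_start(candidates: list[StartCandidate], region_id: str = "") -> StartCall:
    """Pick the start codon.

    Any ATG wins irrespective of conservation and Kozak strength; among
    several ATGs the one nearest the peptides (most 3') is chosen, since a
    further-upstream ATG would imply an unobserved longer product.  Among
    near-cognates the ranking is conservation depth, then Kozak strength,
    then proximity to the peptides; offsets are unique so there are no ties
    and the choice is independent of input order.
    """
    if not candidates:
        return StartCall(region_id, None, None, None, NOT_FOUND)
    atgs = [c for c in candidates if c.is_atg]
    if atgs:
        chosen = max(atgs, key=lambda c: c.offset)
    else:
        chosen = max(
            candidates,
            key=lambda c: (c.conserved_depth, _KOZAK_RANK[c.kozak], -c.dist_to_first_peptide, c.offset),
        )
    return StartCall(region_id, chosen.codon, chosen.offset, chosen.kozak, FOUND)


def start_codon_census(calls: list[StartCall]) -> pd.DataFrame:
    """Counts per start codon with position-of-difference percentages.

    Percentages are over FOUND near-cognate calls; an all-ATG input yields a
    zero near-cognate denominator and zero percentages.
    """
    found = [c for c in calls if c.status == FOUND]
    counts: dict[str, int] = {}
    for call in found:
        counts[call.codon] = counts.get(call.codon, 0) + 1
    near = sum(n for codon, n in counts.items() if codon != "ATG")
    rows = []
    for codon in ("ATG", *NEAR_COGNATES):
        n = counts.get(codon, 0)
        pos = POSITION_OF_DIFFERENCE.get(codon)
        pct = 100.0 * n / near if (near and codon != "ATG") else 0.0
        rows.append({"codon": codon, "count": n, "diff_position": pos, "pct_of_near_cognate": pct})
    df = pd.DataFrame(rows).set_index("codon")
    return df


def position_shares(census: pd.DataFrame) -> dict[int, float]:
    """Share of near-cognate starts differing from ATG at each codon position."""
    near = census.drop(index="ATG")
    total = near["count"].sum()
    out = {}
    for pos in (1, 2, 3):
        n = near.loc[near["diff_position"] == pos, "count"].sum()
        out[pos] = 100.0 * n / total if total else 0.0
    return out
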