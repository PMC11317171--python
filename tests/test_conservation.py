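"""Clade-binned reading-frame conservation from orthologous alignments."""

import itertools

import numpy as np
import pytest

from uptrans.conservation import (
    CLADES,
    CLADE_DEPTH,
    AlignmentBlock,
    assign_bin,
    codon_depth,
    conservation_summary,
    load_alignment,
    load_clades,
    species_verdict,
)
from uptrans.synthetic_data import species_table
from uptrans.upstream_db import STOP_CODONS, translate_nt

HUMAN = "ATGGCAGAAGCATTCGCA"  # 6 codons, stop-free


def _block(rows: dict[str, str], clades=None) -> AlignmentBlock:
    clades = clades or {sp: "CHIMP" for sp in rows if sp != "human"}
    return AlignmentBlock("r", {"human": HUMAN, **rows}, "human", clades)


class TestSpeciesVerdict:
    def test_identical_row_is_conserved(self):
        v = species_verdict(_block({"chimp_1": HUMAN}), "chimp_1")
        assert v.frame_conserved and v.stop_count == 0 and v.frameshift_count == 0
        assert v.start_conserved and v.syn_count == 0 and v.nonsyn_count == 0

    def test_two_nt_deletion_is_frameshift(self):
        row = HUMAN[:6] + "--" + HUMAN[8:]
        v = species_verdict(_block({"sp": row}), "sp")
        assert v.frameshift_count == 1 and not v.frame_conserved

    def test_three_nt_deletion_keeps_frame(self):
        row = HUMAN[:6] + "---" + HUMAN[9:]
        v = species_verdict(_block({"sp": row}), "sp")
        assert v.frameshift_count == 0 and v.frame_conserved

    def test_inframe_stop_breaks_frame(self):
        row = HUMAN[:6] + "TGA" + HUMAN[9:]
        v = species_verdict(_block({"sp": row}), "sp")
        assert v.stop_count == 1 and not v.frame_conserved

    def test_synonymous_and_nonsynonymous_counts(self):
        # GCA->GCC (syn, codon 2); GAA->CAA (nonsyn, codon 3)
        row = HUMAN[:5] + "C" + "C" + HUMAN[7:]
        v = species_verdict(_block({"sp": row}), "sp")
        assert v.syn_count == 1 and v.nonsyn_count == 1

    def test_start_codon_must_match_exactly(self):
        row = "GTG" + HUMAN[3:]
        v = species_verdict(_block({"sp": row}), "sp", start_offset=0)
        assert not v.start_conserved and v.frame_conserved

    def test_all_gap_row_unalignable(self):
        v = species_verdict(_block({"sp": "-" * len(HUMAN)}), "sp")
        assert not v.alignable and not v.frame_conserved

    def test_uorf_stop_codon_conservation(self):
        human = HUMAN[:-3] + "TGA"
        sp_ok = human[:-3] + "TAA"       # still a stop
        sp_bad = human[:-3] + "GGA"      # stop lost
        block = AlignmentBlock("r", {"human": human, "a": sp_ok, "b": sp_bad},
                               "human", {"a": "CHIMP", "b": "CHIMP"})
        assert species_verdict(block, "a", "UORF").stop_codon_conserved
        assert not species_verdict(block, "b", "UORF").stop_codon_conserved

    def test_matches_exhaustive_small_alignment_oracle(self):
        """Single-substitution and single-gap species rows vs a naive oracle."""

        def oracle(h_row, s_row):
            def gap_runs(row):
                runs, run = [], 0
                for ch in row:
                    run = run + 1 if ch == "-" else (runs.append(run) if run else None) or 0
                if run:
                    runs.append(run)
                return runs

            fs = sum(1 for r in gap_runs(h_row) + gap_runs(s_row) if r % 3)
            cols = [i for i, ch in enumerate(h_row) if ch != "-"]
            stops = syn = nonsyn = 0
            for k in range(0, len(cols) - 2, 3):
                c3 = cols[k : k + 3]
                h = "".join(h_row[i] for i in c3)
                s = "".join(s_row[i] for i in c3)
                if "-" in s:
                    continue
                if s in STOP_CODONS and h not in STOP_CODONS:
                    stops += 1
                if sum(a != b for a, b in zip(h, s)) == 1:
                    if translate_nt(h) == translate_nt(s):
                        syn += 1
                    else:
                        nonsyn += 1
            return fs, stops, syn, nonsyn

        cases = []
        for pos, alt in itertools.product(range(len(HUMAN)), "ACGT-"):
            row = HUMAN[:pos] + alt + HUMAN[pos + 1 :]
            cases.append((HUMAN, row))
        for h_gap in range(len(HUMAN)):  # insertion in the species = gap in human
            h_row = HUMAN[:h_gap] + "-" + HUMAN[h_gap:]
            s_row = HUMAN[:h_gap] + "A" + HUMAN[h_gap:]
            cases.append((h_row, s_row))
        for h_row, s_row in cases:
            block = AlignmentBlock("r", {"human": h_row, "sp": s_row}, "human", {"sp": "CHIMP"})
            v = species_verdict(block, "sp")
            assert (v.frameshift_count, v.stop_count, v.syn_count, v.nonsyn_count) == oracle(
                h_row, s_row
            )


def _planted_block(depth: str, n_per_clade: int = 2, break_with: str = "stop") -> AlignmentBlock:
    clades = species_table(n_per_clade)
    rows = {"human": HUMAN}
    for sp, clade in sorted(clades.items()):
        if CLADE_DEPTH[clade] <= CLADE_DEPTH[depth]:
            rows[sp] = HUMAN
        elif break_with == "stop":
            rows[sp] = "GTG" + HUMAN[3:6] + "TGA" + HUMAN[9:]  # start lost + stop
        else:
            rows[sp] = "GTG" + HUMAN[3:6] + "-" + HUMAN[7:]
    return AlignmentBlock("r", rows, "human", clades)


class TestAssignBin:
    @pytest.mark.parametrize("depth", list(CLADES))
    @pytest.mark.parametrize("break_with", ["stop", "gap"])
    def test_planted_depth_recovered(self, depth, break_with):
        block = _planted_block(depth, break_with=break_with)
        verdicts = [
            species_verdict(block, sp) for sp in block.rows if sp != "human"
        ]
        assert assign_bin(verdicts, block.species_clade) == depth

    def test_nestedness_with_full_fraction(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            depth = CLADES[int(rng.integers(len(CLADES)))]
            block = _planted_block(depth)
            verdicts = [species_verdict(block, sp) for sp in block.rows if sp != "human"]
            got = assign_bin(verdicts, block.species_clade, min_fraction=1.0)
            # conservation at the assigned bin implies every shallower clade qualifies
            assert CLADE_DEPTH[got] <= CLADE_DEPTH[depth]
            if CLADE_DEPTH[got] >= 1:
                sub = [v for v in verdicts if block.species_clade[v.species] == "CHIMP"]
                assert all(v.frame_conserved for v in sub)

    def test_unknown_species_errors(self):
        block = _planted_block("CHIMP")
        verdicts = [species_verdict(block, "chimp_1")]
        with pytest.raises(KeyError):
            assign_bin(verdicts, {})


def test_codon_depth_of_start_codon():
    block = _planted_block("MAMMALS")
    assert codon_depth(block, 0) == CLADE_DEPTH["MAMMALS"]
    # broken species mutate codon 2 (TGA): its depth is capped at the planted clade
    assert codon_depth(block, 6) == CLADE_DEPTH["MAMMALS"]


def test_conservation_summary_shares():
    bins = ["MAMMALS"] * 42 + ["PRIMATES"] * 27 + ["HUMAN"] * 23 + ["CHIMP"] * 14 + \
        ["CHIMP_GORILLA"] * 19 + ["APES"] * 22 + ["MONKEYS"] * 45
    s = conservation_summary(bins)
    assert s["not_all_primates"] == pytest.approx(100 * 123 / 192, abs=0.01)
    assert s["not_beyond_gorilla"] == pytest.approx(29.2, abs=0.05)
    assert conservation_summary(["HUMAN"])["human_only"] == 100.0


def test_alignment_io_roundtrip(tmp_path):
    fa = tmp_path / "r1.fa"
    fa.write_text(">human\nATGGCA\n>chimp_1\nATGGCC\n")
    clades_path = tmp_path / "clades.tsv"
    clades_path.write_text("chimp_1\tCHIMP\n")
    block = load_alignment(fa, load_clades(clades_path))
    assert block.human == "human" and block.region_id == "r1"
    assert block.rows["chimp_1"] == "ATGGCC"


def test_ragged_alignment_rejected():
    with pytest.raises(ValueError):
        AlignmentBlock("r", {"human": "ATGGCA", "sp": "ATG"}, "human", {"sp": "CHIMP"})
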