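"""GC-content, variant effects, NS/Syn tables and the Fisher exact test."""

import itertools
import math
import random
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from uptrans.annotation_io import GenomeSequence, TranscriptModel, revcomp
from uptrans.selection_stats import (
    expression_summary,
    fisher_2x2,
    gc_content,
    ns_syn_table,
    select_reference_utr,
    variant_effect_in_frame,
)
from uptrans.upstream_db import translate_nt


class TestGcContent:
    def test_extremes(self):
        assert gc_content("GC" * 10) == 100.0
        assert gc_content("AT" * 10) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_character_tally(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGTN") for _ in range(100))
        expected = 100 * (seq.count("G") + seq.count("C")) / sum(seq.count(b) for b in "ACGT")
        assert gc_content(seq) == pytest.approx(expected)

    def test_reverse_complement_invariance(self):
        rng = random.Random(1)
        seq = "".join(rng.choice("ACGT") for _ in range(60))
        assert gc_content(seq) == pytest.approx(gc_content(revcomp(seq)))

    def test_below_minimum_skipped(self):
        assert gc_content("GCGC") is None


def _model(tid, utr_len, tags, contig="c"):
    total = utr_len + 30
    return TranscriptModel(tid, "G", contig, "+", [(0, total)], [(utr_len, total)], tags=set(tags))


class TestSelectReferenceUtr:
    def _genome(self, n=200):
        return GenomeSequence({"c": "ACGT" * n})

    def test_unique_principal_wins(self):
        models = [_model("T1", 50, {"APPRIS_PRINCIPAL"}), _model("T2", 80, {"APPRIS_MINOR"})]
        chosen = select_reference_utr({"G": models}, self._genome())
        assert chosen["G"].transcript_id == "T1"

    def test_mane_breaks_principal_tie(self):
        models = [
            _model("T1", 50, {"APPRIS_PRINCIPAL"}),
            _model("T2", 40, {"APPRIS_PRINCIPAL", "MANE_SELECT"}),
        ]
        chosen = select_reference_utr({"G": models}, self._genome())
        assert chosen["G"].transcript_id == "T2"

    def test_longest_utr_without_mane(self):
        models = [_model("T1", 50, {"APPRIS_PRINCIPAL"}), _model("T2", 80, {"APPRIS_PRINCIPAL"})]
        chosen = select_reference_utr({"G": models}, self._genome())
        assert chosen["G"].transcript_id == "T2"

    def test_no_principal_falls_back_to_longest(self):
        models = [_model("T1", 50, {"APPRIS_MINOR"}), _model("T2", 80, {"APPRIS_MINOR"})]
        chosen = select_reference_utr({"G": models}, self._genome())
        assert chosen["G"].transcript_id == "T2"

    def test_short_utr_disqualifies_gene(self):
        models = [_model("T1", 10, {"APPRIS_PRINCIPAL"})]
        assert select_reference_utr({"G": models}, self._genome()) == {}


REGION = "ATGGCGTGGTAGAAA"  # 5 codons: M A W * K


class TestVariantEffect:
    def test_spec_examples(self):
        assert variant_effect_in_frame(REGION, 5, "G", "A") == "SYN"          # GCG->GCA
        assert variant_effect_in_frame(REGION, 7, "G", "A") == "STOP_GAINED"  # TGG->TAG
        assert variant_effect_in_frame(REGION, 2, "GGC", "G") == "FRAMESHIFT"

    def test_stop_lost(self):
        assert variant_effect_in_frame(REGION, 10, "A", "C") == "STOP_LOST"

    def test_outside_region_or_mismatch_errors(self):
        with pytest.raises(ValueError):
            variant_effect_in_frame(REGION, 99, "A", "C")
        with pytest.raises(ValueError):
            variant_effect_in_frame(REGION, 0, "C", "G")

    def test_all_snvs_match_translate_and_compare_oracle(self):
        for pos, alt in itertools.product(range(len(REGION)), "ACGT"):
            ref = REGION[pos]
            if alt == ref:
                continue
            got = variant_effect_in_frame(REGION, pos, ref, alt)
            mutated = REGION[:pos] + alt + REGION[pos + 1 :]
            old_aa, new_aa = translate_nt(REGION), translate_nt(mutated)
            if new_aa == old_aa:
                expected = "SYN"
            elif new_aa.count("*") > old_aa.count("*"):
                expected = "STOP_GAINED"
            elif new_aa.count("*") < old_aa.count("*"):
                expected = "STOP_LOST"
            else:
                expected = "NONSYN"
            assert got == expected, (pos, ref, alt)


class TestNsSynTable:
    def test_ratio_arithmetic(self):
        # 18 NS + 10 Syn rare, 9 NS + 5 Syn common -> both ratios 1.8
        seq = "GCTGCA" * 30
        rows = []
        for i in range(18):
            rows.append({"region_id": "r", "pos": 3 * i, "ref": "G", "alt": "T", "af": 1e-4})
        for i in range(10):
            rows.append({"region_id": "r", "pos": 3 * i + 2, "ref": seq[3 * i + 2], "alt": "G" if seq[3*i+2] != "G" else "C", "af": 1e-4})
        for i in range(9):
            rows.append({"region_id": "r", "pos": 3 * i, "ref": "G", "alt": "T", "af": 0.1})
        for i in range(5):
            rows.append({"region_id": "r", "pos": 3 * i + 2, "ref": seq[3 * i + 2], "alt": "G" if seq[3*i+2] != "G" else "C", "af": 0.1})
        table = ns_syn_table(pd.DataFrame(rows), {"r": seq}, {"r": "MAMMALS"})
        all_rows = table[table["stratum"] == "ALL"].set_index("af_class")
        assert all_rows.loc["RARE", "ratio"] == pytest.approx(1.8)
        assert all_rows.loc["COMMON", "ratio"] == pytest.approx(1.8)
        cons = table[table["stratum"] == "CONSERVED_GE_PRIMATES"]
        assert cons["nonsyn"].sum() == 27  # the region is mammal-conserved

    def test_zero_synonymous_gives_nan_ratio(self):
        seq = "GCTGCA" * 10
        rows = [{"region_id": "r", "pos": 0, "ref": "G", "alt": "T", "af": 1e-4}]
        table = ns_syn_table(pd.DataFrame(rows), {"r": seq}, {})
        rare_all = table[(table["stratum"] == "ALL") & (table["af_class"] == "RARE")]
        assert math.isnan(float(rare_all["ratio"].iloc[0]))
        # and a purely synonymous class gives ratio 0, not NaN
        syn_rows = [{"region_id": "r", "pos": 2, "ref": "T", "alt": "C", "af": 1e-4}]
        t2 = ns_syn_table(pd.DataFrame(syn_rows), {"r": seq}, {})
        assert float(t2[(t2["stratum"] == "ALL") & (t2["af_class"] == "RARE")]["ratio"].iloc[0]) == 0.0


def _fisher_oracle(a, b, c, d) -> float:
    """Exact enumeration over tables with fixed margins (rational arithmetic)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs))


class TestFisher:
    def test_no_association(self):
        assert fisher_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_all_zero_warns_one(self):
        with pytest.warns(UserWarning):
            assert fisher_2x2(0, 0, 0, 0) == 1.0

    def test_strong_association_matches_enumeration(self):
        assert fisher_2x2(10, 1, 1, 10) == pytest.approx(_fisher_oracle(10, 1, 1, 10), abs=1e-9)

    def test_exhaustive_small_tables_vs_oracle(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                            continue
                        assert fisher_2x2(a, b, c, d) == pytest.approx(
                            _fisher_oracle(a, b, c, d), abs=1e-8
                        ), (a, b, c, d)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 10, size=4))
            assert fisher_2x2(a, b, c, d) == pytest.approx(fisher_2x2(a, c, b, d), abs=1e-12)


class TestExpressionSummary:
    def _frames(self, tur_psms=10, canon_psms=90):
        psm = pd.DataFrame(
            [{"gene_id": "G1", "is_tur": True, "sample_class": "cell_line"}] * tur_psms
            + [{"gene_id": "G1", "is_tur": False, "sample_class": "tissue"}] * canon_psms
        )
        calls = pd.DataFrame(
            [{"gene_id": "G1", "region_type": "EXTENSION", "kozak": "STRONG",
              "conservation_bin": "MAMMALS"}]
        )
        return psm, calls

    def test_tur_share_of_gene_psms(self):
        psm, calls = self._frames()
        out = expression_summary(psm, calls)
        strata = out["kozak_strata"].set_index("kozak")
        assert strata.loc["STRONG", "pct_of_gene_psms"] == pytest.approx(10.0)
        assert out["mean_psm_tur_genes"] == 100

    def test_kozak_strata_monotone_on_planted_rates(self):
        # planted per-gene upstream shares ~0.78 / 1.16 / 2.09 percent
        rows, call_rows = [], []
        for kozak, rate in (("WEAK", 0.0078), ("MODERATE", 0.0116), ("STRONG", 0.0209)):
            gene = f"G_{kozak}"
            n_tur = round(10000 * rate)
            rows += [{"gene_id": gene, "is_tur": True, "sample_class": "cell_line"}] * n_tur
            rows += [{"gene_id": gene, "is_tur": False, "sample_class": "tissue"}] * (10000 - n_tur)
            call_rows.append({"gene_id": gene, "region_type": "EXTENSION", "kozak": kozak,
                              "conservation_bin": "HUMAN"})
        out = expression_summary(pd.DataFrame(rows), pd.DataFrame(call_rows))
        strata = out["kozak_strata"].set_index("kozak")["pct_of_gene_psms"]
        assert strata["WEAK"] < strata["MODERATE"] < strata["STRONG"]
        assert strata["STRONG"] == pytest.approx(2.09, abs=0.01)
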