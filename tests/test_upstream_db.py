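"""Search-database construction: 3-frame translation, extensions, decoys."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from uptrans.annotation_io import GenomeSequence, TranscriptModel
from uptrans.upstream_db import (
    STOP_CODONS,
    build_database,
    deduplicate,
    extend_cds_upstream,
    make_decoy,
    translate_nt,
    translate_three_frames,
    write_fasta,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _oracle_fragments(seq: str, frame: int, min_aa: int) -> list[str]:
    """Brute-force codon walk: translate, split at stops, filter by length."""
    aas = []
    i = frame
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        aas.append("*" if codon in STOP_CODONS else translate_nt(codon))
        i += 3
    return [f for f in "".join(aas).split("*") if len(f) >= min_aa]


def test_three_frame_translation_splits_at_stops():
    orfs = translate_three_frames("ATGAAATAGGGG", "T", "G", min_orf_aa=2)
    frame0 = [o.protein for o in orfs if o.frame == 0]
    assert frame0 == ["MK"]  # the post-stop "G" fragment is below min length
    assert all("*" not in o.protein for o in orfs)


def test_all_stop_frame_yields_no_fragments():
    orfs = translate_three_frames("TAATAGTGA", "T", "G", min_orf_aa=1)
    assert [o for o in orfs if o.frame == 0] == []


@pytest.mark.parametrize("seed", range(5))
def test_three_frame_matches_bruteforce_oracle(seed):
    rng = random.Random(seed)
    seq = "".join(rng.choice("ACGT") for _ in range(200))
    orfs = translate_three_frames(seq, "T", "G", min_orf_aa=3)
    for frame in range(3):
        got = [o.protein for o in orfs if o.frame == frame]
        assert got == _oracle_fragments(seq, frame, 3)
    # codon-count arithmetic across the three frames
    n_codons = sum(len(seq[f:]) // 3 for f in range(3))
    assert n_codons == len(seq) // 3 + (len(seq) - 1) // 3 + (len(seq) - 2) // 3


def test_fragment_spans_are_consistent():
    seq = "ATGAAATAGGGGCCCAAATTTGGG"
    for orf in translate_three_frames(seq, "T", "G", min_orf_aa=2):
        s, e = orf.nt_span
        assert translate_nt(seq[s:e]) == orf.protein


def _single_exon_model(t_seq: str, utr_len: int) -> tuple[TranscriptModel, GenomeSequence]:
    genome = GenomeSequence({"c": t_seq})
    model = TranscriptModel(
        "T1", "G1", "c", "+", exons=[(0, len(t_seq))], cds=[(utr_len, len(t_seq))]
    )
    return model, genome


class TestExtendCdsUpstream:
    def test_extension_stops_at_inframe_stop(self):
        # UTR ...TAG GCG GCG | CDS ATG...: extension is "AA" fused to the CDS prefix
        utr = "CCCCCC" + "TAG" + "GCG" + "GCG"
        cds = "ATGAAAGGGTAA"
        model, genome = _single_exon_model(utr + cds, len(utr))
        orf = extend_cds_upstream(model, genome, cds_prefix_aa=60)
        assert orf is not None
        assert orf.protein == "AA" + "MKG"
        assert orf.boundary_flag
        assert orf.nt_span == (len(utr) - 6, len(utr) + 9)

    def test_stop_directly_upstream_yields_none(self):
        utr = "CCCCCCCCC" + "TGA"
        model, genome = _single_exon_model(utr + "ATGAAATAA", len(utr))
        assert extend_cds_upstream(model, genome) is None

    def test_no_stop_runs_to_transcript_start_truncating_partial_codon(self):
        utr = "CC" + "GCGGCG"  # 8 nt: two full codons plus a 2-nt remainder
        model, genome = _single_exon_model(utr + "ATGAAATAA", len(utr))
        orf = extend_cds_upstream(model, genome)
        assert orf.protein.startswith("AA")
        assert orf.nt_span[0] == 2


def test_deduplicate_merges_and_is_order_invariant():
    orfs1 = translate_three_frames("ATGAAAGCGGCGTTTCCCGGG", "T1", "G1", 3)
    orfs2 = translate_three_frames("ATGAAAGCGGCGTTTCCCGGG", "T2", "G1", 3)
    merged = deduplicate(orfs1 + orfs2)
    for orf in merged:
        assert {p.transcript_id for p in orf.provenance} == {"T1", "T2"}
        assert orf.orf_id.startswith("T1:")  # lexicographically smallest survivor
    shuffled = deduplicate(list(reversed(orfs2 + orfs1)))
    assert [(o.orf_id, o.protein) for o in shuffled] == [
        (o.orf_id, o.protein) for o in merged
    ]


@pytest.mark.parametrize(
    "protein,expected",
    [("ABCK", "CBAK"), ("K", "K"), ("ABCKDEFR", "CBAKFEDR"), ("ABC", "CBA")],
)
def test_make_decoy_examples(protein, expected):
    assert make_decoy(protein) == expected


@settings(max_examples=200, deadline=None)
@given(st.text(alphabet=AA20, min_size=1, max_size=60))
def test_make_decoy_preserves_multiset_and_tryptic_residues(protein):
    decoy = make_decoy(protein)
    assert len(decoy) == len(protein)
    assert sorted(decoy) == sorted(protein)
    for i, aa in enumerate(protein):
        if aa in "KR":
            assert decoy[i] == aa
    # involution on single-segment inputs
    if not any(aa in "KR" for aa in protein[:-1]):
        assert make_decoy(decoy) == protein


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet=AA20, min_size=1, max_size=60))
def test_whole_protein_decoy_mode(protein):
    decoy = make_decoy(protein, mode="whole")
    assert sorted(decoy) == sorted(protein)
    for i, aa in enumerate(protein):
        if aa in "KR":
            assert decoy[i] == aa


def test_build_database_invariants_and_determinism(tmp_path):
    utr = "GGG" + "TAG" + "GCGGCGGCGGCGGCGGCGGCGGCG"  # 30 nt
    cds = "ATG" + "AAA" * 20 + "TAA"
    seq = utr + cds
    genome = GenomeSequence({"c1": seq, "c2": seq})
    models = [
        TranscriptModel("Ta", "Ga", "c1", "+", [(0, len(seq))], [(len(utr), len(seq))]),
        TranscriptModel("Tb", "Gb", "c2", "+", [(0, len(seq))], [(len(utr), len(seq))]),
    ]
    db = build_database(models, genome)
    db.check_invariants()
    classes = {}
    for acc, prot, cls in db.entries:
        classes[cls] = classes.get(cls, 0) + 1
        if cls == "target_novel":
            assert "*" not in prot
            assert acc.startswith("novel|")
    assert classes["target_novel"] == classes["decoy_novel"]
    assert classes["target_known"] == classes["decoy_known"] == 2

    f1, f2 = tmp_path / "a.fa", tmp_path / "b.fa"
    write_fasta(db, f1)
    write_fasta(build_database(models, genome), f2)
    assert f1.read_bytes() == f2.read_bytes()


def test_build_database_skips_short_utrs():
    utr = "GCGGCGGCG"  # 9 nt < 20
    cds = "ATG" + "AAA" * 20 + "TAA"
    seq = utr + cds
    genome = GenomeSequence({"c": seq})
    models = [TranscriptModel("T", "G", "c", "+", [(0, len(seq))], [(len(utr), len(seq))])]
    db = build_database(models, genome)
    assert all(cls != "target_novel" for _, _, cls in db.entries)
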