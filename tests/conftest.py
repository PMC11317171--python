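"""Shared fixtures: hand-traced toy transcripts and one simulated dataset."""

from __future__ import annotations

import pytest

from uptrans.annotation_io import GenomeSequence, TranscriptModel, revcomp
from uptrans.pipeline import run_pipeline
from uptrans.synthetic_data import PlantSpec, generate

# deterministic 200-nt toy contig (no special structure needed; coordinates
# below were traced by hand against this string)
TOY_SEQ = ("ACGT" * 50)
TOY_LEN = len(TOY_SEQ)


@pytest.fixture
def toy_genome() -> GenomeSequence:
    return GenomeSequence({"toy": TOY_SEQ, "toy_rc": revcomp(TOY_SEQ)})


@pytest.fixture
def toy_plus(toy_genome) -> TranscriptModel:
    """Two-exon '+' transcript: exon1 [10,40), exon2 [60,160); CDS [90,150).

    5'UTR = exon1 (30 nt) + exon2[:30] (30 nt) = 60 nt."""
    return TranscriptModel(
        transcript_id="TP", gene_id="GP", contig="toy", strand="+",
        exons=[(10, 40), (60, 160)], cds=[(90, 150)],
    )


@pytest.fixture
def toy_minus(toy_genome) -> TranscriptModel:
    """Mirror of toy_plus on the reverse-complemented contig."""
    flip = lambda iv: (TOY_LEN - iv[1], TOY_LEN - iv[0])
    return TranscriptModel(
        transcript_id="TM", gene_id="GM", contig="toy_rc", strand="-",
        exons=sorted([flip((10, 40)), flip((60, 160))]), cds=[flip((90, 150))],
    )


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """A small mixed simulated dataset shared across tests."""
    out = tmp_path_factory.mktemp("sim")
    spec = PlantSpec.default(n_extension=3, n_uorf=2, n_uoorf=2, n_none=3, n_traps=1, seed=17)
    truth = generate(spec, out)
    return out, truth


@pytest.fixture(scope="session")
def sim_result(sim_dir):
    out, truth = sim_dir
    return run_pipeline(out), truth
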