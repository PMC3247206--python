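import pytest

from coraltrx import simulate


@pytest.fixture(scope="session")
def small_truth():
    """A small synthetic transcriptome shared across read-only tests."""
    cfg = simulate.SimConfig(n_transcripts=60, seed=7)
    return simulate.generate_transcriptome(cfg)


@pytest.fixture(scope="session")
def fragmented(small_truth):
    contigs, provenance = simulate.fragment_contigs(small_truth, 2.2, seed=11)
    return contigs, provenance


@pytest.fixture(scope="session")
def planted_alignments(fragmented):
    contigs, _ = fragmented
    alignments, planted = simulate.plant_snps(
        contigs, density=1.0 / 272.0, tstv_odds=2.4, seed=13
    )
    return alignments, planted
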