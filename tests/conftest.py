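import numpy as np
import pytest

from minorintron import classify, genome, synthetic


def _sample_set(spec: synthetic.MotifSpec, n: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    return [spec.sample(int(rng.integers(60, 120)), rng) for _ in range(n)]


@pytest.fixture(scope="session")
def default_model():
    """Scorer trained on the packaged synthetic reference sets."""
    return classify.load_default_model()


@pytest.fixture(scope="session")
def consensus_model():
    """Scorer trained on consensus-exact minor/major draws (complete separation)."""
    minor = _sample_set(synthetic.consensus_minor_motifs(), 50, 11)
    major = _sample_set(synthetic.consensus_major_motifs(), 50, 12)
    return classify.train_scorer(minor, major)


@pytest.fixture(scope="session")
def toy_extraction(tmp_path_factory):
    """Default-motif toy genome written to disk, parsed back and extracted."""
    toy = synthetic.generate_toy_genome(20, 3, 0.3, seed=7)
    paths = toy.write(tmp_path_factory.mktemp("toy"))
    seqs = genome.read_genome(paths["genome"])
    tx = genome.build_transcriptome(paths["annotation"], seqs)
    introns = genome.extract_introns(tx, seqs)
    return {"toy": toy, "paths": paths, "genome": seqs, "transcripts": tx,
            "introns": introns}


@pytest.fixture(scope="session")
def consensus_toy(tmp_path_factory):
    """Consensus-exact toy genome (for planted-truth classifier recovery)."""
    spec = (synthetic.consensus_minor_motifs(), synthetic.consensus_major_motifs())
    toy = synthetic.generate_toy_genome(60, 3, 0.1, motif_spec=spec, seed=3)
    paths = toy.write(tmp_path_factory.mktemp("ctoy"))
    seqs = genome.read_genome(paths["genome"])
    tx = genome.build_transcriptome(paths["annotation"], seqs)
    introns = genome.extract_introns(tx, seqs)
    return {"toy": toy, "paths": paths, "genome": seqs, "transcripts": tx,
            "introns": introns}
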