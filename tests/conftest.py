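import matplotlib

matplotlib.use("Agg")

import pytest

from motiftracks import fixtures


@pytest.fixture(scope="session")
def default_truth():
    """The generator's default conditions: protein, 20 sequences, 10 motifs of widths 4-7."""
    return fixtures.generate(fixtures.SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_truth():
    """A 20-sequence, 2-motif fixture that plants exactly 37 occurrences."""
    truth = fixtures.generate(fixtures.SyntheticSpec(seed=1, n_motifs=2, site_prob=0.9))
    assert len(truth.result.occurrences) == 37
    return truth


@pytest.fixture()
def sim_dir(tmp_path, default_truth):
    """Default-truth fixture files written to disk."""
    fixtures.write_meme_xml(default_truth, tmp_path / "meme.xml")
    fixtures.write_meme_text(default_truth, tmp_path / "meme.txt")
    fixtures.write_newick(default_truth, tmp_path / "tree.nwk", seed=12)
    fixtures.write_annotations(default_truth, tmp_path / "anno.tsv", seed=13)
    return tmp_path
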