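import numpy as np
import pytest
from hypothesis import settings

from sincbird import synth
from sincbird.pipeline import run_experiment, scaled_synthetic_experiment

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A small labeled corpus: 3 species, 6 one-or-two-event files each."""
    out = tmp_path_factory.mktemp("corpus")
    spec = synth.CorpusSpec(
        n_species=3, files_per_class_dist=(6, 6), file_len_range=(0.8, 1.5),
        fs=16000, overlap_prob=0.25, noise_snr_db=15.0, seed=42,
        events_per_file=(1, 2))
    manifest = synth.make_corpus(spec, out)
    return {"dir": out, "spec": spec, "manifest": manifest}


@pytest.fixture(scope="session")
def scaled_experiments(tmp_path_factory):
    """The desk-scale end-to-end study: sinc and standard-conv variants
    trained on one shared 5-species corpus, 3 replicate splits each."""
    root = tmp_path_factory.mktemp("scaled")
    cfg_sinc = scaled_synthetic_experiment(master_seed=11, frontend="sinc")
    spec = synth.CorpusSpec(
        **{k: tuple(v) if isinstance(v, list) else v
           for k, v in cfg_sinc["corpus"].items()})
    corpus_dir = root / "corpus"
    synth.make_corpus(spec, corpus_dir)
    sinc = run_experiment(cfg_sinc, root / "sinc", corpus_dir=corpus_dir)
    cfg_std = scaled_synthetic_experiment(master_seed=11,
                                          frontend="standard_conv")
    std = run_experiment(cfg_std, root / "std", corpus_dir=corpus_dir)
    return {"sinc": sinc, "standard": std}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
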