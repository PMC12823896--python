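import numpy as np
import pytest
from hypothesis import settings

import lingscreen as ls

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus() -> ls.SyntheticCorpus:
    """A compact synthetic corpus shared across tests (80 transcripts)."""
    cfg = ls.SyntheticConfig(n_per_group=40, tokens_per_transcript=200, seed=11)
    return ls.generate_synthetic_corpus(cfg)


@pytest.fixture(scope="session")
def small_pipeline_result(small_corpus) -> ls.PipelineResult:
    """One full pipeline run on the small corpus, reused by read-only tests."""
    cfg = ls.PipelineConfig(seed=11, embedding_dim=64)
    return ls.run_full_pipeline(
        cfg, transcripts=small_corpus.transcripts, parses=small_corpus.parses
    )


@pytest.fixture()
def daic_tsv(tmp_path):
    """A 3-row DAIC-style transcript file (2 participant rows, 1 interviewer)."""
    path = tmp_path / "300_TRANSCRIPT.csv"
    path.write_text(
        "start_time\tstop_time\tspeaker\tvalue\n"
        "0.0\t1.5\tEllie\thow are you doing today\n"
        "2.0\t4.0\tParticipant\tI'm doing OK, I guess.\n"
        "5.0\t9.0\tParticipant\tMostly tired... you know?\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
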