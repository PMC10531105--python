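import pytest

import radresponse as rr


@pytest.fixture(scope="session")
def small_corpus() -> rr.Corpus:
    """Synthetic corpus used across tests (200 patients, fixed seed)."""
    return rr.generate_corpus(rr.GeneratorConfig(n_patients=200, seed=7))


@pytest.fixture(scope="session")
def split_corpus(small_corpus) -> rr.Corpus:
    return rr.split_by_patient(small_corpus, rr.SplitSpec(seed=1))


def make_record(text: str, label=rr.ResponseLabel.SD, rid="R1", pid="P1"):
    return rr.ReportRecord(report_id=rid, patient_id=pid,
                           conclusion_text=text, label=label)
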