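import numpy as np
import pytest

from ecgdx import ClassVocabulary, analyze_record, generate, preset


@pytest.fixture(scope="session")
def vocab():
    return ClassVocabulary.load()


@pytest.fixture(scope="session")
def nsr_record():
    """One clean normal-sinus-rhythm record plus its ground truth."""
    return generate(preset("nsr", seed=7))


@pytest.fixture(scope="session")
def nsr_analysis(nsr_record):
    rec, _truth = nsr_record
    return analyze_record(rec)


@pytest.fixture(scope="session")
def analyzed():
    """Memoised preset -> (record, truth, AnalysisResult) pipeline runner."""
    cache = {}

    def run(name, seed=0, **overrides):
        key = (name, seed, repr(sorted(overrides.items())))
        if key not in cache:
            rec, truth = generate(preset(name, seed=seed, **overrides))
            cache[key] = (rec, truth, analyze_record(rec))
        return cache[key]

    return run


def fired_classes(result, threshold=0.5):
    return {k for k, v in result.scores.scores.items() if v >= threshold}
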