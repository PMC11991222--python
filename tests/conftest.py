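import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from habitmine import default_scenario, generate, label_events
from habitmine.config import PipelineConfig
from habitmine.pipeline import prepare_windows


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario: (records, ground truth)."""
    spec = default_scenario()
    return generate(spec)


@pytest.fixture(scope="session")
def labelled_stream(scenario):
    records, _ = scenario
    return label_events(records)


@pytest.fixture(scope="session")
def prepared(scenario):
    """Windows prepared with the default pipeline config (SEW 25)."""
    records, _ = scenario
    return prepare_windows(records, PipelineConfig())


TINY_LOG = """\
2010-11-04 00:03:50.209589 M003 ON Sleeping begin
2010-11-04 00:03:57.399391 M003 OFF
2010-11-04 00:15:08.984841 T002 21.5
2010-11-04 05:40:51.303739 M004 ON Sleeping end
2010-11-04 05:43:45.119359 M004 OFF
"""


@pytest.fixture
def tiny_log(tmp_path):
    path = tmp_path / "tiny.log"
    path.write_text(TINY_LOG)
    return path
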