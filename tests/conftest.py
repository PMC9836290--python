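import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

GOLDEN_DIR = Path(__file__).parent / "data" / "golden"


@pytest.fixture(scope="session")
def golden_dir() -> Path:
    return GOLDEN_DIR


@pytest.fixture
def golden_inputs(golden_dir):
    """The committed 1-gene, 6-sample fixture as in-memory objects."""
    from tnscreen import read_annotation, read_insertion_table, read_sample_sheet

    return (
        read_insertion_table(golden_dir / "counts.tsv"),
        read_annotation(golden_dir / "genes.tsv"),
        read_sample_sheet(golden_dir / "sheet.tsv"),
    )
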