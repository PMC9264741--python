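import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    """Seeded stdlib RNG for ad-hoc shuffling in tests."""
    return random.Random(20220708)


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA bytes/records to a temp file and return the path."""

    def _write(content, name="input.fasta"):
        from seqinfo.formats import write_fasta

        path = tmp_path / name
        if isinstance(content, bytes):
            path.write_bytes(content)
        elif isinstance(content, str):
            path.write_text(content)
        else:
            path.write_bytes(write_fasta(content))
        return path

    return _write
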