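import pytest

from utrsat import TranscriptModel, eng_like_transcript


@pytest.fixture(scope="session")
def eng():
    """Synthetic ENG-like transcript (303-nt 5'UTR, 1977-nt CDS)."""
    return eng_like_transcript()


@pytest.fixture
def tiny():
    """Minimal hand-written transcript: 6-nt UTR, 9-nt CDS."""
    return TranscriptModel(id="tiny", utr5="CCCCCC", cds="ATGAAATGA")
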