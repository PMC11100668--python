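import pytest

from neoscan import build_locus


@pytest.fixture(scope="session")
def kpn_locus():
    """Designed Kpn-like surrogate: 119-nt template, period 120, one
    stop-free frame (frame 0), planted RBS/start and junction promoter.
    Synthetic stand-in for the published locus (sequence not deposited)."""
    return build_locus(119, designed_frame=0, seed=7, locus_id="kpn_like")


@pytest.fixture(scope="session")
def plain_locus():
    """Undesigned random locus with a 60-nt template (no frame constraints)."""
    return build_locus(60, seed=11, locus_id="plain60")
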