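import logging

import pytest

from bisfoot.bisulfite import ConversionCall, ConversionProfile
from bisfoot.simulate import SimParams, simulate_bisulfite_clones, simulate_reference


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.getLogger("bisfoot").setLevel(logging.ERROR)
    yield


def make_profile(statuses, contexts=None, strand="top", positions=None, clone_id="c"):
    """Build a ConversionProfile from short status codes:
    '1' converted, '0' unconverted, 'E' excluded, 'M' mismatch_other."""
    code = {"1": "converted", "0": "unconverted", "E": "excluded", "M": "mismatch_other"}
    if positions is None:
        positions = list(range(len(statuses)))
    if contexts is None:
        contexts = ["non-CpG"] * len(statuses)
    calls = [
        ConversionCall(pos, ctx, code[s])
        for pos, ctx, s in zip(positions, contexts, statuses)
    ]
    n_other = sum(1 for s in statuses if s == "M")
    return ConversionProfile(clone_id, strand, calls, n_other)


@pytest.fixture
def bottom_footprint_sim():
    """50 bottom-strand clones over a 600 nt locus with one planted
    60 nt bottom-strand footprint [200, 260)."""
    params = SimParams(
        ref_length=600,
        footprints=[("bottom", 200, 260)],
        p_ss=0.9,
        p_bg=0.02,
        n_clones=50,
        strand_mix=1.0,
        seed=42,
    )
    ref, _ = simulate_reference(params)
    clones, truth = simulate_bisulfite_clones(ref, params)
    return params, ref, clones, truth
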