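"""Shared fixtures: scripted co-elution scenarios for the TG resolver.

The overlay scenarios mirror the three canonical patterns of isobaric TG
resolution on a C30 column: (A) two molecular species of one precursor
separated in time but sharing one FA channel; (B) a 2:1 channel-height
ratio revealing a doubled chain; (C) three equal channels for a fully
distinct triplet.
"""

import pytest
from hypothesis import settings

from lipidmrm.panel import build_tg_panel
from lipidmrm.simulate import make_trace

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

TG_WINDOW = (15.0, 25.0)


def traces_for(tg_name: str, species_at: list[tuple[str, float, float]], baseline=0.0):
    """Build XIC traces for one TG precursor.

    ``species_at`` is a list of (composition, rt_min, abundance); each
    species feeds every acyl-loss channel of its FAs with height =
    abundance x multiplicity.
    """
    from lipidmrm.panel import TGComposition

    panel = build_tg_panel([tg_name])
    comps = [(TGComposition.parse(c), rt, ab) for c, rt, ab in species_at]
    traces = []
    for t in panel:
        fa = t.channel.split(":", 1)[1]
        peaks = []
        for comp, rt, ab in comps:
            from lipidmrm.chem import FattyAcyl

            m = comp.multiplicity(FattyAcyl.parse(fa))
            if m:
                peaks.append((rt, ab * m))
        traces.append(make_trace(t, peaks, TG_WINDOW, baseline=baseline))
    return traces


@pytest.fixture
def fig_a_traces():
    """TG 58:5: 18:2_18:2_22:1 and 18:1_18:3_22:1, 0.6 min apart, sharing
    the 22:1 channel."""
    return traces_for(
        "TG 58:5",
        [("18:2_18:2_22:1", 19.0, 1.0e5), ("18:1_18:3_22:1", 19.6, 8.0e4)],
    )


@pytest.fixture
def fig_b_traces():
    """TG 62:5: single species 18:3_22:1_22:1 — the 22:1 channel runs at
    twice the 18:3 channel."""
    return traces_for("TG 62:5", [("18:3_22:1_22:1", 21.0, 1.0e5)])


@pytest.fixture
def fig_c_traces():
    """TG 64:4: 18:2_22:1_24:1, three near-identical channel heights."""
    return traces_for("TG 64:4", [("18:2_22:1_24:1", 22.0, 1.0e5)])


@pytest.fixture
def triple_18_1_traces():
    """TG 54:3 as trioleoylglycerol: a single 18:1 channel."""
    return traces_for("TG 54:3", [("18:1_18:1_18:1", 18.0, 1.0e5)])
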