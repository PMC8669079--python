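"""Shared fixtures.

Expensive tissue-scale objects (the induced reentrant episode and its
therapy runs) are session-scoped so the induction pipeline runs once for
the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from isthmus import geometry as G
from isthmus import ionic as I
from isthmus import solver as S
from isthmus import synthetic as SY
from isthmus import protocols as P

SEED = 20260929


@pytest.fixture(scope="session")
def default_grid():
    """The study's default synthetic infarct lattice."""
    return SY.default_infarct_grid()


@pytest.fixture()
def small_infarct_grid():
    """Coarser, smaller infarct for cheap geometry-level tests."""
    return G.build_slab_geometry(
        tissue_size=(4.0, 3.2),
        spacing=0.05,
        scar=G.ScarSpec(
            band_thickness=2.0,
            isthmus_width=0.4,
            bz_rim=0.05,
            ci_bz_fraction=0.375,
            islet_width=0.075,
            islet_margin=0.12,
        ),
        bath=(1.2, 1.2),
    )


@pytest.fixture()
def healthy_sheet():
    """Plain 1 x 1 cm healthy sheet without bath."""
    return G.build_slab_geometry(
        tissue_size=(1.0, 1.0), spacing=0.025, scar=None, bath=(0.0, 0.0)
    )


@pytest.fixture()
def reduced_model():
    return I.ReducedModel.from_cell_model(I.healthy_porcine(base="reduced"))


@pytest.fixture(scope="session")
def episode():
    """Induced + stabilised reentrant episode on the default infarct.

    The S2 scan starts at 280 ms (the protocol's decremental search simply
    entered lower) to keep the suite fast; the resulting circuit is the same
    as from a full scan.
    """
    setup = SY.default_infarct_setup()
    raw = P.induce_vt(setup, s2_start=280.0)
    return P.stabilize_vt(raw)


@pytest.fixture(scope="session")
def fast_episode(episode):
    """Fast-class library variant (channel conductivity raised), the
    preparation on which single transmural shocks terminate."""
    eps = P.generate_vt_library(episode, [{"ci_factor": 2.5}])
    assert len(eps) == 2, "fast library variant was not sustained"
    return eps[-1]


@pytest.fixture(scope="session")
def shock_grid():
    """Voltage grid and delivery fraction for the on-tissue strength-search
    check: a coarse 3-point grid bracketing the fast episode's termination
    threshold at its vulnerable phase."""
    return 100.0, 300.0, 0.45


@pytest.fixture(scope="session")
def timing_trend(fast_episode):
    """Mean minimum far-field (bipolar-array) strength at early vs late
    delivery, on a coarse grid; NotFound entries are reported as such."""
    ep_b, array = P.with_electrodes(
        fast_episode, lambda g: G.place_bipolar_array(g)
    )
    out = {}
    for frac in (0.50, 0.88):
        v = P.find_min_strength(
            ep_b, array, step=1000.0, vmax=2000.0, fraction=frac
        )
        out[frac] = float(v) if v is not P.NotFound else "NotFound"
    return out[0.50], out[0.88]
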