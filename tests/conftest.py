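"""Shared fixtures: cached simulation runs reused across the suite.

Full-length runs are expensive, so each genotype is simulated once per seed
at session scope and shared by every test that inspects final patterns.
Unit tests use a reduced domain (1 mm x 0.6 mm, ending at stage PR) that
completes in a couple of seconds.
"""
from __future__ import annotations

import numpy as np
import pytest

import stripesim as ss


def _runs(genotype, seeds, **kw):
    return [ss.run_simulation(genotype, seed=s, **kw) for s in seeds]


@pytest.fixture(scope="session")
def tiny_params():
    """Small, fast domain for engine-level unit tests."""
    return ss.Params(init_length=1.0, init_height=0.6, end_sl=9.8)


@pytest.fixture(scope="session")
def tiny_run(tiny_params):
    return ss.run_simulation("WT", seed=7, params=tiny_params)


@pytest.fixture(scope="session")
def wt_runs():
    return _runs("WT", (101, 102, 103, 104), checkpoint_stages=("SP", "J"))


@pytest.fixture(scope="session")
def wt_aspect_runs(wt_runs):
    """Extra wild-type runs for the straightness-vs-aspect-ratio scatter."""
    return wt_runs + _runs("WT", (105, 106, 107, 108, 109, 110),
                           checkpoint_stages=("J",))


@pytest.fixture(scope="session")
def shd_runs():
    return _runs("shd", (201, 202, 203, 204))


@pytest.fixture(scope="session")
def pfe_runs():
    return _runs("pfe", (301, 302, 303))


@pytest.fixture(scope="session")
def nac_runs():
    return _runs("nac", (401, 402))


@pytest.fixture(scope="session")
def cho_runs():
    return _runs("cho", (501, 502))


@pytest.fixture(scope="session")
def double_mutant_runs():
    # run a little past J+ ("by adulthood the remaining cell type fills
    # the domain")
    return {name: ss.run_simulation(name, seed=601, extra_days=10.0)
            for name in ("shd;pfe", "shd;nac", "nac;pfe")}


@pytest.fixture(scope="session")
def knockout_runs():
    out = {}
    for base in ("WT", "pfe", "nac"):
        for ko in ("no-l2d", "no-d2l"):
            out[(base, ko)] = ss.run_simulation(f"{base};{ko}", seed=701)
    return out


@pytest.fixture(scope="session")
def seurat_runs():
    return _runs("seurat", (101, 102, 103), checkpoint_stages=("J",))


def small_random_state(seed, rows=6, cols=8, density=0.25):
    """A random small three-layer state for oracle comparisons."""
    rng = np.random.default_rng(seed)
    p = ss.Params()
    st = ss.DomainState(p, rows, cols, seed=seed)
    st.m[rng.random(st.m.shape) < density] = ss.CellKind.M
    xr = rng.random(st.x.shape)
    st.x[xr < density / 2] = ss.CellKind.X
    st.x[(xr >= density / 2) & (xr < density)] = ss.CellKind.XB
    ir = rng.random(st.i.shape)
    st.i[ir < density / 2] = ss.CellKind.ID
    st.i[(ir >= density / 2) & (ir < density)] = ss.CellKind.IL
    return st
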