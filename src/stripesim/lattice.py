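"""Three-layer growing lattice domain.

The trunk skin is modelled as three stacked, independent square lattices
sharing one physical rectangle:

* the M layer (melanophores) at coarse pitch (0.02 mm by default), and
* the X layer (xanthophores/xanthoblasts) and I layer (dense/loose
  S-iridophores) at half that pitch, so each coarse site nests exactly a
  2 x 2 block of fine sites.

Each site holds at most one agent (volume exclusion).  The domain grows by
inserting empty rows/columns at uniformly random positions; a coarse
insertion always inserts the two aligned fine rows/columns so the 2:1
nesting is preserved.
"""
from __future__ import annotations

import enum
import math
from typing import Optional

import numpy as np

from .params import Params

__all__ = [
    "CellKind", "EMPTY", "DomainState", "init_state", "grow_domain",
    "site_center_mm", "simulated_SL", "simulated_HAA", "stage_of",
]

EMPTY = 0


class CellKind(enum.IntEnum):
    """The five modelled pigment cell types."""
    M = 1    # melanophore            (M layer)
    X = 2    # xanthophore            (X layer)
    XB = 3   # xanthoblast            (X layer)
    ID = 4   # dense S-iridophore     (I layer)
    IL = 5   # loose S-iridophore     (I layer)


KIND_TOKENS = {CellKind.M: "M", CellKind.X: "X", CellKind.XB: "Xb",
               CellKind.ID: "Id", CellKind.IL: "Il"}
TOKEN_KINDS = {v: k for k, v in KIND_TOKENS.items()}
LAYER_OF_KIND = {CellKind.M: "M", CellKind.X: "X", CellKind.XB: "X",
                 CellKind.ID: "I", CellKind.IL: "I"}


def site_center_mm(pitch: float, site) -> tuple:
    """Physical centre (y, x) in mm of ``site = (row, col)`` on a lattice of
    the given pitch.  Row 0 / col 0 is the bottom-left of the rectangle."""
    r, c = site
    if r < 0 or c < 0:
        raise IndexError(f"site {site} out of bounds")
    return ((r + 0.5) * pitch, (c + 0.5) * pitch)


class DomainState:
    """Complete simulation state: three lattice layers, clock and RNG seed.

    Grids are stored padded to a capacity larger than the current active
    region; ``m``, ``x`` and ``i`` expose trimmed views of the active
    region.  ``rows``/``cols`` are the coarse (M-layer) dimensions; the fine
    layers are exactly twice as large.
    """

    def __init__(self, params: Params, rows: int, cols: int,
                 cap_rows: Optional[int] = None, cap_cols: Optional[int] = None,
                 seed: int = 0, genotype_name: str = "WT"):
        self.params = params
        self.rows = rows
        self.cols = cols
        cap_rows = max(cap_rows or 0, rows)
        cap_cols = max(cap_cols or 0, cols)
        self.mgrid = np.zeros((cap_rows, cap_cols), dtype=np.int8)
        self.xgrid = np.zeros((2 * cap_rows, 2 * cap_cols), dtype=np.int8)
        self.igrid = np.zeros((2 * cap_rows, 2 * cap_cols), dtype=np.int8)
        self.t = 0.0
        self.seed = seed
        self.genotype_name = genotype_name
        self.fixed_events_done: set = set()

    # --- views -------------------------------------------------------------
    @property
    def m(self) -> np.ndarray:
        return self.mgrid[: self.rows, : self.cols]

    @property
    def x(self) -> np.ndarray:
        return self.xgrid[: 2 * self.rows, : 2 * self.cols]

    @property
    def i(self) -> np.ndarray:
        return self.igrid[: 2 * self.rows, : 2 * self.cols]

    def layer(self, name: str) -> np.ndarray:
        return {"M": self.m, "X": self.x, "I": self.i}[name]

    def layer_pitch(self, name: str) -> float:
        return self.params.pitch_m if name == "M" else self.params.pitch_f

    # --- physical geometry ---------------------------------------------------
    @property
    def length(self) -> float:
        return self.cols * self.params.pitch_m

    @property
    def height(self) -> float:
        return self.rows * self.params.pitch_m

    # --- bookkeeping ---------------------------------------------------------
    def counts(self) -> dict:
        return {
            CellKind.M: int((self.m == CellKind.M).sum()),
            CellKind.X: int((self.x == CellKind.X).sum()),
            CellKind.XB: int((self.x == CellKind.XB).sum()),
            CellKind.ID: int((self.i == CellKind.ID).sum()),
            CellKind.IL: int((self.i == CellKind.IL).sum()),
        }

    def copy(self) -> "DomainState":
        new = DomainState.__new__(DomainState)
        new.params = self.params
        new.rows, new.cols = self.rows, self.cols
        new.mgrid = self.mgrid.copy()
        new.xgrid = self.xgrid.copy()
        new.igrid = self.igrid.copy()
        new.t = self.t
        new.seed = self.seed
        new.genotype_name = self.genotype_name
        new.fixed_events_done = set(self.fixed_events_done)
        return new

    def __repr__(self) -> str:  # pragma: no cover
        c = self.counts()
        occ = ", ".join(f"{KIND_TOKENS[k]}={v}" for k, v in c.items() if v)
        return (f"<DomainState {self.genotype_name} t={self.t:.2f}d "
                f"{self.length:.2f}x{self.height:.2f}mm SL={simulated_SL(self):.2f} "
                f"[{occ or 'empty'}]>")


def simulated_SL(state: DomainState) -> float:
    """Simulated standard length (mm) from the current domain length."""
    return state.params.simulated_sl(state.length)


def simulated_HAA(state: DomainState) -> float:
    """Simulated height at the anterior of the anal fin: the domain height."""
    return state.height


def stage_of(sl: float, stages=None) -> str:
    """Largest developmental stage whose SL threshold is <= ``sl``."""
    from .params import DEFAULT_STAGES
    stages = stages or DEFAULT_STAGES
    if sl <= 0:
        raise ValueError("SL must be positive")
    current = stages[0][0]
    for label, thr in stages:
        if sl >= thr - 1e-12:
            current = label
    return current


def _capacity_for(params: Params, rows0: int, cols0: int,
                  extra_days: float = 0.0) -> tuple:
    """Generous preallocation bounds for a run to end_SL (+ optional extra
    days of post-metamorphic growth, e.g. regeneration follow-up)."""
    end_len = params.length_at_sl(params.end_sl) + params.growth_h * extra_days
    cap_cols = int(math.ceil(end_len / params.pitch_m)) + 4
    days = (end_len - cols0 * params.pitch_m) / max(params.growth_h, 1e-9)
    exp_v = params.growth_v * max(days, 0.0) / params.pitch_m
    cap_rows = rows0 + int(math.ceil(exp_v + 8.0 * math.sqrt(exp_v + 1.0))) + 4
    return cap_rows, max(cap_cols, cols0 + 4)


def init_state(params: Params, genotype, seed: int = 0,
               extra_days: float = 0.0) -> DomainState:
    """Initialise the domain as a typical fish at the onset of adult pattern
    metamorphosis (stage PB, ~25 dpf).

    Wild type: the central three fine rows of the S-iridophore layer are
    fully occupied by dense S-iridophores (the myoseptum band), melanophores
    are placed uniformly at random on the M layer at density 0.04 and
    xanthoblasts on the X layer at density 0.4.  Genotypes may remove
    lineages, rescale the initial band or densities, or replace the initial
    condition wholesale (in-silico experiments).
    """
    from .genotypes import Genotype  # deferred: avoid import cycle
    if not isinstance(genotype, Genotype):
        raise TypeError("genotype must be a Genotype (see make_genotype)")

    rows0 = int(round(genotype.init_height(params) / params.pitch_m))
    cols0 = int(round(params.init_length / params.pitch_m))
    cap_rows, cap_cols = _capacity_for(params, rows0, cols0, extra_days)
    state = DomainState(params, rows0, cols0, cap_rows, cap_cols,
                        seed=seed, genotype_name=genotype.name)
    rng = np.random.default_rng(seed)
    genotype.initialise(state, rng)
    state.fixed_events_done.add("init")
    return state


def grow_domain(state: DomainState, axis: str,
                rng: Optional[np.random.Generator] = None,
                index: Optional[int] = None) -> DomainState:
    """Insert one empty coarse row (``axis='vertical'``) or column
    (``'horizontal'``) and the two aligned fine rows/columns, at a position
    drawn uniformly at random (or at ``index`` if given).  Agent counts are
    unchanged; the physical extent increases by one coarse pitch.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError(f"unknown axis {axis!r}")
    vertical = axis == "vertical"
    n = state.rows if vertical else state.cols
    if index is None:
        rng = rng or np.random.default_rng()
        index = int(rng.integers(0, n + 1))
    if not 0 <= index <= n:
        raise IndexError("insertion index out of range")

    def _ins(grid, active_r, active_c, k, vert):
        if vert:
            grid[k + 1: active_r + 1, :active_c] = grid[k: active_r, :active_c]
            grid[k, :active_c] = EMPTY
        else:
            grid[:active_r, k + 1: active_c + 1] = grid[:active_r, k: active_c]
            grid[:active_r, k] = EMPTY

    r, c = state.rows, state.cols
    if vertical:
        if r + 1 > state.mgrid.shape[0]:
            raise MemoryError("coarse-grid capacity exceeded")
        _ins(state.mgrid, r, c, index, True)
        for g in (state.xgrid, state.igrid):
            _ins(g, 2 * r, 2 * c, 2 * index, True)
            _ins(g, 2 * r + 1, 2 * c, 2 * index, True)
        state.rows += 1
    else:
        if c + 1 > state.mgrid.shape[1]:
            raise MemoryError("coarse-grid capacity exceeded")
        _ins(state.mgrid, r, c, index, False)
        for g in (state.xgrid, state.igrid):
            _ins(g, 2 * r, 2 * c, 2 * index, False)
            _ins(g, 2 * r, 2 * c + 1, 2 * index, False)
        state.cols += 1
    return state
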