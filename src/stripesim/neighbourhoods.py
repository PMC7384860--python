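"""Short-range disk and long-range annulus queries across lattice layers.

Cells interact at two ranges: a short-range uniform disk of radius ~0.04 mm
(about one cell-cell distance) and a long-range annulus 0.22-0.24 mm from
the cell (about half a stripe width), modelling contact through long
cellular projections.  Distances are measured between *site centres* in mm;
a range (lo, hi] is open at the inner and closed at the outer boundary so
that disk = disk(0, inner] + annulus(inner, outer] exactly.

Because the X and I layers have half the pitch of the M layer, a query from
an agent on one layer into another enumerates a fixed stencil of integer
offsets that depends only on the pitches, the query range, and (for
fine-to-coarse queries) the parity of the fine site.  The stencils are
precomputed here and shared with the event kernel.
"""
from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .lattice import CellKind, DomainState
from .params import Params

_EPS = 1e-9

#: the eight compass directions, row-major order (dr, dc)
DIRS = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)], dtype=np.int64)
DIR_UNIT = DIRS / np.linalg.norm(DIRS, axis=1, keepdims=True)


def _enumerate_offsets(step: float, origin: float, lo: float, hi: float):
    """Integer offsets (a, b) whose displacement ((a*step + origin),
    (b*step + origin)) has Euclidean norm in (lo, hi]."""
    nmax = int(math.ceil((hi + abs(origin)) / step)) + 1
    offs, disp = [], []
    for a in range(-nmax, nmax + 1):
        dy = a * step + origin
        for b in range(-nmax, nmax + 1):
            dx = b * step + origin
            d = math.hypot(dy, dx)
            if lo + _EPS < d <= hi + _EPS:
                offs.append((a, b))
                disp.append((dy, dx))
    offs = np.array(offs, dtype=np.int64).reshape(-1, 2)
    disp = np.array(disp, dtype=np.float64).reshape(-1, 2)
    return offs, disp


def _unit(disp: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(disp, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return disp / n


class Stencils:
    """Precomputed offset stencils for one (pitch, range) geometry.

    Attributes (``rng`` is ``"short"`` or ``"long"``):

    * ``cc[rng]``     coarse agent -> coarse sites, offsets relative to the
      agent's own (row, col).
    * ``cf[rng]``     coarse agent -> fine sites, offsets relative to the
      fine site (2 row, 2 col).
    * ``fc[rng]``     fine agent -> coarse sites; one stencil per parity
      ``(row % 2, col % 2)``, offsets relative to (row // 2, col // 2).
    * ``ff[rng]``     fine agent -> fine sites.

    ``*_uv`` hold matching unit displacement vectors (for movement bias).
    """

    def __init__(self, pitch_m: float, short_radius: float,
                 long_inner: float, long_outer: float):
        p = pitch_m / 2.0
        ranges = {"short": (0.0, short_radius), "long": (long_inner, long_outer)}
        self.cc, self.cf, self.fc, self.ff = {}, {}, {}, {}
        self.cc_uv, self.cf_uv, self.fc_uv, self.ff_uv = {}, {}, {}, {}
        for name, (lo, hi) in ranges.items():
            self.cc[name], d = _enumerate_offsets(pitch_m, 0.0, lo, hi)
            self.cc_uv[name] = _unit(d)
            # coarse centre sits +p/2 from the centre of fine site (2r, 2c)
            self.cf[name], d = _enumerate_offsets(p, -p / 2.0, lo, hi)
            self.cf_uv[name] = _unit(d)
            self.ff[name], d = _enumerate_offsets(p, 0.0, lo, hi)
            self.ff_uv[name] = _unit(d)
            fcs, fcu = [], []
            for ei in (0, 1):
                for ej in (0, 1):
                    nmax = int(math.ceil(hi / pitch_m)) + 2
                    offs, disp = [], []
                    for dR in range(-nmax, nmax + 1):
                        dy = p * (2 * dR + 0.5 - ei)
                        for dC in range(-nmax, nmax + 1):
                            dx = p * (2 * dC + 0.5 - ej)
                            dd = math.hypot(dy, dx)
                            if lo + _EPS < dd <= hi + _EPS:
                                offs.append((dR, dC))
                                disp.append((dy, dx))
                    fcs.append(np.array(offs, dtype=np.int64).reshape(-1, 2))
                    fcu.append(_unit(np.array(disp, dtype=np.float64).reshape(-1, 2)))
            self.fc[name] = fcs      # parity index 2*(row%2) + (col%2)
            self.fc_uv[name] = fcu


@lru_cache(maxsize=8)
def get_stencils(pitch_m: float, short_radius: float,
                 long_inner: float, long_outer: float) -> Stencils:
    return Stencils(pitch_m, short_radius, long_inner, long_outer)


def stencils_for(params: Params) -> Stencils:
    return get_stencils(params.pitch_m, params.short_radius,
                        params.long_inner, params.long_outer)


# ---------------------------------------------------------------------------
# counting queries
# ---------------------------------------------------------------------------

def _count_in_range(state: DomainState, target_layer: str, center,
                    lo: float, hi: float, kinds) -> int:
    grid = state.layer(target_layer)
    pitch = state.layer_pitch(target_layer)
    cy, cx = center
    r0 = max(0, int(math.floor((cy - hi) / pitch - 1)))
    r1 = min(grid.shape[0], int(math.ceil((cy + hi) / pitch + 1)))
    c0 = max(0, int(math.floor((cx - hi) / pitch - 1)))
    c1 = min(grid.shape[1], int(math.ceil((cx + hi) / pitch + 1)))
    if r0 >= r1 or c0 >= c1:
        return 0
    sub = grid[r0:r1, c0:c1]
    rr = (np.arange(r0, r1) + 0.5) * pitch - cy
    cc = (np.arange(c0, c1) + 0.5) * pitch - cx
    d = np.hypot(rr[:, None], cc[None, :])
    in_range = (d > lo + _EPS) & (d <= hi + _EPS)
    kindset = {int(k) for k in (kinds if hasattr(kinds, "__iter__") else [kinds])}
    occ = np.isin(sub, list(kindset))
    return int((in_range & occ).sum())


def count_in_disk(state: DomainState, target_layer: str, center,
                  radius: float, kinds) -> int:
    """Number of agents of ``kinds`` on ``target_layer`` whose site centre
    lies at distance 0 < d <= radius from ``center`` (mm).  A focal agent at
    the query centre itself is excluded (d = 0)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return _count_in_range(state, target_layer, center, 0.0, radius, kinds)


def count_in_annulus(state: DomainState, target_layer: str, center,
                     inner: float, outer: float, kinds) -> int:
    """Number of agents of ``kinds`` with inner < d <= outer from ``center``."""
    if not 0 <= inner < outer:
        raise ValueError("require 0 <= inner < outer")
    return _count_in_range(state, target_layer, center, inner, outer, kinds)


# ---------------------------------------------------------------------------
# movement bias
# ---------------------------------------------------------------------------

def default_bias_table(params: Params, kind: CellKind):
    """Influencing pairs (target_layer, target_kind, range, signed strength)
    for a focal agent of ``kind``: xanthophores chase melanophores, which are
    repelled by xanthophores; dense S-iridophores are drawn to xanthophores;
    loose S-iridophores repel each other; xanthoblasts pull melanophores at
    long range."""
    if kind == CellKind.M:
        return [("X", CellKind.X, "short", params.s_m_from_x),
                ("X", CellKind.XB, "long", params.s_m_to_xb)]
    if kind == CellKind.X:
        return [("M", CellKind.M, "short", params.s_x_to_m)]
    if kind == CellKind.ID:
        return [("X", CellKind.X, "short", params.s_id_to_x)]
    if kind == CellKind.IL:
        return [("I", CellKind.IL, "short", params.s_il_from_il)]
    return []


def movement_weights(state: DomainState, layer: str, site, bias_table,
                     beta: float | None = None) -> np.ndarray:
    """Probabilities for the eight compass moves of the focal agent.

    The bias vector is B = sum_j s_j * u_j over influencing neighbours j
    (unit vector u_j from the focal agent towards j, within the pair's
    range); the weight of direction d is proportional to exp(beta * B.u_d).
    With no neighbours (or all strengths zero) the result is uniform 1/8.
    """
    params = state.params
    beta = params.beta if beta is None else beta
    pitch = state.layer_pitch(layer)
    cy, cx = site_center(pitch, site)
    B = np.zeros(2)
    for tlayer, tkind, rng_name, s in bias_table:
        if s == 0.0:
            continue
        lo, hi = ((0.0, params.short_radius) if rng_name == "short"
                  else (params.long_inner, params.long_outer))
        grid = state.layer(tlayer)
        tp = state.layer_pitch(tlayer)
        r0 = max(0, int(math.floor((cy - hi) / tp - 1)))
        r1 = min(grid.shape[0], int(math.ceil((cy + hi) / tp + 1)))
        c0 = max(0, int(math.floor((cx - hi) / tp - 1)))
        c1 = min(grid.shape[1], int(math.ceil((cx + hi) / tp + 1)))
        for r in range(r0, r1):
            dy = (r + 0.5) * tp - cy
            for c in range(c0, c1):
                if grid[r, c] != tkind:
                    continue
                dx = (c + 0.5) * tp - cx
                d = math.hypot(dy, dx)
                if lo + _EPS < d <= hi + _EPS:
                    B += s * np.array([dy, dx]) / d
    z = beta * (DIR_UNIT @ B)
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def site_center(pitch: float, site):
    return ((site[0] + 0.5) * pitch, (site[1] + 0.5) * pitch)
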