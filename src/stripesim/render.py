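"""Rendering of lattice states.

Follows the usual colour convention for this system: xanthophores yellow,
xanthoblasts faint outline, dense S-iridophores silvery white, loose
S-iridophores blue, melanophores black; layers composited X under I under M
(anatomically the melanophores sit below, but render order only affects
which glyph wins a pixel).
"""
from __future__ import annotations

import numpy as np
from PIL import Image

from .lattice import CellKind, DomainState

__all__ = ["render_state", "state_to_rgb", "ascii_art"]

_BG = (120, 144, 156)
_COLORS = {
    CellKind.X: (240, 200, 40),
    CellKind.XB: (190, 185, 160),
    CellKind.ID: (245, 245, 245),
    CellKind.IL: (60, 90, 220),
    CellKind.M: (10, 10, 10),
}


def state_to_rgb(state: DomainState) -> np.ndarray:
    """RGB array at fine-lattice resolution (row 0 at the bottom)."""
    rf, cf = state.x.shape
    img = np.empty((rf, cf, 3), dtype=np.uint8)
    img[:] = _BG
    for kind in (CellKind.XB, CellKind.X):
        img[state.x == kind] = _COLORS[kind]
    for kind in (CellKind.ID, CellKind.IL):
        img[state.i == kind] = _COLORS[kind]
    mfine = np.kron(state.m == CellKind.M, np.ones((2, 2), dtype=bool))
    img[mfine] = _COLORS[CellKind.M]
    return img[::-1]   # image row 0 at the top


def render_state(state: DomainState, path, scale: int = 3):
    """Write a PNG of the state; each fine lattice site is ``scale`` px."""
    img = state_to_rgb(state)
    im = Image.fromarray(img, mode="RGB")
    im = im.resize((img.shape[1] * scale, img.shape[0] * scale),
                   Image.NEAREST)
    im.save(path)
    return path


def ascii_art(state: DomainState, width: int = 110) -> str:
    """Terminal sketch of the pattern (one char per block of fine sites):
    ``M`` melanophore, ``#`` dense S-iridophore, ``:`` loose, ``x``
    xanthophore, ``.`` xanthoblast, space empty."""
    rf, cf = state.x.shape
    step = max(1, int(np.ceil(cf / width)))
    rows = []
    for r0 in range(0, rf, 2 * step):
        line = []
        for c0 in range(0, cf, step):
            xs = state.x[r0:r0 + 2 * step, c0:c0 + step]
            is_ = state.i[r0:r0 + 2 * step, c0:c0 + step]
            ms = state.m[r0 // 2:(r0 + 2 * step) // 2,
                         c0 // 2:(c0 + step) // 2]
            if (ms == CellKind.M).any():
                ch = "M"
            elif (is_ == CellKind.ID).mean() > 0.25:
                ch = "#"
            elif (is_ == CellKind.IL).any():
                ch = ":"
            elif (xs == CellKind.X).mean() > 0.25:
                ch = "x"
            elif (xs == CellKind.XB).any():
                ch = "."
            else:
                ch = " "
            line.append(ch)
        rows.append("".join(line))
    return "\n".join(reversed(rows))
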