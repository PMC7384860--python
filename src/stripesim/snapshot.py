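"""Snapshot persistence.

A snapshot is a CSV of agents (``layer,row,col,kind``; layers ``M,X,I``;
kinds ``M,X,Xb,Id,Il``; 0-based indices) plus a JSON sidecar with pitches,
dimensions, clock, SL, seed and genotype, so a state round-trips losslessly.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

from .lattice import (CellKind, DomainState, KIND_TOKENS, LAYER_OF_KIND,
                      TOKEN_KINDS, simulated_SL)
from .params import Params

__all__ = ["write_snapshot", "read_snapshot"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_snapshot(state: DomainState, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["layer", "row", "col", "kind"])
        for layer in ("M", "X", "I"):
            g = state.layer(layer)
            for (r, c) in zip(*g.nonzero()):
                w.writerow([layer, int(r), int(c),
                            KIND_TOKENS[CellKind(g[r, c])]])
    meta = {
        "rows": state.rows, "cols": state.cols,
        "pitch_m": state.params.pitch_m, "pitch_f": state.params.pitch_f,
        "t": state.t, "sl": simulated_SL(state),
        "seed": state.seed, "genotype": state.genotype_name,
        "fixed_events_done": sorted(state.fixed_events_done),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_snapshot(path, params: Params | None = None) -> DomainState:
    path = Path(path)
    with open(_sidecar_path(path)) as fh:
        meta = json.load(fh)
    params = params or Params()
    if abs(params.pitch_m - meta["pitch_m"]) > 1e-12:
        params = params.replace(pitch_m=meta["pitch_m"])
    state = DomainState(params, meta["rows"], meta["cols"],
                        seed=meta.get("seed", 0),
                        genotype_name=meta.get("genotype", "WT"))
    state.t = meta["t"]
    state.fixed_events_done = set(meta.get("fixed_events_done", ()))
    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        if header != ["layer", "row", "col", "kind"]:
            raise ValueError(f"{path}:1: bad snapshot header {header}")
        for ln, row in enumerate(rd, start=2):
            if not row:
                continue
            try:
                layer, r, c, tok = row[0], int(row[1]), int(row[2]), row[3]
                kind = TOKEN_KINDS[tok]
            except (ValueError, KeyError, IndexError) as e:
                raise ValueError(f"{path}:{ln}: malformed row {row}") from e
            if LAYER_OF_KIND[kind] != layer:
                raise ValueError(f"{path}:{ln}: kind {tok} not valid on "
                                 f"layer {layer}")
            g = state.layer(layer)
            if not (0 <= r < g.shape[0] and 0 <= c < g.shape[1]):
                raise ValueError(f"{path}:{ln}: site ({r},{c}) out of bounds")
            if g[r, c] != 0:
                raise ValueError(f"{path}:{ln}: site ({r},{c}) already "
                                 "occupied (volume exclusion)")
            g[r, c] = kind
    return state
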