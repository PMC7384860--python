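"""Genotypes, rule knockouts and in-silico experiments.

A :class:`Genotype` bundles everything that distinguishes a simulated fish
from wild type: lineage removals (the 'missing cell' mutants remove a cell
type from the initial conditions and switch off its birth), parameter
overrides/rescalings (*sbr*, *seurat*), rule toggles (the *leo* hypotheses
and the rule-knockout switches), fixed-event schedule edits (*cho*) and
replacement initial conditions (the initial-condition experiments).

The registry ships as JSON data; crosses compose by joining names with
``;`` (composition is commutative and idempotent, e.g. ``"leo;nac"``).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .lattice import CellKind, DomainState
from .params import Params

__all__ = ["Genotype", "make_genotype", "list_genotypes", "perturb_parameters",
           "ablate_window", "ablate_iridophore_segment",
           "experimental_initializer"]

_LINEAGES = {"iridophore", "melanophore", "xanthophore"}
_TOGGLES = {"h2", "h4", "d2l_no_xlong", "d2l_no_xshort",
            "l2d_no_mshort", "l2d_no_xshort"}
_ZEROABLE = {"diff_m_base", "diff_m_irid", "diff_m_xan", "diff_m_loose"}

# re-export: the sweep lives with Params but is a genotype-level experiment
from .params import perturb_parameters  # noqa: E402,F401


def _load_registry() -> dict:
    with resources.files("stripesim.data").joinpath("genotypes.json").open() as fh:
        return json.load(fh)


_REGISTRY = _load_registry()


@dataclass(frozen=True)
class Genotype:
    name: str
    removals: frozenset = frozenset()
    init_id_fraction: float = 1.0
    m_density: Optional[float] = None
    param_overrides: tuple = ()        # ((field, value), ...)
    param_scales: tuple = ()           # ((field, factor), ...)
    zero_weights: frozenset = frozenset()
    toggles: frozenset = frozenset()
    fixed_events: tuple = ()           # schedule edits, dicts
    initializer: Optional[str] = None

    # ------------------------------------------------------------------ params
    def apply_params(self, params: Params) -> Params:
        """Genotype-adjusted parameter set (overrides, then rescalings)."""
        kw = dict(self.param_overrides)
        for f, s in self.param_scales:
            kw[f] = kw.get(f, getattr(params, f)) * s
        return params.replace(**kw) if kw else params

    def has(self, lineage: str) -> bool:
        return lineage not in self.removals

    # -------------------------------------------------------------- initialise
    def init_height(self, params: Params) -> float:
        if self.initializer == "tall_domain":
            return 3.0
        return params.init_height

    def initialise(self, state: DomainState, rng: np.random.Generator) -> None:
        params = state.params
        if self.initializer == "pre_striped":
            _init_pre_striped(state, rng, self)
            return
        # dense S-iridophore band along the myoseptum (a t=0 fixed event)
        if self.has("iridophore") and self.init_id_fraction > 0:
            band = _band_sites(state, self.initializer)
            if self.init_id_fraction < 1.0:
                keep = rng.random(len(band)) < self.init_id_fraction
                band = [s for s, k in zip(band, keep) if k]
            for (i, j) in band:
                state.i[i, j] = CellKind.ID
        if self.has("melanophore"):
            dens = self.m_density if self.m_density is not None \
                else params.init_m_density
            mask = rng.random(state.m.shape) < dens
            state.m[mask] = CellKind.M
        if self.has("xanthophore"):
            mask = rng.random(state.x.shape) < params.init_xb_density
            state.x[mask] = CellKind.XB


def _band_sites(state: DomainState, initializer: Optional[str]):
    """Sites of the initial dense S-iridophore band (width three fine sites)."""
    rf, cf = state.i.shape
    if initializer == "vertical_interstripe":
        mid = cf // 2
        return [(i, j) for j in range(mid - 1, mid + 2) for i in range(rf)]
    if initializer == "off_center_interstripe":
        mid = rf // 4
    else:
        mid = rf // 2
    return [(i, j) for i in range(mid - 1, mid + 2) for j in range(cf)]


def _init_pre_striped(state: DomainState, rng: np.random.Generator,
                      genotype: Genotype) -> None:
    """Adult-width stripes/interstripes already in place at stage PB.

    Band widths default to typical J+ values: 0.2 mm interstripes (dense
    S-iridophores with xanthophores above) alternating with 0.3 mm stripes
    (melanophores with loose S-iridophores and persisting xanthoblasts),
    with an interstripe centred at mid-height.
    """
    p = state.params
    inter_w, stripe_w = 0.2, 0.3
    period = inter_w + stripe_w
    rf, _ = state.i.shape
    y = (np.arange(rf) + 0.5) * p.pitch_f
    mid = state.height / 2.0
    phase = np.mod(y - (mid - inter_w / 2.0), period)
    inter_rows = phase < inter_w
    if genotype.has("iridophore"):
        state.i[inter_rows, :] = CellKind.ID
        il = (~inter_rows)[:, None] & (rng.random(state.i.shape) < 0.15)
        state.i[il] = CellKind.IL
    if genotype.has("xanthophore"):
        x = inter_rows[:, None] & (rng.random(state.x.shape) < 0.8)
        xb = (~inter_rows)[:, None] & (rng.random(state.x.shape) < 0.4)
        state.x[x] = CellKind.X
        state.x[xb] = CellKind.XB
    if genotype.has("melanophore"):
        inter_coarse = inter_rows[::2] | inter_rows[1::2]
        m = (~inter_coarse)[:, None] & (rng.random(state.m.shape) < 0.55)
        state.m[m] = CellKind.M


def _parse_entry(name: str, entry: dict) -> Genotype:
    if "compose" in entry:
        parts = [_parse_entry(n, _REGISTRY[n]) for n in entry["compose"]]
        return _merge(name, parts)
    removals = frozenset(entry.get("removals", ()))
    if not removals <= _LINEAGES:
        raise ValueError(f"unknown lineage in genotype {name!r}")
    toggles = frozenset(k for k, v in entry.get("toggles", {}).items() if v)
    if not toggles <= _TOGGLES:
        raise ValueError(f"unknown toggle in genotype {name!r}")
    zero = frozenset(entry.get("zero_weights", ()))
    if not zero <= _ZEROABLE:
        raise ValueError(f"unknown weight in genotype {name!r}")
    return Genotype(
        name=name,
        removals=removals,
        init_id_fraction=float(entry.get("init_id_fraction", 1.0)),
        m_density=entry.get("m_density"),
        param_overrides=tuple(sorted(entry.get("param_overrides", {}).items())),
        param_scales=tuple(sorted(entry.get("param_scales", {}).items())),
        zero_weights=zero,
        toggles=toggles,
        fixed_events=tuple(tuple(sorted(e.items())) for e in
                           entry.get("fixed_events", ())),
        initializer=entry.get("initializer"),
    )


def _merge(name: str, parts: list) -> Genotype:
    removals = frozenset().union(*(g.removals for g in parts))
    overrides: dict = {}
    scales: dict = {}
    for g in parts:
        overrides.update(dict(g.param_overrides))
        for f, s in g.param_scales:
            scales[f] = scales.get(f, 1.0) * s
    frac = 1.0
    m_density = None
    initializer = None
    fixed: list = []
    for g in parts:
        frac = min(frac, g.init_id_fraction)
        if g.m_density is not None:
            m_density = g.m_density
        if g.initializer is not None:
            initializer = g.initializer
        fixed.extend(g.fixed_events)
    return Genotype(
        name=name,
        removals=removals,
        init_id_fraction=frac,
        m_density=m_density,
        param_overrides=tuple(sorted(overrides.items())),
        param_scales=tuple(sorted(scales.items())),
        zero_weights=frozenset().union(*(g.zero_weights for g in parts)),
        toggles=frozenset().union(*(g.toggles for g in parts)),
        fixed_events=tuple(dict.fromkeys(fixed)),
        initializer=initializer,
    )


def make_genotype(name) -> Genotype:
    """Resolve a genotype name (``"WT"``, ``"shd"``, ``"leo;nac"``, ...).

    Crosses join component names with ``;``; the composition is independent
    of order and of repetition.
    """
    if isinstance(name, Genotype):
        return name
    parts = sorted(set(p.strip() for p in str(name).split(";") if p.strip()))
    if not parts:
        raise KeyError("empty genotype name")
    for p in parts:
        if p not in _REGISTRY:
            raise KeyError(f"unknown genotype {p!r} "
                           f"(known: {', '.join(sorted(_REGISTRY))})")
    resolved = [_parse_entry(p, _REGISTRY[p]) for p in parts]
    if len(resolved) == 1:
        return resolved[0]
    return _merge(";".join(parts), resolved)


def list_genotypes() -> dict:
    """Registry names with their one-line descriptions."""
    return {k: v.get("note", "") for k, v in sorted(_REGISTRY.items())}


# ---------------------------------------------------------------------------
# in-silico surgery
# ---------------------------------------------------------------------------

def ablate_window(state: DomainState, rect) -> DomainState:
    """Remove all agents, on all three layers, whose site centres fall in
    ``rect = (y0, y1, x0, x1)`` (mm).  Mimics laser ablation of a window of
    skin."""
    y0, y1, x0, x1 = rect
    if not (y1 > y0 and x1 > x0):
        raise ValueError("degenerate ablation rectangle")
    for layer in ("M", "X", "I"):
        g = state.layer(layer)
        p = state.layer_pitch(layer)
        yc = (np.arange(g.shape[0]) + 0.5) * p
        xc = (np.arange(g.shape[1]) + 0.5) * p
        rows = (yc >= y0) & (yc <= y1)
        cols = (xc >= x0) & (xc <= x1)
        g[np.ix_(rows, cols)] = 0
    return state


def ablate_iridophore_segment(state: DomainState, span) -> DomainState:
    """Remove dense S-iridophores whose centres fall in the horizontal span
    ``(x0, x1)`` (mm) — the myoseptum-band ablation experiment."""
    x0, x1 = span
    g = state.i
    p = state.params.pitch_f
    xc = (np.arange(g.shape[1]) + 0.5) * p
    cols = (xc >= x0) & (xc <= x1)
    sub = g[:, cols]
    sub[sub == CellKind.ID] = 0
    g[:, cols] = sub
    return state


def experimental_initializer(name: str) -> Genotype:
    """Initial-condition experiment presets (altered band orientation or
    position, enlarged domain, pre-formed stripes)."""
    key = name.replace("_", "-")
    if key not in _REGISTRY or "initializer" not in _REGISTRY[key]:
        raise KeyError(f"unknown experimental initializer {name!r}")
    return make_genotype(key)
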