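"""Exact continuous-time simulation loop.

The loop follows the Gillespie algorithm: all fixed events due at the
current stage are applied once, the fifteen propensities are computed from
the current state, an exponential waiting time tau = ln(1/u0)/alpha0 and an
event index (the smallest j with cumulative propensity >= u1*alpha0) are
drawn, and the chosen event is attempted.  The run ends when the simulated
standard length reaches ``end_sl`` (13.5 mm, stage J+, by default).

The per-event work is delegated to the numba kernel (:mod:`._kernel`); this
module owns fixed events, stage checkpoints and reproducibility (a single
integer seed determines the whole trajectory bit-for-bit).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield
from typing import Optional, Sequence

import numpy as np

from . import _kernel as K
from .lattice import CellKind, DomainState, init_state, simulated_SL, stage_of
from .genotypes import Genotype, make_genotype
from .neighbourhoods import Stencils, stencils_for
from .params import Params

__all__ = ["next_event", "run_simulation", "continue_simulation", "Trajectory"]


def next_event(alphas: Sequence[float], rng: np.random.Generator):
    """One Gillespie draw: waiting time and event index.

    tau is exponential with rate alpha0 = sum(alphas); the event is the
    smallest index whose cumulative propensity reaches u1 * alpha0.  Raises
    ``StalledError`` when every propensity is zero.
    """
    alphas = np.asarray(alphas, dtype=float)
    a0 = alphas.sum()
    if a0 <= 0:
        raise StalledError("all propensities are zero")
    u0, u1 = rng.random(2)
    tau = math.log(1.0 / u0) / a0
    j = int(np.searchsorted(np.cumsum(alphas), u1 * a0))
    return tau, min(j, len(alphas) - 1)


class StalledError(RuntimeError):
    """No continuous-time event can fire and no fixed event is pending."""


@dataclass
class Trajectory:
    """Recorded run: stage checkpoints, event tallies and provenance."""
    genotype: str
    seed: int
    params: Params
    checkpoints: list = dfield(default_factory=list)   # (stage, t, SL, state)
    final_state: Optional[DomainState] = None
    event_attempts: dict = dfield(default_factory=dict)
    event_firings: dict = dfield(default_factory=dict)
    status: str = "completed"

    @property
    def final_sl(self) -> float:
        return simulated_SL(self.final_state)

    def checkpoint(self, stage: str) -> DomainState:
        for lbl, _t, _sl, st in self.checkpoints:
            if lbl == stage:
                return st
        raise KeyError(stage)


def _kernel_params(params: Params, genotype: Genotype):
    b = {w: getattr(params, w) for w in
         ("diff_m_base", "diff_m_irid", "diff_m_xan", "diff_m_loose")}
    for w in genotype.zero_weights:
        b[w] = 0.0
    cap = sum(b.values())
    prm = np.zeros(K.N_PRM)
    prm[K.R_MOVE_M] = params.speed_m / params.pitch_m
    prm[K.R_MOVE_X] = params.speed_x / params.pitch_f
    prm[K.R_MOVE_I] = params.speed_i / params.pitch_f
    prm[K.R_PRO_XB] = params.prolif_xb
    prm[K.R_PRO_X] = params.prolif_x
    prm[K.R_PRO_ID] = params.prolif_id
    prm[K.R_PRO_IL] = params.prolif_il
    prm[K.R_DIFF_M_CAP] = cap
    prm[K.B_0] = b["diff_m_base"]
    prm[K.B_I] = b["diff_m_irid"]
    prm[K.B_X] = b["diff_m_xan"]
    prm[K.B_LOC] = b["diff_m_loose"]
    prm[K.R_DIFF_XB] = params.diff_xb_rate
    prm[K.R_DIFF_XB_SOLO] = params.diff_xb_solo_rate
    prm[K.R_DIFF_XB_AUTO] = params.diff_xb_auto_rate
    prm[K.K_DIFF_PER_ID] = params.diff_m_per_id
    prm[K.K_DIFF_PER_X] = params.diff_m_per_x
    prm[K.R_DIFF_SOLO] = params.diff_m_solo
    prm[K.R_DEATH_M] = params.death_m_rate
    prm[K.R_D2L] = params.trans_d2l_rate
    prm[K.R_L2D] = params.trans_l2d_rate
    prm[K.R_GROW_H] = params.growth_h / params.pitch_m
    prm[K.R_GROW_V] = params.growth_v / params.pitch_m
    prm[K.BETA] = params.beta
    prm[K.S_M_FROM_X] = params.s_m_from_x
    prm[K.S_M_TO_XB] = params.s_m_to_xb
    prm[K.S_X_TO_M] = params.s_x_to_m
    prm[K.S_ID_TO_X] = params.s_id_to_x
    prm[K.S_IL_FROM_IL] = params.s_il_from_il
    prm[K.THETA_XL] = params.theta_xl
    prm[K.THETA_XS] = params.theta_xs
    prm[K.THETA_XB_ID] = params.theta_xb_id

    tog = np.zeros(K.N_TOG, dtype=np.int8)
    tog[K.T_HAS_M] = 1 if genotype.has("melanophore") else 0
    tog[K.T_H2] = 1 if "h2" in genotype.toggles else 0
    tog[K.T_H4] = 1 if "h4" in genotype.toggles else 0
    tog[K.T_D2L_NO_XLONG] = 1 if "d2l_no_xlong" in genotype.toggles else 0
    tog[K.T_D2L_NO_XSHORT] = 1 if "d2l_no_xshort" in genotype.toggles else 0
    tog[K.T_L2D_NO_MSHORT] = 1 if "l2d_no_mshort" in genotype.toggles else 0
    tog[K.T_L2D_NO_XSHORT] = 1 if "l2d_no_xshort" in genotype.toggles else 0
    return prm, tog


def _pack_parity(stencils, uvs):
    nmax = max(len(s) for s in stencils)
    offs = np.zeros((4, nmax, 2), dtype=np.int64)
    uv = np.zeros((4, nmax, 2), dtype=np.float64)
    lens = np.zeros(4, dtype=np.int64)
    for p in range(4):
        n = len(stencils[p])
        lens[p] = n
        offs[p, :n] = stencils[p]
        uv[p, :n] = uvs[p]
    return offs, lens, uv


def _kernel_stencils(st: Stencils):
    fc_s, fc_s_len, fc_s_uv = _pack_parity(st.fc["short"], st.fc_uv["short"])
    return dict(
        cc_s=st.cc["short"],
        cf_s=st.cf["short"], cf_s_uv=st.cf_uv["short"],
        cf_l=st.cf["long"], cf_l_uv=st.cf_uv["long"],
        fc_s=fc_s, fc_s_len=fc_s_len, fc_s_uv=fc_s_uv,
        ff_s=st.ff["short"], ff_s_uv=st.ff_uv["short"],
        ff_l=st.ff["long"],
    )


def _chunk_seed(seed: int, counter: int) -> int:
    return int((seed * 2654435761 + counter * 97531) % (2 ** 31 - 1))


def _grow_capacity(state: DomainState, extra_rows: int = 64,
                   extra_cols: int = 64) -> None:
    old_m, old_x, old_i = state.mgrid, state.xgrid, state.igrid
    cr = old_m.shape[0] + extra_rows
    cc = old_m.shape[1] + extra_cols
    state.mgrid = np.zeros((cr, cc), dtype=np.int8)
    state.xgrid = np.zeros((2 * cr, 2 * cc), dtype=np.int8)
    state.igrid = np.zeros((2 * cr, 2 * cc), dtype=np.int8)
    state.mgrid[:old_m.shape[0], :old_m.shape[1]] = old_m
    state.xgrid[:old_x.shape[0], :old_x.shape[1]] = old_x
    state.igrid[:old_i.shape[0], :old_i.shape[1]] = old_i


class _Runner:
    """Drives the kernel for one state; owns the chunk-seed counter."""

    def __init__(self, state: DomainState, params: Params, genotype: Genotype,
                 seed: int):
        self.state = state
        self.params = params
        self.genotype = genotype
        self.seed = seed
        self.counter = 0
        self.prm, self.tog = _kernel_params(params, genotype)
        self.sten = _kernel_stencils(stencils_for(params))
        self.ev_att = np.zeros(K.N_EVENTS, dtype=np.int64)
        self.ev_fire = np.zeros(K.N_EVENTS, dtype=np.int64)

    def advance(self, stop_sl: Optional[float] = None,
                stop_t: Optional[float] = None) -> str:
        """Run until the domain length implies SL >= stop_sl, or t >= stop_t."""
        s = self.state
        p = self.params
        if stop_sl is None:
            stop_cols = np.iinfo(np.int64).max
        else:
            stop_cols = int(math.ceil(p.length_at_sl(stop_sl) / p.pitch_m - 1e-9))
        stop_time = np.inf if stop_t is None else float(stop_t)
        dims = np.array([s.rows, s.cols], dtype=np.int64)
        cts = s.counts()
        counts = np.array([cts[CellKind.M], cts[CellKind.X], cts[CellKind.XB],
                           cts[CellKind.ID], cts[CellKind.IL]], dtype=np.int64)
        tvec = np.array([s.t], dtype=np.float64)
        while True:
            self.counter += 1
            status = K.run_chunk(
                s.mgrid, s.xgrid, s.igrid, dims, counts, tvec,
                self.prm, self.tog, **self.sten,
                stop_cols=stop_cols, stop_t=stop_time,
                max_events=200_000_000,
                seed=_chunk_seed(self.seed, self.counter),
                ev_att=self.ev_att, ev_fire=self.ev_fire)
            s.rows, s.cols = int(dims[0]), int(dims[1])
            s.t = float(tvec[0])
            if status == K.ST_CAPACITY:
                _grow_capacity(s)
                continue
            if status == K.ST_MAX_EVENTS:
                continue
            if status == K.ST_STOP_LEN:
                return "length"
            if status == K.ST_STOP_T:
                return "time"
            return "stalled"


def _bootstrap_x0(state: DomainState, params: Params,
                  rng: np.random.Generator) -> None:
    """t=0 fixed event: the first adult xanthophores differentiate over the
    initial dense S-iridophore band (the X0 interstripe)."""
    from scipy.signal import convolve2d
    if params.xb_bootstrap_frac <= 0:
        return
    xb = state.x == CellKind.XB
    if not xb.any() or not (state.i == CellKind.ID).any():
        state.fixed_events_done.add("x0-bootstrap")
        return
    sten = stencils_for(params).ff["short"]
    kr = sten[:, 0].max() - sten[:, 0].min() + 1
    kc = sten[:, 1].max() - sten[:, 1].min() + 1
    kern = np.zeros((kr, kc))
    kern[sten[:, 0] - sten[:, 0].min(), sten[:, 1] - sten[:, 1].min()] = 1.0
    idn = convolve2d((state.i == CellKind.ID).astype(float), kern[::-1, ::-1],
                     mode="same")
    hot = xb & (np.rint(idn) >= params.theta_xb_id)
    hot &= rng.random(hot.shape) < params.xb_bootstrap_frac
    state.x[hot] = CellKind.X
    state.fixed_events_done.add("x0-bootstrap")


def _myoseptum_x_band(state: DomainState, params: Params,
                      rng: np.random.Generator) -> None:
    """Stage-PR fixed event: the first adult xanthophores differentiate from
    xanthoblasts along the horizontal myoseptum, initiating interstripe X0.
    (Driven by the myoseptum itself, so it occurs with or without the dense
    S-iridophore band — real shd fish still form a central X0.)"""
    half = max(1, int(round(0.05 / params.pitch_f)))
    mid = state.x.shape[0] // 2
    band = state.x[mid - half: mid + half, :]
    hot = (band == CellKind.XB) & (rng.random(band.shape) < 0.8)
    band[hot] = CellKind.X


def _apply_fixed_event(state: DomainState, event: dict,
                       rng: np.random.Generator) -> None:
    action = event["action"]
    if action == "myoseptum_x_band":
        _myoseptum_x_band(state, state.params, rng)
    elif action == "seed_loose_iridophores":
        n = int(event["count"])
        empty = np.argwhere(state.i == 0)
        if len(empty):
            take = rng.choice(len(empty), size=min(n, len(empty)),
                              replace=False)
            for i, j in empty[take]:
                state.i[i, j] = CellKind.IL
    else:
        raise ValueError(f"unknown fixed event action {action!r}")


def run_simulation(genotype="WT", seed: int = 0, params: Optional[Params] = None,
                   end_sl: Optional[float] = None,
                   checkpoint_stages: Sequence[str] = ("PR", "SP", "SA", "J"),
                   extra_days: float = 0.0) -> Trajectory:
    """Simulate one fish from stage PB until the simulated SL reaches
    ``end_sl`` (default: the parameter set's 13.5 mm).

    Identical ``(params, genotype, seed)`` give a bit-identical trajectory.
    Snapshots are recorded at each requested stage boundary and at the end.
    """
    geno = make_genotype(genotype)
    params = geno.apply_params(params or Params())
    end_sl = params.end_sl if end_sl is None else end_sl
    state = init_state(params, geno, seed=seed, extra_days=extra_days)
    _bootstrap_x0(state, params, np.random.default_rng(_chunk_seed(seed, 555)))
    traj = Trajectory(genotype=geno.name, seed=seed, params=params)
    runner = _Runner(state, params, geno, seed)
    fe_rng = np.random.default_rng(_chunk_seed(seed, 999_983))

    pending = []
    if geno.has("xanthophore") and geno.initializer is None:
        pending.append((params.stage_threshold("PR"),
                        {"label": "myoseptum-x0", "action": "myoseptum_x_band"}))
    for ev in geno.fixed_events:
        d = dict(ev)
        pending.append((params.stage_threshold(d["stage"]), d))
    stops = sorted({params.stage_threshold(st) for st in checkpoint_stages
                    if params.stage_threshold(st) < end_sl}
                   | {sl for sl, _ in pending if sl < end_sl}
                   | {end_sl})

    for stop_sl in stops:
        if simulated_SL(state) < stop_sl:
            res = runner.advance(stop_sl=stop_sl)
            if res == "stalled" and not any(sl <= stop_sl and d["label"]
                                            not in state.fixed_events_done
                                            for sl, d in pending):
                traj.status = "stalled"
                break
        sl_now = simulated_SL(state)
        for sl, d in pending:
            if sl <= sl_now and d["label"] not in state.fixed_events_done:
                _apply_fixed_event(state, d, fe_rng)
                state.fixed_events_done.add(d["label"])
        for st_name in checkpoint_stages:
            if (abs(params.stage_threshold(st_name) - stop_sl) < 1e-9
                    and sl_now >= stop_sl):
                traj.checkpoints.append((st_name, state.t, sl_now,
                                         state.copy()))
    if traj.status == "completed" and extra_days > 0:
        runner.advance(stop_t=state.t + extra_days)
    traj.final_state = state
    traj.event_attempts = dict(zip(K.EVENT_LABELS, runner.ev_att.tolist()))
    traj.event_firings = dict(zip(K.EVENT_LABELS, runner.ev_fire.tolist()))
    return traj


def continue_simulation(state: DomainState, days: float, genotype="WT",
                        seed: int = 0,
                        params: Optional[Params] = None) -> DomainState:
    """Resume a (possibly surgically altered) state for a further ``days``
    days of events — used by the regeneration experiments.  Growth and all
    cellular events continue as normal."""
    geno = make_genotype(genotype)
    params = geno.apply_params(params or state.params)
    runner = _Runner(state, params, geno, seed + 77_000)
    runner.advance(stop_t=state.t + days)
    return state
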