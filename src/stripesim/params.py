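"""Model parameters.

All rates are per day, all lengths in mm.  A single :class:`Params` instance
is the sole source of every rate, radius, threshold and density used by the
simulator; the robustness sweep perturbs exactly the fields listed in
:data:`RATE_FIELDS`.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: fields that are kinetic rates/speeds/strengths and take part in the
#: robustness perturbation sweep (structural constants — pitches, radii,
#: densities, thresholds — are never perturbed).
RATE_FIELDS = (
    "speed_m",
    "speed_x",
    "speed_i",
    "prolif_xb",
    "prolif_x",
    "prolif_id",
    "prolif_il",
    "diff_xb_rate",
    "diff_xb_solo_rate",
    "diff_xb_auto_rate",
    "death_m_rate",
    "trans_d2l_rate",
    "trans_l2d_rate",
    "growth_h",
    "growth_v",
    "diff_m_base",
    "diff_m_irid",
    "diff_m_xan",
    "diff_m_loose",
    "diff_m_per_id",
    "diff_m_per_x",
    "diff_m_solo",
    "beta",
    "s_x_to_m",
    "s_m_from_x",
    "s_id_to_x",
    "s_il_from_il",
    "s_m_to_xb",
)

#: developmental stages and the standard-length (mm) threshold at which each
#: begins.  PB is the initial stage, J+ ends the simulated window.
DEFAULT_STAGES = (
    ("PB", 7.6),
    ("PR", 8.6),
    ("SP", 9.8),
    ("SA", 10.6),
    ("J", 11.5),
    ("Jplus", 13.5),
)


@dataclass
class Params:
    # --- lattice geometry -------------------------------------------------
    pitch_m: float = 0.02          # melanophore site edge (mm)
    short_radius: float = 0.04     # short-range disk radius (mm)
    long_inner: float = 0.22       # long-range annulus, inner radius (mm)
    long_outer: float = 0.24       # long-range annulus, outer radius (mm)

    # --- initial conditions ----------------------------------------------
    init_length: float = 2.0       # mm
    init_height: float = 1.0       # mm
    init_m_density: float = 0.04   # melanophores per M-layer site
    init_xb_density: float = 0.4   # xanthoblasts per X-layer site

    # --- staging ----------------------------------------------------------
    sl0: float = 7.6               # simulated SL at t = 0 (mm)
    end_sl: float = 13.5           # end-of-run SL (mm)
    metamorphosis_days: float = 20.0   # nominal PB -> J+ duration (days)
    sl_mapping: str = "affine"     # "affine" (default) or "proportional"
    dpf_offset: float = 25.0       # days post fertilisation at t = 0
    stages: tuple = DEFAULT_STAGES

    # --- movement (speeds in mm/day; converted to step rates by pitch) ----
    speed_m: float = 0.11
    speed_x: float = 0.033
    speed_i: float = 0.1           # both dense and loose S-iridophores

    # --- proliferation (per agent per day) --------------------------------
    prolif_xb: float = 0.5
    prolif_x: float = 0.5
    prolif_id: float = 1.8
    prolif_il: float = 1.5

    # --- differentiation and death ----------------------------------------
    diff_xb_rate: float = 0.5      # Xb -> X over dense sheets in reach of X
    diff_xb_solo_rate: float = 0.001   # isolated seeding over dense sheets
    diff_xb_auto_rate: float = 0.016   # autonomous rate, iridophore-free fish
    xb_bootstrap_frac: float = 0.8     # Xb over the initial band that
                                       # differentiate at the t=0 fixed event
    death_m_rate: float = 1.0      # death attempt rate per M per day
    # melanophore differentiation.  The overall attempt rate scales with the
    # domain totals of dense S-iridophores and xanthophores (plus a
    # spontaneous per-site term that acts only when no other pigment cells
    # exist on the domain); dimensionless signal weights then decide where
    # attempts succeed, w_I >> w_loc > w_X > w_0:
    diff_m_per_id: float = 0.12    # attempts/day per dense S-iridophore
    diff_m_per_x: float = 0.5      # attempts/day per xanthophore
    diff_m_solo: float = 0.15      # per empty site/day, no-signal regime
    diff_m_base: float = 0.05      # weight w_0 (baseline)
    diff_m_irid: float = 10.0      # weight w_I (dense S-iridophores, long range)
    diff_m_xan: float = 0.3        # weight w_X (xanthophores, long range)
    diff_m_loose: float = 3.0      # weight w_loc (loose S-iridophores, short)

    # --- S-iridophore shape transitions (attempt rate per agent per day) --
    trans_d2l_rate: float = 1.0
    trans_l2d_rate: float = 1.0

    # --- shape-transition / differentiation thresholds (counts) -----------
    theta_xl: int = 5              # "many xanthophores in the long range"
    theta_xs: int = 2              # "many xanthophores in the short range"
    theta_xb_id: int = 8           # dense S-iridophores needed near an Xb for
                                   # the fast differentiation path

    # --- domain growth (mm/day) -------------------------------------------
    growth_h: float = 0.13
    growth_v: float = 0.033

    # --- movement bias -----------------------------------------------------
    beta: float = 3.0              # sharpness of the directional bias
    s_x_to_m: float = 1.0          # X attracted to M (short range)
    s_m_from_x: float = -1.0       # M repelled by X (short range)
    s_id_to_x: float = 1.0         # Id attracted to X (short range)
    s_il_from_il: float = -1.0     # Il repelled by Il (short range)
    s_m_to_xb: float = 2.5         # M attracted to Xb (long-range annulus)

    def __post_init__(self) -> None:
        if not (0 < self.short_radius < self.long_inner < self.long_outer):
            raise ValueError("require 0 < short_radius < long_inner < long_outer")
        if self.diff_m_irid <= self.diff_m_xan:
            raise ValueError("iridophore differentiation signal must exceed "
                             "the xanthophore signal (w_I > w_X)")
        for name in ("init_m_density", "init_xb_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sl_mapping not in ("affine", "proportional"):
            raise ValueError(f"unknown sl_mapping {self.sl_mapping!r}")

    # --- derived geometry ---------------------------------------------------
    @property
    def pitch_f(self) -> float:
        """Pitch of the fine (X and I) layers: half the melanophore pitch."""
        return self.pitch_m / 2.0

    def simulated_sl(self, length_mm: float) -> float:
        """Map current domain length to a simulated standard length.

        The affine default is anchored so that SL runs from ``sl0`` to
        ``end_sl`` over ``metamorphosis_days`` of horizontal growth at
        ``growth_h`` mm/day, which reproduces the observed mean SL growth of
        real fish (~0.295 mm/day).  The proportional variant scales SL with
        relative domain length.
        """
        if self.sl_mapping == "proportional":
            return self.sl0 * length_mm / self.init_length
        slope = (self.end_sl - self.sl0) / (self.growth_h * self.metamorphosis_days)
        return self.sl0 + slope * (length_mm - self.init_length)

    def length_at_sl(self, sl: float) -> float:
        """Inverse of :meth:`simulated_sl`."""
        if self.sl_mapping == "proportional":
            return sl * self.init_length / self.sl0
        slope = (self.end_sl - self.sl0) / (self.growth_h * self.metamorphosis_days)
        return self.init_length + (sl - self.sl0) / slope

    def stage_threshold(self, name: str) -> float:
        for label, thr in self.stages:
            if label == name:
                return thr
        raise KeyError(name)

    def replace(self, **kw) -> "Params":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = [list(s) for s in self.stages]
        return d


def perturb_parameters(params: Params, rng: np.random.Generator,
                       lo: float = 0.75, hi: float = 1.25) -> Params:
    """Independently rescale every rate-class parameter by U(lo, hi).

    Structural constants (pitches, radii, densities, count thresholds,
    staging) are untouched.  The same ``rng`` state yields the same
    perturbation.
    """
    if not lo < hi:
        if lo == hi:
            return params.replace(**{f: getattr(params, f) * lo for f in RATE_FIELDS})
        raise ValueError("require lo <= hi")
    factors = {f: getattr(params, f) * rng.uniform(lo, hi) for f in RATE_FIELDS}
    return params.replace(**factors)
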