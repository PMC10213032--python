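"""Growth-law parameters for the lattice-free mycelium simulator.

Defaults are the values measured for *Podospora anserina* grown on
standard (M2) medium: apical dominance length 180 µm with base-2
exponential branching rate 10.4e-3 µm⁻¹ and subapical offset 41±11 µm;
lateral dominance 480 µm with a burst/uniform mixture (decay
2.3e-3 µm⁻¹, 22% uniform share, isolated rate 6e-3 µm⁻¹ per 90-min
window) and temporal rate 41e-3 min⁻¹; tip speed ramping from 0 to
4.5 µm min⁻¹ with 500 µm of cumulative germination growth at 7 h.

All exponential laws are base-2: a rate ``k`` means survival
``2^(-k x)``.  Internally the simulator works in micrometres and hours;
minute-denominated rates are converted at this boundary.

Branching-angle magnitudes are not among the measured values above: the
operating/exploratory/lateral angle defaults (70°/20°/90°, 10° jitter)
are calibration knobs chosen to reproduce a thallus growth rate
ω ≈ 0.5 h⁻¹, not measured quantities.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, asdict
from typing import Any

__all__ = [
    "ApicalBranchingParams",
    "LateralBranchingParams",
    "CurvatureParams",
    "GerminationParams",
    "GrowthConfig",
    "reference_config",
    "dense_lateral_config",
    "no_lateral_config",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class ApicalBranchingParams:
    """Subapical branching: latency L0 then a memoryless base-2 law."""

    L0_um: float = 180.0              # apical dominance length
    alpha_rate_per_um: float = 10.4e-3  # base-2 exponential rate beyond L0
    L_api_mean_um: float = 41.0       # subapical offset behind the tip
    L_api_sd_um: float = 11.0
    operating_angle_deg: float = 70.0   # calibration knob (widest daughter)
    exploratory_angle_deg: float = 20.0  # calibration knob (smallest daughter)
    p_opposite_curvature: float = 0.82  # operating branch opposite the bend

    def __post_init__(self) -> None:
        _require(self.L0_um > 0, "L0 must be positive")
        _require(self.alpha_rate_per_um > 0, "apical branching rate must be positive")
        _require(self.L_api_sd_um >= 0, "L_api sd must be nonnegative")
        _require(0.0 <= self.p_opposite_curvature <= 1.0,
                 "p_opposite_curvature must be a probability")


@dataclass
class LateralBranchingParams:
    """Lateral branching: 480 µm dominance, burst + uniform superposition."""

    L_dominance_um: float = 480.0      # no laterals closer to the apex
    temporal_rate_per_min: float = 41e-3  # base-2 inter-event rate
    gamma1_per_um: float = 2.3e-3      # base-2 burst spacing decay
    uniform_fraction: float = 0.22     # isolated (uniformly seeded) share
    p_isolated_per_um: float = 6e-3    # per µm per aging window
    aging_window_min: float = 90.0     # activity window of new regions
    lateral_angle_deg: float = 90.0    # calibration knob
    p_opposite_curvature: float = 0.72
    rate_multiplier: float = 1.0       # variant knob ("many laterals")

    def __post_init__(self) -> None:
        _require(self.L_dominance_um > 0, "lateral dominance must be positive")
        _require(self.temporal_rate_per_min > 0, "temporal rate must be positive")
        _require(self.gamma1_per_um > 0, "gamma1 must be positive")
        _require(0.0 <= self.uniform_fraction <= 1.0,
                 "uniform_fraction must be in [0, 1]")
        _require(self.p_isolated_per_um > 0, "isolated rate must be positive")
        _require(self.aging_window_min > 0, "aging window must be positive")
        _require(self.rate_multiplier >= 0, "rate multiplier must be nonnegative")


@dataclass
class CurvatureParams:
    """Per-step heading perturbation: density ∝ (θ0−θ)^a (θ+θ0)^b on (−θ0, θ0).

    With ``a == b`` the mean turn is zero (no chirality); ``a != b``
    breaks chirality.  One turn is applied per ``step_length_um`` of apex
    advance so curvature statistics do not depend on the integration step.
    The amplitude is fixed by normalization of the density.
    """

    theta0_rad: float = math.radians(40.0)  # calibrated to tortuosity ≈ 0.038
    a: float = 2.0
    b: float = 2.0
    step_length_um: float = 20.0

    def __post_init__(self) -> None:
        _require(self.theta0_rad > 0, "theta0 must be positive")
        _require(self.a > 0 and self.b > 0,
                 "shape exponents must be positive for a normalizable density")
        _require(self.step_length_um > 0, "step length must be positive")

    @property
    def mean_angle_rad(self) -> float:
        """Closed-form mean of the shifted-Beta turn angle."""
        return self.theta0_rad * (self.b - self.a) / (self.a + self.b + 2.0)


@dataclass
class GerminationParams:
    """Initial hyphae and the tip-velocity ramp.

    The ramp v(t) = v_asym (1 − 2^(−t/τ)) starts at zero, is monotone,
    saturates at ``v_asym`` and has τ calibrated so the cumulative length
    grown reaches ``ramp_length_um`` at ``ramp_time_h``.
    """

    n_initial_hyphae: int = 6
    spore_radius_um: float = 15.0   # germ tubes emerge from the spore boundary
    v_asym_um_per_min: float = 4.5
    ramp_length_um: float = 500.0
    ramp_time_h: float = 7.0

    def __post_init__(self) -> None:
        _require(self.n_initial_hyphae >= 1, "need at least one germination hypha")
        _require(self.v_asym_um_per_min > 0, "asymptotic velocity must be positive")
        _require(self.ramp_length_um > 0 and self.ramp_time_h > 0,
                 "ramp constraint must be positive")

    @property
    def v_asym_um_per_h(self) -> float:
        return self.v_asym_um_per_min * 60.0


def _curvature_defaults() -> dict:
    return {
        "exploratory": CurvatureParams(),
        "operating": CurvatureParams(),
        "lateral": CurvatureParams(),
    }


@dataclass
class GrowthConfig:
    """Full configuration of one simulated thallus."""

    apical: ApicalBranchingParams = field(default_factory=ApicalBranchingParams)
    lateral: LateralBranchingParams = field(default_factory=LateralBranchingParams)
    curvature: dict = field(default_factory=_curvature_defaults)
    germination: GerminationParams = field(default_factory=GerminationParams)
    dt_h: float = 0.1
    t_end_h: float = 15.0
    seed: int = 0
    snapshot_cadence_min: float = 18.0  # matches the experimental imaging cadence
    angle_jitter_deg: float = 10.0
    apical_enabled: bool = True
    lateral_enabled: bool = True

    def __post_init__(self) -> None:
        _require(self.dt_h > 0, "dt must be positive")
        _require(self.t_end_h > self.dt_h, "t_end must exceed dt")
        _require(self.snapshot_cadence_min > 0, "snapshot cadence must be positive")
        for k in ("exploratory", "operating", "lateral"):
            _require(k in self.curvature, f"missing curvature params for {k!r}")

    def curvature_for(self, branch_type: str) -> CurvatureParams:
        # germination hyphae propagate like exploratory ones
        if branch_type in ("germination", "apical"):
            branch_type = "exploratory"
        return self.curvature[branch_type]

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["curvature"] = {k: asdict(v) if dataclasses.is_dataclass(v) else dict(v)
                          for k, v in self.curvature.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GrowthConfig":
        d = dict(d)
        if "apical" in d:
            d["apical"] = ApicalBranchingParams(**d["apical"])
        if "lateral" in d:
            d["lateral"] = LateralBranchingParams(**d["lateral"])
        if "germination" in d:
            d["germination"] = GerminationParams(**d["germination"])
        if "curvature" in d:
            d["curvature"] = {k: CurvatureParams(**v) for k, v in d["curvature"].items()}
        return cls(**d)


def reference_config(seed: int = 0, t_end_h: float = 15.0, **kw) -> GrowthConfig:
    """M2-calibrated reference simulation."""
    return GrowthConfig(seed=seed, t_end_h=t_end_h, **kw)


def dense_lateral_config(seed: int = 0, t_end_h: float = 15.0, **kw) -> GrowthConfig:
    """Densifying variant: many lateral branches, 120° operating angle."""
    cfg = GrowthConfig(seed=seed, t_end_h=t_end_h, **kw)
    cfg.apical.operating_angle_deg = 120.0
    cfg.lateral.rate_multiplier = 5.0
    return cfg


def no_lateral_config(seed: int = 0, t_end_h: float = 15.0, **kw) -> GrowthConfig:
    """Exploring variant: no lateral branches, 10° exploratory angle."""
    cfg = GrowthConfig(seed=seed, t_end_h=t_end_h, **kw)
    cfg.apical.exploratory_angle_deg = 10.0
    cfg.lateral_enabled = False
    return cfg
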