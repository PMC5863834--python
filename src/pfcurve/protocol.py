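"""Boundary-condition sweep protocols.

Two sweeps produce the (flow, lesion pressure-drop) point sets the
curve fit consumes:

* patient mode — a fixed inlet pressure (88 mmHg) with the total distal
  microvascular resistance started at 240 mmHg.s/ml and reduced through
  87.5, 75, 62.5, 50, 37.5 and 25% of that rest level: seven steady
  solves per lesion.  The total resistance is split across outlets by a
  form-function (caliber-to-resistance) rule.
* idealized mode — a single vessel with zero outlet pressure and inlet
  pressure stepped from 0.5 to 11 mmHg in 0.5 mmHg increments: 22
  steady solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow_engine import (
    FluidProperties,
    FlowSolution,
    SegmentCoefficients,
    cumulative_viscous_coefficient,
    expansion_coefficient,
    mla_position,
    solve_single_vessel,
    solve_tree,
    viscous_coefficient,
)
from .geometry import AreaProfile, VesselTree

__all__ = [
    "SweepConfig",
    "SweepResult",
    "distribute_outlet_resistances",
    "run_patient_sweep",
    "run_idealized_sweep",
    "extract_lesion_drop",
    "lesion_drop_coefficients",
]

PATIENT_FRACTIONS = (100.0, 87.5, 75.0, 62.5, 50.0, 37.5, 25.0)


@dataclass(frozen=True)
class SweepConfig:
    """Boundary-condition sweep parameters.

    mode : "patient" or "idealized"
    p_in : inlet static pressure for patient mode, mmHg
    r_total_base : rest-level total distal microvascular resistance,
        mmHg.s/ml
    r_fractions : percentages of ``r_total_base`` applied in turn
    idealized_p_min/max/step : inlet-pressure ladder for idealized
        mode, mmHg, endpoints inclusive
    outlet_exponent : form-function exponent k; outlet resistances scale
        as (equivalent diameter)^-k up to the parallel-sum normalization
    p_ref : downstream reference pressure, mmHg
    """

    mode: str = "patient"
    p_in: float = 88.0
    r_total_base: float = 240.0
    r_fractions: tuple[float, ...] = PATIENT_FRACTIONS
    idealized_p_min: float = 0.5
    idealized_p_max: float = 11.0
    idealized_p_step: float = 0.5
    outlet_exponent: float = 2.6
    p_ref: float = 0.0
    reference_window_mm: float = 3.0

    def __post_init__(self):
        if self.mode not in ("patient", "idealized"):
            raise ValueError(f"unknown sweep mode {self.mode!r}")
        if any(not (0 < fr <= 100) for fr in self.r_fractions):
            raise ValueError("resistance fractions must lie in (0, 100]")
        if self.idealized_p_min > self.idealized_p_max or self.idealized_p_step <= 0:
            raise ValueError("idealized pressure ladder must be increasing")

    def pressure_ladder(self) -> np.ndarray:
        n = int(round((self.idealized_p_max - self.idealized_p_min) / self.idealized_p_step)) + 1
        return self.idealized_p_min + self.idealized_p_step * np.arange(n)


@dataclass
class SweepResult:
    """Lesion (Q, dp) points, one per boundary condition."""

    flow: np.ndarray           # ml/s
    drop: np.ndarray           # mmHg
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.flow = np.asarray(self.flow, dtype=float)
        self.drop = np.asarray(self.drop, dtype=float)
        if self.flow.shape != self.drop.shape:
            raise ValueError("flow and drop must have equal length")
        if np.any(self.flow < 0) or np.any(self.drop < 0):
            raise ValueError("flows and drops must be non-negative")

    def __len__(self) -> int:
        return self.flow.size

    def fractions(self) -> np.ndarray | None:
        """Resistance fractions per point (patient sweeps only)."""
        if all("fraction_percent" in p for p in self.provenance) and self.provenance:
            return np.array([p["fraction_percent"] for p in self.provenance])
        return None

    def to_dataframe(self) -> pd.DataFrame:
        cond = [p.get("condition", str(i)) for i, p in enumerate(self.provenance)] \
            if self.provenance else [str(i) for i in range(len(self))]
        return pd.DataFrame({"condition": cond, "Q_ml_s": self.flow, "dp_mmHg": self.drop})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        df = pd.read_csv(path)
        prov = []
        for cond in df["condition"].astype(str):
            p = {"condition": cond}
            if cond.endswith("%"):
                try:
                    p["fraction_percent"] = float(cond.rstrip("%"))
                except ValueError:
                    pass
            prov.append(p)
        return cls(flow=df["Q_ml_s"].to_numpy(float),
                   drop=df["dp_mmHg"].to_numpy(float), provenance=prov)


def distribute_outlet_resistances(
    outlet_areas: dict[str, float], r_total: float, k: float = 2.6
) -> dict[str, float]:
    """Split a total distal resistance across outlets by caliber.

    With equivalent diameters d_i = sqrt(4 A_i / pi), each outlet gets

        R_i = r_total * (sum_j d_j^k) / d_i^k

    so that the parallel combination of all R_i equals r_total exactly
    and conductance scales as d^k (form-function rule).
    """
    if not outlet_areas:
        raise ValueError("at least one outlet is required")
    if r_total <= 0 or any(a <= 0 for a in outlet_areas.values()):
        raise ValueError("areas and r_total must be positive")
    d = {o: np.sqrt(4.0 * a / np.pi) for o, a in outlet_areas.items()}
    total_w = sum(di ** k for di in d.values())
    return {o: r_total * total_w / (di ** k) for o, di in d.items()}


def lesion_drop_coefficients(
    profile: AreaProfile, fluid: FluidProperties, window_mm: float = 3.0
) -> SegmentCoefficients:
    """Loss coefficients restricted to the lesion window.

    The viscous part integrates only over [lesion_start, lesion_end];
    the expansion loss is lumped at the MLA location, which lies inside
    the window by construction.
    """
    cum_f = cumulative_viscous_coefficient(profile, fluid)
    f_lesion = float(
        np.interp(profile.lesion_end, profile.arclength, cum_f)
        - np.interp(profile.lesion_start, profile.arclength, cum_f)
    )
    s_lesion = expansion_coefficient(profile, fluid, window_mm=window_mm)
    return SegmentCoefficients(f=f_lesion, s=s_lesion)


def extract_lesion_drop(
    solution: FlowSolution,
    profile: AreaProfile,
    fluid: FluidProperties,
    segment_id: str | None = None,
    window_mm: float = 3.0,
) -> tuple[float, float]:
    """Lesion flow (ml/s) and pressure drop (mmHg) from one solve.

    The intra-segment pressure at arclength position x is the segment
    inlet pressure minus the accumulated viscous drop to x, with the
    expansion loss assigned at the MLA location; the lesion drop is the
    pressure difference between the start and end planes, which reduces
    to f_lesion Q + s Q^2 with the lesion-window coefficients.
    """
    if segment_id is None:
        if len(solution.segment_flow) != 1:
            raise ValueError("segment_id is required for multi-segment solutions")
        segment_id = next(iter(solution.segment_flow))
    q = solution.segment_flow[segment_id]
    coeffs = lesion_drop_coefficients(profile, fluid, window_mm=window_mm)
    return q, coeffs.drop(q)


def pressure_along_profile(
    profile: AreaProfile,
    fluid: FluidProperties,
    q: float,
    p_in: float,
    window_mm: float = 3.0,
) -> np.ndarray:
    """Intra-segment static pressure at every profile sample (mmHg)."""
    cum_f = cumulative_viscous_coefficient(profile, fluid)
    s_coef = expansion_coefficient(profile, fluid, window_mm=window_mm)
    p = p_in - cum_f * q
    p = p - s_coef * q * abs(q) * (profile.arclength >= mla_position(profile))
    return p


def run_patient_sweep(
    tree: VesselTree, fluid: FluidProperties, config: SweepConfig | None = None
) -> SweepResult:
    """Patient-mode sweep: one steady tree solve per resistance fraction.

    Fixed inlet pressure, total distal resistance r_total_base scaled by
    each configured fraction and distributed across outlets by the
    form-function rule; the default seven fractions yield seven points.
    """
    config = config or SweepConfig(mode="patient")
    if config.mode != "patient":
        raise ValueError("run_patient_sweep requires a patient-mode config")
    lesion_sid = tree.lesion_segment
    lesion_profile = tree.segments[lesion_sid].profile

    flows, drops, prov = [], [], []
    for frac in config.r_fractions:
        r_total = config.r_total_base * frac / 100.0
        resist = distribute_outlet_resistances(
            tree.outlet_areas, r_total, k=config.outlet_exponent
        )
        try:
            sol = solve_tree(
                tree, fluid, resist, p_in=config.p_in, p_ref=config.p_ref,
                window_mm=config.reference_window_mm,
            )
        except Exception as exc:
            raise RuntimeError(f"solve failed at resistance fraction {frac}%") from exc
        q, dp = extract_lesion_drop(
            sol, lesion_profile, fluid, segment_id=lesion_sid,
            window_mm=config.reference_window_mm,
        )
        flows.append(q)
        drops.append(dp)
        prov.append({
            "condition": f"{frac:g}%",
            "fraction_percent": frac,
            "r_total_mmHg_s_ml": r_total,
            "p_in_mmHg": config.p_in,
        })
    return SweepResult(flow=np.array(flows), drop=np.array(drops), provenance=prov)


def run_idealized_sweep(
    profile: AreaProfile, fluid: FluidProperties, config: SweepConfig | None = None
) -> SweepResult:
    """Idealized-mode sweep: zero outlet pressure, inlet pressure ladder.

    The default ladder 0.5 to 11 mmHg in 0.5 mmHg steps (inclusive)
    yields 22 points.
    """
    config = config or SweepConfig(mode="idealized")
    if config.mode != "idealized":
        raise ValueError("run_idealized_sweep requires an idealized-mode config")
    whole = SegmentCoefficients(
        f=viscous_coefficient(profile, fluid),
        s=expansion_coefficient(profile, fluid, window_mm=config.reference_window_mm),
    )
    lesion = lesion_drop_coefficients(profile, fluid, window_mm=config.reference_window_mm)

    flows, drops, prov = [], [], []
    for p_in in config.pressure_ladder():
        q = solve_single_vessel(whole, p_in=float(p_in), p_out=0.0)
        flows.append(q)
        drops.append(lesion.drop(q))
        prov.append({"condition": f"p_in={p_in:g}", "p_in_mmHg": float(p_in)})
    return SweepResult(flow=np.array(flows), drop=np.array(drops), provenance=prov)
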