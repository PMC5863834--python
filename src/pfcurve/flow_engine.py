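"""Reduced-order steady hemodynamics.

Each vessel segment obeys the quadratic pressure-flow law

    dp = f Q + s Q^2

with geometry-derived coefficients: ``f`` is the Poiseuille integral of
the area profile and ``s`` is a Young-Tsai-type expansion loss set by
the throat-to-reference area contrast.  Branched trees with lumped
terminal resistances are solved by damped Newton iteration on the
terminal flows.  The quadratic structure is what the downstream curve
fit estimates; no 3-D flow field is computed.

``kt`` (expansion-loss constant) and ``gamma_ecc`` (eccentricity loss
multiplier) are engine parameters of this package, not measured
quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import units
from .geometry import AreaProfile, VesselTree, minimal_lumen_area, reference_area

__all__ = [
    "FluidProperties",
    "SegmentCoefficients",
    "FlowSolution",
    "viscous_coefficient",
    "expansion_coefficient",
    "segment_coefficients",
    "solve_single_vessel",
    "solve_tree",
    "SolverError",
]


class SolverError(RuntimeError):
    """Raised when the network solve cannot produce a valid solution."""


@dataclass(frozen=True)
class FluidProperties:
    """Blood rheology plus the engine's loss-model parameters.

    viscosity : dynamic viscosity, cP (default 3.5)
    density : kg/m^3 (default 1050)
    kt : expansion-loss constant, dimensionless (default 1.52)
    gamma_ecc : eccentricity loss multiplier coefficient (default 0.25);
        the expansion loss is scaled by (1 + gamma_ecc * e_throat).
    """

    viscosity: float = 3.5
    density: float = 1050.0
    kt: float = 1.52
    gamma_ecc: float = 0.25

    def __post_init__(self):
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")
        if self.kt < 0 or self.gamma_ecc < 0:
            raise ValueError("kt and gamma_ecc must be non-negative")


@dataclass(frozen=True)
class SegmentCoefficients:
    """Viscous (f, mmHg.s/ml) and expansion-loss (s, mmHg.s^2/ml^2)
    coefficients of one segment."""

    f: float
    s: float

    def __post_init__(self):
        if self.f < 0 or self.s < 0:
            raise ValueError("loss coefficients must be non-negative")

    def drop(self, q: float) -> float:
        """Pressure drop (mmHg) at flow q (ml/s), odd in q."""
        return self.f * q + self.s * q * abs(q)


@dataclass
class FlowSolution:
    """Result of one steady network solve.

    segment_flow : ml/s per segment id
    node_pressure : mmHg at each segment's distal node, plus ``"inlet"``
    residual : max pressure-balance residual of the solve, mmHg
    """

    segment_flow: dict[str, float]
    node_pressure: dict[str, float]
    residual: float
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "segment_flow_ml_s": self.segment_flow,
            "node_pressure_mmHg": self.node_pressure,
            "residual_mmHg": self.residual,
            "meta": self.meta,
        }


def viscous_coefficient(profile: AreaProfile, fluid: FluidProperties) -> float:
    """Poiseuille viscous coefficient f (mmHg.s/ml) of a whole profile.

    f = integral of 8 pi mu / A(s)^2 ds, evaluated by composite
    trapezoidal quadrature on the profile samples.  For a uniform tube
    this reduces to 128 mu L / (pi D^4).
    """
    if np.any(profile.area <= 0):
        raise ValueError("areas must be positive for the viscous integral")
    mu = fluid.viscosity * units.CP_TO_PA_S
    s_m = profile.arclength * units.MM_TO_M
    a_m2 = profile.area * units.MM2_TO_M2
    integrand = 8.0 * np.pi * mu / a_m2 ** 2
    f_si = float(np.trapezoid(integrand, s_m))
    return units.linear_coeff_to_working(f_si)


def cumulative_viscous_coefficient(profile: AreaProfile, fluid: FluidProperties) -> np.ndarray:
    """Running viscous coefficient from the profile inlet to each sample."""
    from scipy.integrate import cumulative_trapezoid

    mu = fluid.viscosity * units.CP_TO_PA_S
    s_m = profile.arclength * units.MM_TO_M
    a_m2 = profile.area * units.MM2_TO_M2
    integrand = 8.0 * np.pi * mu / a_m2 ** 2
    cum = cumulative_trapezoid(integrand, s_m, initial=0.0)
    return cum / units.LINEAR_COEFF_SI_PER_WORKING


def expansion_coefficient(
    profile: AreaProfile, fluid: FluidProperties, window_mm: float = 3.0
) -> float:
    """Expansion-loss coefficient s (mmHg.s^2/ml^2).

    s = kt (1 + gamma_ecc e_throat) (rho/2) (1/A_min - 1/A_ref)^2

    where A_min is the minimal lumen area, A_ref the reference area and
    e_throat the eccentricity index at the MLA location.  Returns 0 when
    the profile has no area contrast (A_min >= A_ref).
    """
    a_min = minimal_lumen_area(profile)
    a_ref = reference_area(profile, window_mm=window_mm)
    if a_min >= a_ref * (1.0 - 1e-12):
        if a_min > a_ref * (1.0 + 1e-12):
            warnings.warn("minimal lumen area exceeds reference area; treating as no stenosis")
        return 0.0
    mask = profile.lesion_mask()
    idx_local = int(np.argmin(profile.area[mask]))
    e_throat = float(profile.eccentricity[mask][idx_local])
    rho = fluid.density
    a_min_m2 = a_min * units.MM2_TO_M2
    a_ref_m2 = a_ref * units.MM2_TO_M2
    s_si = fluid.kt * (1.0 + fluid.gamma_ecc * e_throat) * (rho / 2.0) * (
        1.0 / a_min_m2 - 1.0 / a_ref_m2
    ) ** 2
    return units.quadratic_coeff_to_working(s_si)


def segment_coefficients(
    profile: AreaProfile, fluid: FluidProperties, window_mm: float = 3.0
) -> SegmentCoefficients:
    """Both loss coefficients of one profile."""
    return SegmentCoefficients(
        f=viscous_coefficient(profile, fluid),
        s=expansion_coefficient(profile, fluid, window_mm=window_mm),
    )


def mla_position(profile: AreaProfile) -> float:
    """Arclength (mm) of the minimal lumen area within the lesion window."""
    mask = profile.lesion_mask()
    idx_local = int(np.argmin(profile.area[mask]))
    return float(profile.arclength[mask][idx_local])


def solve_single_vessel(coeffs: SegmentCoefficients, p_in: float, p_out: float) -> float:
    """Flow (ml/s) through one segment between fixed pressures.

    Solves s Q^2 + f Q = p_in - p_out for the non-negative root,
    Q = (-f + sqrt(f^2 + 4 s dp)) / (2 s), with the linear limit dp/f
    when s = 0.
    """
    dp = p_in - p_out
    if dp < 0:
        raise ValueError("p_in must be >= p_out")
    if dp == 0:
        return 0.0
    f, s = coeffs.f, coeffs.s
    if f == 0 and s == 0:
        raise SolverError("zero-loss segment with a positive pressure drop has unbounded flow")
    if s == 0:
        return dp / f
    return (-f + np.sqrt(f * f + 4.0 * s * dp)) / (2.0 * s)


def solve_tree(
    tree: VesselTree,
    fluid: FluidProperties,
    outlet_resistance: dict[str, float],
    p_in: float,
    p_ref: float = 0.0,
    tol: float = 1e-11,
    max_iter: int = 200,
    window_mm: float = 3.0,
) -> FlowSolution:
    """Steady solve of a vessel tree with lumped terminal resistances.

    Unknowns are the terminal flows; internal segment flows follow from
    conservation (children sum to parent).  Along every root-to-terminal
    path the balance

        p_in - sum_i (f_i Q_i + s_i Q_i |Q_i|) - R_t Q_t = p_ref

    must hold.  A damped Newton iteration (factor 0.5 on sign-changing
    steps, flows clipped non-negative) is initialized from the
    linearized (s = 0) resistor network.
    """
    if p_in <= p_ref:
        raise ValueError("p_in must exceed p_ref")
    terminals = tree.terminal_ids()
    missing = set(terminals) - set(outlet_resistance)
    if missing:
        raise ValueError(f"missing outlet resistances for {sorted(missing)}")
    if any(outlet_resistance[t] <= 0 for t in terminals):
        raise ValueError("outlet resistances must be positive")

    coeffs = {
        sid: segment_coefficients(seg.profile, fluid, window_mm=window_mm)
        for sid, seg in tree.segments.items()
    }
    paths = {t: tree.path_to_root(t) for t in terminals}
    seg_ids = list(tree.segments)
    n_t = len(terminals)
    dp_total = p_in - p_ref

    # membership[i, j] = 1 if segment seg_ids[i] lies on the path to terminal j
    membership = np.zeros((len(seg_ids), n_t))
    for j, t in enumerate(terminals):
        for sid in paths[t]:
            membership[seg_ids.index(sid), j] = 1.0

    f_vec = np.array([coeffs[sid].f for sid in seg_ids])
    s_vec = np.array([coeffs[sid].s for sid in seg_ids])
    r_vec = np.array([outlet_resistance[t] for t in terminals])

    def seg_flows(q_t: np.ndarray) -> np.ndarray:
        return membership @ q_t

    def residuals(q_t: np.ndarray) -> np.ndarray:
        q_seg = seg_flows(q_t)
        drop_seg = f_vec * q_seg + s_vec * q_seg * np.abs(q_seg)
        return dp_total - membership.T @ drop_seg - r_vec * q_t

    # linearized (s = 0) initialization: (F + diag R) q = dp_total
    shared_f = membership.T @ (f_vec[:, None] * membership)
    q = np.linalg.solve(shared_f + np.diag(r_vec), np.full(n_t, dp_total))
    q = np.clip(q, 0.0, None)

    res = residuals(q)
    for _ in range(max_iter):
        if np.max(np.abs(res)) < tol:
            break
        q_seg = seg_flows(q)
        dprime = f_vec + 2.0 * s_vec * np.abs(q_seg)
        jac = membership.T @ (dprime[:, None] * membership) + np.diag(r_vec)
        step = np.linalg.solve(jac, res)
        q_new = q + step
        if np.any(q_new < 0):
            q_new = np.clip(q + 0.5 * step, 0.0, None)
        res_new = residuals(q_new)
        if np.max(np.abs(res_new)) > np.max(np.abs(res)):
            q_new = q + 0.5 * step  # damp sign-changing / overshooting steps
            q_new = np.clip(q_new, 0.0, None)
            res_new = residuals(q_new)
        q, res = q_new, res_new
    else:
        raise SolverError(
            f"tree solve did not converge: max residual {np.max(np.abs(res)):.3e} mmHg"
        )

    q_seg = seg_flows(q)
    segment_flow = {sid: float(q_seg[i]) for i, sid in enumerate(seg_ids)}
    node_pressure = {"inlet": float(p_in)}
    for sid in seg_ids:
        path = tree.path_to_root(sid)
        p = p_in
        for pid in path:
            qp = segment_flow[pid]
            p -= coeffs[pid].f * qp + coeffs[pid].s * qp * abs(qp)
        node_pressure[sid] = float(p)

    return FlowSolution(
        segment_flow=segment_flow,
        node_pressure=node_pressure,
        residual=float(np.max(np.abs(residuals(q)))),
        meta={"p_in_mmHg": p_in, "p_ref_mmHg": p_ref},
    )
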