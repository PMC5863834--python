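"""Seeded synthetic lesion cohorts and a virtual-FFR fixture.

Real inputs to the method are lumen reconstructions from coronary CT
angiography; none ship with this package.  This module generates
idealized concentric/eccentric stenosis profiles with randomized
severity and caliber so the full pipeline — sweep, fit, indices,
correlation report — is exercisable and testable end to end.

The virtual FFR computed here is a test fixture: the distal-to-proximal
pressure ratio at the sweep's lowest-resistance condition, standing in
for hyperemia.  It is not a clinical FFR and is labeled "virtual" in
all outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortRecord
from .curvefit import PressureFlowModel
from .flow_engine import FluidProperties
from .geometry import (
    AreaProfile,
    IdealizedSpec,
    VesselTree,
    area_stenosis_percent,
    make_idealized_stenosis,
    minimal_lumen_area,
)
from .protocol import (
    SweepConfig,
    SweepResult,
    distribute_outlet_resistances,
    extract_lesion_drop,
    run_patient_sweep,
)
from .flow_engine import solve_tree

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "apply_drop_noise",
    "virtual_ffr",
    "evaluate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Sampling scheme for a synthetic lesion cohort.

    n : number of lesions
    seed : root seed; lesion i draws from the substream (seed, i) so
        cohorts are reproducible and per-lesion draws are independent
        of n
    as_range : AS% sampling interval, default [30, 95]
    shape_mix : probability a lesion is eccentric, default 0.5
    noise_sigma : multiplicative pressure-drop noise fraction applied
        after each solve (0 disables; 0.02 emulates the variability of
        a 3-D flow solve around the quadratic law)
    diameter_range : reference diameter interval, mm
    as_grid : optional explicit AS% sequence; when set, lesion i takes
        as_grid[i] deterministically (e.g. the idealized seven-model
        family 65..95) instead of sampling as_range
    """

    n: int = 40
    seed: int = 0
    as_range: tuple[float, float] = (30.0, 95.0)
    shape_mix: float = 0.5
    noise_sigma: float = 0.0
    diameter_range: tuple[float, float] = (2.5, 4.0)
    as_grid: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 <= self.as_range[0] <= self.as_range[1] < 100):
            raise ValueError("as_range must lie within [0, 100)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0 <= self.shape_mix <= 1):
            raise ValueError("shape_mix must be a probability")
        if self.as_grid is not None and len(self.as_grid) != self.n:
            raise ValueError("as_grid must provide one AS% per lesion")


def generate_cohort(spec: CohortSpec) -> list[tuple[AreaProfile, dict]]:
    """Draw ``spec.n`` idealized stenosis profiles.

    AS% uniform over ``as_range``, shape Bernoulli(``shape_mix``)
    eccentric, reference diameter uniform over ``diameter_range``.
    Fully reproducible from the seed; each profile's metadata records
    the generating parameters.
    """
    out = []
    for i in range(spec.n):
        rng = np.random.default_rng([spec.seed, i])
        as_pct = float(rng.uniform(*spec.as_range))
        if spec.as_grid is not None:
            as_pct = float(spec.as_grid[i])
        if spec.shape_mix == 0.0:
            shape = "concentric"
        elif spec.shape_mix == 1.0:
            shape = "eccentric"
        else:
            shape = "eccentric" if rng.random() < spec.shape_mix else "concentric"
        diameter = float(rng.uniform(*spec.diameter_range))
        profile = make_idealized_stenosis(
            IdealizedSpec(shape=shape, as_percent=as_pct, ref_diameter=diameter)
        )
        meta = dict(profile.meta)
        meta.update({"lesion_id": f"L{i:03d}", "seed": spec.seed, "index": i,
                     "noise_sigma": spec.noise_sigma})
        out.append((profile, meta))
    return out


def apply_drop_noise(sweep: SweepResult, sigma: float, rng: np.random.Generator) -> SweepResult:
    """Multiplicative Gaussian noise on the pressure drops.

    Each drop is scaled by (1 + eps) with eps ~ N(0, sigma) truncated
    at +/- 3 sigma, emulating departures of a full 3-D flow solve from
    the quadratic law.  Flows are left untouched.
    """
    if sigma == 0:
        return sweep
    eps = np.clip(rng.normal(0.0, sigma, size=len(sweep)), -3 * sigma, 3 * sigma)
    return SweepResult(flow=sweep.flow, drop=sweep.drop * (1.0 + eps),
                       provenance=sweep.provenance)


def virtual_ffr(
    model: AreaProfile | VesselTree,
    fluid: FluidProperties | None = None,
    config: SweepConfig | None = None,
) -> float:
    """Virtual FFR fixture: (p_in - lesion drop) / p_in at the lowest
    configured resistance fraction (default 25% of 240 mmHg.s/ml)."""
    fluid = fluid or FluidProperties()
    config = config or SweepConfig(mode="patient")
    if config.mode != "patient":
        raise ValueError("virtual FFR requires a patient-mode config")
    tree = model if isinstance(model, VesselTree) else VesselTree.single_vessel(model)
    frac = min(config.r_fractions)
    r_total = config.r_total_base * frac / 100.0
    resist = distribute_outlet_resistances(tree.outlet_areas, r_total,
                                           k=config.outlet_exponent)
    sol = solve_tree(tree, fluid, resist, p_in=config.p_in, p_ref=config.p_ref,
                     window_mm=config.reference_window_mm)
    lesion_sid = tree.lesion_segment
    _, dp = extract_lesion_drop(sol, tree.segments[lesion_sid].profile, fluid,
                                segment_id=lesion_sid,
                                window_mm=config.reference_window_mm)
    return (config.p_in - dp) / config.p_in


def evaluate_cohort(
    spec: CohortSpec,
    fluid: FluidProperties | None = None,
    config: SweepConfig | None = None,
    with_ffr: bool = True,
) -> list[CohortRecord]:
    """Run the full pipeline over a synthetic cohort.

    For each generated lesion: patient-mode sweep, optional drop noise,
    curve fit, indices and virtual FFR, collected as cohort records.
    """
    fluid = fluid or FluidProperties()
    config = config or SweepConfig(mode="patient")
    records = []
    for profile, meta in generate_cohort(spec):
        tree = VesselTree.single_vessel(profile)
        sweep = run_patient_sweep(tree, fluid, config)
        if spec.noise_sigma > 0:
            rng = np.random.default_rng([spec.seed, meta["index"], 7919])
            sweep = apply_drop_noise(sweep, spec.noise_sigma, rng)
        res = PressureFlowModel.from_sweep(sweep).fit()
        ar = res.areas
        records.append(CohortRecord(
            id=meta["lesion_id"],
            as_percent=area_stenosis_percent(profile,
                                             window_mm=config.reference_window_mm),
            mla=minimal_lumen_area(profile),
            f=res.f, s=res.s, s1=ar.s1, s2=ar.s2,
            ffr=virtual_ffr(profile, fluid, config) if with_ffr else None,
        ))
    return records
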