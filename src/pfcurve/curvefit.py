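"""Pressure-flow curve estimation and the derived resistance indices.

The lesion model is

    dp = f Q + s Q^2,   f, s >= 0

which is linear in (f, s): the least-squares problem through the origin
is solved exactly by non-negative linear least squares.  An iterative
nonlinear-regression mode is provided for parity and must agree with
the direct solution to high precision.

The integral indices

    S(q) = (f/2) q^2 + (s/3) q^3

evaluated at q = 1 and 2 ml/s (S1, S2) summarize the curve's steepness,
i.e. the lesion's flow resistance over the physiological flow range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import SweepResult

__all__ = [
    "PressureFlowModel",
    "PressureFlowResults",
    "PressureFlowCurve",
    "CurveAreas",
    "fit_pressure_flow",
    "predict_drop",
    "curve_area",
    "curve_areas",
    "subset_rmse",
    "SUBSET_FRACTIONS",
    "InsufficientDataError",
]

# Resistance-fraction selections for the reduced-simulation-count
# analysis, keyed by the number of steady solves retained.
SUBSET_FRACTIONS: dict[int, tuple[float, ...]] = {
    7: (100.0, 87.5, 75.0, 62.5, 50.0, 37.5, 25.0),
    4: (100.0, 75.0, 50.0, 25.0),
    3: (100.0, 62.5, 25.0),
    2: (100.0, 25.0),
}


class InsufficientDataError(ValueError):
    """Raised when the point set cannot identify the two coefficients."""


@dataclass(frozen=True)
class PressureFlowCurve:
    """Fitted pressure-flow curve: coefficients plus fit diagnostics."""

    f: float                 # viscous coefficient, mmHg.s/ml
    s: float                 # expansion coefficient, mmHg.s^2/ml^2
    n_points: int
    rmse: float              # mmHg, on the fitted points

    def __post_init__(self):
        if self.f < 0 or self.s < 0 or self.rmse < 0:
            raise ValueError("f, s and rmse must be non-negative")
        if self.n_points < 2:
            raise ValueError("a curve requires at least two points")


@dataclass(frozen=True)
class CurveAreas:
    """Areas under the pressure-flow curve up to 1 and 2 ml/s."""

    s1: float  # mmHg.ml/s
    s2: float

    def __post_init__(self):
        if not (0 <= self.s1 <= self.s2):
            raise ValueError("curve areas must satisfy 0 <= s1 <= s2")


def _validate_points(q: np.ndarray, dp: np.ndarray) -> None:
    if q.size < 2:
        raise InsufficientDataError("at least two points are required")
    positive = q[q > 0]
    if positive.size == 0:
        raise InsufficientDataError("all flows are zero")
    if np.unique(q).size < 2:
        raise InsufficientDataError("all flows are identical")


class PressureFlowModel:
    """Quadratic pressure-flow model for one lesion.

    Parameters
    ----------
    flow : array, ml/s
        Mean trans-lesion flow per boundary condition.
    drop : array, mmHg
        Mean lesion pressure drop per boundary condition.
    provenance : list of dict, optional
        Boundary-condition labels per point (carried from a sweep).

    Examples
    --------
    >>> model = PressureFlowModel([0.5, 1.0, 2.0], [0.8, 2.0, 5.6])
    >>> res = model.fit()
    >>> round(res.f, 6), round(res.s, 6)
    (1.2, 0.8)
    """

    def __init__(self, flow, drop, provenance: list[dict] | None = None):
        self.flow = np.asarray(flow, dtype=float)
        self.drop = np.asarray(drop, dtype=float)
        if self.flow.shape != self.drop.shape or self.flow.ndim != 1:
            raise ValueError("flow and drop must be equal-length 1-D arrays")
        self.provenance = provenance or []

    @classmethod
    def from_sweep(cls, sweep: SweepResult) -> "PressureFlowModel":
        return cls(sweep.flow, sweep.drop, provenance=sweep.provenance)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, flow_col: str = "Q_ml_s", drop_col: str = "dp_mmHg"
    ) -> "PressureFlowModel":
        return cls(df[flow_col].to_numpy(float), df[drop_col].to_numpy(float))

    def fit(self, method: str = "nnls") -> "PressureFlowResults":
        """Estimate (f, s) by least squares with f, s >= 0.

        method "nnls" uses the exact non-negative linear least-squares
        solution; "iterative" uses bounded nonlinear least squares and
        exists for parity with iterative estimation practice.
        """
        _validate_points(self.flow, self.drop)
        design = np.column_stack([self.flow, self.flow ** 2])
        if method == "nnls":
            from scipy.optimize import nnls
            params, _ = nnls(design, self.drop)
        elif method == "iterative":
            from scipy.optimize import least_squares
            from scipy.optimize import nnls
            x0, _ = nnls(design, self.drop)  # start from the direct solution
            sol = least_squares(
                lambda p: design @ p - self.drop,
                x0=np.clip(x0, 1e-12, None),
                bounds=(0.0, np.inf),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
            params = sol.x
        else:
            raise ValueError(f"unknown fit method {method!r}")
        f, s = float(params[0]), float(params[1])
        resid = self.drop - design @ params
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        curve = PressureFlowCurve(f=f, s=s, n_points=self.flow.size, rmse=rmse)
        return PressureFlowResults(self, curve, method=method)


class PressureFlowResults:
    """Fit results: coefficients, indices, diagnostics, plotting."""

    def __init__(self, model: PressureFlowModel, curve: PressureFlowCurve, method: str):
        self.model = model
        self.curve = curve
        self.method = method

    @property
    def f(self) -> float:
        return self.curve.f

    @property
    def s(self) -> float:
        return self.curve.s

    @property
    def rmse(self) -> float:
        return self.curve.rmse

    @property
    def n_points(self) -> int:
        return self.curve.n_points

    @property
    def areas(self) -> CurveAreas:
        return curve_areas(self.curve)

    def predict(self, q) -> np.ndarray | float:
        """Predicted lesion pressure drop (mmHg) at flow q (ml/s)."""
        return predict_drop(self.curve, q)

    def to_dict(self) -> dict:
        ar = self.areas
        return {
            "f": self.f, "s": self.s, "n_points": self.n_points,
            "rmse": self.rmse, "s1": ar.s1, "s2": ar.s2,
        }

    def summary(self) -> str:
        ar = self.areas
        lines = [
            "Pressure-Flow Curve Fit",
            "=" * 47,
            f"{'points':<28}{self.n_points:>19d}",
            f"{'method':<28}{self.method:>19}",
            f"{'f (viscous) [mmHg.s/ml]':<28}{self.f:>19.6g}",
            f"{'s (expansion) [mmHg.s2/ml2]':<28}{self.s:>19.6g}",
            f"{'S1 (q=1) [mmHg.ml/s]':<28}{ar.s1:>19.6g}",
            f"{'S2 (q=2) [mmHg.ml/s]':<28}{ar.s2:>19.6g}",
            f"{'RMSE [mmHg]':<28}{self.rmse:>19.6g}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the fitted curve over the sweep points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.flow, self.model.drop, "o", label="simulated")
        qq = np.linspace(0, max(self.model.flow.max(), 1e-9) * 1.05, 200)
        ax.plot(qq, self.predict(qq), "-", label="fitted")
        ax.set_xlabel("mean flow rate $\\bar{Q}$ (ml/s)")
        ax.set_ylabel("mean pressure drop $\\Delta\\bar{p}$ (mmHg)")
        ax.legend()
        return ax


def fit_pressure_flow(points, method: str = "nnls") -> PressureFlowCurve:
    """Fit (f, s) from (flow, drop) pairs; functional form of
    :meth:`PressureFlowModel.fit`."""
    if isinstance(points, SweepResult):
        model = PressureFlowModel.from_sweep(points)
    else:
        arr = np.asarray(points, dtype=float)
        model = PressureFlowModel(arr[:, 0], arr[:, 1])
    return model.fit(method=method).curve


def predict_drop(curve: PressureFlowCurve, q) -> np.ndarray | float:
    """dp = f q + s q^2 for q >= 0."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("flow must be non-negative")
    out = curve.f * q + curve.s * q ** 2
    return float(out) if out.ndim == 0 else out


def curve_area(curve: PressureFlowCurve, q: float) -> float:
    """Area under the pressure-flow curve from 0 to q ml/s:
    S = (f/2) q^2 + (s/3) q^3, in mmHg.ml/s."""
    if q < 0:
        raise ValueError("flow must be non-negative")
    return curve.f / 2.0 * q ** 2 + curve.s / 3.0 * q ** 3


def curve_areas(curve: PressureFlowCurve) -> CurveAreas:
    """S1 and S2: the curve areas at q = 1 and 2 ml/s."""
    return CurveAreas(s1=curve_area(curve, 1.0), s2=curve_area(curve, 2.0))


def subset_rmse(sweep: SweepResult, subset: int, method: str = "nnls") -> float:
    """RMSE (mmHg) of a reduced-simulation-count fit.

    Fits the curve on the subset's resistance fractions only, then
    evaluates the RMSE of its predicted drops against all points of the
    full patient sweep.
    """
    if subset not in SUBSET_FRACTIONS:
        raise ValueError(f"subset must be one of {sorted(SUBSET_FRACTIONS)}")
    fracs = sweep.fractions()
    if fracs is None:
        raise ValueError("sweep points carry no resistance-fraction provenance")
    wanted = SUBSET_FRACTIONS[subset]
    mask = np.isin(fracs, wanted)
    if sorted(fracs[mask].tolist()) != sorted(wanted):
        missing = set(wanted) - set(fracs.tolist())
        raise ValueError(f"requested fractions absent from sweep: {sorted(missing)}")
    curve = PressureFlowModel(sweep.flow[mask], sweep.drop[mask]).fit(method=method).curve
    resid = sweep.drop - predict_drop(curve, sweep.flow)
    return float(np.sqrt(np.mean(resid ** 2)))
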