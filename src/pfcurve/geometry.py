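"""Stenosis geometries as centerline area profiles.

A vessel segment is represented by its lumen cross-sectional area as a
function of centerline arclength, together with a scalar eccentricity
index per sample (0 = concentric cross-section, 1 = fully eccentric)
and the arclength positions of the lesion's start and end planes.

Two sources of geometry are supported: idealized concentric/eccentric
stenosis models (a uniform reference tube with a tapered constriction),
and generic profiles loaded from CSV/JSON as produced by an external
lumen segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AreaProfile",
    "IdealizedSpec",
    "VesselSegment",
    "VesselTree",
    "make_idealized_stenosis",
    "minimal_lumen_area",
    "reference_area",
    "area_stenosis_percent",
    "load_profile",
    "save_profile",
    "load_tree",
    "save_tree",
]


class InvalidGeometryError(ValueError):
    """Raised when a profile or spec violates its invariants."""


@dataclass(frozen=True)
class AreaProfile:
    """Lumen area and eccentricity sampled along the centerline.

    Parameters
    ----------
    arclength : array, mm
        Strictly increasing sample positions.
    area : array, mm^2
        Lumen cross-sectional area at each sample; all positive.
    eccentricity : array, dimensionless in [0, 1]
        Cross-section eccentricity index at each sample.
    lesion_start, lesion_end : float, mm
        Arclength positions of the lesion's start and end planes.
    """

    arclength: np.ndarray
    area: np.ndarray
    eccentricity: np.ndarray
    lesion_start: float
    lesion_end: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        s = np.asarray(self.arclength, dtype=float)
        a = np.asarray(self.area, dtype=float)
        e = np.asarray(self.eccentricity, dtype=float)
        if not (s.shape == a.shape == e.shape) or s.ndim != 1 or s.size < 2:
            raise InvalidGeometryError("arclength/area/eccentricity must be equal-length 1-D arrays")
        if not np.all(np.diff(s) > 0):
            raise InvalidGeometryError("arclength must be strictly increasing")
        if not np.all(a > 0):
            raise InvalidGeometryError("all areas must be positive")
        if np.any(e < 0) or np.any(e > 1):
            raise InvalidGeometryError("eccentricity index must lie in [0, 1]")
        if not (s[0] <= self.lesion_start < self.lesion_end <= s[-1]):
            raise InvalidGeometryError("lesion bounds must satisfy start < end within the profile")
        object.__setattr__(self, "arclength", s)
        object.__setattr__(self, "area", a)
        object.__setattr__(self, "eccentricity", e)

    @property
    def length(self) -> float:
        return float(self.arclength[-1] - self.arclength[0])

    def lesion_mask(self) -> np.ndarray:
        return (self.arclength >= self.lesion_start) & (self.arclength <= self.lesion_end)

    def shifted(self, offset: float) -> "AreaProfile":
        """Translate all arclength coordinates by ``offset`` mm."""
        return replace(
            self,
            arclength=self.arclength + offset,
            lesion_start=self.lesion_start + offset,
            lesion_end=self.lesion_end + offset,
        )


@dataclass(frozen=True)
class IdealizedSpec:
    """Specification of an idealized concentric or eccentric stenosis.

    The reference vessel is a uniform tube of diameter ``ref_diameter``;
    the stricture is a uniform throat whose area realizes the requested
    area stenosis, with linear area tapers on both sides.
    """

    shape: str = "concentric"
    as_percent: float = 0.0
    ref_diameter: float = 3.0
    stricture_length_factor: float = 2.0
    taper_length: float | None = None
    proximal_length: float | None = None
    distal_length: float | None = None
    samples_per_section: int = 25

    def __post_init__(self):
        if self.shape not in ("concentric", "eccentric"):
            raise InvalidGeometryError(f"unknown stenosis shape {self.shape!r}")
        if not (0.0 <= self.as_percent < 100.0):
            raise InvalidGeometryError("as_percent must lie in [0, 100)")
        if self.ref_diameter <= 0 or self.stricture_length_factor <= 0:
            raise InvalidGeometryError("ref_diameter and stricture_length_factor must be positive")

    @property
    def taper(self) -> float:
        return self.ref_diameter / 2.0 if self.taper_length is None else self.taper_length

    @property
    def proximal(self) -> float:
        return 2.0 * self.ref_diameter if self.proximal_length is None else self.proximal_length

    @property
    def distal(self) -> float:
        return 2.0 * self.ref_diameter if self.distal_length is None else self.distal_length

    @property
    def reference_area(self) -> float:
        return np.pi * self.ref_diameter ** 2 / 4.0

    @property
    def throat_area(self) -> float:
        return self.reference_area * (1.0 - self.as_percent / 100.0)


def make_idealized_stenosis(spec: IdealizedSpec) -> AreaProfile:
    """Build the area profile of an idealized stenosis model.

    Sections, in order: uniform proximal tube, linear taper down to the
    throat, uniform throat of length ``stricture_length_factor`` reference
    diameters, linear taper back up, uniform distal tube.  Lesion bounds
    are the taper extremes.  Eccentricity is 0 everywhere for concentric
    models and 1 within the stricture (tapers included, ramped linearly)
    for eccentric models.
    """
    a0 = spec.reference_area
    a_min = spec.throat_area
    stricture = spec.stricture_length_factor * spec.ref_diameter
    n = max(int(spec.samples_per_section), 2)

    # section breakpoints along the arclength axis
    x0 = 0.0
    x1 = x0 + spec.proximal
    x2 = x1 + spec.taper
    x3 = x2 + stricture
    x4 = x3 + spec.taper
    x5 = x4 + spec.distal

    sections = [
        (np.linspace(x0, x1, n), np.full(n, a0)),
        (np.linspace(x1, x2, n), np.linspace(a0, a_min, n)),
        (np.linspace(x2, x3, 2 * n), np.full(2 * n, a_min)),
        (np.linspace(x3, x4, n), np.linspace(a_min, a0, n)),
        (np.linspace(x4, x5, n), np.full(n, a0)),
    ]
    s = np.concatenate([xs for xs, _ in sections])
    a = np.concatenate([ar for _, ar in sections])
    # drop duplicated breakpoints
    keep = np.concatenate([[True], np.diff(s) > 0])
    s, a = s[keep], a[keep]

    if spec.shape == "eccentric" and spec.as_percent > 0:
        ecc = np.interp(s, [x1, x2, x3, x4], [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)
    else:
        ecc = np.zeros_like(s)

    return AreaProfile(
        arclength=s,
        area=a,
        eccentricity=ecc,
        lesion_start=x1,
        lesion_end=x4,
        meta={
            "shape": spec.shape,
            "as_percent": spec.as_percent,
            "ref_diameter": spec.ref_diameter,
            "kind": "idealized",
        },
    )


def minimal_lumen_area(profile: AreaProfile) -> float:
    """Minimal lumen area (MLA, mm^2) within the lesion window."""
    mask = profile.lesion_mask()
    if not mask.any():
        raise InvalidGeometryError("lesion window contains no samples")
    return float(profile.area[mask].min())


def reference_area(profile: AreaProfile, window_mm: float = 3.0) -> float:
    """Reference lumen area: mean area over a window immediately proximal
    to the lesion start plane.

    The window is ``[lesion_start - window_mm, lesion_start]``, clipped to
    the profile; it must contain at least one sample.
    """
    lo = profile.lesion_start - window_mm
    mask = (profile.arclength >= lo) & (profile.arclength <= profile.lesion_start)
    if not mask.any():
        raise InvalidGeometryError("reference window proximal to the lesion is empty")
    return float(profile.area[mask].mean())


def area_stenosis_percent(profile: AreaProfile, window_mm: float = 3.0) -> float:
    """Area stenosis AS% = 100 x (1 - MLA / reference area), clipped to [0, 100]."""
    mla = minimal_lumen_area(profile)
    a_ref = reference_area(profile, window_mm=window_mm)
    return float(np.clip(100.0 * (1.0 - mla / a_ref), 0.0, 100.0))


# ---------------------------------------------------------------------------
# Vessel trees

@dataclass
class VesselSegment:
    """One segment of a vessel tree: an area profile plus connectivity."""

    id: str
    profile: AreaProfile
    parent: str | None = None


@dataclass
class VesselTree:
    """A rooted tree of vessel segments with terminal outlet areas.

    ``outlet_areas`` maps terminal segment ids to outlet areas (mm^2),
    the attachment points for lumped distal resistances.
    ``lesion_segment`` names the segment whose lesion the analysis
    targets; defaults to the root.
    """

    segments: dict[str, VesselSegment]
    outlet_areas: dict[str, float]
    lesion_segment: str | None = None

    def __post_init__(self):
        roots = [sid for sid, seg in self.segments.items() if seg.parent is None]
        if len(roots) != 1:
            raise InvalidGeometryError(f"tree must have exactly one root, found {len(roots)}")
        self._root = roots[0]
        for sid, seg in self.segments.items():
            if seg.parent is not None and seg.parent not in self.segments:
                raise InvalidGeometryError(f"segment {sid!r} has unknown parent {seg.parent!r}")
        # cycle check: every segment must reach the root
        for sid in self.segments:
            seen = set()
            cur = sid
            while cur is not None:
                if cur in seen:
                    raise InvalidGeometryError("connectivity contains a cycle")
                seen.add(cur)
                cur = self.segments[cur].parent
        terminals = set(self.terminal_ids())
        if set(self.outlet_areas) != terminals:
            raise InvalidGeometryError("outlet_areas must cover exactly the terminal segments")
        if any(a <= 0 for a in self.outlet_areas.values()):
            raise InvalidGeometryError("outlet areas must be positive")
        if self.lesion_segment is None:
            self.lesion_segment = self._root
        elif self.lesion_segment not in self.segments:
            raise InvalidGeometryError(f"unknown lesion segment {self.lesion_segment!r}")

    @property
    def root(self) -> str:
        return self._root

    def children(self, sid: str) -> list[str]:
        return [c for c, seg in self.segments.items() if seg.parent == sid]

    def terminal_ids(self) -> list[str]:
        return [sid for sid in self.segments if not self.children(sid)]

    def path_to_root(self, sid: str) -> list[str]:
        """Segment ids from the root down to ``sid`` inclusive."""
        path = []
        cur = sid
        while cur is not None:
            path.append(cur)
            cur = self.segments[cur].parent
        return path[::-1]

    @classmethod
    def single_vessel(cls, profile: AreaProfile, outlet_area: float | None = None) -> "VesselTree":
        """Wrap a single profile as a one-segment tree; the outlet area
        defaults to the profile's distal lumen area."""
        if outlet_area is None:
            outlet_area = float(profile.area[-1])
        return cls(
            segments={"v0": VesselSegment("v0", profile)},
            outlet_areas={"v0": outlet_area},
        )


# ---------------------------------------------------------------------------
# Serialization

def _profile_to_dict(profile: AreaProfile) -> dict:
    return {
        "s_mm": profile.arclength.tolist(),
        "area_mm2": profile.area.tolist(),
        "ecc": profile.eccentricity.tolist(),
        "lesion_start_mm": profile.lesion_start,
        "lesion_end_mm": profile.lesion_end,
        "meta": profile.meta,
    }


def _profile_from_dict(d: dict) -> AreaProfile:
    return AreaProfile(
        arclength=np.asarray(d["s_mm"], dtype=float),
        area=np.asarray(d["area_mm2"], dtype=float),
        eccentricity=np.asarray(d["ecc"], dtype=float),
        lesion_start=float(d["lesion_start_mm"]),
        lesion_end=float(d["lesion_end_mm"]),
        meta=d.get("meta", {}),
    )


def save_profile(profile: AreaProfile, path: str | Path) -> None:
    """Write a profile to disk.

    ``.json`` holds the combined form; ``.csv`` holds the sample table
    (header ``s_mm,area_mm2,ecc``) with a ``.json`` sidecar for the
    lesion bounds and metadata.
    """
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(_profile_to_dict(profile), indent=1))
    elif path.suffix == ".csv":
        pd.DataFrame(
            {"s_mm": profile.arclength, "area_mm2": profile.area, "ecc": profile.eccentricity}
        ).to_csv(path, index=False)
        sidecar = {
            "lesion_start_mm": profile.lesion_start,
            "lesion_end_mm": profile.lesion_end,
            "meta": profile.meta,
        }
        path.with_suffix(".lesion.json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported profile format {path.suffix!r}")


def load_profile(path: str | Path) -> AreaProfile:
    """Read a profile written by :func:`save_profile`."""
    path = Path(path)
    if path.suffix == ".json":
        return _profile_from_dict(json.loads(path.read_text()))
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".lesion.json").read_text())
        return AreaProfile(
            arclength=df["s_mm"].to_numpy(float),
            area=df["area_mm2"].to_numpy(float),
            eccentricity=df["ecc"].to_numpy(float),
            lesion_start=float(sidecar["lesion_start_mm"]),
            lesion_end=float(sidecar["lesion_end_mm"]),
            meta=sidecar.get("meta", {}),
        )
    raise ValueError(f"unsupported profile format {path.suffix!r}")


def save_tree(tree: VesselTree, path: str | Path) -> None:
    doc = {
        "root": tree.root,
        "lesion_segment": tree.lesion_segment,
        "segments": [
            {"id": seg.id, "parent": seg.parent, "profile": _profile_to_dict(seg.profile)}
            for seg in tree.segments.values()
        ],
        "outlets": [{"segment": sid, "area_mm2": a} for sid, a in tree.outlet_areas.items()],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_tree(path: str | Path) -> VesselTree:
    doc = json.loads(Path(path).read_text())
    segments = {
        d["id"]: VesselSegment(d["id"], _profile_from_dict(d["profile"]), d.get("parent"))
        for d in doc["segments"]
    }
    outlets = {d["segment"]: float(d["area_mm2"]) for d in doc["outlets"]}
    return VesselTree(segments=segments, outlet_areas=outlets,
                      lesion_segment=doc.get("lesion_segment"))
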