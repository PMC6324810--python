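"""Parametric models of the patterned bioceramic substrate architectures.

The study substrates are 2.5D bioceramic surfaces carrying periodic
semicircular grooves (concavities) or ridges (convexities) at the
hundred-micron scale, plus a flat control.  Six patterned architectures
are defined by three parameters each: feature width (the chord of the
semicircular cross-section), periodicity (centre-to-centre feature
spacing) and depth (height, for convex designs).  Dimensions are the
post-sintering values measured on the final ceramic parts, since all
imaging was performed on sintered substrates; the as-designed radii of
curvature (400 / 200 um) are retained as metadata only.

Cross-section model
-------------------
Depth ``z`` is measured downward from the uppermost surface plane
(ridge tops / flat shoulders), so grooves are ``z > 0`` regions.  A
concave feature of width ``w`` and depth ``D`` is a circular-arc dip of
radius ``r = w/2``: for ``D > r`` ("deep" variants) the dip is a
semicircle of radius ``r`` sitting below vertical walls of height
``D - r``; for ``D <= r`` the dip is the semicircular arc scaled to the
measured depth (a semi-ellipse).  Convex designs are the mirror image:
bumps of the same shape rising from a base plane at ``z = D``, the bump
top defining ``z = 0``.  For convex designs "grooves" means the regions
between bumps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubstrateDesign",
    "DepthProfile",
    "GrooveSet",
    "DESIGN_NAMES",
    "make_design",
    "designs_from_config",
    "depth_profile",
    "groove_truth",
]

CONCAVE = "concave"
CONVEX = "convex"
FLAT = "flat"


@dataclass(frozen=True)
class SubstrateDesign:
    """One substrate architecture (post-sintering dimensions, um)."""

    name: str
    feature_width: float
    periodicity: float
    depth: float
    polarity: str
    designed_radius: float | None = None  # as-designed, pre-shrinkage (metadata)

    def __post_init__(self) -> None:
        if self.polarity not in (CONCAVE, CONVEX, FLAT):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.polarity == FLAT:
            if self.depth != 0:
                raise ValueError("flat design must have depth 0")
            return
        if self.feature_width <= 0 or self.periodicity <= 0:
            raise ValueError("patterned designs need positive width and periodicity")
        if self.feature_width > self.periodicity:
            raise ValueError("feature_width must not exceed periodicity")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def radius(self) -> float:
        """Radius of the semicircular cross-section, um."""
        return self.feature_width / 2.0

    @property
    def is_flat(self) -> bool:
        return self.polarity == FLAT


#: Measured (post-shrinkage) dimensions of the seven architectures.
_DESIGN_TABLE: dict[str, tuple[float, float, float, str, float | None]] = {
    "large": (660.0, 1240.0, 300.0, CONCAVE, 400.0),
    "large_deep": (660.0, 1240.0, 585.0, CONCAVE, 400.0),
    "large_convex": (660.0, 1240.0, 300.0, CONVEX, 400.0),
    "small": (330.0, 630.0, 150.0, CONCAVE, 200.0),
    "small_deep": (330.0, 630.0, 300.0, CONCAVE, 200.0),
    "small_convex": (330.0, 630.0, 150.0, CONVEX, 200.0),
    "flat": (0.0, 0.0, 0.0, FLAT, None),
}

DESIGN_NAMES: tuple[str, ...] = tuple(_DESIGN_TABLE)


def make_design(name: str) -> SubstrateDesign:
    """Return the named architecture with its measured dimensions."""
    try:
        w, p, d, pol, r0 = _DESIGN_TABLE[name]
    except KeyError:
        raise ValueError(
            f"unknown design {name!r}; valid designs: {', '.join(DESIGN_NAMES)}"
        ) from None
    return SubstrateDesign(name, w, p, d, pol, r0)


def designs_from_config(text: str) -> dict[str, SubstrateDesign]:
    """Parse additional designs from a plain ``key: value`` text config.

    Blocks are separated by blank lines; each block needs ``name``,
    ``feature_width``, ``periodicity``, ``depth`` and ``polarity``.
    """
    designs: dict[str, SubstrateDesign] = {}
    for block in text.split("\n\n"):
        fields: dict[str, str] = {}
        for line in block.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
        if not fields:
            continue
        d = SubstrateDesign(
            name=fields["name"],
            feature_width=float(fields.get("feature_width", 0)),
            periodicity=float(fields.get("periodicity", 0)),
            depth=float(fields.get("depth", 0)),
            polarity=fields.get("polarity", FLAT),
        )
        designs[d.name] = d
    return designs


@dataclass(frozen=True)
class DepthProfile:
    """Surface depth sampled along the cross-sectional axis.

    ``x`` is uniformly spaced (um); ``z`` is depth below the ridge plane
    (um, >= 0 downward).
    """

    x: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        if x.ndim != 1 or x.shape != z.shape:
            raise ValueError("x and z must be 1-D arrays of equal length")
        if x.size >= 2:
            dx = np.diff(x)
            if np.any(dx <= 0):
                raise ValueError("x must be strictly increasing")
            if not np.allclose(dx, dx[0], rtol=1e-6, atol=1e-9):
                raise ValueError("x must be uniformly spaced")
        if np.any(z < -1e-9):
            raise ValueError("depth must be non-negative")

    @property
    def sampling(self) -> float:
        if self.x.size < 2:
            return 0.0
        return float(self.x[1] - self.x[0])

    @property
    def extent(self) -> float:
        return float(self.x[-1] - self.x[0] + self.sampling)


@dataclass(frozen=True)
class GrooveSet:
    """Ordered disjoint groove intervals along the cross-sectional axis.

    Intervals are half-open ``[start, end)`` in um within ``[0, extent)``.
    Partial intervals clipped at the extent boundary are kept (real
    samples are cropped mid-pattern).
    """

    intervals: np.ndarray  # (n, 2)
    extent: float

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "intervals", iv)
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        if iv.size:
            if np.any(iv[:, 0] >= iv[:, 1]):
                raise ValueError("each interval needs start < end")
            if np.any(np.diff(iv[:, 0]) <= 0):
                raise ValueError("intervals must be sorted by start")
            if np.any(iv[:-1, 1] > iv[1:, 0] + 1e-9):
                raise ValueError("intervals must be disjoint")
            if iv[0, 0] < -1e-9 or iv[-1, 1] > self.extent + 1e-9:
                raise ValueError("intervals must lie within [0, extent)")

    @property
    def n_grooves(self) -> int:
        return len(self.intervals)

    @property
    def groove_length(self) -> float:
        if not len(self.intervals):
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    @property
    def outside_length(self) -> float:
        return self.extent - self.groove_length

    def contains(self, x) -> np.ndarray:
        """Half-open membership of positions ``x`` (um) in any groove."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros(x.shape, dtype=bool)
        for s, e in self.intervals:
            out |= (x >= s) & (x < e)
        return out

    def centers(self) -> np.ndarray:
        return self.intervals.mean(axis=1) if len(self.intervals) else np.empty(0)


def _dip(design: SubstrateDesign, u: np.ndarray) -> np.ndarray:
    """Dip shape (um downward) at signed offset ``u`` from a feature centre.

    Semicircle of radius w/2 under vertical walls when depth > w/2;
    semi-elliptical arc of the measured depth otherwise.  Zero outside
    the feature span.
    """
    r = design.radius
    a = min(design.depth, r)  # arc depth
    wall = design.depth - a  # vertical wall height above the arc
    inside = np.abs(u) < r
    z = np.zeros_like(u)
    z[inside] = wall + a * np.sqrt(np.maximum(0.0, 1.0 - (u[inside] / r) ** 2))
    return z


def depth_profile(
    design: SubstrateDesign,
    extent: float,
    sampling: float = 2.0,
    phase: float = 0.0,
) -> DepthProfile:
    """Analytic depth profile of a design over ``[0, extent)``.

    ``phase`` shifts the pattern laterally; with phase 0 each feature is
    centred in its period, i.e. the first feature spans
    ``[(P - w)/2, (P + w)/2)``.
    """
    if extent <= 0 or sampling <= 0:
        raise ValueError("extent and sampling must be positive")
    if not design.is_flat:
        if not 0 <= phase < design.periodicity:
            raise ValueError("phase must lie in [0, periodicity)")
        if sampling > design.feature_width / 4:
            raise ValueError(
                f"sampling {sampling} um undersamples features of width "
                f"{design.feature_width} um (need <= width/4)"
            )
    x = np.arange(0.0, extent, sampling)
    if design.is_flat:
        return DepthProfile(x, np.zeros_like(x))
    P = design.periodicity
    u = ((x - phase) % P) - P / 2.0  # offset from nearest feature centre
    bump = _dip(design, u)
    if design.polarity == CONCAVE:
        z = bump
    else:  # convex: bumps rise from the base plane at z = depth
        z = design.depth - bump
    return DepthProfile(x, z)


def groove_truth(
    design: SubstrateDesign, extent: float, phase: float = 0.0
) -> GrooveSet:
    """Ground-truth groove intervals for a design over ``[0, extent)``.

    Concave designs: the feature-width spans (where z > 0).  Convex
    designs: the complement of the bump spans — the regions between
    convexities.  Flat: empty set over the full extent.
    """
    if extent <= 0:
        raise ValueError("extent must be positive")
    if design.is_flat:
        return GrooveSet(np.empty((0, 2)), extent)
    if not 0 <= phase < design.periodicity:
        raise ValueError("phase must lie in [0, periodicity)")
    P, w = design.periodicity, design.feature_width
    # feature centres covering [0, extent)
    k0 = math.floor((0.0 - phase) / P) - 1
    k1 = math.ceil((extent - phase) / P) + 1
    spans = []
    for k in range(k0, k1 + 1):
        c = phase + (k + 0.5) * P
        s, e = c - w / 2.0, c + w / 2.0
        s, e = max(s, 0.0), min(e, extent)
        if e - s > 1e-9:
            spans.append((s, e))
    spans_arr = np.asarray(spans, dtype=float).reshape(-1, 2)
    if design.polarity == CONCAVE:
        return GrooveSet(spans_arr, extent)
    # convex: complement of the bump spans
    comp = []
    prev = 0.0
    for s, e in spans_arr:
        if s - prev > 1e-9:
            comp.append((prev, s))
        prev = e
    if extent - prev > 1e-9:
        comp.append((prev, extent))
    return GrooveSet(np.asarray(comp, dtype=float).reshape(-1, 2), extent)
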