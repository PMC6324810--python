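"""Synthetic confocal stacks of CD31-like vessel signal on patterned substrates.

The study's raw confocal images are not deposited, so this module
generates stand-in Z-stacks with known ground truth: bright, smooth,
filamentous structures (microcapillary-like, tens of um wide) on a dark
noisy background, laid over one of the substrate architectures.  Two
properties of the real data are the controllable dials the analysis is
tested against:

* **alignment** — filament orientations are drawn from an axial von
  Mises distribution centred on the groove axis (0 deg) with
  concentration ``alignment_kappa`` (kappa = 0 is exactly uniform on
  [-90, 90)); and
* **containment** — each filament is placed wholly inside a groove
  interval with probability ``containment_prob``, otherwise anywhere.

Grooves run along the image y axis (the localization convention:
vertical grooves, cross-sectional axis = x).  Each filament's Z position
tracks the substrate depth profile at its x location, so depth maps are
recoverable from the stack.  Identical arguments and seed give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .geometry import SubstrateDesign, depth_profile, groove_truth

__all__ = [
    "ImageStack",
    "BinaryMask",
    "VesselGroundTruth",
    "FRAME_FULL",
    "FRAME_HALF",
    "PIXEL_SIZE_UM",
    "generate_coculture_stack",
    "generate_particle_mask",
]

#: Analysis crop of the study: 5740 x 5023 um = 2400 x 2100 px.
PIXEL_SIZE_UM = 5740.0 / 2400.0  # 2.3917 um/px
FRAME_FULL = (2400, 2100)  # (width, height) px
FRAME_HALF = (1200, 1050)  # half-scale preset for fast runs

#: Gaussian FWHM-to-sigma conversion.
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ImageStack:
    """3-D intensity grid (z, y, x) with physical voxel spacing in um."""

    voxels: np.ndarray
    pixel_size_xy: float
    z_spacing: float

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        object.__setattr__(self, "voxels", v)
        if v.ndim != 3:
            raise ValueError("voxels must be (z, y, x)")
        if self.pixel_size_xy <= 0 or self.z_spacing <= 0:
            raise ValueError("voxel spacings must be positive")
        if np.any(v < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def z_positions_um(self) -> np.ndarray:
        """Depth of each slice below the top slice (um)."""
        return np.arange(self.n_slices) * self.z_spacing


@dataclass(frozen=True)
class BinaryMask:
    """2-D boolean foreground mask with pixel size in um."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.dtype != bool:
            p = p.astype(bool)
        object.__setattr__(self, "pixels", p)
        if p.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class VesselGroundTruth:
    """Per-filament ground truth for one synthetic stack."""

    centerlines: list  # list of (n, 2) arrays of (x, y) in um
    orientations: np.ndarray  # degrees in [-90, 90), groove axis = 0
    contained: np.ndarray  # bool per filament
    design: SubstrateDesign
    phase: float
    seed: int

    def to_frame(self):
        """Tabular (one row per filament) view for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "filament": np.arange(len(self.centerlines)),
                "orientation_deg": self.orientations,
                "contained": self.contained,
                "length_um": [
                    float(np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)))
                    for c in self.centerlines
                ],
            }
        )


def _sample_orientation(rng: np.random.Generator, kappa: float) -> float:
    """Axial orientation in degrees: von Mises on the doubled angle."""
    if kappa == 0:
        return float(rng.uniform(-90.0, 90.0))
    theta2 = rng.vonmises(0.0, 2.0 * kappa)  # doubled-angle concentration
    return float(np.degrees(theta2 / 2.0))


def _build_centerline(
    rng: np.random.Generator,
    orientation_deg: float,
    length_um: float,
    step_um: float = 10.0,
    wander_sd_deg: float = 25.0,
) -> np.ndarray:
    """Smooth random curve of the given length and mean orientation.

    Heading along arc length is the base orientation plus a smooth
    random heading wander of the given sd, giving bounded curvature.
    Unguided microcapillary-like structures are markedly tortuous
    (heading sd ~25 deg); guidance that concentrates orientations also
    straightens individual structures, so the sd shrinks with the
    alignment concentration, and groove-confined structures get a
    gentle wiggle only (``wander_sd_deg = 0``).
    """
    n = max(2, int(round(length_um / step_um)) + 1)
    s = np.linspace(0.0, length_um, n)
    if wander_sd_deg > 0:
        # smooth heading random walk: white noise low-passed over ~300 um
        wander = gaussian_filter1d(
            rng.normal(0.0, 1.0, n), max(1.0, 300.0 / (2 * step_um)),
            mode="nearest",
        )
        sd = wander.std() or 1.0
        heading = np.radians(orientation_deg + wander_sd_deg * wander / sd)
    else:
        amp = rng.uniform(2.0, 10.0)  # deg
        lam = rng.uniform(500.0, 1500.0)  # um
        psi = rng.uniform(0.0, 2.0 * np.pi)
        heading = np.radians(
            orientation_deg + amp * np.sin(2.0 * np.pi * s / lam + psi)
        )
    # orientation measured from the groove (y) axis: dx = sin, dy = cos
    dx = np.sin(heading)
    dy = np.cos(heading)
    pts = np.empty((n, 2))
    pts[0] = 0.0
    pts[1:, 0] = np.cumsum(dx[:-1] * np.diff(s))
    pts[1:, 1] = np.cumsum(dy[:-1] * np.diff(s))
    return pts


def _build_structure(
    rng: np.random.Generator,
    orientation_deg: float,
    length_um: float,
    branched: bool,
    alignment_kappa: float = 0.0,
) -> list[np.ndarray]:
    """One microcapillary-like structure: a main curve plus side branches.

    Unconfined structures branch laterally (heading offset 25-65 deg
    from the local main direction) and wander; orientation guidance
    straightens them (wander sd 25 deg at kappa 0, shrinking with
    kappa).  Groove walls suppress lateral branching, so confined
    structures are rendered unbranched.
    """
    wander = 25.0 / (1.0 + alignment_kappa / 4.0) if branched else 0.0
    main = _build_centerline(rng, orientation_deg, length_um,
                             wander_sd_deg=wander)
    parts = [main]
    if branched:
        for _ in range(rng.poisson(1.5)):
            i = rng.integers(1, len(main) - 1)
            seg = main[min(i + 1, len(main) - 1)] - main[i - 1]
            base = np.degrees(np.arctan2(seg[0], seg[1]))
            off = rng.uniform(25.0, 65.0) * (1 if rng.random() < 0.5 else -1)
            blen = rng.uniform(0.3, 0.7) * length_um
            branch = _build_centerline(rng, base + off, blen,
                                       wander_sd_deg=wander)
            parts.append(branch + main[i])
    return parts


def generate_coculture_stack(
    design: SubstrateDesign,
    n_filaments: int = 40,
    alignment_kappa: float = 4.0,
    containment_prob: float = 0.8,
    filament_width_um: float = 20.0,
    snr: float = 8.0,
    image_size_px: tuple[int, int] = FRAME_FULL,
    pixel_size: float = PIXEL_SIZE_UM,
    n_slices: int = 10,
    phase: float = 0.0,
    seed: int = 0,
    monolayer_amplitude: float = 0.015,
    background_cells_per_mm2: float = 150.0,
    cell_amplitude: float = 0.4,
    cell_diameter_um: float = 12.0,
) -> tuple[ImageStack, VesselGroundTruth]:
    """Render a synthetic CD31 co-culture Z-stack plus its ground truth.

    Parameters
    ----------
    design : substrate architecture the stack sits on.
    n_filaments : number of vessel-like filaments.
    alignment_kappa : orientation concentration about the groove axis
        (0 = isotropic).
    containment_prob : probability a filament is placed wholly inside a
        groove interval.
    filament_width_um : FWHM of the Gaussian cross-profile.
    snr : peak filament amplitude over the noise sigma at that peak
        (noise is signal-dependent, as shot-noise-limited confocal
        acquisition is; darker voxels are proportionally cleaner).
    image_size_px : (width, height) of each slice.
    n_slices : Z slices spanning [0, design depth + 50 um].
    phase : lateral pattern shift (um).
    seed : RNG seed; identical calls are bit-identical.
    monolayer_amplitude : mean intensity of the confluent co-culture
        monolayer, a continuous faint sheet (osteoblasts plus
        non-assembled endothelial cells carry weak nonspecific signal)
        lying on the substrate surface.  It is what carries depth
        information over ridges as well as grooves, exactly as in the
        real stacks; it is too dim and too uniform to survive the
        segmentation path.
    background_cells_per_mm2 : density of additional brighter cell-sized
        spots on the monolayer; individually below the particle-area
        cutoff, so the segmentation path removes them.
    cell_amplitude : peak intensity of a background cell (filament = 1).
    cell_diameter_um : FWHM of a background cell spot.
    """
    W, H = image_size_px
    if W < 256 or H < 256:
        raise ValueError("image must be at least 256 x 256 px")
    if not 0.0 <= containment_prob <= 1.0:
        raise ValueError("containment_prob must lie in [0, 1]")
    if design.is_flat and containment_prob > 0:
        raise ValueError("flat design has no grooves: containment_prob must be 0")
    if n_slices < 1:
        raise ValueError("need at least one slice")
    rng = np.random.default_rng(seed)

    extent_x = W * pixel_size
    extent_y = H * pixel_size
    grooves = groove_truth(design, extent_x, phase) if not design.is_flat else None
    z_span = design.depth + 50.0
    z_spacing = z_span / max(1, n_slices - 1)
    sigma_px = (filament_width_um / _FWHM) / pixel_size

    stack = np.zeros((n_slices, H, W), dtype=np.float64)
    centerlines: list[np.ndarray] = []
    orientations = np.empty(n_filaments)
    contained = np.zeros(n_filaments, dtype=bool)
    len_cap = min(3000.0, 0.9 * min(extent_x, extent_y))

    for i in range(n_filaments):
        want_contained = bool(rng.random() < containment_prob)
        parts = None
        for _ in range(60):
            phi = _sample_orientation(rng, alignment_kappa)
            L = rng.uniform(min(500.0, len_cap), len_cap)
            if not want_contained:
                cand = _build_structure(rng, phi, L, branched=True, alignment_kappa=alignment_kappa)
                center = np.vstack(cand).mean(axis=0)
                shift = np.array([rng.uniform(0, extent_x),
                                  rng.uniform(0, extent_y)]) - center
                parts = [p + shift for p in cand]
                break
            # confined: unbranched, placed wholly inside a groove interval
            main = _build_structure(rng, phi, L, branched=False, alignment_kappa=alignment_kappa)[0]
            main = main - main.mean(axis=0)
            x_half = main[:, 0].max() - main[:, 0].min()
            fits = [(s, e) for s, e in grooves.intervals if (e - s) > x_half + 2.0]
            if not fits:
                continue
            s, e = fits[rng.integers(len(fits))]
            cx = rng.uniform(s - main[:, 0].min() + 1.0,
                             e - main[:, 0].max() - 1.0)
            cy = rng.uniform(0.0, extent_y)
            parts = [main + [cx, cy]]
            contained[i] = True
            break
        if parts is None:
            # could not fit inside a groove: fall back to free placement
            phi = _sample_orientation(rng, alignment_kappa)
            L = rng.uniform(min(500.0, len_cap), len_cap)
            cand = _build_structure(rng, phi, L, branched=True, alignment_kappa=alignment_kappa)
            center = np.vstack(cand).mean(axis=0)
            shift = np.array([rng.uniform(0, extent_x),
                              rng.uniform(0, extent_y)]) - center
            parts = [p + shift for p in cand]
        orientations[i] = phi
        centerlines.append(parts[0])
        for part in parts:
            _render_filament(stack, part, design, phase, pixel_size,
                             sigma_px, z_spacing)

    if monolayer_amplitude > 0:
        _render_monolayer(
            stack, rng, design, phase, pixel_size, z_spacing,
            monolayer_amplitude,
        )
    if background_cells_per_mm2 > 0:
        _render_background_cells(
            stack, rng, design, phase, pixel_size, z_spacing,
            background_cells_per_mm2, cell_amplitude, cell_diameter_um,
        )

    # smooth low-amplitude background gradient + per-voxel Gaussian noise
    peak = 1.0
    yy = np.linspace(-1, 1, H)[:, None]
    xx = np.linspace(-1, 1, W)[None, :]
    c = rng.uniform(-1, 1, size=4)
    background = 0.03 * peak * (
        1.0 + 0.5 * (c[0] * xx + c[1] * yy + c[2] * xx * yy + c[3] * xx**2)
    )
    stack += background[None, :, :]
    # signal-dependent (shot-like) noise: dark voxels are nearly clean,
    # bright voxels carry the stated snr at the filament peak
    sigma = (peak / snr) * np.sqrt(0.005 + np.clip(stack, 0.0, None) / peak)
    stack += rng.standard_normal(stack.shape) * sigma
    np.clip(stack, 0.0, None, out=stack)

    truth = VesselGroundTruth(
        centerlines=centerlines,
        orientations=orientations,
        contained=contained,
        design=design,
        phase=phase,
        seed=seed,
    )
    return ImageStack(stack.astype(np.float32), pixel_size, z_spacing), truth


def _render_filament(
    stack: np.ndarray,
    pts_um: np.ndarray,
    design: SubstrateDesign,
    phase: float,
    pixel_size: float,
    sigma_px: float,
    z_spacing: float,
) -> None:
    """Stamp one filament into the stack with unit peak amplitude.

    The filament's 2-D footprint (Gaussian cross-profile) is rendered on
    a cropped canvas, then distributed over Z slices column-by-column
    with a one-slice Gaussian bleed centred on the substrate depth at
    each x position.
    """
    n_slices, H, W = stack.shape
    # dense resampling at half-pixel steps
    seg = np.linalg.norm(np.diff(pts_um, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n_dense = max(2, int(total / (pixel_size / 2.0)))
    sd = np.linspace(0.0, total, n_dense)
    xd = np.interp(sd, s, pts_um[:, 0]) / pixel_size
    yd = np.interp(sd, s, pts_um[:, 1]) / pixel_size

    margin = int(math.ceil(4 * sigma_px)) + 2
    x0 = max(0, int(np.floor(xd.min())) - margin)
    x1 = min(W, int(np.ceil(xd.max())) + margin)
    y0 = max(0, int(np.floor(yd.min())) - margin)
    y1 = min(H, int(np.ceil(yd.max())) + margin)
    if x1 <= x0 or y1 <= y0:
        return  # entirely outside the frame
    canvas = np.zeros((y1 - y0, x1 - x0))
    xi = np.round(xd).astype(int) - x0
    yi = np.round(yd).astype(int) - y0
    keep = (xi >= 0) & (xi < canvas.shape[1]) & (yi >= 0) & (yi < canvas.shape[0])
    np.add.at(canvas, (yi[keep], xi[keep]), 1.0)
    canvas = gaussian_filter(canvas, sigma_px, mode="constant")
    m = canvas.max()
    if m <= 0:
        return
    canvas /= m  # unit peak amplitude

    # substrate depth at each canvas column
    x_um = (np.arange(x0, x1) + 0.5) * pixel_size
    prof = depth_profile(
        design, design.periodicity, design.feature_width / 32.0, phase
    ) if not design.is_flat else None
    if prof is None:
        depths = np.zeros(x1 - x0)
    else:
        pos = x_um % design.periodicity
        depths = np.interp(pos, prof.x, prof.z, period=design.periodicity)
    z_idx = depths / z_spacing
    k = np.arange(n_slices)[:, None]
    w = np.exp(-0.5 * (k - z_idx[None, :]) ** 2)  # one-slice Gaussian bleed
    w /= w.sum(axis=0, keepdims=True)
    stack[:, y0:y1, x0:x1] += w[:, None, :] * canvas[None, :, :]


def _render_monolayer(
    stack: np.ndarray,
    rng: np.random.Generator,
    design: SubstrateDesign,
    phase: float,
    pixel_size: float,
    z_spacing: float,
    amplitude: float,
) -> None:
    """Continuous faint cell sheet draped over the substrate surface.

    Intensity is the mean amplitude modulated by a smooth random texture
    (correlation length ~200 um); the sheet sits at the substrate depth
    at each x, with the same one-slice Gaussian bleed as the filaments.
    """
    n_slices, H, W = stack.shape
    corr_px = max(2.0, 200.0 / pixel_size)
    texture = gaussian_filter(rng.normal(0.0, 1.0, (H, W)), corr_px,
                              mode="reflect")
    t = texture.std()
    texture = 1.0 + 0.3 * (texture / t if t > 0 else texture)
    sheet = amplitude * np.clip(texture, 0.0, None)
    x_um = (np.arange(W) + 0.5) * pixel_size
    if design.is_flat:
        depths = np.zeros(W)
    else:
        prof = depth_profile(
            design, design.periodicity, design.feature_width / 32.0, phase
        )
        depths = np.interp(
            x_um % design.periodicity, prof.x, prof.z,
            period=design.periodicity,
        )
    k = np.arange(n_slices)[:, None]
    wz = np.exp(-0.5 * (k - (depths / z_spacing)[None, :]) ** 2)
    wz /= wz.sum(axis=0, keepdims=True)
    stack += wz[:, None, :] * sheet[None, :, :]


def _render_background_cells(
    stack: np.ndarray,
    rng: np.random.Generator,
    design: SubstrateDesign,
    phase: float,
    pixel_size: float,
    z_spacing: float,
    density_mm2: float,
    amplitude: float,
    diameter_um: float,
) -> None:
    """Scatter faint cell-sized Gaussian spots over the substrate surface."""
    n_slices, H, W = stack.shape
    area_mm2 = (H * pixel_size / 1000.0) * (W * pixel_size / 1000.0)
    n = rng.poisson(density_mm2 * area_mm2)
    if n == 0:
        return
    sigma_px = (diameter_um / _FWHM) / pixel_size
    xs = rng.uniform(0, W, n)
    ys = rng.uniform(0, H, n)
    amps = amplitude * rng.uniform(0.7, 1.3, n)
    if design.is_flat:
        depths = np.zeros(n)
    else:
        prof = depth_profile(
            design, design.periodicity, design.feature_width / 32.0, phase
        )
        depths = np.interp(
            (xs * pixel_size) % design.periodicity,
            prof.x, prof.z, period=design.periodicity,
        )
    k = np.arange(n_slices)[:, None]
    wz = np.exp(-0.5 * (k - (depths / z_spacing)[None, :]) ** 2)
    wz /= wz.sum(axis=0, keepdims=True)
    xi = np.clip(np.round(xs).astype(int), 0, W - 1)
    yi = np.clip(np.round(ys).astype(int), 0, H - 1)
    gain = 2.0 * np.pi * sigma_px**2  # delta -> unit peak after smoothing
    for kz in range(n_slices):
        plane = np.zeros((H, W))
        np.add.at(plane, (yi, xi), amps * wz[kz] * gain)
        stack[kz] += gaussian_filter(plane, sigma_px, mode="constant")


def generate_particle_mask(
    areas_px: list[int],
    image_size_px: tuple[int, int] = (256, 256),
    pixel_size: float = PIXEL_SIZE_UM,
    seed: int = 0,
    max_tries: int = 200,
) -> BinaryMask:
    """Binary mask containing one connected component per requested area.

    Components are grown by random 4-connected accretion to exactly the
    requested pixel areas and placed so that no two components touch
    (8-connectivity).  Raises if placement fails after bounded retries.
    """
    W, H = image_size_px
    rng = np.random.default_rng(seed)
    mask = np.zeros((H, W), dtype=bool)
    occupied = np.zeros((H, W), dtype=bool)  # mask dilated by 1 px
    for area in areas_px:
        if area < 1:
            raise ValueError("particle areas must be >= 1 px")
        placed = False
        for _ in range(max_tries):
            blob = _grow_blob(rng, int(area))
            h, w = blob.shape
            if h > H or w > W:
                continue
            r = rng.integers(0, H - h + 1)
            c = rng.integers(0, W - w + 1)
            if np.any(occupied[r : r + h, c : c + w] & blob):
                continue
            mask[r : r + h, c : c + w] |= blob
            rr0, rr1 = max(0, r - 1), min(H, r + h + 1)
            cc0, cc1 = max(0, c - 1), min(W, c + w + 1)
            pad = np.zeros((rr1 - rr0, cc1 - cc0), dtype=bool)
            pad[r - rr0 : r - rr0 + h, c - cc0 : c - cc0 + w] = blob
            from scipy.ndimage import binary_dilation

            occupied[rr0:rr1, cc0:cc1] |= binary_dilation(
                pad, structure=np.ones((3, 3), bool)
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place a {area}-px particle without contact "
                f"after {max_tries} tries"
            )
    return BinaryMask(mask, pixel_size)


def _grow_blob(rng: np.random.Generator, area: int) -> np.ndarray:
    """Random 4-connected blob of exactly ``area`` pixels (tight crop)."""
    side = int(math.ceil(2.5 * math.sqrt(area))) + 2
    grid = np.zeros((side, side), dtype=bool)
    cy = cx = side // 2
    grid[cy, cx] = True
    frontier = [(cy + 1, cx), (cy - 1, cx), (cy, cx + 1), (cy, cx - 1)]
    count = 1
    while count < area:
        i = rng.integers(len(frontier))
        y, x = frontier.pop(i)
        if not (0 <= y < side and 0 <= x < side) or grid[y, x]:
            continue
        grid[y, x] = True
        count += 1
        frontier.extend([(y + 1, x), (y - 1, x), (y, x + 1), (y, x - 1)])
        if not frontier:  # pathological; restart
            return _grow_blob(rng, area)
    ys, xs = np.nonzero(grid)
    return grid[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
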