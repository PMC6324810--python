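"""Orchestration of the two analysis paths and the simulated study.

``run_pipeline`` takes one Z-stack through both quantification paths:

* directionality — max projection, rotation/crop, rolling-ball
  background subtraction, Fourier orientation histogram, DOA;
* localization — the same head, then auto-contrast, 8-bit conversion,
  Phansalkar thresholding, small-particle removal, vertically averaged
  signal profile, groove detection from the stack's depth profile, DOC.

``simulate_study`` reproduces the study layout — all seven architectures
in triplicate — on synthetic stacks and returns the tidy group table the
statistics stage consumes.  Identical config and seed give byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .directionality import (DOAResult, OrientationHistogram,
                             degree_of_alignment, orientation_histogram)
from .geometry import GrooveSet, groove_truth, make_design
from .groupstats import kruskal_dunn, summarize_groups
from .localization import (DOCResult, SignalProfile, degree_of_containment,
                           depth_profile_from_stack, detect_grooves,
                           vertical_signal_profile)
from .preprocess import (Image2D, autocontrast_to_8bit, filter_small_particles,
                         max_projection, phansalkar_mask, rolling_ball_subtract,
                         rotate_and_crop)
from .synthetic import BinaryMask, ImageStack, generate_coculture_stack

__all__ = ["PipelineReport", "run_pipeline", "simulate_study", "compare_groups"]

log = logging.getLogger("angioarch")


@dataclass
class PipelineReport:
    """Everything one stack's analysis produced."""

    config: PipelineConfig
    doa: DOAResult
    doc: DOCResult
    histogram: OrientationHistogram
    grooves: GrooveSet
    profile: SignalProfile
    mask: BinaryMask
    projection: Image2D
    input_sha256: str

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "design": self.config.design,
                    "seed": self.config.seed,
                    "doa": self.doa.doa,
                    "doc": self.doc.doc,
                    "signal_along": self.doa.signal_along,
                    "signal_perp": self.doa.signal_perp,
                    "n_grooves": self.grooves.n_grooves,
                    "groove_length_um": self.grooves.groove_length,
                    "input_sha256": self.input_sha256,
                }
            ]
        )

    def write(self, outdir: str | Path) -> None:
        """Write report CSVs plus a manifest that reproduces the run."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(outdir / "report.csv", index=False)
        pd.DataFrame(
            {"angle_deg": self.histogram.bin_centers, "weight": self.histogram.weights}
        ).to_csv(outdir / "histogram.csv", index=False)
        pd.DataFrame(self.grooves.intervals, columns=["start_um", "end_um"]).to_csv(
            outdir / "grooves.csv", index=False
        )
        pd.DataFrame({"x_um": self.profile.x, "value": self.profile.value}).to_csv(
            outdir / "profile.csv", index=False
        )
        manifest = (
            f"angioarch {__version__}\n"
            f"input_sha256: {self.input_sha256}\n"
            f"--- config ---\n{self.config.to_yaml()}"
        )
        (outdir / "manifest.txt").write_text(manifest)


def _stage(name: str, t0: float, **params) -> None:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, kv)


def run_pipeline(
    config: PipelineConfig,
    stack: ImageStack | None = None,
    stack_path: str | Path | None = None,
) -> PipelineReport:
    """Run both analysis paths on a stack (given, from file, or synthetic).

    With neither ``stack`` nor ``stack_path``, a synthetic stack is
    generated from the config's design and generation settings.
    """
    design = make_design(config.design)
    if stack is None and stack_path is not None:
        from .tiffio import read_stack

        stack = read_stack(stack_path)
    if stack is None:
        t0 = time.perf_counter()
        stack, _ = generate_coculture_stack(
            design,
            n_filaments=config.n_filaments,
            alignment_kappa=config.alignment_kappa,
            containment_prob=config.containment_prob,
            filament_width_um=config.filament_width_um,
            snr=config.snr,
            image_size_px=config.image_size_px,
            pixel_size=config.pixel_size_um,
            n_slices=config.n_slices,
            phase=config.phase_um,
            seed=config.seed,
        )
        _stage("generate", t0, design=config.design, seed=config.seed)
    sha = hashlib.sha256(np.ascontiguousarray(stack.voxels).tobytes()).hexdigest()

    t0 = time.perf_counter()
    mip = max_projection(stack)
    _stage("max_projection", t0, shape=mip.pixels.shape)

    if config.crop_px is not None or config.groove_angle_deg % 360 != 0:
        t0 = time.perf_counter()
        crop = config.crop_px or (mip.pixels.shape[1], mip.pixels.shape[0])
        mip = rotate_and_crop(mip, config.groove_angle_deg, crop)
        _stage("rotate_and_crop", t0, angle=config.groove_angle_deg, crop=crop)

    t0 = time.perf_counter()
    sub = rolling_ball_subtract(
        mip, config.rolling_ball_radius_px, config.rolling_ball_downscale
    )
    _stage("rolling_ball", t0, radius=config.rolling_ball_radius_px)

    # --- directionality path ---
    t0 = time.perf_counter()
    hist = orientation_histogram(sub, config.n_bins)
    doa = degree_of_alignment(hist, config.doa_window_deg)
    _stage("directionality", t0, doa=f"{doa.doa:.3f}")
    if not doa.is_finite:
        log.warning("DOA is an infinite-alignment sentinel")

    # --- localization path ---
    t0 = time.perf_counter()
    img8 = autocontrast_to_8bit(sub, config.saturation_fraction)
    mask = phansalkar_mask(
        img8,
        config.phansalkar_radius_px,
        config.phansalkar_k,
        config.phansalkar_r,
        config.phansalkar_p,
        config.phansalkar_q,
        config.phansalkar_window,
    )
    mask = filter_small_particles(mask, config.min_particle_area_um2)
    profile = vertical_signal_profile(mask)
    _stage("segmentation", t0, foreground=float(mask.pixels.mean()))

    t0 = time.perf_counter()
    if design.is_flat:
        grooves = GrooveSet(np.empty((0, 2)), profile.extent)
    elif config.groove_source == "truth":
        grooves = groove_truth(design, profile.extent, config.phase_um)
    else:
        depth = depth_profile_from_stack(stack, params=config.groovej)
        grooves = detect_grooves(depth, config.groovej)
        grooves = GrooveSet(
            np.clip(grooves.intervals, 0, profile.extent), profile.extent
        ) if grooves.n_grooves else GrooveSet(np.empty((0, 2)), profile.extent)
    doc = degree_of_containment(profile, grooves)
    _stage("localization", t0, n_grooves=grooves.n_grooves,
           doc=f"{doc.doc:.3f}" if doc.is_finite else "undefined")
    if doc.undefined:
        log.warning("DOC undefined: no groove or no outside region")
    elif not doc.is_finite:
        log.warning("DOC is an infinite-containment sentinel")

    return PipelineReport(
        config=config,
        doa=doa,
        doc=doc,
        histogram=hist,
        grooves=grooves,
        profile=profile,
        mask=mask,
        projection=mip,
        input_sha256=sha,
    )


def simulate_study(config: PipelineConfig) -> pd.DataFrame:
    """Synthetic replica of the study layout: 7 architectures x replicates.

    Per-architecture generation settings come from
    ``config.study_generation``; replicate seeds derive deterministically
    from ``config.seed``.  Returns the tidy group table (architecture,
    replicate, statistic, value).
    """
    rows = []
    designs = list(config.study_generation)
    for di, name in enumerate(designs):
        kappa, containment = config.study_generation[name]
        for rep in range(config.replicates):
            sub = dataclasses.replace(
                config,
                design=name,
                alignment_kappa=kappa,
                containment_prob=containment,
                seed=(config.seed * 1000 + di * 100 + rep) % (2**31),
            )
            report = run_pipeline(sub)
            for stat, value in (("DOA", report.doa.doa), ("DOC", report.doc.doc)):
                rows.append(
                    {
                        "architecture": name,
                        "replicate": rep,
                        "statistic": stat,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def compare_groups(table: pd.DataFrame, statistic: str, adjust: str | None = None):
    """Summary plus Kruskal-Wallis/Dunn comparison for one statistic."""
    summary = summarize_groups(table[table["statistic"] == statistic])
    result = kruskal_dunn(table, statistic=statistic, adjust=adjust)
    return summary, result
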