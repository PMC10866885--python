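"""Synthetic-data generators with known ground truth.

Three generators emulate the package's experimental inputs:

* :func:`simulate_frap` — particle-based Brownian dynamics on a periodic
  2-D membrane patch with a Gaussian confocal bleach, observational
  photofading, background and shot noise. It serves as the numerical oracle
  for the confocal Soumpasis relation D = 0.25 r_e^2 / t_half.
* :func:`simulate_cell_population` — two-channel images of a heterogeneous
  cell population with membrane-ring expression and a configurable
  activation law (null / linear / quadratic threshold), plus the ROI pairs
  and a ground-truth table.
* :func:`simulate_timecourse` — piecewise linear-rise / exponential-decay
  phosphorylation time courses with multiplicative noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FrapSeries, RoiPair, TimeCourse
from .exceptions import ValidationError

__all__ = [
    "FrapSimConfig",
    "FrapSimResult",
    "simulate_frap",
    "brownian_step",
    "CellPopConfig",
    "CellPopResult",
    "simulate_cell_population",
    "simulate_timecourse",
    "default_timecourse_grid",
]


# --------------------------------------------------------------------------
# FRAP: Brownian particles on a periodic membrane patch
# --------------------------------------------------------------------------

@dataclass
class FrapSimConfig:
    """Conditions of a simulated confocal FRAP acquisition.

    Defaults mirror the acquisition this package analyses: a 1.2 um nominal
    bleach spot, 500 ms bleach, 10 prebleach and 120 post-bleach frames at
    2 frames/s. ``bleach_depth`` is the bleach probability at the spot
    centre for a stationary fluorophore.
    """

    d: float = 0.02                 # um^2/s
    n_particles: int = 100000       # ~700 receptors/um^2 on the 12 um patch
    domain_size: float = 12.0       # um, periodic square
    nominal_radius: float = 1.2     # um
    bleach_depth: float = 0.8       # K0 in (0, 1]
    bleach_duration: float = 0.5    # s
    frame_interval: float = 0.5     # s
    n_pre: int = 10
    n_post: int = 120
    photofade_rate: float = 0.002   # 1/s
    background: float = 20.0        # arb. units added to every trace
    noise: str = "poisson"          # "none" | "poisson"
    gaussian_sd: float = 0.0        # extra additive read noise
    n_substeps: int = 10            # Brownian substeps per frame interval
    render_pixels: int = 256        # rendered frame resolution
    seed: int = 0

    def validate(self) -> None:
        if self.domain_size < 10 * self.nominal_radius:
            raise ValidationError(
                "domain_size must be >= 10 * nominal_radius (reservoir limit)"
            )
        if not (0 < self.bleach_depth <= 1):
            raise ValidationError("bleach_depth must be in (0, 1]")
        for name in ("d", "photofade_rate", "background", "gaussian_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("n_particles", "n_pre", "n_post", "n_substeps", "render_pixels"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.noise not in ("none", "poisson"):
            raise ValidationError("noise must be 'none' or 'poisson'")


@dataclass
class FrapSimResult:
    series: FrapSeries
    postbleach_frame: np.ndarray     # first post-bleach frame / prebleach mean
    pixel_size: float                # um per rendered pixel
    center_px: tuple[float, float]
    radial_profile: pd.DataFrame     # radius_um, intensity (exact positions)
    ground_truth: dict
    fluorescent_per_frame: np.ndarray
    dark_per_frame: np.ndarray


def brownian_step(
    positions: np.ndarray, d: float, dt: float, domain_size: float, rng
) -> np.ndarray:
    """One free-diffusion step: per-axis displacement variance 2*D*dt.

    Positions wrap periodically; the patch approximates an unbounded
    membrane reservoir.
    """
    if d > 0 and dt > 0:
        positions = positions + rng.normal(
            0.0, np.sqrt(2.0 * d * dt), size=positions.shape
        )
    return np.mod(positions, domain_size)


def _min_image_r2(positions: np.ndarray, center: np.ndarray, L: float) -> np.ndarray:
    delta = positions - center
    delta -= L * np.round(delta / L)
    return np.einsum("ij,ij->i", delta, delta)


def simulate_frap(config: FrapSimConfig) -> FrapSimResult:
    """Run one FRAP acquisition; returns traces, rendered frame, ground truth.

    The spot trace is the confocal readout of the bleach region: each
    fluorescent particle contributes with the Gaussian beam weight
    exp(-2 r^2 / r_n^2), matching the observation profile under which the
    0.25 coefficient of the Soumpasis relation holds. The whole-cell trace
    counts fluorescent particles outside the nominal spot disk, and the
    background trace is an empty (cell-free) region.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.domain_size
    rn = config.nominal_radius
    center = np.array([L / 2.0, L / 2.0])
    dt_sub = config.frame_interval / config.n_substeps

    pos = rng.uniform(0.0, L, size=(config.n_particles, 2))
    fluorescent = np.ones(config.n_particles, dtype=bool)

    n_fluor, n_dark = [], []
    pre_traces = {"roi": [], "total": [], "bg": []}
    post_traces = {"roi": [], "total": [], "bg": []}

    def record(store):
        r2 = _min_image_r2(pos, center, L)
        w = np.exp(-2.0 * r2 / rn**2)
        f_roi = float(np.sum(w[fluorescent])) + config.background
        outside = fluorescent & (r2 > rn**2)
        f_total = float(np.count_nonzero(outside)) + config.background
        f_bg = config.background
        if config.noise == "poisson":
            f_roi = float(rng.poisson(f_roi))
            f_total = float(rng.poisson(f_total))
            f_bg = float(rng.poisson(max(f_bg, 0.0)))
        if config.gaussian_sd > 0:
            f_roi += rng.normal(0.0, config.gaussian_sd)
            f_total += rng.normal(0.0, config.gaussian_sd)
            f_bg += rng.normal(0.0, config.gaussian_sd)
        store["roi"].append(f_roi)
        store["total"].append(f_total)
        store["bg"].append(f_bg)
        n_fluor.append(int(np.count_nonzero(fluorescent)))
        n_dark.append(config.n_particles - n_fluor[-1])

    def advance_frame():
        nonlocal pos, fluorescent
        # observational photofading over the frame interval
        if config.photofade_rate > 0:
            survive = rng.random(config.n_particles) < np.exp(
                -config.photofade_rate * config.frame_interval
            )
            fluorescent &= survive
        # free-diffusion increments compose exactly, so one step per frame
        # interval is distribution-identical to substepping; substeps are
        # only needed while the bleach acts (see below)
        pos = brownian_step(pos, config.d, config.frame_interval, L, rng)

    # prebleach acquisition
    for _ in range(config.n_pre):
        record(pre_traces)
        advance_frame()

    n_fluor_prebleach = int(np.count_nonzero(fluorescent))

    # bleach: probability K0*exp(-2 r^2/r_n^2) integrated over the bleach
    # duration in substeps of frame_interval/n_substeps while diffusion
    # continues
    n_bleach_sub = max(1, int(round(config.bleach_duration / dt_sub)))
    for _ in range(n_bleach_sub):
        r2 = _min_image_r2(pos, center, L)
        g = config.bleach_depth * np.exp(-2.0 * r2 / rn**2)
        p_dark = 1.0 - np.power(np.clip(1.0 - g, 1e-300, 1.0), 1.0 / n_bleach_sub)
        bleached = rng.random(config.n_particles) < p_dark
        fluorescent &= ~bleached
        pos = brownian_step(pos, config.d, config.bleach_duration / n_bleach_sub, L, rng)

    # first post-bleach frame: rendered image + exact radial profile
    npix = config.render_pixels
    pixel_size = L / npix
    counts, _, _ = np.histogram2d(
        pos[fluorescent, 1], pos[fluorescent, 0],
        bins=npix, range=[[0, L], [0, L]],
    )
    density_pre = n_fluor_prebleach / npix**2
    frame = counts / density_pre
    center_px = (center[0] / pixel_size - 0.5, center[1] / pixel_size - 0.5)

    r_exact = np.sqrt(_min_image_r2(pos[fluorescent], center, L))
    edges = np.arange(0.0, L / 2.0, pixel_size)
    hist, _ = np.histogram(r_exact, bins=edges)
    area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    expected = n_fluor_prebleach / L**2 * area
    profile = pd.DataFrame(
        {
            "radius_um": 0.5 * (edges[1:] + edges[:-1]),
            "intensity": hist / expected,
        }
    )

    # post-bleach acquisition; frame 0 recorded immediately at bleach end
    for i in range(config.n_post):
        record(post_traces)
        if i < config.n_post - 1:
            advance_frame()

    times = np.arange(config.n_post) * config.frame_interval
    series = FrapSeries(
        times=times,
        f_roi=np.array(post_traces["roi"]),
        f_total=np.array(post_traces["total"]),
        f_bg=np.array(post_traces["bg"]),
        pre_roi=np.array(pre_traces["roi"]),
        pre_total=np.array(pre_traces["total"]),
        pre_bg=np.array(pre_traces["bg"]),
        frame_interval=config.frame_interval,
        nominal_radius=rn,
    )
    ground_truth = {
        "d_true": config.d,
        "nominal_radius": rn,
        "bleach_depth": config.bleach_depth,
        "n_fluorescent_prebleach": n_fluor_prebleach,
        "n_fluorescent_postbleach": int(np.count_nonzero(fluorescent)),
        "seed": config.seed,
    }
    return FrapSimResult(
        series=series,
        postbleach_frame=frame,
        pixel_size=pixel_size,
        center_px=center_px,
        radial_profile=profile,
        ground_truth=ground_truth,
        fluorescent_per_frame=np.array(n_fluor),
        dark_per_frame=np.array(n_dark),
    )


# --------------------------------------------------------------------------
# Cell populations: membrane rings with configurable activation laws
# --------------------------------------------------------------------------

@dataclass
class CellPopConfig:
    """Heterogeneous cell population with membrane-localised expression.

    Expression (total membrane signal per cell, arb. units) is log-normal,
    spanning the wide range a transient transfection produces. The phospho
    signal follows the activation law:

    * ``("null", {"basal": b})`` — density-independent basal signal;
    * ``("linear", {"f": f})`` — ligand-dependent behaviour, phospho = f * x;
    * ``("quadratic_threshold", {"c": c, "x0": x0})`` — ligand-independent
      behaviour, phospho = c * max(x - x0, 0)^2: negligible below the
      critical density x0 and supra-linear above it.

    ``bio_sd`` is the cell-to-cell multiplicative scatter of the phospho
    response; ``noise`` adds per-pixel Poisson shot noise to the rendering.
    """

    n_cells: int = 100
    expr_mean_log: float = 9.2      # ln arb. units; exp(9.2) ~ 9900
    expr_sd_log: float = 0.8
    law: tuple = ("linear", None)
    bio_sd: float = 0.2
    ring_outer_px: int = 10
    ring_inner_px: int = 7
    cyto_fraction: float = 0.5      # interior signal relative to membrane
    background: float = 10.0        # per-pixel background, both channels
    noise: str = "poisson"          # "none" | "poisson"
    seed: int = 0

    _LAW_DEFAULTS = {
        "null": {"basal": 200.0},
        "linear": {"f": 0.3},
        "quadratic_threshold": {"c": 1.5e-5, "x0": 10000.0},
    }

    def law_params(self) -> tuple[str, dict]:
        name, params = self.law
        if name not in self._LAW_DEFAULTS:
            raise ValidationError(f"unknown activation law {name!r}")
        merged = dict(self._LAW_DEFAULTS[name])
        if params:
            merged.update(params)
        return name, merged

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if not (0 < self.ring_inner_px < self.ring_outer_px):
            raise ValidationError("require 0 < ring_inner_px < ring_outer_px")
        if self.noise not in ("none", "poisson"):
            raise ValidationError("noise must be 'none' or 'poisson'")
        self.law_params()


@dataclass
class CellPopResult:
    expression: np.ndarray          # (H, W) expression-channel image
    phospho: np.ndarray             # (H, W) phospho-channel image
    rois: list = field(default_factory=list)
    ground_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    background: float = 0.0


def _activation(name: str, params: dict, x: np.ndarray) -> np.ndarray:
    if name == "null":
        return np.full_like(x, params["basal"])
    if name == "linear":
        return params["f"] * x
    return params["c"] * np.clip(x - params["x0"], 0.0, None) ** 2


def _ring_polygon(cx: float, cy: float, radius: float, n_vertices: int = 64) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])


def simulate_cell_population(config: CellPopConfig) -> CellPopResult:
    """Render a two-channel population image with ROI pairs and ground truth.

    Cells are laid out on a square grid (a layout error is raised when they
    cannot be packed). Each cell is an annular membrane ring carrying the
    expression amplitude plus a dimmer cytoplasmic interior; the phospho
    channel carries the activation-law response on the same ring.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    name, params = config.law_params()

    n = config.n_cells
    r_out, r_in = config.ring_outer_px, config.ring_inner_px
    margin = 4
    spacing = 2 * (r_out + margin)
    per_side = int(np.ceil(np.sqrt(n)))
    size = per_side * spacing
    if size > 4096:
        raise ValidationError("population exceeds the packing limit")

    x_true = rng.lognormal(config.expr_mean_log, config.expr_sd_log, size=n)
    g_clean = _activation(name, params, x_true)
    scatter = rng.lognormal(0.0, config.bio_sd, size=n) if config.bio_sd > 0 else 1.0
    g_true = g_clean * scatter

    yy, xx = np.mgrid[0:size, 0:size]
    expr_img = np.full((size, size), float(config.background))
    phospho_img = np.full((size, size), float(config.background))
    rois, rows = [], []

    for i in range(n):
        gx = (i % per_side) * spacing + spacing // 2
        gy = (i // per_side) * spacing + spacing // 2
        sl = np.s_[gy - r_out - 1 : gy + r_out + 2, gx - r_out - 1 : gx + r_out + 2]
        r2 = (xx[sl] - gx) ** 2 + (yy[sl] - gy) ** 2
        ring = (r2 <= r_out**2) & (r2 > r_in**2)
        interior = r2 <= r_in**2
        n_ring, n_int = int(ring.sum()), int(interior.sum())

        expr_img[sl][ring] += x_true[i] / n_ring
        expr_img[sl][interior] += config.cyto_fraction * x_true[i] / n_int
        phospho_img[sl][ring] += g_true[i] / n_ring
        phospho_img[sl][interior] += config.cyto_fraction * g_true[i] / n_int

        cell_id = f"cell{i:03d}"
        # roi2 sits in the radius gap between the outermost interior pixel
        # (centre radius <= r_in) and the innermost ring pixel (> r_in), so
        # the interior/cytoplasm cancels exactly in I_roi1 - I_roi2
        rois.append(
            RoiPair(
                cell_id=cell_id,
                roi1=_ring_polygon(gx, gy, r_out + margin / 2),
                roi2=_ring_polygon(gx, gy, r_in + 0.03),
            )
        )
        rows.append(
            {
                "cell_id": cell_id,
                "x_true": x_true[i],
                "g_true": g_true[i],
                "g_clean": g_clean[i],
                "law": name,
            }
        )

    if config.noise == "poisson":
        expr_img = rng.poisson(expr_img).astype(float)
        phospho_img = rng.poisson(phospho_img).astype(float)

    return CellPopResult(
        expression=expr_img,
        phospho=phospho_img,
        rois=rois,
        ground_truth=pd.DataFrame(rows),
        background=config.background,
    )


# --------------------------------------------------------------------------
# Phospho time courses
# --------------------------------------------------------------------------

def default_timecourse_grid(window: float = 60.0) -> np.ndarray:
    """Sampling times (minutes) typical of a stimulation time course."""
    grid = np.array([0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0])
    return grid[grid <= window]


def simulate_timecourse(
    rise_slope: float,
    peak_time: float | None = None,
    t_half: float = 14.0,
    window: float = 60.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    times: np.ndarray | None = None,
    construct_id: str = "synthetic",
) -> tuple[TimeCourse, dict]:
    """Piecewise linear-rise / exponential-decay time course.

    The curve rises with ``rise_slope`` (normalised units/min) until
    ``peak_time`` (default 1/rise_slope so the peak value is exactly 1),
    then decays exponentially with half-life ``t_half`` minutes
    (``t_half=inf`` gives a sustained plateau). Multiplicative Gaussian
    noise of sd ``noise_sd`` is applied. The sampling grid always includes
    the peak time so noiseless curves round-trip exactly through the
    kinetics fits.
    """
    if rise_slope <= 0 or t_half <= 0 or window <= 0:
        raise ValidationError("rise_slope, t_half and window must be positive")
    if peak_time is None:
        peak_time = 1.0 / rise_slope
    if peak_time >= window:
        raise ValidationError("peak_time must lie inside the observation window")
    if times is None:
        times = default_timecourse_grid(window)
    times = np.union1d(np.asarray(times, dtype=float), [peak_time])
    times = times[times <= window]

    peak_value = rise_slope * peak_time
    clean = np.where(
        times <= peak_time,
        rise_slope * times,
        peak_value
        * (np.exp(-np.log(2.0) * (times - peak_time) / t_half) if np.isfinite(t_half) else 1.0),
    )
    rng = np.random.default_rng(seed)
    noisy = clean.copy()
    if noise_sd > 0:
        noisy = np.clip(clean * (1.0 + rng.normal(0.0, noise_sd, size=len(clean))), 0.0, None)
    tc = TimeCourse(construct_id=construct_id, times=times, intensity=noisy)
    truth = {
        "rise_slope": rise_slope,
        "peak_time": peak_time,
        "peak_value": peak_value,
        "t_half": t_half,
        "window": window,
        "noise_sd": noise_sd,
        "seed": seed,
        "clean": clean,
    }
    return tc, truth
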