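"""Synthetic plate generator with known ground truth.

Emulates the imaging regime of a YFP-quench dose-response screen: each well
of a 384-well plate is imaged once in agonist-free control solution and then
at increasing agonist concentrations (11 frames by default).  Fields contain
on the order of 100-500 fluorescent cells; a cell co-expressing the halide
reporter and a functional channel responds with a sigmoidal fluorescence
quench in concentration, while transfection inefficiency leaves a fraction
of non-responding (flat) cells, and debris (dead cells, reporter-only cells,
cells detaching during perfusion) contaminates every field.

Two output routes with the same latent truth: :func:`generate_traces`
produces per-cell fluorescence tables directly, and
:func:`render_image_series` draws the cells onto 16-bit frames for testing
the segmentation stage.  Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fit import curve_model
from .io import ImageSeries, substream, traces_to_frame

__all__ = [
    "DEFAULT_LADDER",
    "PopulationSpec",
    "WellSpec",
    "GroundTruthCell",
    "ConfigurationError",
    "PlacementError",
    "sample_population",
    "true_response",
    "generate_traces",
    "render_image_series",
    "background_level",
]

# Control frame (c=0) followed by the first ten points of the standard
# half-log agonist series in µM.  The two top concentrations of the printed
# twelve-value series (10000, 30000 µM) are left to explicit configuration.
DEFAULT_LADDER = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0)

# Imaging field at 10x with 2x2 binning: 696 x 520 pixels (width x height).
DEFAULT_FIELD = (520, 696)

# Flat background as a fraction of the mean cell baseline.
BACKGROUND_FRAC = 0.05


class ConfigurationError(ValueError):
    """Invalid generator configuration; message names the offending field."""


class PlacementError(RuntimeError):
    """Cells could not be placed without overlap on the requested field."""


@dataclass
class PopulationSpec:
    """One functional phenotype: the latent parameter distributions of its cells.

    Per-cell EC50 is log-normal around ``ec50_median`` (µM) with spread
    ``ec50_log_sd`` in log10 units; Hill slope and dynamic range ΔF (percent
    quench) are uniform over their ranges.  ``fraction_responders`` models
    transfection efficiency: non-responders carry the reporter but no
    functional channel, so their trace is flat (ΔF = 0).
    """

    name: str
    ec50_median: float
    n_cells: int
    ec50_log_sd: float = 0.15
    slope_range: tuple = (0.8, 2.0)
    dF_range: tuple = (30.0, 70.0)
    fraction_responders: float = 0.85
    baseline_range: tuple = (1000.0, 4000.0)
    radius_range: tuple = (5.0, 9.0)

    def validate(self):
        if self.ec50_median <= 0:
            raise ConfigurationError(f"ec50_median must be > 0 (got {self.ec50_median})")
        if self.ec50_log_sd < 0:
            raise ConfigurationError(f"ec50_log_sd must be >= 0 (got {self.ec50_log_sd})")
        if not (0 <= self.fraction_responders <= 1):
            raise ConfigurationError(
                f"fraction_responders must be in [0, 1] (got {self.fraction_responders})"
            )
        if not (0 < self.slope_range[0] <= self.slope_range[1]):
            raise ConfigurationError(f"slope_range invalid (got {self.slope_range})")
        if not (0 <= self.dF_range[0] <= self.dF_range[1] <= 100):
            raise ConfigurationError(f"dF_range must lie in [0, 100] (got {self.dF_range})")
        if self.n_cells < 0:
            raise ConfigurationError(f"n_cells must be >= 0 (got {self.n_cells})")


@dataclass
class GroundTruthCell:
    """Latent truth for one rendered object (cell or debris)."""

    cell_id: str
    well_id: str
    class_label: str
    baseline_F: float
    true_EC50: float
    true_slope: float
    true_dF: float
    responder: bool
    radius: float
    center: tuple | None = None  # (x, y) pixels, assigned at placement
    detach_frame: int | None = None


@dataclass
class WellSpec:
    """One well: population mixture, agonist ladder and nuisance processes."""

    well_id: str = "A1"
    populations: list = field(default_factory=list)  # [(PopulationSpec, fraction)]
    concentration_ladder: tuple = DEFAULT_LADDER
    n_cells: int | None = None
    debris_count: int = 0
    detach_probability: float = 0.0
    noise_sd_frac: float = 0.02
    seed: int = 0
    field_shape: tuple = DEFAULT_FIELD

    def validate(self):
        ladder = np.asarray(self.concentration_ladder, dtype=float)
        if len(ladder) < 5:
            raise ConfigurationError("concentration_ladder needs >= 5 points")
        if ladder[0] != 0:
            raise ConfigurationError("concentration_ladder must start at 0 (control)")
        if np.any(np.diff(ladder) <= 0):
            raise ConfigurationError("concentration_ladder must be strictly increasing")
        if not self.populations:
            raise ConfigurationError("populations must be non-empty")
        fracs = [f for _, f in self.populations]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError(f"mixing fractions must sum to 1 (got {sum(fracs)})")
        if not (0 <= self.detach_probability <= 1):
            raise ConfigurationError(
                f"detach_probability must be in [0, 1] (got {self.detach_probability})"
            )
        if self.noise_sd_frac < 0:
            raise ConfigurationError(f"noise_sd_frac must be >= 0 (got {self.noise_sd_frac})")
        if self.debris_count < 0:
            raise ConfigurationError(f"debris_count must be >= 0 (got {self.debris_count})")
        for spec, _ in self.populations:
            spec.validate()


def sample_population(spec: PopulationSpec, seed: int, well_id: str = "A1",
                      rng: np.random.Generator | None = None) -> list:
    """Draw ``spec.n_cells`` ground-truth cells from one population.

    log10(EC50) ~ Normal(log10(median), ec50_log_sd); slope and ΔF uniform
    over their ranges; responder status Bernoulli(fraction_responders).
    Reproducible for a fixed seed.
    """
    spec.validate()
    if rng is None:
        rng = substream(seed, "sample_population", spec.name, well_id)
    cells = []
    for i in range(spec.n_cells):
        ec50 = 10.0 ** rng.normal(math.log10(spec.ec50_median), spec.ec50_log_sd)
        slope = rng.uniform(*spec.slope_range)
        responder = bool(rng.random() < spec.fraction_responders)
        dF = rng.uniform(*spec.dF_range) if responder else 0.0
        cells.append(
            GroundTruthCell(
                cell_id=f"{well_id}:{spec.name}:{i}",
                well_id=well_id,
                class_label=spec.name,
                baseline_F=float(rng.uniform(*spec.baseline_range)),
                true_EC50=float(ec50),
                true_slope=float(slope),
                true_dF=float(dF),
                responder=responder,
                radius=float(rng.uniform(*spec.radius_range)),
            )
        )
    return cells


def true_response(cell: GroundTruthCell, c):
    """Noise-free fluorescence of one cell at concentration(s) ``c`` (µM).

    Responders follow the same sigmoidal quench model the fit stage uses,
    from ``baseline_F`` at c = 0 down to ``baseline_F·(1 − ΔF/100)``;
    non-responders stay at baseline.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be non-negative")
    if not cell.responder:
        out = np.full_like(c_arr, cell.baseline_F, dtype=float)
        return out if out.ndim else float(out)
    F_min = cell.baseline_F * (1.0 - cell.true_dF / 100.0)
    return curve_model(c_arr, cell.baseline_F, F_min, cell.true_EC50, cell.true_slope)


def background_level(cells) -> float:
    """Flat imaging background: a small fraction of the mean cell baseline."""
    baselines = [c.baseline_F for c in cells if c.class_label != "debris"]
    ref = float(np.mean(baselines)) if baselines else 2000.0
    return BACKGROUND_FRAC * ref


def _population_counts(well: WellSpec):
    if well.n_cells is None:
        return [spec.n_cells for spec, _ in well.populations]
    counts = [int(round(frac * well.n_cells)) for _, frac in well.populations]
    counts[-1] += well.n_cells - sum(counts)
    return counts


def _sample_well(well: WellSpec):
    """All latent objects of a well: population cells, then debris."""
    well.validate()
    rng = substream(well.seed, "well", well.well_id)
    cells = []
    for (spec, _), n in zip(well.populations, _population_counts(well)):
        cells.extend(sample_population(replace(spec, n_cells=n), 0,
                                       well_id=well.well_id, rng=rng))
    n_frames = len(well.concentration_ladder)
    for cell in cells:
        if well.detach_probability and rng.random() < well.detach_probability:
            cell.detach_frame = int(rng.integers(1, n_frames))
    for j in range(well.debris_count):
        cells.append(
            GroundTruthCell(
                cell_id=f"{well.well_id}:debris:{j}",
                well_id=well.well_id,
                class_label="debris",
                baseline_F=float(rng.uniform(200.0, 5000.0)),
                true_EC50=float("nan"),
                true_slope=float("nan"),
                true_dF=0.0,
                responder=False,
                radius=float(rng.uniform(1.2, 2.2)),
            )
        )
    return cells, rng


def ground_truth_frame(cells) -> pd.DataFrame:
    rows = []
    for c in cells:
        x, y = (c.center if c.center is not None else (float("nan"), float("nan")))
        rows.append(
            {
                "cell_id": c.cell_id,
                "well_id": c.well_id,
                "class_label": c.class_label,
                "x": x,
                "y": y,
                "radius": c.radius,
                "baseline_F": c.baseline_F,
                "true_EC50": c.true_EC50,
                "true_slope": c.true_slope,
                "true_dF": c.true_dF,
                "responder": c.responder,
                "detach_frame": -1 if c.detach_frame is None else c.detach_frame,
            }
        )
    return pd.DataFrame(rows)


def _debris_trace(cell, n_frames, rng):
    # non-sigmoidal frame-to-frame intensity: independent multiplicative jitter
    return cell.baseline_F * rng.uniform(0.4, 1.6, size=n_frames)


def generate_traces(well: WellSpec):
    """Per-cell dose-response traces plus the ground-truth table.

    Trace = noise-free response at each ladder point + additive Gaussian
    noise with sd = ``noise_sd_frac * baseline_F``.  Detaching cells drop to
    background level from their detach frame onward; debris produce
    non-sigmoidal traces.  Returns ``(trace_table, truth_table)`` joined on
    ``cell_id``.
    """
    cells, rng = _sample_well(well)
    conc = np.asarray(well.concentration_ladder, dtype=float)
    n_frames = len(conc)
    bg = background_level(cells)
    F = np.empty((len(cells), n_frames))
    for i, cell in enumerate(cells):
        if cell.class_label == "debris":
            trace = _debris_trace(cell, n_frames, rng)
        else:
            trace = true_response(cell, conc)
        if well.noise_sd_frac > 0:
            trace = trace + rng.normal(0.0, well.noise_sd_frac * cell.baseline_F,
                                       size=n_frames)
        if cell.detach_frame is not None:
            trace = trace.copy()
            trace[cell.detach_frame:] = bg + (
                rng.normal(0.0, well.noise_sd_frac * bg, size=n_frames - cell.detach_frame)
                if well.noise_sd_frac > 0 else 0.0
            )
        F[i] = trace
    traces = traces_to_frame([c.cell_id for c in cells], well.well_id, conc, F)
    return traces, ground_truth_frame(cells)


def _place_cells(cells, shape, rng, margin=3.0, max_tries=20000):
    """Rejection-sample non-overlapping disc centers on the field."""
    H, W = shape
    placed_xy = np.empty((0, 2))
    placed_r = np.empty(0)
    for cell in cells:
        r = cell.radius
        for _ in range(max_tries):
            x = rng.uniform(r + 1, W - r - 1)
            y = rng.uniform(r + 1, H - r - 1)
            if placed_xy.size:
                d = np.hypot(placed_xy[:, 0] - x, placed_xy[:, 1] - y)
                if np.any(d < placed_r + r + margin):
                    continue
            break
        else:
            raise PlacementError(
                f"could not place {len(cells)} objects on a {W}x{H} field"
            )
        cell.center = (float(x), float(y))
        placed_xy = np.vstack([placed_xy, [x, y]])
        placed_r = np.append(placed_r, r)


def _disc_mask(shape, x, y, r):
    H, W = shape
    x0, x1 = max(0, int(x - r - 1)), min(W, int(x + r + 2))
    y0, y1 = max(0, int(y - r - 1)), min(H, int(y + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - x) ** 2 + (yy - y) ** 2 <= r**2
    return yy[inside], xx[inside]


def render_image_series(well: WellSpec):
    """Draw the well's objects as 16-bit frames; returns (series, truth table).

    Each cell is a uniform disc whose value on frame k is its noise-free
    response at the ladder's k-th concentration (background after detaching);
    debris are small blobs with non-sigmoidal frame-to-frame intensity.
    Gaussian pixel noise (sd = ``noise_sd_frac`` x mean cell baseline) and a
    flat background are added, then values are clipped to the 16-bit range.
    """
    cells, rng = _sample_well(well)
    H, W = well.field_shape
    conc = np.asarray(well.concentration_ladder, dtype=float)
    n_frames = len(conc)
    _place_cells(cells, (H, W), rng)
    bg = background_level(cells)

    values = np.empty((len(cells), n_frames))
    for i, cell in enumerate(cells):
        if cell.class_label == "debris":
            values[i] = _debris_trace(cell, n_frames, rng)
        else:
            values[i] = true_response(cell, conc)
        if cell.detach_frame is not None:
            values[i, cell.detach_frame:] = bg

    masks = [_disc_mask((H, W), c.center[0], c.center[1], c.radius) for c in cells]
    mean_baseline = float(np.mean([c.baseline_F for c in cells
                                   if c.class_label != "debris"] or [2000.0]))
    frames = np.empty((n_frames, H, W), dtype=np.uint16)
    for k in range(n_frames):
        canvas = np.full((H, W), bg, dtype=float)
        for i, (yy, xx) in enumerate(masks):
            canvas[yy, xx] = values[i, k]
        if well.noise_sd_frac > 0:
            canvas += rng.normal(0.0, well.noise_sd_frac * mean_baseline, size=(H, W))
        frames[k] = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)
    series = ImageSeries(frames=frames, concentrations=conc, well_id=well.well_id)
    return series, ground_truth_frame(cells)
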