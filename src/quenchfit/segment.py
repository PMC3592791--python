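"""Cell identification by iterative size- and intensity-based thresholding.

Cells are segmented once, on the agonist-free control frame, where the
anion-sensitive reporter is unquenched and brightest.  The threshold starts
at a high intensity and is lowered stepwise; at each level, connected
components whose area falls inside the configured size gates are accepted
and masked out, so bright cells are claimed first and dimmer cells are
picked up as the threshold descends.  Accepted pixel sets are held fixed
across all frames of the series; cells that detach during perfusion are not
tracked but are removed downstream by the dose-response quality filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing, binary_dilation
from skimage.measure import label, regionprops

from .io import ImageSeries, traces_to_frame

__all__ = ["SegmentationParams", "SegmentedObject", "segment_reference", "measure_series"]


@dataclass
class SegmentationParams:
    """Controls for the descending-threshold sweep.

    ``threshold_start`` is an intensity percentile of the control frame;
    ``threshold_step`` an absolute intensity decrement (None: derived so the
    sweep spans start-to-floor in ``max_iterations`` steps).  The floor is a
    robust background estimate (median + 6 sigma via MAD).  Size gates are in
    pixels at the 2x2-binned 10x scale of a 696x520 field.
    ``central_fraction`` < 1 keeps only objects whose centroid lies in the
    central crop of the field.
    """

    threshold_start: float = 99.5
    threshold_step: float | None = None
    min_area: int = 20
    max_area: int = 800
    max_iterations: int = 25
    central_fraction: float = 1.0

    def validate(self):
        if not (0 < self.min_area < self.max_area):
            raise ValueError(f"need 0 < min_area < max_area (got {self.min_area}, {self.max_area})")
        if self.threshold_step is not None and self.threshold_step <= 0:
            raise ValueError(f"threshold_step must be > 0 (got {self.threshold_step})")
        if not (0 < self.central_fraction <= 1):
            raise ValueError(f"central_fraction must be in (0, 1] (got {self.central_fraction})")


@dataclass
class SegmentedObject:
    """One accepted object: fixed pixel set and per-frame mean intensities."""

    object_id: int
    coords: tuple  # (rows, cols) index arrays
    area: int
    centroid: tuple  # (x, y)
    mean_intensity_per_frame: np.ndarray | None = None


def _background_floor(img: np.ndarray) -> float:
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    return med + 6.0 * 1.4826 * mad


def segment_reference(frame0: np.ndarray, params: SegmentationParams | None = None):
    """Segment the control frame; returns (label map, list of SegmentedObject).

    Deterministic sweep: threshold at the start percentile, accept in-gate
    8-connected components, mask them out, lower the threshold, repeat until
    the background floor or the iteration cap.  An all-background image
    yields an empty result.
    """
    params = params or SegmentationParams()
    params.validate()
    img = np.asarray(frame0, dtype=float)
    start = float(np.percentile(img, params.threshold_start))
    floor = _background_floor(img)
    if start <= floor:
        return np.zeros(img.shape, dtype=np.int32), []
    if params.threshold_step is not None:
        thresholds = np.arange(start, floor - 1e-9, -params.threshold_step)
        thresholds = thresholds[: params.max_iterations]
    else:
        # descend from the start percentile all the way to the floor so dim
        # cells just above background are still swept
        thresholds = np.linspace(start, floor, params.max_iterations)

    claimed = np.zeros(img.shape, dtype=bool)
    labels_out = np.zeros(img.shape, dtype=np.int32)
    objects: list[SegmentedObject] = []
    struct = np.ones((3, 3), dtype=bool)
    for thr in thresholds:
        # closing bridges single-pixel noise gaps so one cell does not
        # fragment into several in-gate components at the same threshold
        mask = binary_closing(img >= thr, structure=struct)
        lab = label(mask, connectivity=2)
        for region in regionprops(lab):
            if params.min_area <= region.area <= params.max_area:
                rr, cc = region.coords[:, 0], region.coords[:, 1]
                # a component overlapping or hugging (within 2 px of) an
                # already-accepted object is that object's halo or a noise
                # fragment of it, not a new cell; checked on a local window
                # so fragments of the same cell in one sweep step are caught
                r0, c0 = max(int(rr.min()) - 2, 0), max(int(cc.min()) - 2, 0)
                win = claimed[r0:int(rr.max()) + 3, c0:int(cc.max()) + 3]
                if win.any() and binary_dilation(
                    win, structure=struct, iterations=2
                )[rr - r0, cc - c0].any():
                    continue
                oid = len(objects) + 1
                labels_out[rr, cc] = oid
                claimed[rr, cc] = True
                cy, cx = region.centroid
                objects.append(
                    SegmentedObject(
                        object_id=oid,
                        coords=(rr, cc),
                        area=int(region.area),
                        centroid=(float(cx), float(cy)),
                    )
                )

    if params.central_fraction < 1.0:
        H, W = img.shape
        fy = 0.5 * (1 - params.central_fraction) * H
        fx = 0.5 * (1 - params.central_fraction) * W
        kept = []
        for obj in objects:
            x, y = obj.centroid
            if fx <= x <= W - fx and fy <= y <= H - fy:
                kept.append(obj)
            else:
                rr, cc = obj.coords
                labels_out[rr, cc] = 0
        objects = kept
    return labels_out, objects


def measure_series(objects, series: ImageSeries) -> pd.DataFrame:
    """Mean intensity of each fixed pixel set on every frame of the series.

    Returns the interchange trace table (cell_id, well_id, x, y, area,
    F_<conc>...), one row per object, paired with each frame's agonist
    concentration.
    """
    frames = np.asarray(series.frames, dtype=float)
    if objects:
        rr, cc = objects[0].coords
        if rr.max() >= frames.shape[1] or cc.max() >= frames.shape[2]:
            raise ValueError("label map does not match frame shape")
    F = np.empty((len(objects), len(frames)))
    for i, obj in enumerate(objects):
        rr, cc = obj.coords
        F[i] = frames[:, rr, cc].mean(axis=1)
        obj.mean_intensity_per_frame = F[i]
    table = traces_to_frame([o.object_id for o in objects], series.well_id,
                            series.concentrations, F)
    table.insert(2, "x", [o.centroid[0] for o in objects])
    table.insert(3, "y", [o.centroid[1] for o in objects])
    table.insert(4, "area", [o.area for o in objects])
    return table
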