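"""Format plumbing: trace/fit CSV, multi-page TIFF image series, scenarios.

Interchange formats between pipeline stages are deliberately plain text:
CSV with header rows for tables, JSON for reports and sidecars, YAML for
scenario configuration.  Trace tables carry one row per cell and one
fluorescence column per ladder point, named ``F_<concentration>`` (µM, ``%g``
formatting) so the ladder round-trips through the header.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageSeries",
    "FormatError",
    "trace_column",
    "trace_concentrations",
    "traces_to_frame",
    "write_trace_csv",
    "read_trace_csv",
    "write_fit_csv",
    "read_fit_csv",
    "write_image_series",
    "read_image_series",
    "load_scenario",
    "substream",
    "derive_seed",
]


class FormatError(ValueError):
    """Malformed or inconsistent on-disk artifact."""


@dataclass
class ImageSeries:
    """Ordered frames of one well with per-frame agonist concentration."""

    frames: np.ndarray          # (n_frames, H, W)
    concentrations: np.ndarray  # µM, first entry 0 (agonist-free control)
    well_id: str = "A1"

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (n, H, W) stack")
        if len(self.concentrations) != len(self.frames):
            raise FormatError(
                f"{len(self.frames)} frames vs {len(self.concentrations)} concentrations"
            )
        if self.concentrations[0] != 0:
            raise FormatError("first frame must be the agonist-free control (c=0)")


def trace_column(c: float) -> str:
    return f"F_{c:g}"


def trace_concentrations(df: pd.DataFrame):
    """Recover (ladder, column names) from a trace table's F_* columns."""
    cols = [c for c in df.columns if c.startswith("F_")]
    if not cols:
        raise FormatError("no F_<conc> trace columns found")
    try:
        conc = np.array([float(c[2:]) for c in cols])
    except ValueError as e:
        raise FormatError(f"malformed trace column name: {e}") from None
    order = np.argsort(conc)
    conc = conc[order]
    cols = [cols[i] for i in order]
    return conc, cols


def traces_to_frame(cell_ids, well_id, conc, F) -> pd.DataFrame:
    """Assemble the interchange trace table from an (n_cells, n_frames) array."""
    F = np.asarray(F, dtype=float)
    df = pd.DataFrame({"cell_id": cell_ids, "well_id": well_id})
    for j, c in enumerate(np.asarray(conc, dtype=float)):
        df[trace_column(c)] = F[:, j]
    return df


def write_trace_csv(df: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def read_trace_csv(path, drop_nan: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise FormatError(f"{path}: missing cell_id column")
    conc, cols = trace_concentrations(df)
    bad = df[cols].isna().any(axis=1)
    if bad.any() and drop_nan:
        import warnings

        warnings.warn(
            f"{path}: dropped {int(bad.sum())} row(s) with NaN fluorescence "
            f"(rows {list(df.index[bad])})",
            stacklevel=2,
        )
        df = df[~bad].reset_index(drop=True)
    return df


FIT_COLUMNS = ["cell_id", "F_max", "F_min", "ec50", "slope", "r2", "dF", "converged"]


def write_fit_csv(df: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def read_fit_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing fit columns {missing}")
    for col in ("F_max", "F_min", "ec50", "slope", "r2", "dF"):
        df[col] = df[col].astype(float)
    return df


def write_image_series(series: ImageSeries, tiff_path):
    """Multi-page 16-bit grayscale TIFF plus a JSON concentration sidecar."""
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(tiff_path, series.frames.astype(np.uint16))
    sidecar = tiff_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "well_id": series.well_id,
                "concentrations_uM": [float(c) for c in series.concentrations],
            },
            indent=2,
        )
        + "\n"
    )
    return tiff_path, sidecar


def read_image_series(tiff_path) -> ImageSeries:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = tiff_path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing concentration sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    conc = meta.get("concentrations_uM")
    if conc is None:
        raise FormatError(f"{sidecar}: missing concentrations_uM")
    if len(conc) != len(frames):
        raise FormatError(
            f"{tiff_path}: {len(frames)} TIFF pages but sidecar lists "
            f"{len(conc)} concentrations"
        )
    return ImageSeries(frames=frames, concentrations=np.asarray(conc),
                       well_id=meta.get("well_id", tiff_path.stem))


def load_scenario(path) -> dict:
    """Load and minimally validate a scenario YAML."""
    with open(path) as fh:
        scenario = yaml.safe_load(fh)
    if not isinstance(scenario, dict) or "wells" not in scenario:
        raise FormatError(f"{path}: scenario must be a mapping with a 'wells' list")
    return scenario


def derive_seed(seed: int, *tags) -> int:
    """Deterministic per-stage/per-well child seed below 2**31."""
    h = zlib.crc32("/".join(str(t) for t in tags).encode())
    return int(np.random.SeedSequence([int(seed), h]).generate_state(1)[0] % (2**31))


def substream(seed: int, *tags) -> np.random.Generator:
    """Named random substream derived from the single global seed."""
    h = zlib.crc32("/".join(str(t) for t in tags).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))
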