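"""Quality filtering of fitted dose-responses.

Four empirically motivated acceptance criteria separate functional cells
from debris, reporter-only cells and detached cells:

* goodness of fit R² >= 0.9,
* dynamic range ΔF in 20-100 % (cells expressing both reporter and channel),
* Hill slope in 0.5-5 (physiologically plausible steepness),
* EC50 in 0.3-3000 µM (the workable assay window).

All windows are closed intervals; a cell is accepted only if it passes all
four, and fits that did not converge fail every criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FilterCriteria", "FilterReport", "CRITERIA", "apply_filters", "filter_report"]

CRITERIA = ("r2", "dF", "slope", "ec50")


@dataclass
class FilterCriteria:
    r2_min: float = 0.9
    dF_window: tuple = (20.0, 100.0)
    slope_window: tuple = (0.5, 5.0)
    ec50_window: tuple = (0.3, 3000.0)

    def validate(self):
        for name in ("dF_window", "slope_window", "ec50_window"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is empty: {lo} > {hi}")


@dataclass
class FilterReport:
    n_total: int
    n_pass_per_criterion: dict
    n_pass_combined: int
    pct_per_criterion: dict = field(default_factory=dict)
    pct_combined: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_pass_per_criterion": self.n_pass_per_criterion,
            "n_pass_combined": self.n_pass_combined,
            "pct_per_criterion": self.pct_per_criterion,
            "pct_combined": self.pct_combined,
        }


def _inside(values, lo, hi):
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        ok = (v >= lo) & (v <= hi)
    return ok & np.isfinite(v)


def apply_filters(fits: pd.DataFrame, criteria: FilterCriteria | None = None) -> pd.DataFrame:
    """Add per-criterion and combined boolean accept columns to a fit table.

    NaN values (e.g. the undefined-R² sentinel of a flat trace) and
    non-converged fits fail everything.  Empty input yields empty output.
    """
    criteria = criteria or FilterCriteria()
    criteria.validate()
    out = fits.copy()
    n = len(out)
    if n == 0:
        for c in CRITERIA:
            out[f"pass_{c}"] = pd.Series(dtype=bool)
        out["pass_all"] = pd.Series(dtype=bool)
        return out
    converged = out["converged"].astype(bool).to_numpy() if "converged" in out else np.ones(n, bool)
    out["pass_r2"] = _inside(out["r2"], criteria.r2_min, np.inf) & converged
    out["pass_dF"] = _inside(out["dF"], *criteria.dF_window) & converged
    out["pass_slope"] = _inside(out["slope"], *criteria.slope_window) & converged
    out["pass_ec50"] = _inside(out["ec50"], *criteria.ec50_window) & converged
    out["pass_all"] = out["pass_r2"] & out["pass_dF"] & out["pass_slope"] & out["pass_ec50"]
    return out


def filter_report(flagged: pd.DataFrame) -> FilterReport:
    """Counts and percentages of cells passing each criterion and all combined."""
    n = len(flagged)
    per = {c: int(flagged[f"pass_{c}"].sum()) for c in CRITERIA} if n else {c: 0 for c in CRITERIA}
    combined = int(flagged["pass_all"].sum()) if n else 0
    pct = {c: 100.0 * per[c] / n if n else float("nan") for c in CRITERIA}
    return FilterReport(
        n_total=n,
        n_pass_per_criterion=per,
        n_pass_combined=combined,
        pct_per_criterion=pct,
        pct_combined=100.0 * combined / n if n else float("nan"),
    )
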