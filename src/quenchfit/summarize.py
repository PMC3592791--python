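"""Well- and plate-level aggregation of accepted single-cell fits.

Per-well EC50 is reported as median ± SEM (sd/sqrt(n)), with 5/25/75/95 %
quantiles for box plots.  Two-group comparisons use the unpaired Student's
t-test on per-cell EC50 values (Welch correction and log-scale testing are
optional, off by default).  A plate map arranges well medians on the
row-letter x column-number grid for color-map reporting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WellSummary", "well_summary", "compare_groups", "plate_matrix", "render_plate_map"]

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


@dataclass
class WellSummary:
    well_id: str
    n_accepted: int
    n_rejected: int
    ec50_median: float = float("nan")
    ec50_sem: float = float("nan")
    slope_median: float = float("nan")
    dF_median: float = float("nan")
    quantiles: dict = field(default_factory=dict)  # {5: .., 25: .., 75: .., 95: ..}
    degenerate: bool = False  # <2 accepted cells: statistics flagged

    def as_dict(self) -> dict:
        d = {
            "well_id": self.well_id,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "ec50_median": self.ec50_median,
            "ec50_sem": self.ec50_sem,
            "slope_median": self.slope_median,
            "dF_median": self.dF_median,
            "degenerate": self.degenerate,
        }
        d.update({f"ec50_q{q}": v for q, v in self.quantiles.items()})
        return d


def well_summary(flagged: pd.DataFrame, well_id: str | None = None) -> WellSummary:
    """Summarize one well's filtered fit table (expects pass_all column).

    Zero accepted cells yields a flagged summary with NaN statistics rather
    than an exception; a single cell reports SEM = 0 by convention.
    """
    if well_id is None:
        well_id = str(flagged["well_id"].iloc[0]) if len(flagged) and "well_id" in flagged else "?"
    accepted = flagged[flagged["pass_all"]] if "pass_all" in flagged else flagged
    n_acc, n_rej = len(accepted), len(flagged) - len(accepted)
    if n_acc == 0:
        return WellSummary(well_id, 0, n_rej, degenerate=True)
    ec50 = accepted["ec50"].to_numpy(dtype=float)
    sem = float(np.std(ec50, ddof=1) / np.sqrt(n_acc)) if n_acc > 1 else 0.0
    qs = np.percentile(ec50, [5, 25, 75, 95])
    return WellSummary(
        well_id=well_id,
        n_accepted=n_acc,
        n_rejected=n_rej,
        ec50_median=float(np.median(ec50)),
        ec50_sem=sem,
        slope_median=float(accepted["slope"].median()),
        dF_median=float(accepted["dF"].median()),
        quantiles={5: qs[0], 25: qs[1], 75: qs[2], 95: qs[3]},
        degenerate=n_acc < 2,
    )


def compare_groups(ec50_a, ec50_b, welch: bool = False, log_scale: bool = False,
                   alpha: float = 0.05):
    """Unpaired two-sample t-test on per-cell EC50 values.

    Returns (t, p, significant) with significant = p < alpha.  Both groups
    need at least two values.
    """
    a = np.asarray(ec50_a, dtype=float)
    b = np.asarray(ec50_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if log_scale:
        a, b = np.log10(a), np.log10(b)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(t) and np.allclose(a.mean(), b.mean()):
        t, p = 0.0, 1.0  # zero variance in both groups, identical means
    return float(t), float(p), bool(p < alpha)


def _split_well(well_id: str):
    m = _WELL_RE.match(well_id)
    if not m:
        raise ValueError(f"well id {well_id!r} is not RowLetter+ColumnNumber")
    return m.group(1).upper(), int(m.group(2))


def plate_matrix(summaries, value: str = "ec50_median") -> pd.DataFrame:
    """Arrange well summaries on the plate grid; NaN marks empty wells.

    ``summaries`` is an iterable of WellSummary (or dicts).  Duplicate well
    coordinates are an error.
    """
    cells = {}
    for s in summaries:
        d = s.as_dict() if isinstance(s, WellSummary) else dict(s)
        row, col = _split_well(d["well_id"])
        if (row, col) in cells:
            raise ValueError(f"duplicate well {d['well_id']}")
        cells[(row, col)] = d.get(value, float("nan"))
    if not cells:
        return pd.DataFrame()
    rows = sorted({r for r, _ in cells})
    cols = sorted({c for _, c in cells})
    mat = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for (r, c), v in cells.items():
        mat.loc[r, c] = v
    return mat


def render_plate_map(matrix: pd.DataFrame, path, low_is_warm: bool = True,
                     title: str = "median EC50 (uM)"):
    """Color-map PNG of a plate matrix.

    ``low_is_warm`` orients the scale (warm colors = low EC50, i.e. no drug
    block); flip it for the opposite convention.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(matrix.columns), 1 + 0.6 * len(matrix)))
    cmap = "coolwarm_r" if low_is_warm else "coolwarm"
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap=cmap, aspect="equal")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, metadata={"Software": "quenchfit"})
    plt.close(fig)
    return path
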