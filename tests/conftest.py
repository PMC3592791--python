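import numpy as np
import pytest

from quenchfit import synth


@pytest.fixture(scope="session")
def ladder():
    return np.array(synth.DEFAULT_LADDER)


@pytest.fixture
def alpha2_pop():
    """Population resembling a mid-potency homomeric receptor (EC50 49 uM)."""
    return synth.PopulationSpec(name="alpha2", ec50_median=49.0, n_cells=100)


def make_well(pop, *, well_id="A1", seed=7, **kwargs):
    defaults = dict(debris_count=0, detach_probability=0.0, noise_sd_frac=0.0)
    defaults.update(kwargs)
    return synth.WellSpec(well_id=well_id, populations=[(pop, 1.0)], seed=seed,
                          **defaults)


@pytest.fixture
def clean_well(alpha2_pop):
    """Noise-free single-population well: every trace equals the true response."""
    return make_well(alpha2_pop)


def match_detections(objects, truth):
    """Greedy matching of detected centroids to true cell centers within radius.

    Returns (recall, precision) against the non-debris rows of the truth table.
    """
    cells = truth[truth.class_label != "debris"]
    cx = cells.x.to_numpy()
    cy = cells.y.to_numpy()
    cr = cells.radius.to_numpy()
    matched = np.zeros(len(cells), dtype=bool)
    fp = 0
    for obj in objects:
        d = np.hypot(cx - obj.centroid[0], cy - obj.centroid[1])
        i = int(np.argmin(d))
        if d[i] <= cr[i] and not matched[i]:
            matched[i] = True
        else:
            fp += 1
    recall = matched.sum() / len(cells) if len(cells) else float("nan")
    precision = (len(objects) - fp) / len(objects) if objects else float("nan")
    return recall, precision
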