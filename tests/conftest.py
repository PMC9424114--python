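import numpy as np
import pandas as pd
import pytest

from tregspatial import MarkerThresholds, SampleCellTable, TissueOutline
from tregspatial.cohort import DEFAULT_THRESHOLDS


@pytest.fixture
def default_thresholds():
    return MarkerThresholds({("*", m): t for m, t in DEFAULT_THRESHOLDS.items()})


def make_table(coords, markers=None, sample_id="S1", series_id="1", regions=None,
               outline=None, core_diameter_mm=1.0):
    """Small hand-built cell table for unit tests."""
    coords = np.asarray(coords, float)
    n = len(coords)
    cells = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]})
    cells["region"] = regions if regions is not None else "unassigned"
    for name, vals in (markers or {}).items():
        cells[name] = np.asarray(vals, float)
    return SampleCellTable(
        sample_id=sample_id, series_id=series_id, cells=cells,
        core_diameter_mm=core_diameter_mm, outline=outline,
    )


@pytest.fixture
def disc_outline():
    return TissueOutline.disc(1.0)
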