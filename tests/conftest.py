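import numpy as np
import pytest

from rtkquant.datatypes import CellMeasurement


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_cells(expr, phospho):
    """Build CellMeasurement list with roi2 = 0 so I_m equals the given values."""
    return [
        CellMeasurement(
            cell_id=f"c{i}",
            expr_roi1=float(e),
            expr_roi2=0.0,
            phospho_roi1=float(p),
            phospho_roi2=0.0,
        )
        for i, (e, p) in enumerate(zip(expr, phospho))
    ]
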