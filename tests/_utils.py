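"""Small helpers shared by the test modules."""

import numpy as np
import pandas as pd

from identestim.sensitivity import SensitivityMatrix


def matrix_from_columns(B, names=None):
    """Wrap bare columns in a SensitivityMatrix (records are synthetic)."""
    B = np.asarray(B, dtype=float)
    n, p = B.shape
    names = tuple(names or (f"p{j}" for j in range(p)))
    records = pd.DataFrame(
        {"time": np.arange(n, dtype=float), "variable": "y", "value": 0.0}
    )
    return SensitivityMatrix(
        raw=B,
        normalized=B,
        parameter_names=names,
        records=records,
        evaluation_point=dict.fromkeys(names, 1.0),
        predictions=np.zeros(n),
    )
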