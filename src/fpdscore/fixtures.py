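"""Packaged 5x5 confusion-matrix fixtures (human vs automated scores).

``table3a`` is the pre-modification cross-tabulation (n = 2,646, human vs
AUT1); ``table3b`` the post-modification one (n = 2,510, human vs AUT2).
Rows are the human scores, columns the automated scores.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .agreement import ConfusionMatrix

_AXIS_B = {"table3a": "AUT1", "table3b": "AUT2"}


def available_fixtures() -> tuple[str, ...]:
    return tuple(sorted(_AXIS_B))


def load_confusion(name: str) -> ConfusionMatrix:
    """Load a packaged confusion-matrix fixture by name."""
    if name not in _AXIS_B:
        raise KeyError(f"unknown fixture {name!r}; have {available_fixtures()}")
    with resources.files("fpdscore.data").joinpath(f"{name}.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    counts = np.asarray(df.values, dtype=np.int64)
    return ConfusionMatrix(counts, axis_a="HUM", axis_b=_AXIS_B[name], levels=(0, 1, 2, 3, 4))
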