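"""Internal: accept either a RatioMatrix-like object or a plain DataFrame."""

from __future__ import annotations

import pandas as pd


def as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    values = getattr(matrix, "values", None)
    if isinstance(values, pd.DataFrame):
        return values
    raise TypeError(f"expected a RatioMatrix or DataFrame, got {type(matrix).__name__}")
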