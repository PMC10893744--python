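"""Display rounding.

All model arithmetic is real-valued; integers exist only at display/report
time. The display convention is round half away from zero (so 148.5 cases
print as 149), which is the convention commercial spreadsheets apply and the
one that reproduces the published tables. Python's built-in round() is
banker's rounding and would print 148.5 as 148.
"""

from __future__ import annotations

import numpy as np


def display_round(x):
    """Round half away from zero.

    Accepts scalars or array-likes; returns a float scalar or ndarray of
    integral floats (cast at the call site when an int dtype is needed).
    """
    arr = np.asarray(x, dtype=float)
    out = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def display_int(x) -> int:
    """Round half away from zero and cast to a Python int (scalar only)."""
    return int(display_round(float(x)))
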