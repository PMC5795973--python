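"""Efficiency-adjusted transformation of Cp values to log2 expression scale.

A well with quantification cycle Cp and per-cycle amplification factor E
started from an amount of template proportional to E^-Cp.  Taking -log2 gives

    y = -log2(E^-Cp) = Cp * log2(E)

so y lives on the log2 scale regardless of each assay's efficiency, and a
*larger* y means *lower* expression.  Computing ``cp * log2(E)`` directly is
algebraically identical to exponentiating first and avoids underflow of
E^-Cp at large Cp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["transform", "transform_all"]


def transform(cp, efficiency):
    """Transform Cp (cycles) to y = cp * log2(E) (log2 units).

    ``efficiency`` is the amplification factor E in (1, 2]; E = 2 is perfect
    doubling, for which y equals Cp exactly.  Accepts scalars or arrays.
    """
    eff = np.asarray(efficiency, float)
    if np.any(eff <= 1.0):
        raise ValueError("amplification factor must exceed 1 (non-amplifying reaction)")
    if np.any(np.asarray(cp, float) < 0):
        raise ValueError("cp must be non-negative")
    out = np.asarray(cp, float) * np.log2(eff)
    return float(out) if out.ndim == 0 else out


def transform_all(wells: pd.DataFrame, efficiencies: dict[str, float]) -> pd.DataFrame:
    """Apply :func:`transform` per well, matching each gene to its efficiency.

    Returns a copy of ``wells`` with an extra ``y`` column; all labels are
    preserved, one output row per input well.
    """
    missing = sorted(set(wells["gene"].unique()) - set(efficiencies))
    if missing:
        raise ValueError(f"genes without an efficiency: {missing}")
    out = wells.copy()
    eff = out["gene"].map(efficiencies).to_numpy(float)
    out["y"] = transform(out["cp"].to_numpy(float), eff)
    return out
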