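"""Diagnostic plots for flagged substances.

One figure style per predictor: boxplots of the response by cycle state or
parity, and a scatter against age with the substance's conditional-mode
slope overlaid.  Matplotlib is imported lazily so the statistical modules
carry no plotting dependency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_substance_effect"]


def plot_substance_effect(
    y: pd.DataFrame,
    metadata: pd.DataFrame,
    substance: str,
    predictor: str,
    slope: float | None = None,
    ax=None,
):
    """Plot one substance's response against a test predictor.

    ``y`` is a samples x substances response matrix (any transform),
    ``metadata`` the per-sample table (``sample_id``, ``cycle_state``,
    ``age``, ``parity``).  For ``age`` the optional ``slope`` (per z-scored
    year, e.g. the screened conditional mode) is drawn through the mean.
    Returns the matplotlib axes.
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg")  # headless default; caller may pass own axes
    import matplotlib.pyplot as plt

    if substance not in y.columns:
        raise ValueError(f"unknown substance {substance!r}")
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta.loc[y.index]
    vals = y[substance]

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))

    if predictor in ("cycle", "cycle_state", "parity"):
        col = "cycle_state" if predictor.startswith("cycle") else "parity"
        levels = list(pd.unique(meta[col]))
        ax.boxplot(
            [vals[meta[col] == lv] for lv in levels],
            tick_labels=levels,
            showfliers=False,
        )
        ax.set_xlabel(col.replace("_", " "))
    elif predictor == "age":
        ages = meta["age"].astype(float)
        ax.scatter(ages, vals, s=12, alpha=0.6)
        if slope is not None:
            # slope is per z-scored year; z-scoring used female-level ages
            if "female" in meta.columns:
                sd = meta.drop_duplicates("female")["age"].astype(float).std(ddof=1)
            else:
                sd = ages.std(ddof=1)
            sd = sd if sd and np.isfinite(sd) else 1.0
            xs = np.linspace(ages.min(), ages.max(), 50)
            ax.plot(xs, vals.mean() + slope * (xs - ages.mean()) / sd, "--", lw=1.5)
        ax.set_xlabel("age (years)")
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    ax.set_ylabel(substance)
    return ax
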