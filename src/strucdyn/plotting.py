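"""Minimal plotting helpers for fitted association results."""

from __future__ import annotations

import numpy as np
from scipy import stats


def _rank_residual_pair(results, feature):
    model = results.model
    region_feat = model.features.groupby(level=-1).mean()[feature]
    s_mean = model.strengths.groupby(level=-1).mean().loc[region_feat.index]
    vols = model.volumes.loc[region_feat.index]
    rz = stats.rankdata(vols.values)
    design = np.column_stack([np.ones_like(rz), rz])

    def resid(v):
        rv = stats.rankdata(v)
        beta, *_ = np.linalg.lstsq(design, rv, rcond=None)
        return rv - design @ beta

    return resid(s_mean.values), resid(region_feat.values)


def rank_residual_scatter(results, feature: str = "rlfp", ax=None):
    """Scatter of rank residuals of strength vs a feature after regressing
    out region-volume ranks (the visual form of the partial Spearman)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    ex, ey = _rank_residual_pair(results, feature)
    rho = results.group.loc[feature, "rho_v"]
    ax.scatter(ex, ey, s=25, alpha=0.8)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("node strength (rank residuals | volume)")
    ax.set_ylabel(f"{feature} (rank residuals | volume)")
    ax.set_title(f"group-level rho_V = {rho:+.2f}")
    return ax


def individual_rho_hist(results, feature: str = "rlfp", ax=None):
    """Histogram of per-subject rho_V with the group value marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    rhos = results.sweeps[feature].table["rho_v"].values
    ax.hist(rhos, bins=20, color="steelblue", alpha=0.85)
    ax.axvline(
        results.group.loc[feature, "rho_v"], color="crimson", lw=2, label="group"
    )
    ax.set_xlabel(f"per-subject rho_V ({feature})")
    ax.set_ylabel("count")
    ax.legend()
    return ax
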