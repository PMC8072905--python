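"""Goodness-of-fit diagnostics for the proportional error model.

The individual weighted residual of an observation is
IWRES = (observed - predicted) / (sigma * predicted), which is standard
normal for a correctly specified model, so about 95.4% of residuals should
fall within [-2, 2]. The tested surface is numeric (tables and summaries);
plotting helpers are optional conveniences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import SubjectDataset
from .fitting import FitResult
from .model import ModelStructureError

__all__ = ["compute_iwres", "gof_tables", "plot_gof"]


def compute_iwres(observed, predicted, sigma: float):
    """Individual weighted residuals (obs - pred) / (sigma * pred)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if np.any(predicted <= 0):
        raise ValueError("predictions must be > 0")
    res = (observed - predicted) / (sigma * predicted)
    return float(res) if res.ndim == 0 else res


def gof_tables(fit: FitResult, data: SubjectDataset
               ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-point GoF records plus summary statistics for one fitted subject.

    Raises :class:`ModelStructureError` when the fit and dataset are not
    aligned (different subject, times or observed values). The summary
    holds the fraction of |IWRES| <= 2, mean and SD of IWRES, and the
    slope/intercept of the observed-on-predicted regression.
    """
    if fit.data_checksum != data.checksum():
        raise ModelStructureError(
            f"fit of {fit.subject_id!r} does not match dataset "
            f"{data.subject_id!r}")
    obs_df = data.observed()
    preds = fit.predictions
    if (len(preds) != len(obs_df)
            or not np.allclose(preds["time_h"], obs_df["time_h"])
            or not np.allclose(preds["observed"], obs_df["conc_ng_ml"])):
        raise ModelStructureError("fit predictions misaligned with dataset")
    records = pd.DataFrame({
        "subject_id": data.subject_id,
        "time_h": preds["time_h"].to_numpy(),
        "observed": preds["observed"].to_numpy(),
        "predicted": preds["predicted"].to_numpy(),
        "iwres": compute_iwres(preds["observed"], preds["predicted"],
                               fit.params.sigma),
    })
    slope, intercept = np.polyfit(records["predicted"], records["observed"], 1)
    iwres = records["iwres"].to_numpy()
    summary = {
        "n": float(len(records)),
        "frac_iwres_within_2": float(np.mean(np.abs(iwres) <= 2.0)),
        "mean_iwres": float(np.mean(iwres)),
        "sd_iwres": float(np.std(iwres, ddof=1)) if iwres.size > 1 else 0.0,
        "obs_on_pred_slope": float(slope),
        "obs_on_pred_intercept": float(intercept),
    }
    return records, summary


def plot_gof(records: pd.DataFrame, path_prefix: str) -> list[str]:
    """Write observed-vs-predicted, IWRES-vs-time and IWRES-vs-predicted
    scatter plots as PNG files; returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    panels = [
        ("predicted", "observed", "obs_vs_pred", True),
        ("time_h", "iwres", "iwres_vs_time", False),
        ("predicted", "iwres", "iwres_vs_pred", False),
    ]
    for x, y, name, unity in panels:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(records[x], records[y], s=12)
        if unity:
            lim = [0, max(records[x].max(), records[y].max()) * 1.05]
            ax.plot(lim, lim, "k--", lw=0.8)
        else:
            ax.axhline(0, color="k", lw=0.8)
            ax.axhline(2, color="r", lw=0.6, ls=":")
            ax.axhline(-2, color="r", lw=0.6, ls=":")
        ax.set_xlabel(x)
        ax.set_ylabel(y)
        fig.tight_layout()
        out = f"{path_prefix}_{name}.png"
        fig.savefig(out, dpi=100)
        plt.close(fig)
        written.append(out)
    return written
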