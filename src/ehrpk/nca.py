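"""Non-compartmental analysis and derived dose/bioavailability arithmetic.

Covers the model-free quantities reported for the rat study: linear
trapezoidal AUC from 0 to 48 h, terminal half-life from a log-linear
regression on the last three quantifiable points, Cmax/Tmax, absolute
bioavailability as a dose-normalized AUC ratio against IV, and the patch /
tongue dose-accounting percentages.

BLQ handling follows standard practice: records below the limit of
quantification are set to 0 before the first quantifiable point and
excluded afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import SubjectDataset

__all__ = ["NcaSummary", "HalfLifeResult", "DoseAccounting", "auc_trapz",
           "terminal_half_life", "f_abs", "released_dose_fraction",
           "tongue_dose_percent", "nca_subject", "nca_route_table"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class HalfLifeResult:
    """Terminal half-life estimate with reliability flags.

    ``t_half`` is ln2/|slope| of the log-linear tail regression; it is
    +inf for a flat tail and is flagged unreliable when the tail is not
    declining (slope >= 0) or the regression is poor (R^2 < 0.8).
    """
    t_half: float
    slope: float
    r_squared: float
    reliable: bool
    n_points: int


@dataclass(frozen=True)
class NcaSummary:
    """Per-subject non-compartmental metrics."""
    subject_id: str
    route: str
    auc_0_48: float
    t_half: float
    t_half_reliable: bool
    cmax: float
    tmax: float
    n_points_used: int


@dataclass(frozen=True)
class DoseAccounting:
    """Absolute amounts (micrograms) for patch/tongue dose accounting."""
    nominal_dose_ug: float
    patch_residue_ug: float | None = None
    tongue_amount_ug: float | None = None
    tongue_conc_ug_g: float | None = None

    def __post_init__(self) -> None:
        for name in ("nominal_dose_ug", "patch_residue_ug",
                     "tongue_amount_ug", "tongue_conc_ug_g"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if (self.patch_residue_ug is not None
                and self.patch_residue_ug > self.nominal_dose_ug):
            raise ValueError("patch residue cannot exceed the nominal dose")

    @property
    def residue_percent(self) -> float:
        if self.patch_residue_ug is None:
            raise ValueError("no patch residue recorded")
        return 100.0 * self.patch_residue_ug / self.nominal_dose_ug

    @property
    def tongue_percent(self) -> float:
        if self.tongue_amount_ug is None:
            raise ValueError("no tongue amount recorded")
        return tongue_dose_percent(self.tongue_amount_ug,
                                   self.nominal_dose_ug)


def _apply_blq(times: np.ndarray, concs: np.ndarray,
               blq: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Zero BLQ records before the first quantifiable point, drop the rest."""
    if blq is None:
        return times, concs
    blq = np.asarray(blq, dtype=bool)
    if not (~blq).any():
        raise ValueError("no quantifiable concentrations")
    first_q = np.argmax(~blq)
    keep = ~blq
    keep[:first_q] = True
    concs = np.where(blq, 0.0, concs)
    return times[keep], concs[keep]


def auc_trapz(times, concs, t_end: float = 48.0, blq=None) -> float:
    """Linear trapezoidal AUC (ng*h/mL) from the first time to ``t_end``.

    ``t_end`` must not exceed the last retained time; if it falls between
    observations the profile is interpolated linearly.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.shape != concs.shape or times.ndim != 1:
        raise ValueError("times and concs must be matching 1-d arrays")
    times, concs = _apply_blq(times, concs, blq)
    if times.size < 2:
        raise ValueError("AUC needs at least 2 points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(concs < 0):
        raise ValueError("concentrations must be >= 0")
    if t_end > times[-1]:
        raise ValueError(f"t_end={t_end} beyond last observation {times[-1]}")
    mask = times <= t_end
    t_seg = times[mask]
    c_seg = concs[mask]
    if t_seg[-1] < t_end:
        c_interp = float(np.interp(t_end, times, concs))
        t_seg = np.append(t_seg, t_end)
        c_seg = np.append(c_seg, c_interp)
    return float(np.trapezoid(c_seg, t_seg))


def terminal_half_life(times, concs, n_tail: int = 3,
                       blq=None) -> HalfLifeResult:
    """Half-life from a log-linear least-squares fit of the last ``n_tail``
    quantifiable positive concentrations: t1/2 = ln2 / |slope|."""
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if blq is not None:
        keep = ~np.asarray(blq, dtype=bool)
        times, concs = times[keep], concs[keep]
    pos = concs > 0
    times, concs = times[pos], concs[pos]
    if times.size < n_tail:
        raise ValueError(f"need at least {n_tail} positive concentrations")
    t = times[-n_tail:]
    y = np.log(concs[-n_tail:])
    slope, intercept = np.polyfit(t, y, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    flat = np.allclose(np.diff(y), 0.0)
    if flat or slope == 0:
        return HalfLifeResult(math.inf, float(slope), r2, False, n_tail)
    t_half = LN2 / abs(float(slope))
    reliable = slope < 0 and r2 >= 0.8
    return HalfLifeResult(t_half, float(slope), r2, reliable, n_tail)


def f_abs(mean_auc_test: float, mean_auc_iv: float,
          dose_test: float, dose_iv: float) -> float:
    """Absolute bioavailability (%):
    100 * (AUC_test * Dose_iv) / (AUC_iv * Dose_test)."""
    for name, v in (("mean_auc_test", mean_auc_test),
                    ("mean_auc_iv", mean_auc_iv),
                    ("dose_test", dose_test), ("dose_iv", dose_iv)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    return 100.0 * (mean_auc_test * dose_iv) / (mean_auc_iv * dose_test)


def released_dose_fraction(residue_percent: float) -> float:
    """Percent of the dose released from the dosage form, 100 - residue%."""
    if not 0 <= residue_percent <= 100:
        raise ValueError("residue percent must be in [0, 100]")
    return 100.0 - residue_percent


def tongue_dose_percent(tongue_amount_ug: float,
                        nominal_dose_ug: float) -> float:
    """Tongue-retained amount as a percentage of the nominal dose."""
    if tongue_amount_ug <= 0 or nominal_dose_ug <= 0:
        raise ValueError("amounts must be > 0")
    return 100.0 * tongue_amount_ug / nominal_dose_ug


def nca_subject(data: SubjectDataset, t_end: float = 48.0,
                n_tail: int = 3) -> NcaSummary:
    """Non-compartmental metrics for one subject's dataset."""
    rec = data.records
    times = rec["time_h"].to_numpy()
    concs = rec["conc_ng_ml"].to_numpy()
    blq = rec["blq"].to_numpy()
    auc = auc_trapz(times, concs, t_end=min(t_end, times[~blq].max()
                                            if (~blq).any() else t_end),
                    blq=blq)
    hl = terminal_half_life(times, concs, n_tail=n_tail, blq=blq)
    obs = data.observed()
    i_max = int(obs["conc_ng_ml"].idxmax())
    return NcaSummary(subject_id=data.subject_id, route=data.route.value,
                      auc_0_48=auc, t_half=hl.t_half,
                      t_half_reliable=hl.reliable,
                      cmax=float(obs.loc[i_max, "conc_ng_ml"]),
                      tmax=float(obs.loc[i_max, "time_h"]),
                      n_points_used=int(data.n_observed))


def nca_route_table(subjects: list[SubjectDataset], t_end: float = 48.0,
                    n_tail: int = 3) -> pd.DataFrame:
    """Per-subject NCA table for a group of subjects."""
    rows = [nca_subject(s, t_end=t_end, n_tail=n_tail).__dict__
            for s in subjects]
    return pd.DataFrame(rows)
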