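"""In-memory concentration-time datasets.

One :class:`SubjectDataset` holds the observations of one animal: times in
hours, plasma concentrations in ng/mL and a below-limit-of-quantification
(BLQ) flag per record. Records flagged BLQ keep whatever value the assay /
simulation produced (possibly empty or negative) but are excluded from
fitting and from non-compartmental tail statistics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DoseSchedule, ModelParams, Route

RECORD_COLUMNS = ["time_h", "conc_ng_ml", "blq"]


@dataclass
class SubjectDataset:
    """Concentration-time records of one subject (one route, one dose)."""

    subject_id: str
    route: Route
    dose_mg_kg: float
    body_weight_g: float
    records: pd.DataFrame
    #: generating parameters, set by the synthetic-cohort generator
    true_params: ModelParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.route = Route(self.route)
        df = self.records
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        df = df.loc[:, RECORD_COLUMNS].copy()
        df["time_h"] = df["time_h"].astype(float)
        df["conc_ng_ml"] = df["conc_ng_ml"].astype(float)
        df["blq"] = df["blq"].astype(bool)
        df = df.sort_values("time_h", kind="stable").reset_index(drop=True)
        if df["time_h"].duplicated().any():
            dup = df.loc[df["time_h"].duplicated(), "time_h"].iloc[0]
            raise ValueError(
                f"duplicate time {dup} h for subject {self.subject_id}")
        bad = (~df["blq"]) & (df["conc_ng_ml"].isna() | (df["conc_ng_ml"] < 0))
        if bad.any():
            t = df.loc[bad, "time_h"].iloc[0]
            raise ValueError(
                f"subject {self.subject_id}, t={t} h: non-BLQ record must "
                "have a nonnegative concentration")
        self.records = df

    @property
    def schedule(self) -> DoseSchedule:
        return DoseSchedule(nominal_dose_mg_kg=self.dose_mg_kg,
                            route=self.route,
                            body_weight_g=self.body_weight_g)

    def observed(self) -> pd.DataFrame:
        """Quantifiable (non-BLQ) records."""
        return self.records.loc[~self.records["blq"]].reset_index(drop=True)

    @property
    def n_observed(self) -> int:
        return int((~self.records["blq"]).sum())

    def checksum(self) -> str:
        """Stable digest of the fitted quantities (times + observations)."""
        obs = self.observed()
        h = hashlib.sha256()
        h.update(self.subject_id.encode())
        h.update(self.route.value.encode())
        h.update(np.ascontiguousarray(obs["time_h"].to_numpy()).tobytes())
        h.update(np.ascontiguousarray(obs["conc_ng_ml"].to_numpy()).tobytes())
        return h.hexdigest()
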