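"""Long-format analysis dataset.

A :class:`PKDataset` wraps a pandas DataFrame in the NONMEM-style long
format: one row per event, dose rows (``EVID=1``) carrying ``AMT`` in mg
and observation rows (``EVID=0``) carrying ``DV`` in mg/L, with ``TIME``
in minutes since the first dose and covariate columns repeated on every
row of a subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .model import CovariateVector, DoseEvent

#: Mandatory event columns.
EVENT_COLUMNS = ["ID", "TIME", "DV", "AMT", "EVID", "MDV"]
#: Covariate columns carried on every row.
COVARIATE_COLUMNS = [
    "ARM", "SEX", "AGE", "WT", "HT", "SCR", "BILI", "ALB", "TPROT", "UREA",
    "BSA", "EGFR",
]
ALL_COLUMNS = EVENT_COLUMNS + ["BLQ"] + COVARIATE_COLUMNS


class DatasetError(ValueError):
    """Dataset fails validation; message lists the offending rows."""


@dataclass
class PKDataset:
    """Validated long-format dose + observation records for a cohort."""

    df: pd.DataFrame

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- views ------------------------------------------------------------

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def covariates(self) -> pd.DataFrame:
        """One row of covariates per subject (indexed by ID)."""
        return (
            self.df.groupby("ID", sort=False)[COVARIATE_COLUMNS].first()
        )

    def covariate_vector(self, subject_id) -> CovariateVector:
        row = self.covariates().loc[subject_id]
        return CovariateVector(
            egfr=row["EGFR"], bsa=row["BSA"], support=row["ARM"], sex=row["SEX"],
            age=row["AGE"], weight=row["WT"], height=row["HT"],
            serum_creatinine=row["SCR"], bilirubin=row["BILI"],
            albumin=row["ALB"], total_protein=row["TPROT"], urea=row["UREA"],
        )

    def dose_events(self, subject_id) -> List[DoseEvent]:
        rows = self.df[(self.df["ID"] == subject_id) & (self.df["EVID"] == 1)]
        return [DoseEvent(time=r.TIME, amount=r.AMT) for r in rows.itertuples()]

    # -- validation -------------------------------------------------------

    def validate(self):
        df = self.df
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing mandatory columns: {missing}")
        bad_dose = df[(df["EVID"] == 1) & ~(df["AMT"] > 0)]
        if len(bad_dose):
            raise DatasetError(
                f"dose rows without a positive AMT at rows {list(bad_dose.index)}"
            )
        obs = df[df["EVID"] == 0]
        bad_conc = obs[(obs["MDV"] == 0) & (obs["DV"] < 0)]
        if len(bad_conc):
            raise DatasetError(
                f"negative concentrations at rows {list(bad_conc.index)}"
            )
        for sid, grp in df.groupby("ID", sort=False):
            times = grp["TIME"].to_numpy()
            if np.any(np.diff(times) < 0):
                raise DatasetError(f"non-monotone times within subject {sid}")
            ot = grp.loc[grp["EVID"] == 0, "TIME"].to_numpy()
            if len(ot) != len(np.unique(ot)):
                raise DatasetError(f"duplicate observation times in subject {sid}")
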