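"""Survival-data container and delimited-text I/O.

The package works on right-censored cohort data: one row per subject with a
positive follow-up time, a 0/1 event indicator, a quantitative exposure, and
optional adjustment covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataValidationError(ValueError):
    """Raised when ingested survival data violate the basic contract."""


@dataclass
class SurvivalData:
    """Right-censored survival data for one cohort.

    Parameters
    ----------
    time : array of positive follow-up times (arbitrary time units).
    event : 0/1 indicator; 1 if the event was observed, 0 if censored.
    exposure : quantitative exposure per subject, >= 0.
    covariates : optional (n, q) matrix of adjustment covariates.
    covariate_names : optional names for the covariate columns.
    """

    time: np.ndarray
    event: np.ndarray
    exposure: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.exposure = np.asarray(self.exposure, dtype=float)
        n = self.time.shape[0]
        if self.event.shape[0] != n or self.exposure.shape[0] != n:
            raise DataValidationError("time, event and exposure lengths differ")
        for name, arr in (("time", self.time), ("exposure", self.exposure)):
            if not np.all(np.isfinite(arr)):
                raise DataValidationError(f"non-finite values in {name!r}")
        if np.any(self.time <= 0):
            raise DataValidationError("follow-up times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise DataValidationError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)
        if self.event.sum() == 0:
            raise DataValidationError("data contain no events")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != n:
                raise DataValidationError("covariate rows do not match n")
            if not np.all(np.isfinite(self.covariates)):
                raise DataValidationError("non-finite covariate values")
            if not self.covariate_names:
                self.covariate_names = [
                    f"z{j + 1}" for j in range(self.covariates.shape[1])
                ]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def case_exposures(self) -> np.ndarray:
        """Exposures of subjects who experienced the event."""
        return self.exposure[self.event == 1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.time, "event": self.event, "exposure": self.exposure}
        )
        if self.covariates is not None:
            for j, name in enumerate(self.covariate_names):
                df[name] = self.covariates[:, j]
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        time: str = "time",
        event: str = "event",
        exposure: str = "exposure",
        covariates: list[str] | None = None,
    ) -> "SurvivalData":
        for col in (time, event, exposure):
            if col not in df.columns:
                raise DataValidationError(f"missing required column {col!r}")
        if covariates is None:
            covariates = [c for c in df.columns if c not in (time, event, exposure)]
        cov = df[covariates].to_numpy(dtype=float) if covariates else None
        return cls(
            time=df[time].to_numpy(dtype=float),
            event=df[event].to_numpy(),
            exposure=df[exposure].to_numpy(dtype=float),
            covariates=cov,
            covariate_names=list(covariates),
        )


def read_survival_csv(
    path,
    time: str = "time",
    event: str = "event",
    exposure: str = "exposure",
    covariates: list[str] | None = None,
) -> SurvivalData:
    """Read cohort data from comma-separated text with a header row."""
    df = pd.read_csv(path, comment="#")
    return SurvivalData.from_frame(
        df, time=time, event=event, exposure=exposure, covariates=covariates
    )


def write_survival_csv(data: SurvivalData, path, header_lines: list[str] | None = None):
    """Write cohort data as comma-separated text, optionally with '#' headers."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        data.to_frame().to_csv(fh, index=False)
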