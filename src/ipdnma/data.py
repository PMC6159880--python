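"""Patient-level survival data: records, datasets, CSV ingest and trial summaries.

The universal input is a long table with one row per randomised patient:
trial identifier, treatment label, follow-up time, event indicator and any
number of patient-level covariates (missing values allowed).  All downstream
modelling — the per-trial spline baselines, the network treatment contrasts
and the treatment-covariate interaction designs — is driven from this one
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSpec",
    "IPDRecord",
    "IPDDataset",
    "TrialSummary",
    "read_ipd",
    "write_ipd",
    "split_multiarm",
    "trial_summaries",
]

RESERVED_COLUMNS = ("trial", "treatment", "time", "event")


class IPDFormatError(ValueError):
    """Malformed input table (bad header, unparseable field)."""


class IPDValidationError(ValueError):
    """Well-formed input that violates a data invariant."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declared metadata for one patient-level covariate.

    Parameters
    ----------
    name
        Column name in the IPD table.
    bounds
        Closed support ``[z_min, z_max]`` of the covariate.  Required for
        truncated-normal imputation of missing values; for a bounded ordinal
        severity score such as disease stage coded 0/1/2 this is ``(0, 2)``.
    ordinal
        Whether the covariate is an ordered categorical treated as linear.
    """

    name: str
    bounds: tuple[float, float] | None = None
    ordinal: bool = False

    def __post_init__(self) -> None:
        if self.bounds is not None and not self.bounds[0] < self.bounds[1]:
            raise IPDValidationError(
                f"covariate {self.name!r}: bounds must be ordered, got {self.bounds}"
            )


@dataclass(frozen=True)
class IPDRecord:
    """One patient: trial, randomised arm, follow-up time and event status."""

    trial_id: str
    treatment: str
    time: float
    event: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise IPDValidationError(f"time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise IPDValidationError(f"event must be 0 or 1, got {self.event}")


class IPDDataset:
    """A validated collection of patient records grouped in trials.

    Internally the records live in a :class:`pandas.DataFrame` with columns
    ``trial, treatment, time, event`` plus one column per declared covariate
    (``NaN`` marks a missing value).  Every trial must randomise at least two
    distinct treatments.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        covariates: Sequence[CovariateSpec] = (),
        treatments: Sequence[str] | None = None,
    ) -> None:
        table = table.reset_index(drop=True).copy()
        for col in RESERVED_COLUMNS:
            if col not in table.columns:
                raise IPDFormatError(f"missing required column {col!r}")
        if len(table) == 0:
            raise IPDValidationError("dataset is empty")
        table["trial"] = table["trial"].astype(str)
        table["treatment"] = table["treatment"].astype(str)
        table["time"] = table["time"].astype(float)
        table["event"] = table["event"].astype(int)

        bad_time = table.index[~(table["time"] > 0)]
        if len(bad_time):
            raise IPDValidationError(
                f"non-positive follow-up time in row(s) {list(bad_time[:5])}"
            )
        bad_event = table.index[~table["event"].isin((0, 1))]
        if len(bad_event):
            raise IPDValidationError(
                f"event indicator outside {{0,1}} in row(s) {list(bad_event[:5])}"
            )
        for spec in covariates:
            if spec.name not in table.columns:
                raise IPDFormatError(f"declared covariate {spec.name!r} not in table")
            table[spec.name] = pd.to_numeric(table[spec.name], errors="raise")

        if treatments is not None:
            unknown = set(table["treatment"]) - set(treatments)
            if unknown:
                raise IPDValidationError(
                    f"undeclared treatment label(s): {sorted(unknown)}"
                )
            self._treatments = list(treatments)
        else:
            # deterministic: order of first appearance
            self._treatments = list(dict.fromkeys(table["treatment"]))

        arms = table.groupby("trial", sort=False)["treatment"].nunique()
        single = arms.index[arms < 2].tolist()
        if single:
            raise IPDValidationError(
                f"trial(s) with fewer than 2 arms: {single}"
            )

        self.table = table
        self.covariates = list(covariates)

    # -- basic views -------------------------------------------------------

    @property
    def trials(self) -> dict[str, set[str]]:
        """Map trial id -> set of treatment labels randomised in it."""
        return {
            t: set(g["treatment"]) for t, g in self.table.groupby("trial", sort=False)
        }

    @property
    def trial_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["trial"]))

    @property
    def treatments(self) -> list[str]:
        return list(self._treatments)

    @property
    def n_patients(self) -> int:
        return len(self.table)

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())

    def covariate_spec(self, name: str) -> CovariateSpec:
        for spec in self.covariates:
            if spec.name == name:
                return spec
        raise KeyError(f"covariate {name!r} not declared")

    def records(self) -> Iterator[IPDRecord]:
        cov_names = [c.name for c in self.covariates]
        for row in self.table.itertuples(index=False):
            covs = {
                name: getattr(row, name)
                for name in cov_names
            }
            yield IPDRecord(row.trial, row.treatment, row.time, row.event, covs)

    def subset(self, mask: np.ndarray | pd.Series) -> "IPDDataset":
        return IPDDataset(self.table[np.asarray(mask)], self.covariates,
                          treatments=self._treatments)

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:
        return (
            f"IPDDataset({len(self.trial_ids)} trials, {self.n_patients} patients, "
            f"{self.n_events} events)"
        )


@dataclass(frozen=True)
class TrialSummary:
    """Per-trial counts and covariate distribution summary."""

    trial_id: str
    n_patients: int
    n_events: int
    arm_counts: dict[str, int]
    covariate_mean: float | None  # mean over observed values; None if all missing
    missing_fraction: float


def read_ipd(
    path,
    covariate_spec: Sequence[CovariateSpec] = (),
    treatments: Sequence[str] | None = None,
) -> IPDDataset:
    """Read a long-format IPD CSV (one row per patient).

    Expected header: ``trial,treatment,time,event`` plus any covariate
    columns.  Missing covariate values may be empty fields or ``NA``.
    Rows with non-positive time or an event indicator outside {0,1} are
    rejected with an error naming the offending rows.
    """
    try:
        table = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise IPDFormatError(str(exc)) from exc
    missing_cols = [c for c in RESERVED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise IPDFormatError(
            f"IPD header must contain {RESERVED_COLUMNS}; missing {missing_cols}"
        )
    return IPDDataset(table, covariate_spec, treatments=treatments)


def write_ipd(dataset: IPDDataset, path) -> None:
    """Write a dataset back to the standard long CSV (missing -> empty field)."""
    dataset.table.to_csv(path, index=False)


def split_multiarm(
    dataset: IPDDataset,
    policy: str = "share_control",
    assignment: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
) -> IPDDataset:
    """Apply the multi-arm trial policy.

    ``share_control`` (default) leaves multi-arm trials intact: all arms of a
    trial share one baseline spline in the one-stage model, which already
    induces the correct correlation between its contrasts.  The alternative,
    ``unconfounded_split``, re-labels the arms of a multi-arm trial into
    separate two-arm pseudo-trials according to a user-supplied assignment
    ``{trial_id: {subtrial_name: [arm, ...]}}`` in which every arm appears in
    exactly one sub-trial (so every patient is analysed exactly once).
    """
    if policy == "share_control":
        return dataset
    if policy != "unconfounded_split":
        raise ValueError(f"unknown policy {policy!r}")
    if assignment is None:
        raise ValueError("unconfounded_split requires an arm-to-subtrial assignment")

    table = dataset.table.copy()
    new_trial = table["trial"].copy()
    for trial_id, submap in assignment.items():
        arms_here = set(table.loc[table["trial"] == trial_id, "treatment"])
        seen: set[str] = set()
        for sub, arms in submap.items():
            arms = list(arms)
            dup = seen.intersection(arms)
            if dup:
                raise ValueError(
                    f"trial {trial_id!r}: arm(s) {sorted(dup)} assigned to more "
                    "than one sub-trial (patients would be reused)"
                )
            seen.update(arms)
            mask = (table["trial"] == trial_id) & table["treatment"].isin(arms)
            new_trial[mask] = f"{trial_id}::{sub}"
        unassigned = arms_here - seen
        if unassigned:
            raise ValueError(
                f"trial {trial_id!r}: arm(s) {sorted(unassigned)} not assigned"
            )
    table["trial"] = new_trial
    return IPDDataset(table, dataset.covariates, treatments=dataset.treatments)


def trial_summaries(dataset: IPDDataset, covariate: str) -> list[TrialSummary]:
    """Summarise each trial: sizes, events and the covariate distribution.

    The covariate mean is computed over observed values only; a trial whose
    covariate is entirely missing gets ``covariate_mean=None`` (its mean is
    undefined until imputation supplies one).
    """
    dataset.covariate_spec(covariate)  # raises if undeclared
    out: list[TrialSummary] = []
    for trial_id, g in dataset.table.groupby("trial", sort=False):
        z = g[covariate]
        n_miss = int(z.isna().sum())
        mean = float(z.mean()) if n_miss < len(g) else None
        out.append(
            TrialSummary(
                trial_id=str(trial_id),
                n_patients=len(g),
                n_events=int(g["event"].sum()),
                arm_counts=g["treatment"].value_counts().to_dict(),
                covariate_mean=mean,
                missing_fraction=n_miss / len(g),
            )
        )
    return out
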