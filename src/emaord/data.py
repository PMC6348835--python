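"""Long-format EMA diary data: loading, validation, filtering, summaries.

The data model is one row per patient-day: a patient identifier, an ordinal
time index, five ordinal diary items (mood, worry, sleep, enjoyed activities,
social contact) and the ordinal outcome (self-esteem), all scored as integers
on a 1..C scale (C = 10 by default). Missing items are permitted on input and
are removed by :func:`filter_complete` before modelling; the models use only
complete patient-days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five diary predictors, in canonical column order.
PREDICTORS: tuple[str, ...] = (
    "mood",
    "worry",
    "sleep",
    "enjoyed_activities",
    "social_contact",
)

#: Outcome column name.
OUTCOME: str = "self_esteem"

#: Full required CSV header.
REQUIRED_COLUMNS: tuple[str, ...] = ("patient_id", "time_index") + PREDICTORS + (OUTCOME,)

#: Score columns (predictors + outcome).
SCORE_COLUMNS: tuple[str, ...] = PREDICTORS + (OUTCOME,)

#: Missing-value spellings accepted in CSV files (plus the empty cell).
NA_VALUES: tuple[str, ...] = ("", "NA", "NaN", "nan")


class SchemaError(ValueError):
    """A required column is absent from the input."""


class ValidationError(ValueError):
    """A cell value violates the ordinal-score contract."""


@dataclass(frozen=True)
class EMARecord:
    """A single patient-day of diary scores.

    ``predictors`` maps item name -> score (int) or None when missing;
    ``outcome`` is the self-esteem score or None.
    """

    patient_id: str
    time_index: int
    predictors: dict[str, int | None]
    outcome: int | None

    @property
    def complete(self) -> bool:
        return self.outcome is not None and all(
            v is not None for v in self.predictors.values()
        )


class EMADataset:
    """An ordered collection of EMA diary records backed by a DataFrame.

    Parameters
    ----------
    frame
        Long-format DataFrame with columns ``patient_id``, ``time_index``,
        the five predictors and ``self_esteem``. Scores may be missing (NA).
    n_categories
        Number of ordinal categories C; every non-missing score must lie in
        ``1..C``. Defaults to 10, the diary's one-to-ten response scale.
    validate
        Skip revalidation when building from an already-validated frame.
    """

    def __init__(self, frame: pd.DataFrame, n_categories: int = 10, validate: bool = True):
        if n_categories < 2:
            raise ValidationError(f"n_categories must be >= 2, got {n_categories}")
        frame = frame.reset_index(drop=True)
        if validate:
            frame = _validate_frame(frame, n_categories)
        self._frame = frame
        self.n_categories = int(n_categories)
        self.predictor_names: tuple[str, ...] = PREDICTORS

    # -- basic container API -------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying long-format DataFrame (do not mutate)."""
        return self._frame

    @property
    def n_obs(self) -> int:
        return len(self._frame)

    @property
    def n_patients(self) -> int:
        return self._frame["patient_id"].nunique()

    @property
    def patient_ids(self) -> list[str]:
        """Unique patient identifiers in order of first appearance."""
        return list(dict.fromkeys(self._frame["patient_id"]))

    def __len__(self) -> int:
        return self.n_obs

    def __iter__(self) -> Iterator[EMARecord]:
        for row in self._frame.itertuples(index=False):
            d = row._asdict()
            yield EMARecord(
                patient_id=d["patient_id"],
                time_index=int(d["time_index"]),
                predictors={
                    k: (None if pd.isna(d[k]) else int(d[k])) for k in PREDICTORS
                },
                outcome=None if pd.isna(d[OUTCOME]) else int(d[OUTCOME]),
            )

    @property
    def records(self) -> list[EMARecord]:
        return list(self)

    def is_complete(self) -> bool:
        """True when no score (predictor or outcome) is missing."""
        return not self._frame[list(SCORE_COLUMNS)].isna().any().any()

    # -- design-matrix views used by the models ------------------------------

    def design_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Return ``(X, y, patient_index, patient_ids)`` for a complete dataset.

        ``X`` is the N x 5 float predictor matrix on the raw 1..C scale,
        ``y`` the N-vector of outcomes in 1..C, ``patient_index`` the
        N-vector of 0-based codes into ``patient_ids``.
        """
        if not self.is_complete():
            raise ValidationError(
                "dataset contains missing scores; apply filter_complete() first"
            )
        ids = self.patient_ids
        code = {p: i for i, p in enumerate(ids)}
        X = self._frame[list(PREDICTORS)].to_numpy(dtype=float)
        y = self._frame[OUTCOME].to_numpy(dtype=int)
        pidx = self._frame["patient_id"].map(code).to_numpy(dtype=int)
        return X, y, pidx, ids

    def subset(self, mask: np.ndarray) -> "EMADataset":
        """Row-subset (boolean mask or integer positions), preserving order."""
        sub = self._frame.iloc[np.asarray(mask).nonzero()[0] if np.asarray(mask).dtype == bool else mask]
        return EMADataset(sub, n_categories=self.n_categories, validate=False)

    # -- I/O ------------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the canonical CSV dialect (UTF-8, header, empty cell = NA)."""
        self._frame.to_csv(path, index=False)


def _validate_frame(frame: pd.DataFrame, n_categories: int) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    frame = frame[list(REQUIRED_COLUMNS)].copy()
    frame["patient_id"] = frame["patient_id"].astype(str)

    if frame["time_index"].isna().any():
        row = int(frame.index[frame["time_index"].isna()][0]) + 1
        raise ValidationError(f"missing time_index in data row {row}")
    t = pd.to_numeric(frame["time_index"], errors="coerce")
    if t.isna().any() or (t != t.round()).any() or (t < 0).any():
        bad = t.isna() | (t != t.round()) | (t < 0)
        row = int(frame.index[bad][0]) + 1
        raise ValidationError(f"time_index must be a nonnegative integer (data row {row})")
    frame["time_index"] = t.astype(int)

    dup = frame.duplicated(subset=["patient_id", "time_index"])
    if dup.any():
        row = int(frame.index[dup][0]) + 1
        raise ValidationError(
            f"duplicate time_index within a patient (data row {row})"
        )

    for col in SCORE_COLUMNS:
        v = pd.to_numeric(frame[col], errors="coerce")
        raw_na = frame[col].isna()
        unparsable = v.isna() & ~raw_na
        if unparsable.any():
            row = int(frame.index[unparsable][0]) + 1
            raise ValidationError(f"non-numeric score in column '{col}', data row {row}")
        nonint = v.notna() & (v != v.round())
        if nonint.any():
            row = int(frame.index[nonint][0]) + 1
            raise ValidationError(f"non-integer score in column '{col}', data row {row}")
        out = v.notna() & ((v < 1) | (v > n_categories))
        if out.any():
            row = int(frame.index[out][0]) + 1
            raise ValidationError(
                f"score out of range 1..{n_categories} in column '{col}', data row {row}"
            )
        frame[col] = v.astype("Int64")
    return frame


def load_ema_csv(path, n_categories: int = 10) -> EMADataset:
    """Read a long-format diary CSV into an :class:`EMADataset`.

    The header must contain ``patient_id``, ``time_index``, the five
    predictor columns and ``self_esteem``. Empty cells and ``NA`` are read
    as missing scores (never coerced to zero). Row numbers in error messages
    are 1-based over the data rows (header excluded).
    """
    frame = pd.read_csv(path, na_values=list(NA_VALUES), keep_default_na=False, dtype={"patient_id": str})
    return EMADataset(frame, n_categories=n_categories)


def filter_complete(dataset: EMADataset) -> EMADataset:
    """Keep only patient-days on which all five items and the outcome were scored.

    Complete-case rule: only days with every factor assessed enter the
    analysis. Logs the number of rows removed; an empty result is allowed
    but warned about.
    """
    mask = dataset.frame[list(SCORE_COLUMNS)].notna().all(axis=1)
    removed = int((~mask).sum())
    if removed:
        logger.info("filter_complete: removed %d of %d records with missing scores", removed, len(mask))
    out = EMADataset(dataset.frame.loc[mask], n_categories=dataset.n_categories, validate=False)
    if out.n_obs == 0:
        logger.warning("filter_complete: no complete records remain")
    return out


@dataclass
class DatasetSummary:
    """Cohort-level summary: sizes and per-item marginal score frequencies."""

    n_patients: int
    n_obs: int
    per_patient_counts: pd.Series
    item_frequencies: pd.DataFrame  # index 1..C, one column per score item

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"patients (J):      {self.n_patients}",
            f"observations (N):  {self.n_obs}",
            f"obs per patient:   median {self.per_patient_counts.median():.0f}, "
            f"range {self.per_patient_counts.min()}-{self.per_patient_counts.max()}",
            "",
            self.item_frequencies.to_string(),
        ]
        return "\n".join(lines)


def dataset_summary(dataset: EMADataset) -> DatasetSummary:
    """Summarize a dataset: J, N, per-patient counts, per-item score frequencies.

    Frequencies are counts of each score 1..C per item over non-missing
    cells; per item they sum to the number of non-missing entries (= N for a
    complete dataset).
    """
    frame = dataset.frame
    counts = frame.groupby("patient_id", sort=False).size()
    C = dataset.n_categories
    freq = pd.DataFrame(
        {
            col: frame[col].value_counts().reindex(range(1, C + 1), fill_value=0)
            for col in SCORE_COLUMNS
        }
    )
    freq.index.name = "score"
    return DatasetSummary(
        n_patients=dataset.n_patients,
        n_obs=dataset.n_obs,
        per_patient_counts=counts,
        item_frequencies=freq,
    )
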