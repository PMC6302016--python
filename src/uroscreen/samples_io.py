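"""Cohort data model, tabular I/O and culture ground-truth labelling.

A cohort is a collection of urine samples, each pairing one automated
analyser measurement (bacteria and leukocyte particle counts, /μL) with its
semi-quantitative urine-culture outcome (CFU/mL, or a categorical label).
Culture is the gold standard: a sample is truth-positive when growth meets
the significant-bacteriuria threshold (default 1e5 CFU/mL) and the culture
is not contaminated.  Contaminated cultures (three or more colony types)
stay in the cohort and count as truth-negative by default.

Tabular dialect (CSV, or TSV for ``.tsv``/``.tab`` paths; UTF-8, header row
mandatory): required columns ``sample_id``, ``device``, ``bacteria_per_uL``,
``wbc_per_uL``, and exactly one of ``culture_cfu_per_mL`` or
``culture_label`` (``positive`` / ``negative`` / ``contaminated``); optional
``contaminated`` (0/1), ``qc_excluded`` (0/1), ``sex``, ``patient_setting``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("uroscreen")

__all__ = [
    "UrineSample",
    "CultureLabelConfig",
    "Cohort",
    "CohortFormatError",
    "CohortRowError",
    "EmptyCohortError",
    "CultureLabelError",
    "label_culture",
    "read_cohort",
    "write_cohort",
]

CATEGORICAL_LABELS = ("positive", "negative", "contaminated")

REQUIRED_COLUMNS = ("sample_id", "device", "bacteria_per_uL", "wbc_per_uL")
OPTIONAL_COLUMNS = ("contaminated", "qc_excluded", "sex", "patient_setting")


class CohortFormatError(ValueError):
    """The file as a whole violates the tabular dialect (e.g. missing column)."""


class CohortRowError(ValueError):
    """A single data row is malformed; the message names the row number."""


class EmptyCohortError(ValueError):
    """No data rows survive reading; evaluation operations need >= 1 sample."""


class CultureLabelError(ValueError):
    """A sample lacks the culture information needed to assign a truth label."""


@dataclass(frozen=True)
class CultureLabelConfig:
    """How culture outcomes map to the binary ground truth.

    Parameters
    ----------
    cfu_threshold:
        Significant-bacteriuria threshold in CFU/mL.  Growth at or above it
        is positive.  1e5 is the conventional midstream threshold; 1e4 is
        the common alternate for symptomatic patients.
    contaminated_is_negative:
        If True (default), a contaminated culture is truth-negative
        regardless of its CFU count.  If False, contamination is ignored
        and the CFU threshold alone decides.
    """

    cfu_threshold: float = 1e5
    contaminated_is_negative: bool = True

    def __post_init__(self) -> None:
        if not (self.cfu_threshold > 0):
            raise ValueError(f"cfu_threshold must be > 0, got {self.cfu_threshold}")


@dataclass(frozen=True)
class UrineSample:
    """One analyser measurement paired with its culture ground truth.

    Exactly one of ``culture_cfu_per_mL`` / ``culture_label`` must be set.
    Counts are particle concentrations reported by the analyser, /μL.
    """

    sample_id: str
    device: str
    bacteria_per_uL: float
    wbc_per_uL: float
    culture_cfu_per_mL: float | None = None
    culture_label: str | None = None
    contaminated: bool = False
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("bacteria_per_uL", "wbc_per_uL"):
            value = getattr(self, name)
            if value is None or not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: {name} must be a finite "
                    f"non-negative count, got {value!r}"
                )
        has_cfu = self.culture_cfu_per_mL is not None
        has_label = self.culture_label is not None
        if has_cfu == has_label:
            raise ValueError(
                f"sample {self.sample_id!r}: exactly one of culture_cfu_per_mL "
                "and culture_label is required"
            )
        if has_cfu and (not math.isfinite(self.culture_cfu_per_mL) or self.culture_cfu_per_mL < 0):
            raise ValueError(
                f"sample {self.sample_id!r}: culture_cfu_per_mL must be a "
                f"finite non-negative value, got {self.culture_cfu_per_mL!r}"
            )
        if has_label and self.culture_label not in CATEGORICAL_LABELS:
            raise ValueError(
                f"sample {self.sample_id!r}: culture_label must be one of "
                f"{CATEGORICAL_LABELS}, got {self.culture_label!r}"
            )
        if self.culture_label == "contaminated" and not self.contaminated:
            object.__setattr__(self, "contaminated", True)


def label_culture(sample: UrineSample, config: CultureLabelConfig | None = None) -> bool:
    """Binary culture truth label for one sample.

    Positive iff growth >= ``cfu_threshold`` (inclusive boundary) and the
    culture is not contaminated (under the default config, which counts
    contaminated cultures as negative).  Deterministic.
    """
    config = config or CultureLabelConfig()
    if sample.contaminated and config.contaminated_is_negative:
        return False
    if sample.culture_cfu_per_mL is not None:
        return sample.culture_cfu_per_mL >= config.cfu_threshold
    if sample.culture_label is not None:
        return sample.culture_label == "positive"
    raise CultureLabelError(f"sample {sample.sample_id!r} has no culture information")


@dataclass
class Cohort:
    """Ordered collection of :class:`UrineSample` with a labelling config."""

    samples: list[UrineSample]
    label_config: CultureLabelConfig = field(default_factory=CultureLabelConfig)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate sample_id {dup!r} in cohort")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def bacteria(self) -> np.ndarray:
        """Bacteria counts (/μL) in cohort order."""
        return np.array([s.bacteria_per_uL for s in self.samples], dtype=float)

    @property
    def wbc(self) -> np.ndarray:
        """Leukocyte counts (/μL) in cohort order."""
        return np.array([s.wbc_per_uL for s in self.samples], dtype=float)

    def truth_labels(self, config: CultureLabelConfig | None = None) -> np.ndarray:
        """Boolean culture truth in cohort order (True = culture positive)."""
        config = config or self.label_config
        return np.array([label_culture(s, config) for s in self.samples], dtype=bool)

    def require_nonempty(self) -> None:
        if not self.samples:
            raise EmptyCohortError("cohort is empty; evaluation needs >= 1 sample")


def _as_bool(value, row: int, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value in (0, 1):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("0", "false", "no", ""):
        return False
    if text in ("1", "true", "yes"):
        return True
    raise CohortRowError(f"row {row}: column {column!r} is not a 0/1 flag: {value!r}")


def _as_count(value, row: int, column: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise CohortRowError(f"row {row}: non-numeric {column!r}: {value!r}") from None
    if math.isnan(out):
        raise CohortRowError(f"row {row}: missing {column!r} (counts may not be blank)")
    return out


def read_cohort(
    path: str | Path,
    label_config: CultureLabelConfig | None = None,
) -> Cohort:
    """Read a cohort from the tabular dialect.

    Rows with a true ``qc_excluded`` flag are dropped and counted in the
    log; missing counts are rejected (never silently zeroed).

    Raises
    ------
    CohortFormatError
        Required column missing, or both/neither culture columns present.
    CohortRowError
        Non-numeric or missing value, naming the 1-based data row.
    EmptyCohortError
        No data rows remain after QC exclusion.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(
        path, sep=sep, dtype={"sample_id": str, "device": str},
        float_precision="round_trip",
    )

    for column in REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise CohortFormatError(f"{path.name}: missing required column {column!r}")
    has_cfu = "culture_cfu_per_mL" in frame.columns
    has_label = "culture_label" in frame.columns
    if has_cfu == has_label:
        raise CohortFormatError(
            f"{path.name}: exactly one of 'culture_cfu_per_mL' and "
            "'culture_label' must be present"
        )

    n_total = len(frame)
    n_excluded = 0
    samples: list[UrineSample] = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        if "qc_excluded" in frame.columns and not pd.isna(row["qc_excluded"]):
            if _as_bool(row["qc_excluded"], pos, "qc_excluded"):
                n_excluded += 1
                continue
        contaminated = False
        if "contaminated" in frame.columns and not pd.isna(row["contaminated"]):
            contaminated = _as_bool(row["contaminated"], pos, "contaminated")
        cfu = None
        cat = None
        if has_cfu:
            cfu = _as_count(row["culture_cfu_per_mL"], pos, "culture_cfu_per_mL")
        else:
            cat = str(row["culture_label"]).strip().lower()
            if cat not in CATEGORICAL_LABELS:
                raise CohortRowError(
                    f"row {pos}: culture_label must be one of {CATEGORICAL_LABELS}, "
                    f"got {row['culture_label']!r}"
                )
        metadata = {
            key: str(row[key])
            for key in ("sex", "patient_setting")
            if key in frame.columns and not pd.isna(row[key])
        }
        try:
            samples.append(
                UrineSample(
                    sample_id=str(row["sample_id"]),
                    device=str(row["device"]),
                    bacteria_per_uL=_as_count(row["bacteria_per_uL"], pos, "bacteria_per_uL"),
                    wbc_per_uL=_as_count(row["wbc_per_uL"], pos, "wbc_per_uL"),
                    culture_cfu_per_mL=cfu,
                    culture_label=cat,
                    contaminated=contaminated,
                    metadata=metadata,
                )
            )
        except CohortRowError:
            raise
        except ValueError as exc:
            raise CohortRowError(f"row {pos}: {exc}") from exc

    logger.info(
        "read %d rows from %s: %d samples kept, %d QC-excluded",
        n_total, path.name, len(samples), n_excluded,
    )
    if not samples:
        raise EmptyCohortError(f"{path.name}: no data rows after QC exclusion")
    return Cohort(samples=samples, label_config=label_config or CultureLabelConfig())


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the tabular dialect (round-trips with read_cohort)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    use_cfu = cohort.samples[0].culture_cfu_per_mL is not None if cohort.samples else True
    rows = []
    for s in cohort.samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "device": s.device,
            "bacteria_per_uL": repr(s.bacteria_per_uL),
            "wbc_per_uL": repr(s.wbc_per_uL),
        }
        if use_cfu:
            row["culture_cfu_per_mL"] = repr(s.culture_cfu_per_mL)
        else:
            row["culture_label"] = s.culture_label
        row["contaminated"] = int(s.contaminated)
        for key, value in s.metadata.items():
            row[key] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
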