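"""Survey data model, CSV I/O, complete-case filtering and descriptives.

The unit of analysis is one survey respondent (a practicing otolaryngologist).
Fields are closed categorical codes; any field may be missing (a skipped
question), encoded as an empty CSV cell.  Modeling restricts to complete
cases on the fields entering a given model.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "Respondent",
    "SurveyDataset",
    "MinAgeSummary",
    "PROVINCES",
    "MODELING_FIELDS",
    "COVARIATES",
    "read_survey_csv",
    "write_survey_csv",
    "complete_case_filter",
    "dichotomize",
    "covariate_group_labels",
    "summarize_min_age",
    "tally_preferences",
    "response_rate",
]

logger = logging.getLogger(__name__)

# The 13 Canadian provinces and territories (two-letter postal codes).
PROVINCES = ("AB", "BC", "MB", "NB", "NL", "NS", "NT", "NU", "ON", "PE", "QC", "SK", "YT")
AGE_GROUPS = ("le40", "gt40")
ROLES = ("staff", "resident", "retired")
SETTINGS = ("academic", "community", "other")
SUBSPECIALTIES = ("pediatric", "general", "other")
VOLUME_GROUPS = ("le50", "gt50")
TECHNIQUES = (
    "extracapsular_monopolar",
    "cold_steel",
    "intracapsular_microdebrider",
    "intracapsular_coblator",
    "other",
)
MIN_AGE_KINDS = ("no_limit", "never", "weight_based", "numeric")

_ENUMS = {
    "province": PROVINCES,
    "age_group": AGE_GROUPS,
    "role": ROLES,
    "setting": SETTINGS,
    "subspecialty": SUBSPECIALTIES,
    "annual_volume_group": VOLUME_GROUPS,
    "technique": TECHNIQUES,
    "min_age_kind": MIN_AGE_KINDS,
}

#: Fields a respondent must have answered to enter the modeling phase.
MODELING_FIELDS = (
    "province",
    "age_group",
    "setting",
    "subspecialty",
    "annual_volume_group",
    "technique",
    "opioid_sparing",
)

#: Dichotomizable covariates of the regression models.
COVARIATES = ("age", "subspecialty", "setting", "volume", "technique")

CSV_COLUMNS = [
    "respondent_id",
    "province",
    "age_group",
    "role",
    "setting",
    "subspecialty",
    "annual_volume_group",
    "technique",
    "opioid_sparing",
    "min_age_kind",
    "min_age_years",
    "preferred_opioid",
    "least_preferred_opioid",
]


@dataclass(frozen=True)
class Respondent:
    """One survey respondent; ``None`` means the question was skipped."""

    respondent_id: str
    province: Optional[str] = None
    age_group: Optional[str] = None
    role: Optional[str] = None
    setting: Optional[str] = None
    subspecialty: Optional[str] = None
    annual_volume_group: Optional[str] = None
    technique: Optional[str] = None
    opioid_sparing: Optional[int] = None
    min_age_kind: Optional[str] = None
    min_age_years: Optional[float] = None
    preferred_opioid: Optional[str] = None
    least_preferred_opioid: Optional[str] = None

    def __post_init__(self) -> None:
        for name, allowed in _ENUMS.items():
            value = getattr(self, name)
            if value is not None and value not in allowed:
                raise ValidationError(
                    f"respondent {self.respondent_id!r}: {name}={value!r} "
                    f"not in {allowed}"
                )
        if self.opioid_sparing is not None and self.opioid_sparing not in (0, 1):
            raise ValidationError(
                f"respondent {self.respondent_id!r}: opioid_sparing must be "
                f"0/1, got {self.opioid_sparing!r}"
            )
        if self.min_age_kind == "numeric":
            if self.min_age_years is None or not 0.0 <= self.min_age_years <= 18.0:
                raise ValidationError(
                    f"respondent {self.respondent_id!r}: numeric min age must "
                    f"lie in [0, 18] years, got {self.min_age_years!r}"
                )
        elif self.min_age_years is not None:
            raise ValidationError(
                f"respondent {self.respondent_id!r}: min_age_years given but "
                f"min_age_kind is {self.min_age_kind!r}"
            )


@dataclass(frozen=True)
class SurveyDataset:
    """Ordered collection of respondents with a province index.

    ``province_index`` maps each province code present in the data to a
    contiguous integer 0..J−1 (sorted code order), the grouping used by the
    random-intercept model.
    """

    respondents: tuple[Respondent, ...]
    province_index: dict[str, int] = field(init=False)

    def __init__(self, respondents: Sequence[Respondent]):
        object.__setattr__(self, "respondents", tuple(respondents))
        ids = [r.respondent_id for r in self.respondents]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate respondent_ids: {dupes}")
        present = sorted({r.province for r in self.respondents if r.province})
        object.__setattr__(
            self, "province_index", {p: j for j, p in enumerate(present)}
        )

    def __len__(self) -> int:
        return len(self.respondents)

    def __iter__(self):
        return iter(self.respondents)

    @property
    def n_provinces(self) -> int:
        return len(self.province_index)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.respondents]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def column(self, name: str) -> list:
        if name not in CSV_COLUMNS:
            raise ValidationError(f"unknown field {name!r}")
        return [getattr(r, name) for r in self.respondents]


def read_survey_csv(path: str | Path) -> SurveyDataset:
    """Read respondents from CSV; empty cells are missing values."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != CSV_COLUMNS:
        raise ValidationError(
            f"{path}: bad header; expected {CSV_COLUMNS}, got {list(df.columns)}"
        )
    respondents = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        kw: dict = {}
        for col in CSV_COLUMNS:
            raw = getattr(row, col).strip()
            if raw == "":
                kw[col] = None
            elif col == "opioid_sparing":
                if raw not in ("0", "1"):
                    raise ValidationError(f"{path}, line {i}: opioid_sparing={raw!r}")
                kw[col] = int(raw)
            elif col == "min_age_years":
                try:
                    kw[col] = float(raw)
                except ValueError as exc:
                    raise ValidationError(f"{path}, line {i}: {exc}") from exc
            else:
                kw[col] = raw
        try:
            respondents.append(Respondent(**kw))
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
    return SurveyDataset(respondents)


def write_survey_csv(dataset: SurveyDataset, path: str | Path) -> None:
    """Canonical CSV writer; round-trips byte-identically with the reader."""
    lines = [",".join(CSV_COLUMNS)]
    for r in dataset:
        cells = []
        for col in CSV_COLUMNS:
            v = getattr(r, col)
            if v is None:
                cells.append("")
            elif col == "min_age_years":
                cells.append(repr(float(v)))
            else:
                cells.append(str(v))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def complete_case_filter(
    dataset: SurveyDataset,
    required_fields: Sequence[str] = MODELING_FIELDS,
) -> SurveyDataset:
    """Retain respondents with no missing value among ``required_fields``."""
    unknown = set(required_fields) - set(CSV_COLUMNS)
    if unknown:
        raise ValidationError(f"unknown required fields: {sorted(unknown)}")
    kept = [
        r
        for r in dataset
        if all(getattr(r, f) is not None for f in required_fields)
    ]
    removed = len(dataset) - len(kept)
    logger.info(
        "complete-case filter: kept %d of %d respondents (%d removed)",
        len(kept), len(dataset), removed,
    )
    if not kept and len(dataset) > 0:
        warnings.warn("complete-case filter removed every respondent", stacklevel=2)
    return SurveyDataset(kept)


# Dichotomy definitions: (source field, {category: 0/1 code}).  Categories
# absent from the map become missing (NaN).
_DICHOTOMIES = {
    "age": ("age_group", {"le40": 0, "gt40": 1}),
    "subspecialty": ("subspecialty", {"pediatric": 1, "general": 0, "other": 0}),
    "setting": ("setting", {"academic": 1, "community": 0}),
    "volume": ("annual_volume_group", {"le50": 0, "gt50": 1}),
    "technique": (
        "technique",
        {
            "intracapsular_coblator": 1,
            "extracapsular_monopolar": 0,
            "cold_steel": 0,
            "intracapsular_microdebrider": 0,
            "other": 0,
        },
    ),
}

_GROUP_LABELS = {
    "age": ("age ≤40", "age >40"),
    "subspecialty": ("general/other", "pediatric"),
    "setting": ("community", "academic"),
    "volume": ("≤50 procedures/yr", ">50 procedures/yr"),
    "technique": ("other techniques", "intracapsular coblation"),
}


def covariate_group_labels(covariate: str) -> tuple[str, str]:
    """(reference, index) group labels for a dichotomized covariate."""
    if covariate not in _GROUP_LABELS:
        raise ValidationError(f"unknown covariate {covariate!r}")
    return _GROUP_LABELS[covariate]


def dichotomize(
    dataset: SurveyDataset,
    covariate: str,
    *,
    setting_other: str = "missing",
    microdebrider_intracapsular: bool = False,
) -> np.ndarray:
    """0/1 coding of a covariate; missing (and unmapped) values become NaN.

    Codings: age >40 → 1; subspecialty pediatric → 1 (general and other
    subspecialties pooled at 0); setting academic → 1 vs community → 0, with
    "other" treated as missing by default (``setting_other="community"``
    pools it instead); volume >50/yr → 1; technique intracapsular coblation
    → 1 vs everything else 0 (``microdebrider_intracapsular=True`` moves the
    intracapsular microdebrider to the 1 arm).
    """
    if covariate not in _DICHOTOMIES:
        raise ValidationError(
            f"unknown covariate {covariate!r}; choose from {sorted(_DICHOTOMIES)}"
        )
    source, mapping = _DICHOTOMIES[covariate]
    mapping = dict(mapping)
    if covariate == "setting":
        if setting_other == "community":
            mapping["other"] = 0
        elif setting_other != "missing":
            raise ValidationError(f"setting_other must be 'missing' or 'community'")
    if covariate == "technique" and microdebrider_intracapsular:
        mapping["intracapsular_microdebrider"] = 1
    out = np.full(len(dataset), np.nan)
    for i, r in enumerate(dataset):
        v = getattr(r, source)
        if v is not None and v in mapping:
            out[i] = mapping[v]
    return out


@dataclass(frozen=True)
class MinAgeSummary:
    """Counts by response kind and mean/SD/CI of the numeric responses."""

    n_no_limit: int
    n_never: int
    n_weight_based: int
    n_numeric: int
    mean_years: float
    sd_years: float
    ci_level: float
    ci_bounds: tuple[float, float]


def summarize_min_age(dataset: SurveyDataset, ci_level: float = 0.95) -> MinAgeSummary:
    """Summary of the minimum-prescribing-age question.

    The CI for the mean uses the t distribution with n−1 degrees of freedom.
    With fewer than 2 numeric responses the CI (and SD) are NaN.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValidationError(f"ci_level must lie in (0,1), got {ci_level}")
    kinds = [r.min_age_kind for r in dataset]
    numeric = np.array(
        [r.min_age_years for r in dataset if r.min_age_kind == "numeric"], float
    )
    n = numeric.size
    if n >= 2:
        mean = float(numeric.mean())
        sd = float(numeric.std(ddof=1))
        half = stats.t.ppf(0.5 + ci_level / 2.0, n - 1) * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    elif n == 1:
        mean, sd, ci = float(numeric[0]), float("nan"), (float("nan"), float("nan"))
        warnings.warn("fewer than 2 numeric min-age responses: CI undefined",
                      stacklevel=2)
    else:
        mean, sd, ci = float("nan"), float("nan"), (float("nan"), float("nan"))
        warnings.warn("no numeric min-age responses", stacklevel=2)
    return MinAgeSummary(
        n_no_limit=kinds.count("no_limit"),
        n_never=kinds.count("never"),
        n_weight_based=kinds.count("weight_based"),
        n_numeric=n,
        mean_years=mean,
        sd_years=sd,
        ci_level=float(ci_level),
        ci_bounds=(float(ci[0]), float(ci[1])),
    )


def tally_preferences(dataset: SurveyDataset, field_name: str) -> pd.DataFrame:
    """Counts and per-respondent percentages of a categorical question.

    Multi-select answers are encoded ``"a;b"``; each selection counts once,
    and percentages are computed over respondents who answered, so a
    multi-select tally may exceed 100% in total.
    """
    if field_name not in ("preferred_opioid", "least_preferred_opioid"):
        raise ValidationError(f"{field_name!r} is not a preference question")
    answers = [getattr(r, field_name) for r in dataset]
    answered = [a for a in answers if a is not None]
    counts: dict[str, int] = {}
    for a in answered:
        for choice in a.split(";"):
            choice = choice.strip()
            if choice:
                counts[choice] = counts.get(choice, 0) + 1
    n = len(answered)
    df = pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
        }
    ).sort_values("count", ascending=False, ignore_index=True)
    df["percent"] = 100.0 * df["count"] / n if n else np.nan
    df.attrs["n_answered"] = n
    return df


def response_rate(n_respondents: int, n_eligible: int) -> float:
    """Survey response rate as a percentage."""
    if n_eligible <= 0 or n_respondents < 0 or n_respondents > n_eligible:
        raise ValidationError(
            f"invalid counts: {n_respondents} respondents of {n_eligible} eligible"
        )
    return 100.0 * n_respondents / n_eligible
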