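"""Survey microdata: loading, validation and recoding into the analysis variable set.

One row per eligible birth (currently married woman, live birth in the five
years before interview). Raw fields carry categorical codes; recoding turns
them into the determinant design matrix used throughout: five-year
age-at-birth dummies (reference 15-19), own and husband's education dummies
(reference: no education), region dummies (reference: urban governorates),
modern-toilet indicator, terminated-pregnancy indicator, preceding birth
interval > 24 months, single birth, birth order, and previous-birth
indicators (medical delivery, caesarean, previous child alive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SurveyDataset",
    "RecodedMatrix",
    "SchemaError",
    "ValidationError",
    "DETERMINANT_COLUMNS",
    "EDUCATION_LEVELS",
    "REGIONS",
    "load_survey",
    "load_schema",
    "recode_outcome",
    "recode_determinants",
]

EDUCATION_LEVELS = ("none", "primary", "secondary", "higher")
REGIONS = ("urban_gov", "urban_lower", "rural_lower", "urban_upper", "rural_upper", "frontier")
TOILET_TYPES = ("modern", "other")

AGE_DUMMIES = ("age_20_24", "age_25_29", "age_30_34", "age_35_39", "age_40p")

#: Design-matrix columns, in reporting order. Reference categories (age 15-19,
#: no education for both spouses, urban governorates) are omitted.
DETERMINANT_COLUMNS = (
    *AGE_DUMMIES,
    "edu_primary", "edu_secondary", "edu_higher",
    "husband_edu_primary", "husband_edu_secondary", "husband_edu_higher",
    "region_urban_lower", "region_rural_lower", "region_urban_upper",
    "region_rural_upper", "region_frontier",
    "toilet_modern",
    "terminated_pregnancy",
    "interval_gt24",
    "single_birth",
    "birth_order",
    "prev_medical",
    "prev_csection",
    "prev_alive",
)

#: Raw columns a survey table must provide (canonical names; a schema map can
#: rename them). `assets` columns are listed separately.
RAW_FIELDS = (
    "urac", "weight", "age_at_birth", "woman_edu", "husband_edu", "region",
    "toilet", "terminated_pregnancy", "birth_interval_months",
    "n_births_this_pregnancy", "birth_order",
    "prev_medical", "prev_csection", "prev_alive",
)


class SchemaError(ValueError):
    """A mapped column is absent or the schema itself is malformed."""


class ValidationError(ValueError):
    """Rows violate the dataset invariants; message lists rows and reasons."""


@dataclass
class SurveyDataset:
    """Validated survey table plus the list of asset-indicator columns."""

    data: pd.DataFrame
    asset_columns: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data["urac"].to_numpy(dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy(dtype=float)

    @property
    def assets(self) -> pd.DataFrame:
        return self.data[self.asset_columns]

    def validate(self) -> list[str]:
        """Return a list of per-row problem descriptions (empty when clean)."""
        problems: list[str] = []
        df = self.data
        for name in ("urac", "weight"):
            if name not in df.columns:
                raise SchemaError(f"required column '{name}' missing")
        bad = df.index[df["urac"].isna() | ~df["urac"].isin((0, 1))]
        problems += [f"row {i}: outcome must be 0 or 1, got {df.at[i, 'urac']!r}" for i in bad]
        bad = df.index[df["weight"].isna() | (df["weight"] <= 0)]
        problems += [f"row {i}: weight must be > 0, got {df.at[i, 'weight']!r}" for i in bad]
        if "woman_edu" in df.columns:
            bad = df.index[~df["woman_edu"].isin(EDUCATION_LEVELS)]
            problems += [f"row {i}: unknown education code {df.at[i, 'woman_edu']!r}" for i in bad]
        if "husband_edu" in df.columns:
            bad = df.index[~df["husband_edu"].isin(EDUCATION_LEVELS)]
            problems += [f"row {i}: unknown education code {df.at[i, 'husband_edu']!r}" for i in bad]
        if "region" in df.columns:
            bad = df.index[~df["region"].isin(REGIONS)]
            problems += [f"row {i}: unknown region code {df.at[i, 'region']!r}" for i in bad]
        if "birth_order" in df.columns:
            bad = df.index[df["birth_order"].isna() | (df["birth_order"] < 1)]
            problems += [f"row {i}: birth order must be >= 1" for i in bad]
        return problems


def load_schema(path) -> dict:
    """Read a YAML schema map ({column_roles: {outcome: ..., weight: ..., assets: [...], determinants: {...}}})."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "column_roles" not in cfg:
        raise SchemaError("schema YAML must contain a 'column_roles' mapping")
    return cfg["column_roles"]


def load_survey(path, schema: dict | None = None) -> SurveyDataset:
    """Load a CSV survey table and validate it.

    Parameters
    ----------
    path : str or file
        CSV with a header row.
    schema : dict, optional
        Column-role map: keys ``outcome``, ``weight``, ``assets`` (list) and
        ``determinants`` (canonical-name -> file-column). Omitted when the
        file already uses canonical column names and ``asset_*`` columns.

    Raises
    ------
    SchemaError
        A mapped column is missing from the file.
    ValidationError
        Any row violates the invariants; the message lists every offending
        row with its reason.
    """
    df = pd.read_csv(path)
    rename: dict[str, str] = {}
    if schema:
        for role, canon in (("outcome", "urac"), ("weight", "weight")):
            col = schema.get(role)
            if col is not None:
                if col not in df.columns:
                    raise SchemaError(f"column '{col}' (role {role}) not in file")
                rename[col] = canon
        for canon, col in (schema.get("determinants") or {}).items():
            if col not in df.columns:
                raise SchemaError(f"column '{col}' (determinant {canon}) not in file")
            rename[col] = canon
        asset_cols = schema.get("assets") or []
        missing = [c for c in asset_cols if c not in df.columns]
        if missing:
            raise SchemaError(f"asset columns not in file: {missing}")
    else:
        asset_cols = [c for c in df.columns if c.startswith("asset_")]
    df = df.rename(columns=rename)
    ds = SurveyDataset(data=df, asset_columns=list(asset_cols))
    problems = ds.validate()
    if problems:
        raise ValidationError(f"{len(problems)} invalid rows:\n" + "\n".join(problems))
    return ds


def recode_outcome(n_anc_visits) -> np.ndarray:
    """Regular antenatal care: 1 iff at least four antenatal visits."""
    v = np.asarray(n_anc_visits)
    if np.any(v < 0):
        raise ValueError("visit counts must be non-negative")
    return (v >= 4).astype(int)


@dataclass
class RecodedMatrix:
    """Determinant design matrix, outcome and weights, ready for modelling."""

    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if len(self.X) != len(self.y) or len(self.y) != len(self.weights):
            raise ValueError("X, y and weights must have equal length")


def _dummies(series: pd.Series, levels, prefix: str, reference: str) -> pd.DataFrame:
    unknown = set(series.dropna().unique()) - set(levels)
    if unknown:
        raise ValueError(f"unknown {prefix} codes: {sorted(map(str, unknown))}")
    out = {}
    for lv in levels:
        if lv == reference:
            continue
        out[f"{prefix}_{lv}"] = (series == lv).astype(int)
    return pd.DataFrame(out, index=series.index)


def recode_determinants(ds: SurveyDataset, *, first_birth_interval: str = "adequate",
                        no_previous_birth_indicator: bool = False) -> RecodedMatrix:
    """Build the determinant design matrix from validated raw fields.

    Parameters
    ----------
    ds : SurveyDataset
        Validated dataset with the canonical raw fields.
    first_birth_interval : {"adequate", "short"}
        First-order births have no preceding interval. ``"adequate"``
        (default) codes them as interval > 24 months — no short-interval
        risk is present; ``"short"`` codes them 0.
    no_previous_birth_indicator : bool
        Add an explicit ``no_previous_birth`` dummy instead of silently
        folding first births into the zero category of the previous-birth
        variables (which are always coded 0 for first births).
    """
    if first_birth_interval not in ("adequate", "short"):
        raise ValueError("first_birth_interval must be 'adequate' or 'short'")
    df = ds.data
    parts = []

    age = df["age_at_birth"].astype(float)
    edges = {"age_20_24": (20, 25), "age_25_29": (25, 30), "age_30_34": (30, 35),
             "age_35_39": (35, 40), "age_40p": (40, np.inf)}
    parts.append(pd.DataFrame(
        {c: ((age >= lo) & (age < hi)).astype(int) for c, (lo, hi) in edges.items()},
        index=df.index))

    parts.append(_dummies(df["woman_edu"], EDUCATION_LEVELS, "edu", "none"))
    parts.append(_dummies(df["husband_edu"], EDUCATION_LEVELS, "husband_edu", "none"))
    parts.append(_dummies(df["region"], REGIONS, "region", "urban_gov"))

    first = df["birth_order"].astype(float) == 1
    interval = df["birth_interval_months"].astype(float)
    gt24 = (interval > 24).fillna(False).astype(int)
    if first_birth_interval == "adequate":
        gt24 = gt24.where(~first, 1)
    extra = {
        "toilet_modern": (df["toilet"] == "modern").astype(int),
        "terminated_pregnancy": df["terminated_pregnancy"].astype(float).fillna(0).astype(int),
        "interval_gt24": gt24,
        "single_birth": (df["n_births_this_pregnancy"].astype(float) == 1).astype(int),
        "birth_order": df["birth_order"].astype(float),
        "prev_medical": df["prev_medical"].astype(float).where(~first, 0).fillna(0).astype(int),
        "prev_csection": df["prev_csection"].astype(float).where(~first, 0).fillna(0).astype(int),
        "prev_alive": df["prev_alive"].astype(float).where(~first, 0).fillna(0).astype(int),
    }
    parts.append(pd.DataFrame(extra, index=df.index))
    X = pd.concat(parts, axis=1)[list(DETERMINANT_COLUMNS)]
    if no_previous_birth_indicator:
        X["no_previous_birth"] = first.astype(int)
    return RecodedMatrix(X=X, y=ds.outcome, weights=ds.weights)
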