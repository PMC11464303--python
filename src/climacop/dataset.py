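"""Likert questionnaire tables: reading, validation, cleansing, normalization, summaries.

A questionnaire table has one row per respondent with an identifier column,
categorical demographic attributes (age group, education, ...), integer
responses on a 1-5 Likert scale for each criterion, and optionally a numeric
target column used downstream for weight learning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Cell contents recognized as missing in input CSV files.
MISSING_MARKERS = ("", "NA", "NaN", "nan", "na", "N/A")

#: Canonical cleansing rule order; a removed row is attributed to the first
#: rule that fires, in this order.
ALL_RULES = (
    "duplicates",
    "missing",
    "out_of_range",
    "straight_line",
    "reverse_item_inconsistency",
)

#: Rules enabled by default. Straight-lining and reverse-item checks need
#: study-specific configuration, so they are opt-in.
DEFAULT_RULES = ("duplicates", "missing", "out_of_range")

LIKERT_MIN, LIKERT_MAX = 1, 5


@dataclass(frozen=True)
class CriteriaSpec:
    """Maps criteria to factors and factors to a benefit/cost direction.

    Benefit (beneficial) criteria are those where a larger score indicates a
    better safety climate; cost (non-beneficial) criteria are the opposite.
    The partition drives the P/R split in COPRAS.
    """

    criteria: tuple[str, ...]
    factor_of: Mapping[str, str]
    direction_of_factor: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ConfigurationError("criteria spec must declare at least one criterion")
        if len(set(self.criteria)) != len(self.criteria):
            raise ConfigurationError("criterion ids must be unique")
        for cid in self.criteria:
            if cid not in self.factor_of:
                raise ConfigurationError(f"criterion {cid!r} has no factor assignment")
            fac = self.factor_of[cid]
            if fac not in self.direction_of_factor:
                raise ConfigurationError(f"factor {fac!r} has no declared direction")
        for fac, direction in self.direction_of_factor.items():
            if direction not in ("benefit", "cost"):
                raise ConfigurationError(
                    f"factor {fac!r} direction must be 'benefit' or 'cost', got {direction!r}"
                )

    def direction(self, criterion: str) -> str:
        return self.direction_of_factor[self.factor_of[criterion]]

    @property
    def benefit_ids(self) -> tuple[str, ...]:
        return tuple(c for c in self.criteria if self.direction(c) == "benefit")

    @property
    def cost_ids(self) -> tuple[str, ...]:
        return tuple(c for c in self.criteria if self.direction(c) == "cost")

    @property
    def factors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.criteria:
            seen.setdefault(self.factor_of[c], None)
        return tuple(seen)

    def to_dict(self) -> dict:
        return {
            "criteria": [{"id": c, "factor": self.factor_of[c]} for c in self.criteria],
            "factors": [
                {"name": f, "direction": self.direction_of_factor[f]} for f in self.factors
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CriteriaSpec":
        try:
            criteria = tuple(entry["id"] for entry in data["criteria"])
            factor_of = {entry["id"]: entry["factor"] for entry in data["criteria"]}
            direction_of_factor = {
                entry["name"]: entry["direction"] for entry in data["factors"]
            }
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed criteria spec: {exc}") from exc
        return cls(criteria, factor_of, direction_of_factor)

    @classmethod
    def from_file(cls, path: str | Path) -> "CriteriaSpec":
        path = Path(path)
        try:
            text = path.read_text()
        except OSError as exc:
            raise DataError(f"cannot read criteria spec {path}: {exc}") from exc
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)


@dataclass
class LikertDataset:
    """Respondent-level questionnaire table.

    ``responses`` is respondents x criteria, float-valued so that missing
    cells (NaN) can be represented before cleansing. After :func:`cleanse`
    every cell is an integer in {1, ..., 5}.
    """

    ids: list[str]
    attributes: pd.DataFrame
    responses: pd.DataFrame
    target: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise DataError("respondent ids must be unique")
        if len(self.attributes) != len(self.ids) or len(self.responses) != len(self.ids):
            raise DataError("ids, attributes and responses must have equal length")
        self.attributes = self.attributes.reset_index(drop=True)
        self.responses = self.responses.reset_index(drop=True).astype(float)
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
            if self.target.shape != (len(self.ids),):
                raise DataError("target length must match respondent count")

    @property
    def n_respondents(self) -> int:
        return len(self.ids)

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(self.responses.columns)

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(self.attributes.columns)

    def is_clean(self) -> bool:
        vals = self.responses.to_numpy()
        return bool(
            np.isfinite(vals).all()
            and (vals == np.round(vals)).all()
            and (vals >= LIKERT_MIN).all()
            and (vals <= LIKERT_MAX).all()
        )

    def take(self, positions: Sequence[int]) -> "LikertDataset":
        pos = list(positions)
        return LikertDataset(
            ids=[self.ids[i] for i in pos],
            attributes=self.attributes.iloc[pos],
            responses=self.responses.iloc[pos],
            target=None if self.target is None else self.target[pos],
        )


@dataclass
class CleansingReport:
    """Accounting of rows removed by each cleansing rule."""

    duplicates: int = 0
    missing: int = 0
    out_of_range: int = 0
    rule_violation: int = 0
    inconsistent: int = 0
    retained: int = 0
    removed_indices: dict[str, list[int]] = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return (
            self.duplicates
            + self.missing
            + self.out_of_range
            + self.rule_violation
            + self.inconsistent
        )

    def to_dict(self) -> dict:
        return {
            "duplicates": self.duplicates,
            "missing": self.missing,
            "out_of_range": self.out_of_range,
            "rule_violation": self.rule_violation,
            "inconsistent": self.inconsistent,
            "retained": self.retained,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def read_likert_csv(
    path: str | Path,
    spec: CriteriaSpec,
    *,
    id_col: str = "id",
    target_col: str | None = None,
) -> LikertDataset:
    """Read a respondent table from CSV.

    Every column other than the id column, the target column, and the
    criteria declared in ``spec`` is treated as a categorical demographic
    attribute. Non-numeric or absent response cells are preserved as missing
    values; :func:`cleanse` decides their fate.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise DataError(f"cannot parse {path}: {exc}") from exc

    required = [id_col, *spec.criteria] + ([target_col] if target_col else [])
    for col in required:
        if col not in frame.columns:
            raise ConfigurationError(f"input file {path} lacks required column {col!r}")

    def _to_numeric(col: pd.Series) -> pd.Series:
        col = col.replace(dict.fromkeys(MISSING_MARKERS, np.nan))
        return pd.to_numeric(col, errors="coerce")

    responses = frame[list(spec.criteria)].apply(_to_numeric)
    target = _to_numeric(frame[target_col]).to_numpy() if target_col else None
    attr_cols = [
        c for c in frame.columns if c != id_col and c != target_col and c not in spec.criteria
    ]
    return LikertDataset(
        ids=frame[id_col].tolist(),
        attributes=frame[attr_cols].copy(),
        responses=responses,
        target=target,
    )


def write_likert_csv(
    ds: LikertDataset,
    path: str | Path,
    *,
    id_col: str = "id",
    target_col: str = "target",
) -> None:
    """Write a respondent table to CSV (inverse of :func:`read_likert_csv`)."""
    out = pd.DataFrame({id_col: ds.ids})
    out = pd.concat([out, ds.attributes.reset_index(drop=True)], axis=1)
    resp = ds.responses.copy()
    # Integer-valued cells are written without a trailing ".0".
    for col in resp.columns:
        vals = resp[col]
        if vals.dropna().mod(1).eq(0).all():
            resp[col] = vals.astype("Int64")
    out = pd.concat([out, resp], axis=1)
    if ds.target is not None:
        out[target_col] = ds.target
    out.to_csv(path, index=False)


def _row_key(attrs: pd.Series, resp: pd.Series) -> tuple:
    def norm(v):
        if isinstance(v, float) and np.isnan(v):
            return None
        return v

    return tuple(norm(v) for v in attrs) + tuple(norm(v) for v in resp)


def cleanse(
    ds: LikertDataset,
    rules: Sequence[str] = DEFAULT_RULES,
    *,
    reverse_pairs: Sequence[tuple[str, str]] | None = None,
    reverse_threshold: float = 3.0,
) -> tuple[LikertDataset, CleansingReport]:
    """Remove contaminated rows; return the clean dataset and an accounting.

    Rules (applied per row in canonical order; the first that fires wins):

    ``duplicates``
        The row's full response vector AND demographic attributes match an
        earlier row (ids excluded). The first occurrence is retained.
    ``missing``
        Any response cell is missing. Rows are removed, never imputed.
    ``out_of_range``
        Any response is not an integer in {1, ..., 5}.
    ``straight_line``
        Zero variance across all items (the respondent gave one answer
        throughout), a common "violated the survey rules" pattern.
    ``reverse_item_inconsistency``
        For a configured reverse-keyed item pair (a, b) on a 1-5 scale,
        |a + b - 6| exceeds ``reverse_threshold``: the respondent strongly
        agreed with both a statement and its negation.
    """
    unknown = set(rules) - set(ALL_RULES)
    if unknown:
        raise ConfigurationError(f"unknown cleansing rule(s): {sorted(unknown)}")
    if "reverse_item_inconsistency" in rules and not reverse_pairs:
        raise ConfigurationError(
            "reverse_item_inconsistency rule requires configured item pairs"
        )
    if reverse_pairs:
        for a, b in reverse_pairs:
            for item in (a, b):
                if item not in ds.criterion_ids:
                    raise ConfigurationError(f"reverse-item pair references unknown item {item!r}")

    active = [r for r in ALL_RULES if r in rules]
    report = CleansingReport(removed_indices={r: [] for r in active})
    seen_keys: set[tuple] = set()
    keep: list[int] = []

    resp_np = ds.responses.to_numpy()
    for i in range(ds.n_respondents):
        row = resp_np[i]
        fired: str | None = None
        key = _row_key(ds.attributes.iloc[i], ds.responses.iloc[i])
        for rule in active:
            if rule == "duplicates" and key in seen_keys:
                fired = rule
            elif rule == "missing" and np.isnan(row).any():
                fired = rule
            elif rule == "out_of_range":
                finite = row[np.isfinite(row)]
                if ((finite < LIKERT_MIN) | (finite > LIKERT_MAX) | (finite != np.round(finite))).any():
                    fired = rule
            elif rule == "straight_line":
                finite = row[np.isfinite(row)]
                if len(finite) and np.ptp(finite) == 0:
                    fired = rule
            elif rule == "reverse_item_inconsistency":
                for a, b in reverse_pairs or ():
                    va = ds.responses[a].iloc[i]
                    vb = ds.responses[b].iloc[i]
                    if np.isfinite(va) and np.isfinite(vb) and abs(va + vb - 6) > reverse_threshold:
                        fired = rule
                        break
            if fired:
                break
        seen_keys.add(key)
        if fired is None:
            keep.append(i)
        else:
            report.removed_indices[fired].append(i)
            if fired == "straight_line":
                report.rule_violation += 1
            elif fired == "reverse_item_inconsistency":
                report.inconsistent += 1
            else:
                setattr(report, fired, getattr(report, fired) + 1)

    report.retained = len(keep)
    clean = ds.take(keep)
    clean.responses = clean.responses.astype(float)
    if not clean.is_clean() and {"missing", "out_of_range"} <= set(rules):
        raise DataError("cleansing left invalid cells; input violates assumptions")
    logger.info(
        "cleanse: retained %d of %d rows (%s)",
        report.retained,
        ds.n_respondents,
        report.to_dict(),
    )
    return clean, report


def minmax_normalize(values: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Column-wise min-max normalization to [0, 1].

    A constant column maps to all zeros (with a warning) rather than 0/0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
        squeeze = True
    else:
        squeeze = False
    if arr.size == 0:
        raise DataError("minmax_normalize requires at least one row")
    lo = arr.min(axis=0)
    hi = arr.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) mapped to all zeros under min-max",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, span)
    out = (arr - lo) / safe
    out[:, constant] = 0.0
    return out[:, 0] if squeeze else out


def summarize(ds: LikertDataset, attribute: str) -> pd.DataFrame:
    """Frequency table (category, count, percent) for one demographic attribute.

    Percentages are reported to two decimals of the total respondent count.
    """
    if attribute not in ds.attribute_names:
        raise ConfigurationError(f"unknown attribute {attribute!r}")
    counts = ds.attributes[attribute].value_counts(sort=False)
    total = ds.n_respondents
    table = pd.DataFrame(
        {
            "category": counts.index,
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / total, 2),
        }
    )
    return table.reset_index(drop=True)


def group_indices(ds: LikertDataset, attribute: str) -> dict[str, np.ndarray]:
    """Row positions per category of ``attribute``, in order of first appearance."""
    if attribute not in ds.attribute_names:
        raise ConfigurationError(f"unknown attribute {attribute!r}")
    col = ds.attributes[attribute]
    order: dict[str, None] = {}
    for v in col:
        order.setdefault(v, None)
    return {cat: np.flatnonzero((col == cat).to_numpy()) for cat in order}
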