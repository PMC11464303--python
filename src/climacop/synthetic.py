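"""Synthetic Likert questionnaire generator with known ground truth.

Emulates a safety-climate survey: 27 items in four factors (safety
communication, management, attitude, awareness) answered on a 1-5 scale by
respondents with demographic attributes whose categories carry planted
factor-level mean shifts. A composite target with known true item weights
supports weight-learning tests, and contamination (duplicates, missing
cells, out-of-range values, straight-lining) is injected with recorded row
indices so cleansing tests are exact rather than statistical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError
from .dataset import CriteriaSpec, LikertDataset
from .weighting import WeightVector

#: Demographic schema shaped after the study population: proportions for
#: gender/age/education follow the published sample statistics (renormalized
#: to sum to one, since the printed percentages carry rounding); the
#: remaining attributes use plausible road-construction workforce mixes.
DEFAULT_ATTRIBUTES: dict[str, dict[str, float]] = {
    "gender": {"Male": 0.9329, "Female": 0.0671},
    "age": {"18-30": 0.1783, "31-40": 0.2657, "41-50": 0.3563, "51 or older": 0.1997},
    "working_years": {
        "First year": 0.12,
        "1-3": 0.18,
        "3-5": 0.18,
        "5-10": 0.22,
        "10-20": 0.20,
        "20 or over": 0.10,
    },
    "accident_experience": {"Experienced": 0.25, "Not experienced": 0.55, "Seen": 0.20},
    "job_type": {"Bridge workers": 0.35, "Road workers": 0.40, "Tunnel workers": 0.25},
    "education": {
        "Primary": 0.3405,
        "Junior high school": 0.5162,
        "High school and above": 0.1433,
    },
}

DEFAULT_FACTORS: dict[str, int] = {
    "safety_communication": 10,
    "safety_management": 7,
    "safety_attitude": 5,
    "safety_awareness": 5,
}

#: Planted per-factor mean shifts by demographic category. The age ordering
#: mirrors the published ranking (41-50 highest, 51+ lowest); attributes not
#: listed carry no planted effect.
DEFAULT_GROUP_EFFECTS: dict[str, dict[str, float]] = {
    "age": {"18-30": -0.05, "31-40": 0.05, "41-50": 0.15, "51 or older": -0.15},
    "education": {
        "Primary": -0.10,
        "Junior high school": 0.0,
        "High school and above": 0.10,
    },
}

#: Contamination rates chosen so the total removal fraction (~7.5%) matches
#: the scale of a real survey's cleansing loss.
DEFAULT_CONTAMINATION: dict[str, float] = {
    "duplicate": 0.02,
    "missing": 0.025,
    "out_of_range": 0.015,
    "straight_line": 0.015,
}


def default_criteria_spec(
    factors: Mapping[str, int] | None = None, cost_factors: Sequence[str] = ("safety_awareness",)
) -> CriteriaSpec:
    """Criteria spec C1..Cn over the configured factors.

    By default safety awareness is the non-beneficial factor and the other
    three are beneficial, mirroring the study configuration.
    """
    factors = dict(factors or DEFAULT_FACTORS)
    criteria = []
    factor_of = {}
    i = 0
    for fac, size in factors.items():
        for _ in range(size):
            i += 1
            cid = f"C{i}"
            criteria.append(cid)
            factor_of[cid] = fac
    direction = {f: ("cost" if f in cost_factors else "benefit") for f in factors}
    return CriteriaSpec(tuple(criteria), factor_of, direction)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_respondents: int = 656
    attributes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ATTRIBUTES.items()}
    )
    n_criteria: int = 27
    factors: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_FACTORS))
    group_effects: Mapping[str, Mapping[str, float]] | Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_EFFECTS.items()}
    )
    base_mean: float = 4.2
    response_sd: float = 0.7
    true_weights: Optional[np.ndarray] = None
    target_noise_sd: float = 0.05
    contamination: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINATION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, cats in self.attributes.items():
            total = sum(cats.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"proportions for attribute {name!r} sum to {total}, expected 1"
                )
        if sum(self.factors.values()) != self.n_criteria:
            raise ConfigurationError(
                f"factor sizes sum to {sum(self.factors.values())}, "
                f"but n_criteria is {self.n_criteria}"
            )
        for rule, rate in self.contamination.items():
            if not (0.0 <= rate <= 0.2):
                raise ConfigurationError(f"contamination rate {rule!r}={rate} outside [0, 0.2]")
        if self.true_weights is not None:
            self.true_weights = np.asarray(self.true_weights, dtype=float)
            if self.true_weights.shape != (self.n_criteria,):
                raise ConfigurationError("true_weights must have one entry per criterion")
            if (self.true_weights < 0).any() or abs(self.true_weights.sum() - 1.0) > 1e-9:
                raise ConfigurationError("true_weights must be nonnegative and sum to 1")

    def resolve_true_weights(self) -> np.ndarray:
        if self.true_weights is not None:
            return self.true_weights
        raw = np.arange(self.n_criteria, 0, -1, dtype=float)  # linearly decreasing
        return raw / raw.sum()

    def criteria_spec(self) -> CriteriaSpec:
        return default_criteria_spec(self.factors)


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream checks."""

    planted_ordering: dict[str, list[str]]
    true_weights: np.ndarray
    contamination_indices: dict[str, list[int]]
    latent_means: dict[str, dict[str, np.ndarray]]
    clean_rows: int = 0


def _shift_for(cfg: SyntheticConfig, attr: str, cat: str, factor: str) -> float:
    table = cfg.group_effects.get(attr, {})
    entry = table.get(cat, 0.0)
    if isinstance(entry, Mapping):
        return float(entry.get(factor, 0.0))
    return float(entry)  # scalar shift applied to every factor


def generate_dataset(cfg: SyntheticConfig | None = None) -> tuple[LikertDataset, GroundTruth]:
    """Generate a contaminated Likert dataset with recorded ground truth.

    Clean rows are drawn as latent = base mean + sum of the respondent's
    category shifts + N(0, sd), rounded and clipped to {1, ..., 5}.
    Contaminated rows are appended after the clean block with their row
    positions recorded per rule, so report counts can be checked exactly.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.criteria_spec()
    n = cfg.n_respondents

    factor_of = [spec.factor_of[c] for c in spec.criteria]
    attr_names = list(cfg.attributes)
    attrs = pd.DataFrame(
        {
            name: rng.choice(list(cats), size=n, p=list(cats.values()))
            for name, cats in cfg.attributes.items()
        }
    )

    shift = np.zeros((n, cfg.n_criteria))
    for name in attr_names:
        for j, fac in enumerate(factor_of):
            col = attrs[name].map(lambda cat: _shift_for(cfg, name, cat, fac)).to_numpy()
            shift[:, j] += col
    latent = cfg.base_mean + shift + rng.normal(0.0, cfg.response_sd, size=(n, cfg.n_criteria))
    clean = np.clip(np.round(latent), 1, 5).astype(float)

    resp = pd.DataFrame(clean, columns=list(spec.criteria))
    rows_attrs = [attrs]
    rows_resp = [resp]
    seen_keys = {tuple(attrs.iloc[i]) + tuple(clean[i]) for i in range(n)}

    def counts(rule: str) -> int:
        return int(round(cfg.contamination.get(rule, 0.0) * n))

    extra_attrs: list[pd.Series] = []
    extra_resp: list[np.ndarray] = []

    k_dup = counts("duplicate")
    if k_dup:
        for i in rng.choice(n, size=k_dup, replace=False):
            extra_attrs.append(attrs.iloc[i])
            extra_resp.append(clean[i].copy())

    k_miss = counts("missing")
    if k_miss:
        for i in rng.choice(n, size=k_miss, replace=False):
            row = clean[i].copy()
            blank = rng.choice(cfg.n_criteria, size=rng.integers(1, 4), replace=False)
            row[blank] = np.nan
            extra_attrs.append(attrs.iloc[i])
            extra_resp.append(row)

    k_range = counts("out_of_range")
    if k_range:
        for i in rng.choice(n, size=k_range, replace=False):
            row = clean[i].copy()
            row[rng.integers(cfg.n_criteria)] = float(rng.choice([0, 6, 7]))
            extra_attrs.append(attrs.iloc[i])
            extra_resp.append(row)

    k_straight = counts("straight_line")
    if k_straight:
        # Constant-answer rows; the guard keeps them from colliding with an
        # existing (attributes, responses) key and being counted as duplicates.
        values = [5.0, 1.0, 4.0, 2.0, 3.0]
        for pos, i in enumerate(rng.choice(n, size=k_straight, replace=False)):
            for tries in range(len(values)):
                val = values[(pos + tries) % len(values)]
                row = np.full(cfg.n_criteria, val)
                key = tuple(attrs.iloc[i]) + tuple(row)
                if key not in seen_keys:
                    break
            seen_keys.add(key)
            extra_attrs.append(attrs.iloc[i])
            extra_resp.append(row)

    # Contaminated rows are appended after the clean block, in rule order.
    contamination_indices: dict[str, list[int]] = {}
    pos = n
    for rule, k in (
        ("duplicate", k_dup),
        ("missing", k_miss),
        ("out_of_range", k_range),
        ("straight_line", k_straight),
    ):
        contamination_indices[rule] = list(range(pos, pos + k))
        pos += k

    if extra_resp:
        rows_attrs.append(pd.DataFrame(extra_attrs).reset_index(drop=True))
        rows_resp.append(pd.DataFrame(np.vstack(extra_resp), columns=list(spec.criteria)))
    all_attrs = pd.concat(rows_attrs, ignore_index=True)
    all_resp = pd.concat(rows_resp, ignore_index=True)
    total = len(all_resp)
    ids = [f"R{i + 1:05d}" for i in range(total)]

    planted_ordering: dict[str, list[str]] = {}
    latent_means: dict[str, dict[str, np.ndarray]] = {}
    for name, cats in cfg.attributes.items():
        mean_shift = {}
        latent_means[name] = {}
        for cat in cats:
            per_crit = np.array(
                [cfg.base_mean + _shift_for(cfg, name, cat, fac) for fac in factor_of]
            )
            latent_means[name][cat] = per_crit
            mean_shift[cat] = float(per_crit.mean())
        order = sorted(cats, key=lambda c: (-mean_shift[c], list(cats).index(c)))
        planted_ordering[name] = order

    truth = GroundTruth(
        planted_ordering=planted_ordering,
        true_weights=cfg.resolve_true_weights(),
        contamination_indices=contamination_indices,
        latent_means=latent_means,
        clean_rows=n,
    )
    ds = LikertDataset(ids=ids, attributes=all_attrs, responses=all_resp)
    return ds, truth


def generate_target(
    ds: LikertDataset,
    w_star: WeightVector | np.ndarray,
    noise_sd: float,
    seed: int = 0,
) -> np.ndarray:
    """Composite target y_i = sum_j w*_j x_ij + N(0, noise_sd), min-max normalized.

    Stands in for a factor-score target with known true item weights. Rows
    with missing responses yield NaN targets (they are removed by cleansing).
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    w = np.asarray(getattr(w_star, "weights", w_star), dtype=float)
    X = ds.responses.to_numpy()
    if w.shape != (X.shape[1],):
        raise DataError("w_star is not aligned with the dataset criteria")
    rng = np.random.default_rng(seed)
    y = X @ w + rng.normal(0.0, noise_sd, size=X.shape[0])
    lo, hi = np.nanmin(y), np.nanmax(y)
    if hi == lo:
        return np.zeros_like(y)
    return (y - lo) / (hi - lo)
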