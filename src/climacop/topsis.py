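"""Cloud-TOPSIS comparators for method-agreement studies.

Variant 1 treats each weighted cloud (wEx, wEn, wHe) as a point in three
dimensions and uses Euclidean distance to per-criterion ideal and negative
ideal clouds. Variant 2 weights the cloud as (wEx, (wEn)^2, (wHe)^2) and
accumulates a composite cloud distance with mixing weights (lambda1,
lambda2, lambda3) over the expectation-offset, entropy-ratio and
hyper-entropy-ratio terms.

Closeness defaults to d-/(d+ + d-) so that larger is better and published
rank directions are reproduced; the literal orientation d+/(d+ + d-) is
available via ``orientation="literal"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError
from .cloud import Cloud
from .copras import CloudDecisionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LambdaWeights:
    """Mixing weights of the three cloud-distance terms; must sum to one."""

    l1: float = 1 / 3
    l2: float = 1 / 3
    l3: float = 1 / 3

    def __post_init__(self) -> None:
        if min(self.l1, self.l2, self.l3) < 0:
            raise ConfigurationError("lambda weights must be nonnegative")
        if abs(self.l1 + self.l2 + self.l3 - 1.0) > 1e-9:
            raise ConfigurationError("lambda weights must sum to 1")


@dataclass
class TopsisResult:
    """Distances to the ideal/negative-ideal clouds, closeness, and ranks."""

    groups: list[str]
    d_plus: np.ndarray
    d_minus: np.ndarray
    closeness: np.ndarray
    rank: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "closeness": self.closeness,
                "rank": self.rank,
            }
        )


def _closeness_and_ranks(groups, d_plus, d_minus, orientation):
    with np.errstate(invalid="ignore"):
        denom = d_plus + d_minus
    closeness = np.full(len(groups), 0.5)
    ok = denom > 0
    if orientation == "distance_to_negative":
        closeness[ok] = d_minus[ok] / denom[ok]
    elif orientation == "literal":
        closeness[ok] = d_plus[ok] / denom[ok]
    else:
        raise ConfigurationError(f"unknown closeness orientation {orientation!r}")
    order = np.lexsort((np.arange(len(closeness)), -closeness))
    rank = np.empty(len(closeness), dtype=int)
    rank[order] = np.arange(1, len(closeness) + 1)
    return TopsisResult(list(groups), d_plus, d_minus, closeness, rank)


def cm_topsis1(
    cdm: CloudDecisionMatrix,
    w,
    *,
    orientation: str = "distance_to_negative",
    apply_direction: bool = False,
    spec=None,
) -> TopsisResult:
    """Euclidean cloud-TOPSIS on weighted clouds (wEx, wEn, wHe).

    Per criterion the ideal cloud is (max wEx, min wEn, min wHe) and the
    negative ideal (min wEx, max wEn, max wHe). With ``apply_direction`` and
    a criteria spec, cost criteria swap the max/min on the expectation.
    """
    weights = np.asarray(getattr(w, "weights", w), dtype=float)
    m, n = cdm.shape
    if m < 2:
        raise DataError("cloud TOPSIS needs at least 2 alternatives")
    if weights.shape != (n,):
        raise DataError("weight vector is not aligned with the criteria")

    wex = cdm.param_array("ex") * weights
    wen = cdm.param_array("en") * weights
    whe = cdm.param_array("he") * weights
    ideal_ex, neg_ex = wex.max(axis=0), wex.min(axis=0)
    if apply_direction:
        if spec is None:
            raise ConfigurationError("apply_direction requires a criteria spec")
        for j, cid in enumerate(cdm.criteria):
            if spec.direction(cid) == "cost":
                ideal_ex[j], neg_ex[j] = neg_ex[j], ideal_ex[j]
    ideal = (ideal_ex, wen.min(axis=0), whe.min(axis=0))
    neg = (neg_ex, wen.max(axis=0), whe.max(axis=0))
    d_plus = np.sqrt(
        ((wex - ideal[0]) ** 2 + (wen - ideal[1]) ** 2 + (whe - ideal[2]) ** 2).sum(axis=1)
    )
    d_minus = np.sqrt(
        ((wex - neg[0]) ** 2 + (wen - neg[1]) ** 2 + (whe - neg[2]) ** 2).sum(axis=1)
    )
    return _closeness_and_ranks(cdm.groups, d_plus, d_minus, orientation)


def cloud_distance(a: Cloud, b: Cloud, lam: LambdaWeights | None = None) -> float:
    """Composite distance between two clouds.

    Term 1 is the expectation offset |Ex_a - Ex_b| scaled by the span of the
    two clouds' 3-En envelopes; terms 2 and 3 are one minus the min/max
    ratios of the entropies and hyper-entropies. A ratio with both operands
    zero contributes 0 (identical degenerate clouds), as does a zero span.
    """
    lam = lam or LambdaWeights()
    hi = max(a.ex + 3 * a.en, b.ex + 3 * b.en)
    lo = min(a.ex - 3 * a.en, b.ex - 3 * b.en)
    span = hi - lo
    t1 = abs(a.ex - b.ex) / span if span > 0 else 0.0

    def ratio_term(x: float, y: float) -> float:
        mx = max(x, y)
        if mx == 0:
            return 0.0
        return 1.0 - min(x, y) / mx

    t2 = ratio_term(a.en, b.en)
    t3 = ratio_term(a.he, b.he)
    return lam.l1 * t1 + lam.l2 * t2 + lam.l3 * t3


def cm_topsis2(
    cdm: CloudDecisionMatrix,
    w,
    lam: LambdaWeights | None = None,
    *,
    orientation: str = "distance_to_negative",
    squared_entropies: bool = True,
) -> TopsisResult:
    """Cloud-distance TOPSIS on weighted clouds (wEx, (wEn)^2, (wHe)^2).

    Distances to the per-criterion ideal and negative-ideal clouds accumulate
    as sums of :func:`cloud_distance` over criteria. ``squared_entropies``
    toggles the literal squared weighting of En/He (the default) versus the
    plain (wEx, wEn, wHe) form.
    """
    lam = lam or LambdaWeights()
    weights = np.asarray(getattr(w, "weights", w), dtype=float)
    m, n = cdm.shape
    if m < 2:
        raise DataError("cloud TOPSIS needs at least 2 alternatives")
    if weights.shape != (n,):
        raise DataError("weight vector is not aligned with the criteria")

    wex = cdm.param_array("ex") * weights
    wen = cdm.param_array("en") * weights
    whe = cdm.param_array("he") * weights
    if squared_entropies:
        wen = wen**2
        whe = whe**2
    cells = [[Cloud(wex[i, j], wen[i, j], whe[i, j]) for j in range(n)] for i in range(m)]
    ideal = [Cloud(wex[:, j].max(), wen[:, j].min(), whe[:, j].min()) for j in range(n)]
    neg = [Cloud(wex[:, j].min(), wen[:, j].max(), whe[:, j].max()) for j in range(n)]
    d_plus = np.array(
        [sum(cloud_distance(cells[i][j], ideal[j], lam) for j in range(n)) for i in range(m)]
    )
    d_minus = np.array(
        [sum(cloud_distance(cells[i][j], neg[j], lam) for j in range(n)) for i in range(m)]
    )
    return _closeness_and_ranks(cdm.groups, d_plus, d_minus, orientation)
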