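"""Cloud decision matrix and COPRAS ranking.

Each respondent group (alternative) is summarized on each criterion by a
cloud estimated from that group's responses. Realizing each cloud as the
mean of a droplet batch gives a crisp decision matrix, which is column-sum
normalized, weighted, and ranked by COPRAS: beneficial criteria accumulate
into P_i, non-beneficial into R_i, and the significance

    Q_i = P_i + (sum_i R_i) / (R_i * sum_i (1/R_i))

rewards small non-beneficial sums. The utility degree U_i = Q_i / Q_max puts
the best alternative at exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DataError
from .cloud import BackwardCloudConfig, Cloud, backward_cloud, forward_cloud
from .dataset import CriteriaSpec, LikertDataset, group_indices

logger = logging.getLogger(__name__)


def _cell_rng(master_seed: int, gi: int, cj: int) -> np.random.Generator:
    # Substream keyed by (master seed, group index, criterion index) so adding
    # a criterion or group does not perturb other cells.
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), gi, cj]))


@dataclass
class CloudDecisionMatrix:
    """m groups x n criteria grid of clouds."""

    groups: list[str]
    criteria: list[str]
    cells: list[list[Cloud]]

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.groups) or any(
            len(row) != len(self.criteria) for row in self.cells
        ):
            raise DataError("cloud decision matrix grid must be complete")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.groups), len(self.criteria))

    def param_array(self, which: str) -> np.ndarray:
        return np.array([[getattr(c, which) for c in row] for row in self.cells])

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: group, criterion, Ex, En, He."""
        rows = []
        for g, row in zip(self.groups, self.cells):
            for cid, cell in zip(self.criteria, row):
                rows.append(
                    {"group": g, "criterion": cid, "Ex": cell.ex, "En": cell.en, "He": cell.he}
                )
        return pd.DataFrame(rows)


@dataclass
class DecisionMatrix:
    """Crisp m x n matrix with a processing stage: raw -> normalized -> weighted."""

    groups: list[str]
    criteria: list[str]
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.groups), len(self.criteria)):
            raise DataError("decision matrix shape mismatch")
        if self.stage not in ("raw", "normalized", "weighted"):
            raise DataError(f"unknown stage {self.stage!r}")


@dataclass
class RankingResult:
    """COPRAS output per group: P, R, Q, the utility degree U, and the rank."""

    groups: list[str]
    P: np.ndarray
    R: np.ndarray
    Q: np.ndarray
    U: np.ndarray
    rank: np.ndarray
    r_min: float
    q_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "P": self.P,
                "R": self.R,
                "Q": self.Q,
                "U": self.U,
                "rank": self.rank,
            }
        )


def build_cloud_decision_matrix(
    ds: LikertDataset,
    attribute: str,
    spec: CriteriaSpec,
    cfg: BackwardCloudConfig | None = None,
    *,
    seed: int = 0,
) -> CloudDecisionMatrix:
    """Backward-cloud every (group, criterion) cell of one grouping attribute.

    Groups follow first-appearance order in the data. Every group must have
    at least the within-group resampling size ``cfg.c`` respondents.
    """
    cfg = cfg or BackwardCloudConfig()
    groups = group_indices(ds, attribute)
    if len(groups) < 2:
        raise DataError(f"attribute {attribute!r} must have at least 2 categories")
    resp = ds.responses[list(spec.criteria)].to_numpy()
    cells: list[list[Cloud]] = []
    for gi, (cat, rows) in enumerate(groups.items()):
        c_needed = cfg.resolve_c(len(rows))
        if len(rows) < c_needed:
            raise DataError(
                f"group {cat!r} has {len(rows)} respondents; "
                f"at least {c_needed} needed for the backward transformation"
            )
        row_cells = []
        for cj in range(len(spec.criteria)):
            cell_cfg = BackwardCloudConfig(c=cfg.c, d=cfg.d, seed=_cell_rng(seed, gi, cj))
            row_cells.append(backward_cloud(resp[rows, cj], cell_cfg))
        cells.append(row_cells)
    return CloudDecisionMatrix(list(groups), list(spec.criteria), cells)


def realize_decision_matrix(
    cdm: CloudDecisionMatrix, n_droplets: int = 2000, *, seed: int = 0
) -> DecisionMatrix:
    """Realize each cloud as the mean of ``n_droplets`` forward-cloud droplets.

    Each cell draws from an independent substream of the master seed, so the
    realization of one cell is unaffected by the rest of the grid.
    """
    if n_droplets < 1:
        raise DataError("n_droplets must be >= 1")
    m, n = cdm.shape
    values = np.empty((m, n))
    for gi in range(m):
        for cj in range(n):
            batch = forward_cloud(cdm.cells[gi][cj], n_droplets, _cell_rng(seed, gi, cj))
            values[gi, cj] = batch.mean
    return DecisionMatrix(cdm.groups, cdm.criteria, values, stage="raw")


def normalize_matrix(dm: DecisionMatrix) -> DecisionMatrix:
    """Column-sum normalization: d_ij = r_ij / sum_i r_ij."""
    col_sums = dm.values.sum(axis=0)
    if (col_sums <= 0).any():
        bad = [dm.criteria[j] for j in np.flatnonzero(col_sums <= 0)]
        raise DataError(
            f"nonpositive column sum(s) for {bad}; Likert-derived scores must be positive"
        )
    return DecisionMatrix(dm.groups, dm.criteria, dm.values / col_sums, stage="normalized")


def apply_weights(dm: DecisionMatrix, w) -> DecisionMatrix:
    """Weighted matrix d_hat_ij = omega_j * d_ij (requires a normalized matrix)."""
    weights = np.asarray(getattr(w, "weights", w), dtype=float)
    if dm.stage != "normalized":
        raise DataError("apply_weights expects a normalized decision matrix")
    if weights.shape != (len(dm.criteria),):
        raise DataError("weight vector is not aligned with the criteria")
    return DecisionMatrix(dm.groups, dm.criteria, dm.values * weights, stage="weighted")


def copras_rank(dm: DecisionMatrix, spec: CriteriaSpec) -> RankingResult:
    """COPRAS significance and utility ranking of a weighted decision matrix.

    Ties in Q are broken by input group order (logged). With no cost
    criteria the correction term has an empty sum and Q_i = P_i.
    """
    if dm.stage != "weighted":
        raise DataError("copras_rank expects a weighted decision matrix")
    benefit = [j for j, c in enumerate(dm.criteria) if spec.direction(c) == "benefit"]
    cost = [j for j, c in enumerate(dm.criteria) if spec.direction(c) == "cost"]
    P = dm.values[:, benefit].sum(axis=1) if benefit else np.zeros(len(dm.groups))
    if cost:
        R = dm.values[:, cost].sum(axis=1)
        if (R == 0).any():
            zero = [dm.groups[i] for i in np.flatnonzero(R == 0)]
            raise DataError(f"zero non-beneficial sum for group(s) {zero}; Q is undefined")
        Q = P + R.sum() / (R * (1.0 / R).sum())
        r_min = float(R.min())
    else:
        R = np.zeros(len(dm.groups))
        Q = P.copy()
        r_min = 0.0
    q_max = float(Q.max())
    U = Q / q_max
    order = np.lexsort((np.arange(len(Q)), -Q))
    rank = np.empty(len(Q), dtype=int)
    rank[order] = np.arange(1, len(Q) + 1)
    if len(np.unique(Q)) < len(Q):
        logger.info("copras_rank: tied significance values; ties broken by group order")
    return RankingResult(
        groups=list(dm.groups), P=P, R=R, Q=Q, U=U, rank=rank, r_min=r_min, q_max=q_max
    )
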