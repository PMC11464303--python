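"""Criterion weights: Garson importance from a BP network, out-of-bag
permutation importance from a random forest, and their fusion by maximizing
deviations.

Both learners consume min-max normalized inputs and a normalized target.
The fused weight on criterion j is omega_j = alpha' u_j + beta' v_j, where
(alpha, beta) on the positive unit circle maximize the weighted sum of
squared sample deviations and (alpha', beta') are their sum-one rescaling.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.tree import DecisionTreeRegressor

from ._errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)


@dataclass
class WeightVector:
    """Nonnegative per-criterion weights summing to one."""

    weights: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise DataError("weights must be a vector")
        if (self.weights < 0).any():
            raise DataError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise DataError("weights must sum to 1")

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def normalized(cls, raw: np.ndarray, provenance: str = "unspecified") -> "WeightVector":
        raw = np.asarray(raw, dtype=float)
        total = raw.sum()
        if total <= 0:
            raise DataError("cannot normalize a nonpositive weight vector")
        return cls(raw / total, provenance)


@dataclass
class NNConfig:
    """Single-hidden-layer BP network configuration.

    The hidden size defaults to floor(sqrt(m + n)) + a; ``a`` is an integer
    constant in [1, 10]. The network uses a logistic sigmoid on both the
    hidden and output layers and a squared-error objective, trained with a
    deterministic gradient-based optimizer on a seeded 70/30 split.
    """

    a: int = 2
    hidden_size: Optional[int] = None
    max_epochs: int = 500
    error_tolerance: float = 1e-6
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.a <= 10):
            raise ConfigurationError("hidden-size constant a must be in [1, 10]")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError("train_fraction must be in (0, 1)")


@dataclass
class NNModel:
    """Trained network: input->hidden weights V, hidden->output weights W,
    thresholds, and the mean squared-error halves on train and test splits."""

    V: np.ndarray
    b_hidden: np.ndarray
    W: np.ndarray
    b_out: np.ndarray
    training_error: float
    test_error: float
    converged: bool
    n_iter: int


@dataclass
class RFConfig:
    """Random-forest regression configuration for oob permutation importance."""

    n_trees: int = 500
    min_leaf: int = 5
    max_features: float = 1 / 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if not (0.0 < self.max_features <= 1.0):
            raise ConfigurationError("max_features must be a fraction in (0, 1]")


@dataclass
class CombinationDiagnostics:
    """Maximizing-deviations fusion diagnostics.

    (alpha, beta) lie on the positive unit circle; (alpha_norm, beta_norm)
    are their sum-one rescaling; ``objective`` is the maximized deviation sum
    and ``deviations`` the per-criterion D_j = sum_i (r_ij - rbar_j)^2.
    """

    alpha: float
    beta: float
    alpha_norm: float
    beta_norm: float
    objective: float
    deviations: np.ndarray = field(repr=False)


def linearity_screen(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each criterion column with the target.

    A screen for (non-)linearity: small max |r| suggests the target-criterion
    relation is nonlinear, motivating a nonlinear learner. Constant columns
    or a constant target yield r = 0 with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise DataError("linearity screen needs at least 3 samples")
    r = np.zeros(X.shape[1])
    y_sd = y.std()
    if y_sd == 0:
        warnings.warn("constant target: all correlations reported as 0", stacklevel=2)
        return r
    yc = y - y.mean()
    for j in range(X.shape[1]):
        col = X[:, j]
        sd = col.std()
        if sd == 0:
            warnings.warn(f"constant column {j}: correlation reported as 0", stacklevel=2)
            continue
        r[j] = float(np.dot(col - col.mean(), yc) / (len(y) * sd * y_sd))
    max_abs = float(np.abs(r).max())
    logger.info(
        "linearity screen: max |r| = %.4f (%s 0.6, the conventional linearity cut)",
        max_abs,
        "<" if max_abs < 0.6 else ">=",
    )
    return r


def hidden_layer_size(m: int, n: int, a: int) -> int:
    """Hidden-neuron count floor(sqrt(m + n)) + a for m inputs and n outputs."""
    if m < 1 or n < 1:
        raise ConfigurationError("m and n must be >= 1")
    if not (1 <= a <= 10):
        raise ConfigurationError("hidden-size constant a must be in [1, 10]")
    return int(math.floor(math.sqrt(m + n))) + a


def _pack(V, b_h, W, b_o):
    return np.concatenate([V.ravel(), b_h, W.ravel(), b_o])


def _unpack(theta, m, j):
    V = theta[: m * j].reshape(m, j)
    b_h = theta[m * j : m * j + j]
    W = theta[m * j + j : m * j + j + j].reshape(j, 1)
    b_o = theta[-1:]
    return V, b_h, W, b_o


def train_bp(X: np.ndarray, y: np.ndarray, cfg: NNConfig | None = None) -> NNModel:
    """Train the single-hidden-layer network on a seeded 70/30 split.

    The objective is E = mean over samples of (1/2)(y - yhat)^2 with logistic
    activations on hidden and output layers, minimized by L-BFGS with the
    analytic gradient. Training stops at ``error_tolerance`` or
    ``max_epochs`` iterations; if the tolerance is not reached the model is
    returned with ``converged=False`` (importances remain computable).
    """
    cfg = cfg or NNConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DataError("train_bp requires finite inputs")
    if X.shape[0] != len(y):
        raise DataError("X and y length mismatch")
    n_samples, m = X.shape
    j = cfg.hidden_size if cfg.hidden_size is not None else hidden_layer_size(m, 1, cfg.a)
    if n_samples < j:
        raise DataError(f"need at least {j} samples for a hidden layer of size {j}")

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n_samples)
    n_train = max(1, int(round(cfg.train_fraction * n_samples)))
    tr, te = perm[:n_train], perm[n_train:]
    Xtr, ytr = X[tr], y[tr]
    Xte, yte = X[te], y[te]

    def objective(theta, Xs, ys, want_grad=True):
        V, b_h, W, b_o = _unpack(theta, m, j)
        Z = expit(Xs @ V + b_h)
        yhat = expit(Z @ W + b_o).ravel()
        resid = yhat - ys
        E = 0.5 * float(np.mean(resid**2))
        if not want_grad:
            return E
        delta_o = (resid / len(ys)) * yhat * (1 - yhat)  # (N,)
        gW = Z.T @ delta_o[:, None]
        gb_o = np.array([delta_o.sum()])
        delta_h = np.outer(delta_o, W.ravel()) * Z * (1 - Z)  # (N, j)
        gV = Xs.T @ delta_h
        gb_h = delta_h.sum(axis=0)
        return E, _pack(gV, gb_h, gW, gb_o)

    theta0 = _pack(
        rng.normal(0.0, 0.5, size=(m, j)),
        rng.normal(0.0, 0.5, size=j),
        rng.normal(0.0, 0.5, size=(j, 1)),
        rng.normal(0.0, 0.5, size=1),
    )

    def callback(theta):
        if objective(theta, Xtr, ytr, want_grad=False) <= cfg.error_tolerance:
            raise StopIteration

    res = minimize(
        objective,
        theta0,
        args=(Xtr, ytr),
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": cfg.max_epochs, "ftol": 1e-15, "gtol": 1e-12},
    )
    V, b_h, W, b_o = _unpack(res.x, m, j)
    train_err = objective(res.x, Xtr, ytr, want_grad=False)
    test_err = objective(res.x, Xte, yte, want_grad=False) if len(te) else float("nan")
    converged = train_err <= cfg.error_tolerance
    if not converged:
        logger.warning(
            "train_bp: tolerance %.2e not reached (final E = %.3e after %d iterations)",
            cfg.error_tolerance,
            train_err,
            res.nit,
        )
    return NNModel(
        V=V,
        b_hidden=b_h,
        W=W,
        b_out=b_o,
        training_error=train_err,
        test_error=test_err,
        converged=converged,
        n_iter=int(res.nit),
    )


def garson_importance(V: np.ndarray, W: np.ndarray) -> WeightVector:
    """Garson connection-weight importance of each input.

    For hidden neuron h, each input's share is |V_ih W_h| / sum_i |V_ih W_h|;
    the importance of input i is its total share over hidden neurons,
    normalized to sum to one. Hidden neurons whose products are all zero are
    skipped. Invariant to positive rescaling of W.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    if V.shape[1] != W.shape[0]:
        raise DataError(f"shape mismatch: V is {V.shape}, W is {W.shape}")

    m = V.shape[0]
    total = np.zeros(m)
    for k in range(W.shape[1]):
        prod = np.abs(V * W[:, k][None, :])  # (m, j)
        col_sums = prod.sum(axis=0)
        usable = col_sums > 0
        if not usable.any():
            continue
        shares = prod[:, usable] / col_sums[usable]
        total += shares.sum(axis=1)
    if total.sum() == 0:
        raise DataError("all connection-weight products are zero; importance undefined")
    return WeightVector(total / total.sum(), provenance="bp")


def bp_weights(
    X: np.ndarray, y: np.ndarray, cfg: NNConfig | None = None, *, n_restarts: int = 5
) -> WeightVector:
    """Garson importance averaged over ``n_restarts`` seeded retrainings.

    Garson importance from a single network is sensitive to the random
    initialization; averaging over independent restarts (seeds derived from
    ``cfg.seed``) gives a markedly more stable estimate and is the
    recommended BP weighting route.
    """
    cfg = cfg or NNConfig()
    if n_restarts < 1:
        raise ConfigurationError("n_restarts must be >= 1")
    acc = None
    for r in range(n_restarts):
        sub = NNConfig(
            a=cfg.a,
            hidden_size=cfg.hidden_size,
            max_epochs=cfg.max_epochs,
            error_tolerance=cfg.error_tolerance,
            train_fraction=cfg.train_fraction,
            seed=cfg.seed * 1000 + r,
        )
        model = train_bp(X, y, sub)
        imp = garson_importance(model.V, model.W).weights
        acc = imp if acc is None else acc + imp
    return WeightVector(acc / acc.sum(), provenance="bp")


def rf_raw_importance(
    X: np.ndarray, y: np.ndarray, cfg: RFConfig | None = None
) -> tuple[np.ndarray, float]:
    """Raw oob permutation importances and the mean oob error.

    Each tree is fit on a bootstrap sample; on its out-of-bag rows the
    squared prediction error e1 is compared with the error e2 after
    permuting one criterion's values among those rows. The raw importance of
    criterion j is sum_t (e2 - e1)/K (can be slightly negative under noise).
    Returns (raw importances, mean oob error) for diagnostics.
    """
    cfg = cfg or RFConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 10:
        raise DataError("rf_importance needs at least 10 samples")

    rng = np.random.default_rng(cfg.seed)
    raw = np.zeros(p)
    oob_errors = []
    for _ in range(cfg.n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            min_samples_leaf=cfg.min_leaf,
            max_features=cfg.max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        if len(oob) == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        e1 = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
        oob_errors.append(e1)
        for jf in range(p):
            Xp = X_oob.copy()
            Xp[:, jf] = rng.permutation(Xp[:, jf])
            e2 = float(np.mean((tree.predict(Xp) - y_oob) ** 2))
            raw[jf] += e2 - e1
    if not oob_errors:
        raise DataError("no tree had out-of-bag rows; increase the number of trees")
    raw /= cfg.n_trees
    return raw, float(np.mean(oob_errors))


def rf_importance(X: np.ndarray, y: np.ndarray, cfg: RFConfig | None = None) -> WeightVector:
    """Normalized oob permutation importance weights.

    Wraps :func:`rf_raw_importance`: negatives are clamped to zero and the
    vector normalized to sum to one. Deterministic given the seed.
    """
    cfg = cfg or RFConfig()
    raw, _ = rf_raw_importance(X, y, cfg)
    p = raw.shape[0]
    raw = np.clip(raw, 0.0, None)
    if raw.sum() == 0:
        warnings.warn(
            "all permutation importances nonpositive; falling back to uniform weights",
            stacklevel=2,
        )
        raw = np.ones(p)
    return WeightVector(raw / raw.sum(), provenance="rf")


def md_combine(
    u: WeightVector, v: WeightVector, R: np.ndarray
) -> tuple[WeightVector, CombinationDiagnostics]:
    """Fuse two weight vectors by maximizing deviations over sample data R.

    With D_j = sum_i (r_ij - rbar_j)^2, A = D.u and B = D.v, the deviation
    sum Z(alpha, beta) = alpha A + beta B over the positive unit circle is
    maximized at alpha = A / sqrt(A^2 + B^2), beta = B / sqrt(A^2 + B^2).
    The fused weights use the sum-one rescaling: omega = alpha' u + beta' v.
    """
    u_w = u.weights
    v_w = v.weights
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if len(u_w) != len(v_w) or R.shape[1] != len(u_w):
        raise DataError("u, v and R must be criterion-aligned")
    D = ((R - R.mean(axis=0)) ** 2).sum(axis=0)
    if not (D > 0).any():
        raise DataError("all criterion deviations are zero; fusion is undefined")
    A = float(D @ u_w)
    B = float(D @ v_w)
    if A == 0 and B == 0:
        raise DataError("both deviation-weighted sums vanish; fusion is undefined")
    norm = math.hypot(A, B)
    alpha = A / norm
    beta = B / norm
    alpha_n = alpha / (alpha + beta)
    beta_n = beta / (alpha + beta)
    omega = alpha_n * u_w + beta_n * v_w
    diag = CombinationDiagnostics(
        alpha=alpha,
        beta=beta,
        alpha_norm=alpha_n,
        beta_norm=beta_n,
        objective=norm,
        deviations=D,
    )
    return WeightVector(omega / omega.sum(), provenance="combined"), diag
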