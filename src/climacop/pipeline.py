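"""End-to-end orchestration: cleanse -> weights -> cloud matrices -> rankings.

A single master seed fans out to named substreams (bp, rf, clouds,
realization) so each stage is reproducible in isolation; the run manifest
records the master seed, the derived stage seeds, and a hash of the
configuration, which together reproduce every output bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._errors import ConfigurationError
from .cloud import BackwardCloudConfig
from .copras import (
    apply_weights,
    build_cloud_decision_matrix,
    copras_rank,
    normalize_matrix,
    realize_decision_matrix,
)
from .dataset import CriteriaSpec, cleanse, minmax_normalize, read_likert_csv
from .topsis import LambdaWeights, cm_topsis1, cm_topsis2
from .weighting import (
    NNConfig,
    RFConfig,
    bp_weights,
    linearity_screen,
    md_combine,
    rf_importance,
)

logger = logging.getLogger(__name__)

_STAGES = ("bp", "rf", "clouds", "realize")

FLOAT_FORMAT = "%.4f"


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    if stage not in _STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Full-pipeline configuration."""

    input: Path
    criteria: Path | CriteriaSpec
    group_by: Sequence[str]
    target: Optional[str] = None
    droplets: int = 2000
    seed: int = 0
    methods: Sequence[str] = ("copras", "topsis1", "topsis2")
    outdir: Path = Path("climacop_out")
    lambdas: LambdaWeights = field(default_factory=LambdaWeights)
    id_col: str = "id"
    cleansing_rules: Sequence[str] | None = None

    def __post_init__(self) -> None:
        bad = set(self.methods) - {"copras", "topsis1", "topsis2"}
        if bad:
            raise ConfigurationError(f"unknown method(s): {sorted(bad)}")
        if not self.group_by:
            raise ConfigurationError("at least one grouping attribute is required")


def compute_weights_table(
    X: np.ndarray,
    y: np.ndarray,
    criteria: Sequence[str],
    *,
    seed: int = 0,
    nn: NNConfig | None = None,
    rf: RFConfig | None = None,
) -> pd.DataFrame:
    """BP, RF, and fused weights for normalized inputs X and target y."""
    nn = nn or NNConfig(seed=stage_seed(seed, "bp"))
    rf = rf or RFConfig(seed=stage_seed(seed, "rf"))
    r = linearity_screen(X, y)
    logger.info("linearity screen max |r| = %.4f", float(np.abs(r).max()))
    w_bp = bp_weights(X, y, nn)
    w_rf = rf_importance(X, y, rf)
    w_comb, diag = md_combine(w_bp, w_rf, X)
    logger.info(
        "weight fusion: alpha=%.4f beta=%.4f (alpha'=%.4f)",
        diag.alpha,
        diag.beta,
        diag.alpha_norm,
    )
    return pd.DataFrame(
        {
            "criterion": list(criteria),
            "weight_bp": w_bp.weights,
            "weight_rf": w_rf.weights,
            "weight_combined": w_comb.weights,
        }
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run cleanse -> weights -> per-attribute rankings; write all artifacts.

    Returns a dict of output paths and in-memory results. Report floats are
    written with 4 decimals.
    """
    t0 = time.perf_counter()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = (
        cfg.criteria
        if isinstance(cfg.criteria, CriteriaSpec)
        else CriteriaSpec.from_file(cfg.criteria)
    )

    ds = read_likert_csv(cfg.input, spec, id_col=cfg.id_col, target_col=cfg.target)
    rules = tuple(cfg.cleansing_rules) if cfg.cleansing_rules else None
    clean, report = cleanse(ds, rules) if rules else cleanse(ds)
    report_path = outdir / "cleansing_report.json"
    report.to_json(report_path)
    logger.info("stage cleanse done (%.2fs)", time.perf_counter() - t0)

    outputs: dict = {"cleansing_report": report_path, "report": report}

    if cfg.target is None:
        raise ConfigurationError("a target column is required to learn criterion weights")
    if clean.target is None or not np.isfinite(clean.target).all():
        raise ConfigurationError(f"target column {cfg.target!r} has missing values after cleansing")

    t1 = time.perf_counter()
    X = minmax_normalize(clean.responses[list(spec.criteria)])
    y = minmax_normalize(clean.target)
    weights_df = compute_weights_table(X, y, spec.criteria, seed=cfg.seed)
    weights_path = outdir / "weights.csv"
    weights_df.to_csv(weights_path, index=False, float_format=FLOAT_FORMAT)
    outputs["weights"] = weights_path
    outputs["weights_table"] = weights_df
    logger.info("stage weights done (%.2fs)", time.perf_counter() - t1)

    from .weighting import WeightVector

    w_comb = WeightVector.normalized(weights_df["weight_combined"].to_numpy(), "combined")

    rankings: dict[str, dict[str, pd.DataFrame]] = {}
    for attribute in cfg.group_by:
        t2 = time.perf_counter()
        cdm = build_cloud_decision_matrix(
            clean,
            attribute,
            spec,
            BackwardCloudConfig(),
            seed=stage_seed(cfg.seed, "clouds"),
        )
        cloud_path = outdir / f"cloud_params_{attribute}.csv"
        cdm.to_frame().to_csv(cloud_path, index=False, float_format=FLOAT_FORMAT)
        dm = realize_decision_matrix(cdm, cfg.droplets, seed=stage_seed(cfg.seed, "realize"))
        weighted = apply_weights(normalize_matrix(dm), w_comb)

        rankings[attribute] = {}
        for method in cfg.methods:
            if method == "copras":
                frame = copras_rank(weighted, spec).to_frame()
            elif method == "topsis1":
                frame = cm_topsis1(cdm, w_comb).to_frame()
            else:
                frame = cm_topsis2(cdm, w_comb, cfg.lambdas).to_frame()
            path = outdir / f"ranking_{attribute}_{method}.csv"
            frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
            rankings[attribute][method] = frame
        logger.info("stage rank[%s] done (%.2fs)", attribute, time.perf_counter() - t2)

    outputs["rankings"] = rankings

    config_repr = json.dumps(
        {
            "input": str(cfg.input),
            "criteria": spec.to_dict(),
            "group_by": list(cfg.group_by),
            "target": cfg.target,
            "droplets": cfg.droplets,
            "seed": cfg.seed,
            "methods": list(cfg.methods),
            "lambdas": [cfg.lambdas.l1, cfg.lambdas.l2, cfg.lambdas.l3],
        },
        sort_keys=True,
    )
    manifest = {
        "package_version": __version__,
        "master_seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        "config": json.loads(config_repr),
        "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
        "retained_rows": report.retained,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    outputs["manifest"] = manifest_path
    logger.info("pipeline complete (%.2fs)", time.perf_counter() - t0)
    return outputs
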