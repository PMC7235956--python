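"""File formats, run configuration and the end-to-end pipeline.

Everything on disk is headered CSV or JSON: an edge table (one row per
subject, one column per edge) with an ``edge_order.json`` sidecar naming
the node pair behind every column, a phenotype CSV keyed by ``subject_id``,
and a ``report.json`` carrying results, the echoed settings, a config hash
and the package version, so outputs are self-describing.  Subjects are
aligned between tables by explicit ID join, never by row order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import neurocpm
from neurocpm.baselines import ElasticNetSpec, elastic_net_cv
from neurocpm.connectome import edge_pairs, n_edges
from neurocpm.errors import InvalidInputError
from neurocpm.phenotype import load_cohort
from neurocpm.validation import make_family_folds, permutation_test, run_cpm_cv

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "edge_columns",
    "load_config",
    "read_edges_csv",
    "run_pipeline",
    "write_edges_csv",
]

EDGE_ORDER_NOTE = "row-major upper triangle, i < j"


def edge_columns(k: int) -> list[str]:
    """Column names for the fixed edge order: e0_1, e0_2, ..."""
    return [f"e{i}_{j}" for i, j in edge_pairs(k)]


def write_edges_csv(edges: np.ndarray, subject_ids, path, k: int | None = None) -> Path:
    """Write the n x E edge matrix as CSV plus an ``edge_order.json`` sidecar."""
    x = np.asarray(edges, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError(f"edges must be 2-D, got shape {x.shape}")
    if k is None:
        k = int(round((1 + np.sqrt(1 + 8 * x.shape[1])) / 2))
    if n_edges(k) != x.shape[1]:
        raise InvalidInputError(f"edge count {x.shape[1]} is not K*(K-1)/2 for K={k}")
    path = Path(path)
    df = pd.DataFrame(x, columns=edge_columns(k))
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, index=False)
    sidecar = {
        "n_nodes": k,
        "ordering": EDGE_ORDER_NOTE,
        "columns": [[i, j] for i, j in edge_pairs(k)],
    }
    path.with_name("edge_order.json").write_text(json.dumps(sidecar))
    return path


def read_edges_csv(path) -> tuple[pd.Series, np.ndarray]:
    """Read an edge CSV; returns (subject_ids, n x E float matrix)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise InvalidInputError(f"{path}: edge table lacks a subject_id column")
    ids = df["subject_id"].astype(str)
    return ids, df.drop(columns=["subject_id"]).to_numpy(dtype=float)


@dataclass
class RunConfig:
    """Validated settings for one prediction run."""

    edges: str
    phenotypes: str
    factor: str
    method: str = "cpm"
    threshold: float = 0.01
    covariates: list[str] = field(default_factory=list)
    n_perm: int = 0
    seed: int = 0
    alpha: float = 1.0
    l1_ratio: float = 0.5
    smoothed_p: bool = False
    out: str = "."

    def validate(self) -> None:
        for name in ("edges", "phenotypes"):
            if not Path(getattr(self, name)).exists():
                raise InvalidInputError(f"{name} file not found: {getattr(self, name)}")
        if self.method not in ("cpm", "elastic-net"):
            raise InvalidInputError(f"method must be 'cpm' or 'elastic-net', got {self.method!r}")
        if not 0.0 < self.threshold < 1.0:
            raise InvalidInputError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.n_perm < 0:
            raise InvalidInputError(f"n_perm must be >= 0, got {self.n_perm}")


def load_config(path, **overrides) -> RunConfig:
    """Read a YAML or JSON config file; keyword overrides win over the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _align(ids: pd.Series, pheno: pd.DataFrame) -> pd.DataFrame:
    pheno = pheno.copy()
    pheno["subject_id"] = pheno["subject_id"].astype(str)
    edge_set = set(ids)
    pheno_set = set(pheno["subject_id"])
    only_edges = sorted(edge_set - pheno_set)
    only_pheno = sorted(pheno_set - edge_set)
    if only_edges or only_pheno:
        raise InvalidInputError(
            "subject sets differ between edges and phenotypes; "
            f"only in edges: {only_edges[:10]}; only in phenotypes: {only_pheno[:10]}"
        )
    return pheno.set_index("subject_id").loc[ids.tolist()].reset_index()


def _permute_elastic_net(edges, y, family_ids, spec, n_perm, seed, r_true):
    rng = np.random.default_rng(seed)
    null = np.full(n_perm, np.nan)
    for i in range(n_perm):
        y_perm = y[rng.permutation(y.size)]
        null[i] = elastic_net_cv(edges, y_perm, family_ids, spec).r["elastic_net"]
    valid = null[~np.isnan(null)]
    p = float("nan") if (np.isnan(r_true) or valid.size == 0) else float(
        (valid >= r_true).sum() / valid.size)
    return valid, p


def run_pipeline(config: RunConfig) -> dict:
    """Run one full prediction analysis and write its outputs.

    Writes ``predictions.csv``, ``null_distribution.csv`` (when permutations
    were requested) and ``report.json`` under ``config.out``; returns the
    report dict.  Deterministic given the seed.
    """
    config.validate()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    ids, edges = read_edges_csv(config.edges)
    required = ["subject_id", "family_id", config.factor] + list(config.covariates)
    pheno = _align(ids, load_cohort(config.phenotypes, required=tuple(required)))
    if len(pheno) != len(ids):
        raise InvalidInputError("phenotype rows with missing values for this run's columns")
    y = pheno[config.factor].to_numpy(dtype=float)
    family_ids = pheno["family_id"].to_numpy()
    cov = pheno[config.covariates].to_numpy(dtype=float) if config.covariates else None

    report: dict = {
        "package": "neurocpm",
        "version": neurocpm.__version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "edge_order": EDGE_ORDER_NOTE,
        "n_subjects": int(len(pheno)),
        "n_families": int(len(make_family_folds(family_ids))),
        "n_edges": int(edges.shape[1]),
    }
    pred_table = pd.DataFrame({"subject_id": ids, "actual": y})
    null_table = pd.DataFrame()

    if config.method == "cpm":
        result = run_cpm_cv(edges, y, family_ids, threshold=config.threshold,
                            covariates=cov)
        report["r"] = {t: result.r[t] for t in ("positive", "negative")}
        report["fold_edge_counts"] = result.fold_edge_counts
        report["degenerate_folds"] = result.n_degenerate
        for tail in ("positive", "negative"):
            pred_table[f"predicted_{tail}"] = result.predicted[tail]
        if config.n_perm > 0:
            perm = permutation_test(edges, y, family_ids, threshold=config.threshold,
                                    n_perm=config.n_perm, seed=config.seed,
                                    covariates=cov, smoothed=config.smoothed_p)
            report["p"] = perm.p
            report["n_perm"] = perm.n_perm
            report["n_valid_perm"] = perm.n_valid
            null_table = pd.DataFrame({t: pd.Series(perm.null_r[t]) for t in perm.null_r})
    else:
        spec = ElasticNetSpec(alpha=config.alpha, l1_ratio=config.l1_ratio, seed=config.seed)
        result = elastic_net_cv(edges, y, family_ids, spec)
        r_true = result.r["elastic_net"]
        report["r"] = {"elastic_net": r_true}
        report["fold_edge_counts"] = result.fold_edge_counts
        pred_table["predicted_elastic_net"] = result.predicted["elastic_net"]
        if config.n_perm > 0:
            null, p = _permute_elastic_net(edges, y, family_ids, spec,
                                           config.n_perm, config.seed, r_true)
            report["p"] = {"elastic_net": p}
            report["n_perm"] = config.n_perm
            null_table = pd.DataFrame({"elastic_net": null})

    pred_table.to_csv(out / "predictions.csv", index=False)
    if len(null_table):
        null_table.to_csv(out / "null_distribution.csv", index=False)

    def _jsonable(obj):
        if isinstance(obj, dict):
            return {k: _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            f = float(obj)
            return None if np.isnan(f) else f
        if isinstance(obj, np.integer):
            return int(obj)
        return obj

    report = _jsonable(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s", out / "report.json")
    return report
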