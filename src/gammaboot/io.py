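"""CSV input, draw serialization and run manifests."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .gamma_core import FitConfig, RegressionData
from .samplers import PosteriorDraws

__all__ = [
    "read_regression_csv",
    "summarize_draws",
    "save_draws",
    "write_manifest",
]


def read_regression_csv(
    path, response: str, standardize: bool = False
) -> tuple[RegressionData, list[str]]:
    """Read a header-ed CSV with one response column; all remaining columns
    become covariates.  ``standardize`` centers and scales the covariates
    (recommended before shrinkage-prior fits)."""
    df = pd.read_csv(path)
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not found in {path}")
    y = pd.to_numeric(df[response], errors="raise").to_numpy(dtype=float)
    feats = [c for c in df.columns if c != response]
    if not feats:
        raise ValueError("no covariate columns left after removing the response")
    try:
        X = df[feats].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric covariate column in {path}: {exc}") from exc
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return RegressionData(y=y, X=X), feats


def summarize_draws(
    draws: PosteriorDraws, level: float = 0.95, names: list[str] | None = None
) -> pd.DataFrame:
    """Posterior medians and equal-tailed credible intervals, one row per
    parameter (alpha, beta_1..p, sigma2)."""
    half = 0.5 * (1.0 - level)
    mat = np.column_stack([draws.alpha, draws.beta, draws.sigma2])
    labels = ["alpha"]
    if names is not None and len(names) == draws.p:
        labels += list(names)
    else:
        labels += [f"beta_{k + 1}" for k in range(draws.p)]
    labels.append("sigma2")
    med = np.median(mat, axis=0)
    lo, hi = np.quantile(mat, [half, 1.0 - half], axis=0)
    return pd.DataFrame(
        {"parameter": labels, "median": med, "lower": lo, "upper": hi}
    )


def _config_dict(config: FitConfig) -> dict:
    d = {}
    for k, v in vars(config).items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        d[k] = v
    return d


def save_draws(draws: PosteriorDraws, out_dir, config: FitConfig | None = None) -> None:
    """Write draws.csv plus a JSON sidecar with the configuration and the
    convergence flags."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    draws.to_frame().to_csv(out / "draws.csv", index=False)
    sidecar = {
        "n_draws": int(draws.n_draws),
        "n_converged": int(np.sum(draws.converged)),
        "convergence_flags": draws.converged.astype(bool).tolist(),
    }
    if config is not None:
        sidecar["config"] = _config_dict(config)
    (out / "draws_meta.json").write_text(json.dumps(sidecar, indent=2))


def write_manifest(
    out_dir, command: str, config: dict, seed: int | None, **extra
) -> Path:
    """Write the run manifest (command, resolved config, seed, version,
    timestamps, convergence counts) as manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        version = metadata.version("gammaboot")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": version,
        "python_version": platform.python_version(),
        "written_at": datetime.now(timezone.utc).isoformat(),
        **extra,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
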