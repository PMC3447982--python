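"""Reading and writing the package's file formats.

Configs are JSON or YAML (by extension) with dotted sections::

    trace:  {tau, nu, c, sigma_thin, sigma_large, p0, lambda_resp}
    connection: {u_epsp}
    rates:  {maturation: {A, theta}, shrinkage: {A, theta}, delta, gamma}

Histograms and apposition distributions are CSV; reference datasets pair a
counts CSV (columns k, count) with a JSON sidecar holding p_conn, u_epsp and
the path of the apposition CSV.  Results are written as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dynamics import LifetimeCurves, Trajectory, TurnoverReport
from .inference import FitResult, ReferenceDataset
from .rates import PlasticityParams, RateLaw
from .steady_state import StationaryResult
from .trace import TraceParams

__all__ = [
    "params_to_dict", "params_from_dict", "load_params", "save_params",
    "read_apposition_csv", "write_apposition_csv",
    "read_reference_dataset", "write_reference_dataset",
    "write_trajectory_csv", "stationary_to_dict", "fit_result_to_dict",
    "write_json",
]


def params_to_dict(params: PlasticityParams) -> dict[str, Any]:
    t = params.trace
    return {
        "trace": {
            "tau": t.tau, "nu": t.nu, "c": t.c,
            "sigma_thin": t.sigma_thin, "sigma_large": t.sigma_large,
            "p0": t.p0, "lambda_resp": t.lambda_resp,
        },
        "connection": {"u_epsp": t.u_epsp},
        "rates": {
            "maturation": {"A": params.maturation.amplitude,
                           "theta": params.maturation.threshold},
            "shrinkage": {"A": params.shrinkage.amplitude,
                          "theta": params.shrinkage.threshold},
            "delta": params.delta,
            "gamma": params.gamma,
        },
    }


def params_from_dict(cfg: dict[str, Any]) -> PlasticityParams:
    tr = cfg.get("trace", {})
    conn = cfg.get("connection", {})
    rates = cfg.get("rates", {})
    trace = TraceParams(
        tau=tr.get("tau", 100.0), nu=tr.get("nu", 5.0), c=tr.get("c", 1.0),
        sigma_thin=tr.get("sigma_thin", 1.0),
        sigma_large=tr.get("sigma_large", 1.0),
        p0=tr.get("p0", 0.5), lambda_resp=tr.get("lambda_resp", 0.01),
        u_epsp=conn.get("u_epsp", 1.0),
    )
    mat = rates.get("maturation", {})
    shr = rates.get("shrinkage", {})
    return PlasticityParams(
        maturation=RateLaw(mat.get("A", -1.0), mat.get("theta", 0.0), "thin"),
        shrinkage=RateLaw(shr.get("A", -1.0), shr.get("theta", 0.0), "large"),
        delta=rates.get("delta", 0.0),
        gamma=rates.get("gamma", 1.0),
        trace=trace,
    )


def load_params(path: str | Path) -> PlasticityParams:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    return params_from_dict(cfg)


def save_params(params: PlasticityParams, path: str | Path) -> None:
    path = Path(path)
    cfg = params_to_dict(params)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2))


def read_apposition_csv(path: str | Path) -> np.ndarray:
    """Apposition pmf from a CSV with columns M, probability (must sum to 1)."""
    df = pd.read_csv(path)
    if not {"M", "probability"}.issubset(df.columns):
        raise ValueError("apposition CSV needs columns M, probability")
    m_max = int(df["M"].max())
    pmf = np.zeros(m_max + 1)
    pmf[df["M"].to_numpy(dtype=int)] = df["probability"].to_numpy(dtype=float)
    if abs(pmf.sum() - 1.0) > 1e-6:
        raise ValueError(f"apposition pmf sums to {pmf.sum()}, expected 1")
    return pmf


def write_apposition_csv(pmf: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"M": np.arange(len(pmf)), "probability": pmf}).to_csv(
        path, index=False
    )


def read_reference_dataset(sidecar_path: str | Path) -> ReferenceDataset:
    """Reference dataset from a JSON sidecar pointing at its CSV files."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    base = sidecar_path.parent
    counts_df = pd.read_csv(base / meta["counts_csv"])
    counts = {
        int(k): float(c)
        for k, c in zip(counts_df["k"], counts_df["count"])
    }
    a_dist = read_apposition_csv(base / meta["apposition_csv"])
    return ReferenceDataset(
        counts=counts,
        p_conn=float(meta["p_conn"]),
        u_epsp=float(meta["u_epsp"]),
        apposition_dist=a_dist,
        label=meta.get("label", sidecar_path.stem),
    )


def write_reference_dataset(
    dataset: ReferenceDataset, directory: str | Path, name: str = "reference"
) -> Path:
    """Write counts CSV, apposition CSV and JSON sidecar; returns sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counts_csv = f"{name}_counts.csv"
    appo_csv = f"{name}_appositions.csv"
    pd.DataFrame(
        {"k": list(dataset.counts), "count": list(dataset.counts.values())}
    ).sort_values("k").to_csv(directory / counts_csv, index=False)
    write_apposition_csv(dataset.apposition_dist, directory / appo_csv)
    sidecar = directory / f"{name}.json"
    sidecar.write_text(json.dumps({
        "counts_csv": counts_csv,
        "apposition_csv": appo_csv,
        "p_conn": dataset.p_conn,
        "u_epsp": dataset.u_epsp,
        "label": dataset.label,
    }, indent=2))
    return sidecar


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    rows = [(0.0, "initial", *traj.initial_state)]
    rows += [(t, kind, a, i) for t, kind, (a, i) in traj.events]
    pd.DataFrame(
        rows, columns=["time", "event", "n_active", "n_inactive"]
    ).to_csv(path, index=False)


def stationary_to_dict(result: StationaryResult) -> dict[str, Any]:
    triplets = [
        [int(a), int(i), float(result.averaged[a, i])]
        for a in range(result.averaged.shape[0])
        for i in range(result.averaged.shape[1])
        if result.averaged[a, i] > 0
    ]
    return {
        "averaged_joint": triplets,
        "p_total": result.p_total.tolist(),
        "p_active": result.p_active.tolist(),
        "p_inactive": result.p_inactive.tolist(),
        "moments": dict(result.moments),
        "corr_active_inactive": result.corr_ai,
    }


def fit_result_to_dict(fit: FitResult, max_starts: int = 50) -> dict[str, Any]:
    return {
        "params": params_to_dict(fit.params),
        "error": fit.error,
        "hebbian_index": fit.hebbian_index,
        "n_starts": fit.n_starts,
        "converged": fit.converged,
        "starts": [
            {"error": s["error"], "converged": s["converged"]}
            for s in fit.starts[:max_starts]
        ],
    }


def lifetimes_to_dict(curves: LifetimeCurves) -> dict[str, Any]:
    def _clean(v: float) -> float | str:
        return v if np.isfinite(v) else "inf"

    return {
        "inactive_by_na": {str(k): _clean(v) for k, v in curves.inactive_by_na.items()},
        "active_by_na": {str(k): _clean(v) for k, v in curves.active_by_na.items()},
        "averaged_inactive": _clean(curves.averaged_inactive),
        "averaged_active": _clean(curves.averaged_active),
    }


def turnover_to_dict(report: TurnoverReport) -> dict[str, Any]:
    return {
        "gain_rate": report.gain_rate,
        "loss_rate": report.loss_rate,
        "n_spines": report.n_spines,
        "ratio": report.ratio,
        "window": report.window,
    }


def write_json(obj: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2))
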