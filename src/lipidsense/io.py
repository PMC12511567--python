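"""Tabular readers/writers, fit reports and run configuration.

All tables are plain CSV with a header row; times are seconds (a
``time_min`` column is accepted and converted), fractions are unitless.
Fit reports round-trip through JSON without loss of precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .assays import AssayError, EmissionSpectrum
from .kinetics import (
    GlobalFitResult,
    KineticParams,
    KineticsError,
    validate_loading_dataset,
)
from .mixtures import ContactSeries, MixtureError, PoissonMixtureFit

__all__ = [
    "RunConfig",
    "read_timecourse_table",
    "write_timecourse_table",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_contact_series",
    "write_contact_series",
    "read_contact_matrix",
    "write_fit_report",
    "read_fit_report",
    "write_mixture_report",
    "read_mixture_report",
]


@dataclass
class RunConfig:
    """Seeds, optimizer and mixture settings for a reproducible run."""

    seed: int = 0
    n_starts: int = 16
    bounds: tuple[float, float] = (1e-6, 1e4)
    T: float = 0.75
    K_max: int = 6
    restarts: int = 20
    bound_policy: str = "threshold"
    bound_threshold: float = 15.0
    manual_window: tuple[float, float] = (30.0, 600.0)
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bounds", "manual_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if not isinstance(cfg.seed, int):
            raise ValueError("seed must be an integer")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def read_timecourse_table(path: str | Path, unit_policy: str = "auto") -> pd.DataFrame:
    """Read a loading time-course CSV into a validated dataset.

    Requires columns ``condition`` and ``fraction_loaded`` plus a time
    column: ``time_s`` (seconds) or ``time_min`` (minutes, converted to
    seconds).  ``unit_policy`` may force ``"seconds"`` or ``"minutes"``
    interpretation of a bare ``time`` column.
    """
    df = pd.read_csv(path, comment="#")
    if "time_min" in df.columns and "time_s" not in df.columns:
        df["time_s"] = pd.to_numeric(df["time_min"], errors="coerce") * 60.0
    elif "time" in df.columns and "time_s" not in df.columns:
        if unit_policy == "minutes":
            df["time_s"] = pd.to_numeric(df["time"], errors="coerce") * 60.0
        elif unit_policy in ("seconds", "auto"):
            df["time_s"] = pd.to_numeric(df["time"], errors="coerce")
        else:
            raise KineticsError(f"unknown unit policy {unit_policy!r}")
    try:
        return validate_loading_dataset(df)
    except KineticsError as err:
        raise KineticsError(f"{path}: {err}") from None


def write_timecourse_table(data: pd.DataFrame, path: str | Path) -> None:
    validate_loading_dataset(data).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, spectrum_id: str | None = None) -> EmissionSpectrum:
    """Read an emission spectrum CSV (``wavelength_nm, intensity``).

    Long-format files with a ``spectrum_id`` column hold several spectra;
    pass ``spectrum_id`` to select one.
    """
    df = pd.read_csv(path, comment="#")
    missing = {"wavelength_nm", "intensity"} - set(df.columns)
    if missing:
        raise AssayError(f"{path}: missing columns {sorted(missing)}")
    if "spectrum_id" in df.columns:
        if spectrum_id is None:
            ids = df["spectrum_id"].unique()
            if len(ids) > 1:
                raise AssayError(
                    f"{path}: multiple spectra {list(ids)}; pass spectrum_id"
                )
            spectrum_id = ids[0]
        df = df[df["spectrum_id"] == spectrum_id]
        if df.empty:
            raise AssayError(f"{path}: no spectrum with id {spectrum_id!r}")
    df = df.sort_values("wavelength_nm")
    return EmissionSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
        metadata={"path": str(path), "spectrum_id": spectrum_id},
    )


def write_spectrum_csv(spec: EmissionSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths, "intensity": spec.intensities}
    ).to_csv(path, index=False)


def read_contact_series(path: str | Path, condition: str | None = None) -> ContactSeries:
    """Read contact counts from CSV: single ``count`` column, or long
    format with ``condition, frame, count`` columns."""
    df = pd.read_csv(path, comment="#")
    if "count" not in df.columns:
        raise MixtureError(f"{path}: missing 'count' column")
    if "condition" in df.columns:
        if condition is None:
            conds = df["condition"].unique()
            if len(conds) > 1:
                raise MixtureError(
                    f"{path}: multiple conditions {list(conds)}; pass condition"
                )
            condition = conds[0]
        df = df[df["condition"] == condition]
        if "frame" in df.columns:
            df = df.sort_values("frame")
    return ContactSeries(
        counts=df["count"].to_numpy(), condition=str(condition or ""),
        metadata={"path": str(path)},
    )


def write_contact_series(series: ContactSeries, path: str | Path) -> None:
    pd.DataFrame({"count": series.counts}).to_csv(path, index=False)


def read_contact_matrix(path: str | Path) -> pd.DataFrame:
    """Read a frames × residues contact matrix CSV (1-based residue headers)."""
    df = pd.read_csv(path, comment="#")
    df.columns = [int(c) for c in df.columns]
    return df


# ---------------------------------------------------------------------------
# Fit reports


def write_fit_report(
    result: GlobalFitResult,
    path_prefix: str | Path,
    curve_times: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write a global-fit report: JSON parameters, CSV curves, text summary.

    ``path_prefix`` is extended with ``.json``, ``_curves.csv`` and
    ``_summary.txt``.  The JSON report round-trips through
    :func:`read_fit_report` at full precision.
    """
    prefix = Path(path_prefix)
    payload = {
        "model": "two_state_loading",
        "T": result.T,
        "k3": result.k3,
        "conditions": {
            cond: {"k1": p.k1, "k2": p.k2}
            for cond, p in result.condition_params.items()
        },
        "stderr": result.stderr,
        "rss": result.rss,
        "converged": result.converged,
        "n_starts": result.n_starts,
        "n_data": result.n_data,
    }
    json_path = prefix.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)

    if curve_times is None:
        curve_times = np.geomspace(1e-3, 1e3, 200)
    curves_path = prefix.parent / (prefix.name + "_curves.csv")
    result.fitted_curves(curve_times).to_csv(curves_path, index=False)

    summary_path = prefix.parent / (prefix.name + "_summary.txt")
    lines = [
        "Two-state loading model, global fit",
        f"  shared k3 = {result.k3:.6g} s^-1  (SE {result.stderr.get('k3', float('nan')):.3g})",
        f"  T fixed   = {result.T}",
    ]
    for cond, p in result.condition_params.items():
        lines.append(
            f"  {cond}: k1 = {p.k1:.6g} s^-1, k2 = {p.k2:.6g} s^-1"
        )
    lines += [
        f"  RSS = {result.rss:.6g} over {result.n_data} points",
        f"  converged: {result.converged}",
    ]
    summary_path.write_text("\n".join(lines) + "\n")
    return {"json": json_path, "curves": curves_path, "summary": summary_path}


def read_fit_report(json_path: str | Path) -> GlobalFitResult:
    with open(json_path) as fh:
        payload = json.load(fh)
    params = {
        cond: KineticParams(k1=v["k1"], k2=v["k2"], k3=payload["k3"], T=payload["T"])
        for cond, v in payload["conditions"].items()
    }
    return GlobalFitResult(
        condition_params=params, k3=payload["k3"], T=payload["T"],
        rss=payload["rss"], stderr=payload["stderr"],
        converged=payload["converged"], n_starts=payload["n_starts"],
        n_data=payload["n_data"],
    )


def write_mixture_report(fit: PoissonMixtureFit, path: str | Path,
                         extra: dict[str, Any] | None = None) -> Path:
    payload = {
        "model": "poisson_mixture",
        "K": fit.K,
        "weights": fit.weights.tolist(),
        "means": fit.means.tolist(),
        "log_likelihood": fit.log_likelihood,
        "bic": fit.bic,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
        "n_obs": fit.n_obs,
        "degenerate": fit.degenerate,
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path


def read_mixture_report(path: str | Path) -> PoissonMixtureFit:
    with open(path) as fh:
        payload = json.load(fh)
    return PoissonMixtureFit(
        K=payload["K"], weights=np.asarray(payload["weights"]),
        means=np.asarray(payload["means"]),
        log_likelihood=payload["log_likelihood"], bic=payload["bic"],
        converged=payload["converged"], n_iterations=payload["n_iterations"],
        n_obs=payload["n_obs"], degenerate=payload.get("degenerate", False),
    )
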