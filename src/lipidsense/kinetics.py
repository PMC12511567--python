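"""Two-state conformational kinetics of E2 ubiquitin loading.

The model: the membrane-anchored E2 (UBE2J2) interconverts between an
active conformation A and an inactive, membrane-associated conformation B
with rates k1 (A→B) and k2 (B→A); only A is loaded with ubiquitin by the
E1 enzyme, at rate k3, producing the loaded species C::

    dA/dt = −k3·A − k1·A + k2·B
    dB/dt =  k1·A − k2·B
    dC/dt =  k3·A

The reaction starts from the pre-equilibrated conformational mixture,
B0/A0 = k1/k2 with A0 + B0 = T, the total loadable fraction (fixed at
0.75 in the global fit), and C(0) = 0.  Discharge of C is neglected on
the loading timescale; it enters only the steady-state cycling model
(:func:`steady_state_loaded_fraction`).

The (A, B) subsystem is linear with eigenvalue rates

    r_{1,2} = [−(k1+k2+k3) ± sqrt((k1+k2+k3)² − 4·k2·k3)] / 2,

both real and ≤ 0.  C(t) is obtained as k3·∫A dt from the
eigen-decomposition (with a confluent t·e^{rt} branch for degenerate
eigenvalues) and is validated against direct numerical integration
(:func:`integrate_two_state_ode`); it satisfies C(0) = 0, monotone
growth, and C(t) → T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "TwoStateSolution",
    "CyclingParams",
    "GlobalFitResult",
    "DischargeFit",
    "KineticsError",
    "FitError",
    "equilibrium_initial_state",
    "rate_eigenvalues",
    "loaded_fraction",
    "integrate_two_state_ode",
    "validate_loading_dataset",
    "assemble_loading_dataset",
    "fit_global_two_state",
    "fit_exponential_discharge",
    "steady_state_loaded_fraction",
]

#: Columns of a loading-dataset table (times in seconds).
DATASET_COLUMNS = ("condition", "time_s", "fraction_loaded", "replicate", "source")

_DEGENERATE_RTOL = 1e-10


class KineticsError(ValueError):
    """Invalid kinetic parameters or dataset."""


class FitError(RuntimeError):
    """Optimization failed; carries the best result found so far."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class KineticParams:
    """Rates (s⁻¹) and loadable fraction of the two-state loading model."""

    k1: float
    k2: float
    k3: float
    T: float = 0.75

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3"):
            if getattr(self, name) < 0:
                raise KineticsError(f"{name} must be ≥ 0, got {getattr(self, name)}")
        if not (0 < self.T <= 1):
            raise KineticsError(f"T must be in (0, 1], got {self.T}")


@dataclass(frozen=True)
class CyclingParams:
    """Two-state loading rates plus a discharge rate kd (C→A, s⁻¹)."""

    k1: float
    k2: float
    k3: float
    kd: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "kd"):
            if getattr(self, name) < 0:
                raise KineticsError(f"{name} must be ≥ 0, got {getattr(self, name)}")


@dataclass
class TwoStateSolution:
    """State trajectories of the two-state loading model on a time grid."""

    times: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    r1: float
    r2: float
    params: KineticParams
    degenerate: bool = False


def equilibrium_initial_state(p: KineticParams) -> tuple[float, float]:
    """Pre-reaction conformational equilibrium (A0, B0) with B0/A0 = k1/k2.

    A0 = T·k2/(k1+k2), B0 = T·k1/(k1+k2).  Undefined when k1 = k2 = 0.
    """
    if p.k1 + p.k2 == 0:
        raise KineticsError("degenerate equilibrium: k1 = k2 = 0")
    a0 = p.T * p.k2 / (p.k1 + p.k2)
    return a0, p.T - a0


def rate_eigenvalues(p: KineticParams) -> tuple[float, float]:
    """Eigenvalue rates (r1, r2) of the (A, B) subsystem, r1 ≥ r2.

    Roots of λ² + (k1+k2+k3)·λ + k2·k3 = 0; the discriminant is bounded
    below by (k2−k3)², so both roots are real and ≤ 0.
    """
    s = p.k1 + p.k2 + p.k3
    disc = s * s - 4.0 * p.k2 * p.k3
    root = np.sqrt(max(disc, 0.0))
    return (-s + root) / 2.0, (-s - root) / 2.0


def _phi(r: float, t: np.ndarray) -> np.ndarray:
    """∫₀ᵗ e^{r·s} ds = (e^{r·t} − 1)/r, with the r→0 limit t."""
    if r == 0.0:
        return np.asarray(t, dtype=float).copy()
    return np.expm1(r * t) / r


def loaded_fraction(p: KineticParams, times: Sequence[float] | np.ndarray) -> TwoStateSolution:
    """Closed-form solution of the two-state loading model.

    Starts from the conformational equilibrium (B0/A0 = k1/k2, C0 = 0)
    and evaluates A(t) from the eigen-decomposition of the (A, B)
    subsystem, C(t) = k3·∫A dt, B(t) = T − A − C.  Reduces to
    C(t) = T·(1 − e^{−k3·t}) when k1 = 0, and C(t) → T for k2, k3 > 0.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise KineticsError("times must be ≥ 0")
    a0, b0 = equilibrium_initial_state(p)
    r1, r2 = rate_eigenvalues(p)
    da0 = -(p.k1 + p.k3) * a0 + p.k2 * b0  # A'(0)

    degenerate = abs(r1 - r2) < _DEGENERATE_RTOL * max(abs(r1 + r2), 1.0)
    if not degenerate:
        c1 = (da0 - r2 * a0) / (r1 - r2)
        c2 = a0 - c1
        a = c1 * np.exp(r1 * t) + c2 * np.exp(r2 * t)
        c = p.k3 * (c1 * _phi(r1, t) + c2 * _phi(r2, t))
    else:
        # Confluent branch: A(t) = (a0 + c·t)·e^{r·t}
        r = 0.5 * (r1 + r2)
        cc = da0 - r * a0
        a = (a0 + cc * t) * np.exp(r * t)
        if r == 0.0:
            int_te = 0.5 * t * t
        else:
            int_te = (t * np.exp(r * t) - _phi(r, t)) / r
        c = p.k3 * (a0 * _phi(r, t) + cc * int_te)
    c = np.clip(c, 0.0, p.T)
    a = np.clip(a, 0.0, p.T)
    b = np.clip(p.T - a - c, 0.0, p.T)
    return TwoStateSolution(times=t, A=a, B=b, C=c, r1=r1, r2=r2, params=p,
                            degenerate=bool(degenerate))


def integrate_two_state_ode(
    p: KineticParams,
    times: Sequence[float] | np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> TwoStateSolution:
    """Stiff-safe numerical integration of the loading equations.

    Independent check of :func:`loaded_fraction`: same initial
    conditions, solved with an implicit LSODA integrator instead of the
    eigen-decomposition.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise KineticsError("times must be ≥ 0")
    a0, b0 = equilibrium_initial_state(p)

    def rhs(_t, y):
        a, b, _ = y
        return [-p.k3 * a - p.k1 * a + p.k2 * b, p.k1 * a - p.k2 * b, p.k3 * a]

    t_span = (0.0, float(t.max()) if t.size else 0.0)
    sol = solve_ivp(rhs, t_span, [a0, b0, 0.0], t_eval=np.sort(np.unique(t)),
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise KineticsError(f"ODE integration failed: {sol.message}")
    order = np.searchsorted(sol.t, t)
    r1, r2 = rate_eigenvalues(p)
    return TwoStateSolution(times=t, A=sol.y[0][order], B=sol.y[1][order],
                            C=sol.y[2][order], r1=r1, r2=r2, params=p)


# ---------------------------------------------------------------------------
# Dataset assembly


def validate_loading_dataset(data: pd.DataFrame, source: str | None = None) -> pd.DataFrame:
    """Validate and normalize a loading time-course table.

    Requires columns ``condition``, ``time_s``, ``fraction_loaded``;
    fills ``replicate`` (0) and ``source`` if absent.  Times must be
    finite and ≥ 0, fractions in [0, 1].
    """
    df = data.copy()
    missing = {"condition", "time_s", "fraction_loaded"} - set(df.columns)
    if missing:
        raise KineticsError(f"dataset missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    if "source" not in df.columns:
        df["source"] = source if source is not None else "unknown"
    t = pd.to_numeric(df["time_s"], errors="coerce")
    if t.isna().any():
        rows = df.index[t.isna()].tolist()
        raise KineticsError(f"non-numeric time_s at rows {rows}")
    if (t < 0).any():
        raise KineticsError("negative time_s in dataset")
    f = pd.to_numeric(df["fraction_loaded"], errors="coerce")
    bad = f.isna() | (f < 0) | (f > 1)
    if bad.any():
        rows = df.index[bad].tolist()
        raise KineticsError(f"fraction_loaded outside [0, 1] at rows {rows}")
    df["time_s"] = t.astype(float)
    df["fraction_loaded"] = f.astype(float)
    return df[list(DATASET_COLUMNS)]


def assemble_loading_dataset(
    quenched_flow: pd.DataFrame | None,
    manual: pd.DataFrame | None,
    manual_window: tuple[float, float] = (30.0, 600.0),
) -> pd.DataFrame:
    """Merge quenched-flow and manually sampled time courses.

    Quenched-flow records enter unchanged; manual records are restricted
    to the closed time window ``manual_window`` (default 30 s – 600 s,
    i.e. the regime a manual pipetting assay can resolve).  The
    ``source`` column records provenance.
    """
    parts = []
    if quenched_flow is not None and len(quenched_flow):
        parts.append(validate_loading_dataset(quenched_flow, source="quenched_flow"))
    if manual is not None and len(manual):
        man = validate_loading_dataset(manual, source="manual")
        lo, hi = manual_window
        man = man[(man["time_s"] >= lo) & (man["time_s"] <= hi)]
        if len(man):
            parts.append(man)
    if not parts:
        raise KineticsError("assembled dataset is empty")
    out = pd.concat(parts, ignore_index=True)
    if out.empty:
        raise KineticsError("assembled dataset is empty")
    return out


# ---------------------------------------------------------------------------
# Global fitting


@dataclass
class GlobalFitResult:
    """Result of the global two-state fit (shared k3, per-condition k1, k2)."""

    condition_params: dict[str, KineticParams]
    k3: float
    T: float
    rss: float
    stderr: dict[str, float]
    converged: bool
    n_starts: int
    n_data: int
    message: str = ""

    def predict(self, condition: str, times) -> np.ndarray:
        return loaded_fraction(self.condition_params[condition], times).C

    def fitted_curves(self, times) -> pd.DataFrame:
        """Tidy table of fitted C(t) for every condition on a time grid."""
        t = np.asarray(times, dtype=float)
        frames = [
            pd.DataFrame({"condition": cond, "time_s": t, "fraction_loaded": self.predict(cond, t)})
            for cond in self.condition_params
        ]
        return pd.concat(frames, ignore_index=True)


def _check_fit_preconditions(df: pd.DataFrame) -> list[str]:
    conds = list(dict.fromkeys(df["condition"]))
    if len(conds) < 2:
        raise KineticsError("global fit requires at least 2 conditions")
    for cond in conds:
        t = np.unique(df.loc[df["condition"] == cond, "time_s"])
        t = t[t > 0]
        if t.size < 4:
            raise KineticsError(f"condition {cond!r} has fewer than 4 time points")
        if t.max() / t.min() < 10:
            raise KineticsError(
                f"condition {cond!r} time points span less than one decade"
            )
    return conds


def fit_global_two_state(
    data: pd.DataFrame,
    T: float = 0.75,
    bounds: tuple[float, float] = (1e-6, 1e4),
    start: Mapping[str, float] | None = None,
    n_starts: int = 16,
    seed: int | None = 0,
    weights: np.ndarray | None = None,
    max_nfev: int | None = None,
) -> GlobalFitResult:
    """Global least-squares fit of the two-state model across conditions.

    k3 is shared by all conditions, k1 and k2 are free per condition, and
    the loadable fraction T is fixed.  Rates are optimized in log space
    within ``bounds`` (s⁻¹) by bounded local least squares restarted from
    ``n_starts`` deterministic random initializations; replicates enter
    as individual unweighted residuals unless per-point ``weights``
    (1/σ) are supplied.

    Parameters named ``"<condition>.k1"``, ``"<condition>.k2"`` and
    ``"k3"`` carry linearized standard errors from the Jacobian at the
    optimum.
    """
    df = validate_loading_dataset(data).reset_index(drop=True)
    conds = _check_fit_preconditions(df)
    t_obs = df["time_s"].to_numpy()
    y_obs = df["fraction_loaded"].to_numpy()
    cond_idx = {c: df.index[df["condition"] == c].to_numpy() for c in conds}
    w = np.ones_like(y_obs) if weights is None else np.asarray(weights, float)

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    n_params = 2 * len(conds) + 1
    names = [f"{c}.{k}" for c in conds for k in ("k1", "k2")] + ["k3"]

    def unpack(theta):
        rates = np.exp(theta)
        k3 = rates[-1]
        return {
            c: KineticParams(k1=rates[2 * i], k2=rates[2 * i + 1], k3=k3, T=T)
            for i, c in enumerate(conds)
        }

    def residuals(theta):
        params = unpack(theta)
        res = np.empty_like(y_obs)
        for c, p in params.items():
            idx = cond_idx[c]
            res[idx] = loaded_fraction(p, t_obs[idx]).C - y_obs[idx]
        return res * w

    rng = np.random.default_rng(seed)
    starts = []
    if start is not None:
        theta0 = np.log([
            *(start[f"{c}.{k}"] for c in conds for k in ("k1", "k2")),
            start["k3"],
        ])
        starts.append(np.clip(theta0, lo, hi))
    else:
        # heuristic: moderate interconversion, loading near the fastest data
        tpos = t_obs[t_obs > 0]
        k3_guess = min(max(1.0 / tpos.min(), 1e-3), bounds[1] / 10)
        starts.append(np.clip(np.log([0.1, 0.1] * len(conds) + [k3_guess]), lo, hi))
    while len(starts) < max(n_starts, 1):
        starts.append(rng.uniform(np.log(1e-4), np.log(1e3), size=n_params))

    best = None
    for theta0 in starts:
        try:
            res = least_squares(residuals, theta0, bounds=(lo, hi),
                                method="trf", max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("all optimization starts failed")

    params = unpack(best.x)
    rss = float(2.0 * best.cost)
    # Linearized SEs: covariance of log-rates from JᵀJ, delta method to rates.
    stderr = {}
    dof = max(len(y_obs) - n_params, 1)
    try:
        jtj = best.jac.T @ best.jac
        cov_log = np.linalg.pinv(jtj) * (rss / dof)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
        for name, th, se in zip(names, best.x, se_log):
            stderr[name] = float(np.exp(th) * se)
    except Exception:
        stderr = {name: float("nan") for name in names}

    converged = bool(best.status > 0)
    result = GlobalFitResult(
        condition_params=params, k3=float(np.exp(best.x[-1])), T=T, rss=rss,
        stderr=stderr, converged=converged, n_starts=len(starts),
        n_data=len(y_obs), message=str(best.message),
    )
    if not converged:
        raise FitError(f"global fit did not converge: {best.message}", best=result)
    return result


@dataclass
class DischargeFit:
    """Single-exponential discharge fit C(t) = C0·e^(−kd·t)."""

    kd: float
    c0: float
    rss: float
    increasing_warning: bool = False


def fit_exponential_discharge(data: pd.DataFrame) -> DischargeFit:
    """Fit a single-exponential decay to a discharge time course.

    Expects columns ``time_s`` and ``fraction_loaded``.  Exactly constant
    data yields kd = 0; data with a net upward trend is fitted anyway but
    flagged with ``increasing_warning``.
    """
    t = np.asarray(pd.to_numeric(data["time_s"]), dtype=float)
    y = np.asarray(pd.to_numeric(data["fraction_loaded"]), dtype=float)
    if t.size < 2:
        raise KineticsError("discharge fit needs at least 2 points")
    increasing = bool(np.polyfit(t, y, 1)[0] > 0)
    if np.allclose(y, y[0]):
        return DischargeFit(kd=0.0, c0=float(y[0]), rss=0.0,
                            increasing_warning=increasing)

    def resid(theta):
        log_c0, log_kd = theta
        return np.exp(log_c0) * np.exp(-np.exp(log_kd) * t) - y

    # initial rate from the log-linear slope of the positive samples
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        kd0 = max(-slope, 1e-6)
        c00 = max(y[pos].max(), 1e-6)
    else:
        kd0, c00 = 1e-3, max(y.max(), 1e-6)
    res = least_squares(resid, np.log([c00, kd0]), method="lm")
    c0, kd = np.exp(res.x)
    return DischargeFit(kd=float(kd), c0=float(c0), rss=float(2 * res.cost),
                        increasing_warning=increasing)


def steady_state_loaded_fraction(p: CyclingParams) -> float:
    """Steady-state loaded fraction under continuous loading/discharge cycling.

    For the cycle A⇌B (k1, k2), A→C (k3), C→A (kd), the stationary
    distribution gives C/(A+B+C) = (k3/kd) / (1 + k1/k2 + k3/kd).  With
    kd = 0 the loaded state is absorbing and the fraction is 1.  The
    sensitivity of this fraction to the conformational equilibrium k1/k2
    grows with cycling frequency: as kd → 0 the fraction approaches 1
    regardless of k1/k2, while for fast discharge it approaches
    (k3/kd)/(1 + k1/k2), fully exposed to the equilibrium.
    """
    if p.k2 <= 0:
        raise KineticsError("steady state requires k2 > 0")
    if p.k3 == 0 and p.kd == 0:
        raise KineticsError("steady state undefined for k3 = kd = 0")
    if p.kd == 0:
        return 1.0
    x = p.k3 / p.kd
    return x / (1.0 + p.k1 / p.k2 + x)
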