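"""Synthetic data generators for every analysis stage.

These generators produce inputs with the statistical structure the
analyses assume — biphasic loading time courses from the two-state
kinetic model, contact-count series from a four-component Poisson
mixture (optionally with Markov-modulated switching to emulate
reversible membrane association), and two-band Gaussian emission
spectra — so the full pipeline is testable without any external data.
All draws are deterministic given a seed.

The default loading rates are synthetic magnitudes consistent with the
qualitative kinetic picture (a fast pool loading within tens of
milliseconds and a slow pool on the minute scale, with the fast-pool
size set by the conformational equilibrium); they are not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assays import EmissionSpectrum
from .kinetics import KineticParams, loaded_fraction
from .mixtures import ContactSeries

__all__ = [
    "LoadingSimSpec",
    "ContactSimSpec",
    "DEFAULT_CONDITIONS",
    "DEFAULT_MIXTURE_WEIGHTS",
    "DEFAULT_MIXTURE_MEANS",
    "simulate_loading_timecourse",
    "simulate_contact_counts",
    "simulate_emission_spectrum",
]

#: Synthetic per-condition rates (s⁻¹): a mostly-active, tightly packed
#: condition and a mostly-inactive, loosely packed condition sharing k3.
DEFAULT_CONDITIONS: dict[str, KineticParams] = {
    "60% SFA": KineticParams(k1=0.005, k2=0.02, k3=30.0, T=0.75),
    "10% SFA": KineticParams(k1=0.2, k2=0.02, k3=30.0, T=0.75),
}

#: Four-component contact mixture: unbound, loosely bound (~8 contacts)
#: and two tightly bound conformations (~30 and ~50 contacts).
DEFAULT_MIXTURE_MEANS: tuple[float, ...] = (0.2, 8.0, 30.0, 50.0)
DEFAULT_MIXTURE_WEIGHTS: tuple[float, ...] = (0.40, 0.10, 0.35, 0.15)


def _default_times() -> np.ndarray:
    # log-spaced 5 ms – 600 s: quenched-flow regime through manual sampling
    return np.geomspace(5e-3, 600.0, 20)


@dataclass
class LoadingSimSpec:
    """Specification of a multi-condition loading-curve simulation."""

    conditions: Mapping[str, KineticParams] = field(
        default_factory=lambda: dict(DEFAULT_CONDITIONS)
    )
    times: np.ndarray = field(default_factory=_default_times)
    noise_sd: float = 0.02
    replicates: int = 3
    seed: int | None = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if np.any(self.times <= 0):
            raise ValueError("simulation times must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be ≥ 1")


def simulate_loading_timecourse(spec: LoadingSimSpec) -> pd.DataFrame:
    """Noisy loading time courses from the two-state forward model.

    For each condition and replicate, evaluates C(t) on the spec's time
    grid and adds i.i.d. Gaussian noise (sd ``noise_sd``), clipping to
    [0, 1].  Returns a tidy loading dataset (condition, time_s,
    fraction_loaded, replicate, source="synthetic").
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for cond, params in spec.conditions.items():
        c = loaded_fraction(params, spec.times).C
        for rep in range(spec.replicates):
            noisy = c + rng.normal(0.0, spec.noise_sd, size=c.shape) if spec.noise_sd > 0 else c.copy()
            frames.append(pd.DataFrame({
                "condition": cond,
                "time_s": spec.times,
                "fraction_loaded": np.clip(noisy, 0.0, 1.0),
                "replicate": rep,
                "source": "synthetic",
            }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class ContactSimSpec:
    """Specification of a contact-count simulation.

    ``mode="iid"`` draws the hidden component independently per frame;
    ``mode="markov"`` draws a hidden Markov chain whose stationary
    distribution equals ``weights`` and whose characteristic dwell time
    is ``mean_dwell_frames`` frames, emulating reversible association of
    the protein with the membrane, then emits Poisson counts.
    """

    weights: Sequence[float] = DEFAULT_MIXTURE_WEIGHTS
    means: Sequence[float] = DEFAULT_MIXTURE_MEANS
    n_frames: int = 50_000
    mode: str = "iid"
    mean_dwell_frames: float = 50.0
    condition: str = "synthetic"
    seed: int | None = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if self.weights.shape != self.means.shape:
            raise ValueError("weights and means must have equal length")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if np.any(self.weights < 0) or np.any(self.means < 0):
            raise ValueError("weights and means must be ≥ 0")
        if self.mode not in ("iid", "markov"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        if self.mode == "markov" and self.mean_dwell_frames <= 1:
            raise ValueError("mean_dwell_frames must be > 1")


def _markov_states(spec: ContactSimSpec, rng: np.random.Generator) -> np.ndarray:
    """Hidden-state chain with stationary distribution = weights.

    Transition matrix P = (1 − a)·I + a·1πᵀ with a = 1/mean_dwell: each
    frame the chain resamples its state from the stationary distribution
    π with probability a, otherwise stays.  The dwell in state k is
    geometric with mean 1/(a·(1 − π_k)) = mean_dwell/(1 − π_k) frames.
    """
    a = 1.0 / spec.mean_dwell_frames
    states = np.empty(spec.n_frames, dtype=np.int64)
    states[0] = rng.choice(spec.weights.size, p=spec.weights)
    resample = rng.random(spec.n_frames) < a
    draws = rng.choice(spec.weights.size, size=spec.n_frames, p=spec.weights)
    for i in range(1, spec.n_frames):
        states[i] = draws[i] if resample[i] else states[i - 1]
    return states


def simulate_contact_counts(spec: ContactSimSpec) -> ContactSeries:
    """Draw a per-frame contact-count series from the mixture model."""
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "iid":
        states = rng.choice(spec.weights.size, size=spec.n_frames, p=spec.weights)
    else:
        states = _markov_states(spec, rng)
    counts = rng.poisson(spec.means[states])
    return ContactSeries(
        counts=counts,
        condition=spec.condition,
        metadata={
            "mode": spec.mode,
            "weights": spec.weights.tolist(),
            "means": spec.means.tolist(),
            "seed": spec.seed,
            "states": states,
        },
    )


def simulate_emission_spectrum(
    bands: Sequence[tuple[float, float, float]],
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> EmissionSpectrum:
    """Sum-of-Gaussians emission spectrum on a wavelength grid.

    ``bands`` is a list of (center nm, width nm, height) triples; the
    default grid is 400–600 nm in 2 nm steps.  Gaussian noise of sd
    ``noise_sd`` is added and intensities floored at 0.
    """
    wl = np.arange(400.0, 601.0, 2.0) if grid is None else np.asarray(grid, float)
    if wl.ndim != 1 or not np.all(np.diff(wl) > 0):
        raise ValueError("grid must be strictly increasing")
    intens = np.zeros_like(wl)
    for center, width, height in bands:
        if width <= 0:
            raise ValueError("band width must be > 0")
        intens += height * np.exp(-0.5 * ((wl - center) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intens = intens + rng.normal(0.0, noise_sd, size=wl.shape)
    return EmissionSpectrum(
        wavelengths=wl,
        intensities=np.clip(intens, 0.0, None),
        metadata={"bands": list(bands), "noise_sd": noise_sd, "seed": seed},
    )
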