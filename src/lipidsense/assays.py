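"""Spectroscopy and gel quantification formulas.

Three small, exactly defined observables:

* C-Laurdan generalized polarization, GP = (Ip1 − Ip2)/(Ip1 + Ip2), a
  normalized two-band emission asymmetry reporting lipid packing
  (default bands 402–460 nm and 470–530 nm; −1 < GP < 1).
* FRET acceptor/donor emission ratio (default I614/I516), reporting
  proximity of labelled transmembrane segments.
* Modified-band fraction of a gel lane, i.e. modified intensity
  normalized to total lane intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "BandDefinition",
    "LaneProfile",
    "AssayError",
    "generalized_polarization",
    "fret_ratio",
    "lane_modified_fraction",
]


class AssayError(ValueError):
    """Invalid spectrum, band definition or lane profile."""


@dataclass
class EmissionSpectrum:
    """An emission spectrum sampled at strictly increasing wavelengths (nm)."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape or self.wavelengths.ndim != 1:
            raise AssayError("wavelengths and intensities must be matching 1-D arrays")
        if self.wavelengths.size == 0:
            raise AssayError("empty spectrum")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise AssayError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise AssayError("negative intensity in spectrum")

    def intensity_at(self, wavelength_nm: float) -> float:
        """Intensity at the nearest recorded wavelength."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength_nm <= hi):
            raise AssayError(
                f"wavelength {wavelength_nm} nm outside recorded range [{lo}, {hi}]"
            )
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        return float(self.intensities[idx])

    def band_sum(self, low_nm: float, high_nm: float, mode: str = "sum") -> float:
        """Total intensity inside the closed interval [low_nm, high_nm].

        ``mode="sum"`` adds the raw samples (the default, matching
        plate-reader practice for discrete wavelength steps);
        ``mode="trapezoid"`` integrates with trapezoidal weights.
        """
        mask = (self.wavelengths >= low_nm) & (self.wavelengths <= high_nm)
        if not mask.any():
            raise AssayError(f"spectrum has no samples in [{low_nm}, {high_nm}] nm")
        if mode == "sum":
            return float(self.intensities[mask].sum())
        if mode == "trapezoid":
            return float(np.trapezoid(self.intensities[mask], self.wavelengths[mask]))
        raise AssayError(f"unknown band-sum mode {mode!r}")


@dataclass(frozen=True)
class BandDefinition:
    """Two non-overlapping wavelength bands (low, high) in nm.

    Defaults are the C-Laurdan GP bands: p1 = 402–460 nm (packed,
    blue-shifted), p2 = 470–530 nm (hydrated, red-shifted).  Band bounds
    are inclusive on both ends.
    """

    p1_range: tuple[float, float] = (402.0, 460.0)
    p2_range: tuple[float, float] = (470.0, 530.0)

    def __post_init__(self) -> None:
        for low, high in (self.p1_range, self.p2_range):
            if not low < high:
                raise AssayError(f"band ({low}, {high}) must satisfy low < high")
        a, b = sorted([self.p1_range, self.p2_range])
        if b[0] <= a[1]:
            raise AssayError("p1 and p2 bands overlap")

    def swapped(self) -> "BandDefinition":
        return BandDefinition(p1_range=self.p2_range, p2_range=self.p1_range)


def generalized_polarization(
    spec: EmissionSpectrum,
    bands: BandDefinition = BandDefinition(),
    mode: str = "sum",
) -> float:
    """C-Laurdan generalized polarization GP = (Ip1 − Ip2)/(Ip1 + Ip2).

    Ip1 and Ip2 are total intensities in the two bands (inclusive bounds,
    raw sample sums by default).  GP lies in [−1, 1], is invariant under
    positive rescaling of the spectrum and antisymmetric under swapping
    the bands.
    """
    ip1 = spec.band_sum(*bands.p1_range, mode=mode)
    ip2 = spec.band_sum(*bands.p2_range, mode=mode)
    total = ip1 + ip2
    if total <= 0:
        raise AssayError("GP undefined: zero total band intensity")
    return (ip1 - ip2) / total


def fret_ratio(
    spec: EmissionSpectrum,
    acceptor_nm: float = 614.0,
    donor_nm: float = 516.0,
) -> float:
    """Acceptor/donor emission intensity ratio (default I614/I516).

    Uses the nearest recorded sample at each wavelength; plate readers
    report discrete wavelength steps, so no interpolation is applied.
    """
    donor = spec.intensity_at(donor_nm)
    if donor <= 0:
        raise AssayError("FRET ratio undefined: donor intensity is zero")
    return spec.intensity_at(acceptor_nm) / donor


@dataclass
class LaneProfile:
    """Band intensities of one gel lane plus the total lane intensity."""

    band_intensities: dict[str, float]
    total_intensity: float

    def __post_init__(self) -> None:
        if self.total_intensity <= 0:
            raise AssayError("total lane intensity must be positive")
        for label, val in self.band_intensities.items():
            if val < 0:
                raise AssayError(f"negative intensity for band {label!r}")
            if val > self.total_intensity:
                raise AssayError(
                    f"band {label!r} intensity {val} exceeds lane total "
                    f"{self.total_intensity}"
                )


def lane_modified_fraction(lane: LaneProfile, modified_labels: Iterable[str]) -> float:
    """Fraction of lane intensity in the selected (modified) bands.

    Normalizes the summed intensity of the selected bands to the total
    lane intensity; an empty selection yields 0.
    """
    labels = set(modified_labels)
    unknown = labels - set(lane.band_intensities)
    if unknown:
        raise AssayError(f"unknown band labels: {sorted(unknown)}")
    selected = sum(lane.band_intensities[l] for l in labels)
    return selected / lane.total_intensity
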