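"""Closed-form calculators for gel densitometry and circular dichroism.

Fraction folded from a cold semi-native SDS-PAGE band shift assay:

    fraction_folded = folded / (folded + unfolded)

using band intensities from the unboiled lane.  An alternative mode
divides by the boiled-lane intensity instead, for samples where the
unboiled folded+unfolded intensity decays over time.

Mean residue ellipticity (MRE) normalizes a CD spectrum by the number of
peptide bonds and the optical path:

    MRW = M / (N - 1)
    [theta]_MRE = MRW * theta_lambda / (10 * d * c)

with M the molecular mass (Da), N the residue count, theta_lambda the
measured ellipticity (millidegrees), d the path length (cm) and c the
protein concentration (g/mL), giving MRE in deg cm^2 dmol^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError

__all__ = ["BandIntensities", "CDParams", "fraction_folded",
           "mean_residue_weight", "mean_residue_ellipticity"]


@dataclass(frozen=True)
class BandIntensities:
    """Densitometry intensities for one lane (arbitrary units, >= 0)."""

    folded: float
    unfolded: float
    boiled: float | None = None

    def __post_init__(self):
        if self.folded < 0 or self.unfolded < 0:
            raise DegenerateDataError("band intensities must be >= 0")
        if self.boiled is not None and self.boiled < 0:
            raise DegenerateDataError("boiled band intensity must be >= 0")


@dataclass(frozen=True)
class CDParams:
    """Inputs of the MRE calculation.

    ``concentration`` is in g/mL by default; pass
    ``concentration_unit="mg_per_ml"`` to :func:`mean_residue_ellipticity`
    if the value is in mg/mL.
    """

    molecular_mass_da: float
    n_residues: int
    path_length_cm: float
    concentration: float
    ellipticity_mdeg: np.ndarray

    def __post_init__(self):
        if self.n_residues < 2:
            raise DegenerateDataError("need >= 2 residues")
        if self.path_length_cm <= 0 or self.concentration <= 0:
            raise DegenerateDataError("path length and concentration must be > 0")
        object.__setattr__(self, "ellipticity_mdeg",
                           np.asarray(self.ellipticity_mdeg, dtype=float))


def fraction_folded(bands: BandIntensities,
                    denominator: str = "folded_plus_unfolded") -> float:
    """Fraction of folded protein from band intensities.

    The default divides the folded band by folded+unfolded in the
    unboiled lane; ``denominator="boiled"`` divides by the boiled-lane
    band instead.
    """
    if denominator == "folded_plus_unfolded":
        total = bands.folded + bands.unfolded
        if total <= 0:
            raise DegenerateDataError("folded + unfolded must be > 0")
    elif denominator == "boiled":
        if bands.boiled is None or bands.boiled <= 0:
            raise DegenerateDataError("boiled band intensity required and > 0")
        total = bands.boiled
    else:
        raise DegenerateDataError(f"unknown denominator mode {denominator!r}")
    return bands.folded / total


def mean_residue_weight(molecular_mass_da: float, n_residues: int) -> float:
    """MRW = M / (N - 1), the mass per peptide bond."""
    if n_residues < 2:
        raise DegenerateDataError("need >= 2 residues")
    return molecular_mass_da / (n_residues - 1)


def mean_residue_ellipticity(params: CDParams,
                             concentration_unit: str = "g_per_ml") -> np.ndarray:
    """Elementwise MRE spectrum in deg cm^2 dmol^-1."""
    if concentration_unit == "g_per_ml":
        c = params.concentration
    elif concentration_unit == "mg_per_ml":
        c = params.concentration * 1e-3
    else:
        raise DegenerateDataError(f"unknown concentration unit {concentration_unit!r}")
    mrw = mean_residue_weight(params.molecular_mass_da, params.n_residues)
    return mrw * params.ellipticity_mdeg / (10.0 * params.path_length_cm * c)
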