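"""Quantification of the covalent protein-ssDNA adduct.

Four small computations around the protein-primed polymerization product:

* the intensity-weighted mean length of the attached ssDNA from a gel
  densitometry profile (one label per strand makes band intensity
  proportional to molecule count);
* the theoretical A260/A280 ratio of a protein-DNA adduct as a two-component
  absorbance mixture — absorbances add, ratios do not, so the ratio at DNA
  occupancy f is ``(f*A260_dna + A260_prot) / (f*A280_dna + A280_prot)``
  per mole of protein;
* the inversion of that mixture: the occupancy implied by a measured ratio
  (closed form, exact round-trip);
* a linear initial polymerization-rate estimate from mean product lengths at
  two time points.

Per-base extinction coefficients default to standard deoxynucleotide
monomer values at 260 nm with literature 280/260 ratios; no hypochromicity
correction is applied unless requested.  All coefficients are configurable
because measured values for a given instrument/buffer differ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: standard monomer molar extinction coefficients at 260 nm [1/(M cm)]
EPS260_PER_BASE = {"A": 15400.0, "C": 7400.0, "G": 11500.0, "T": 8700.0}
#: literature eps280/eps260 ratios per deoxynucleotide monomer
EPS280_OVER_EPS260 = {"A": 0.16, "C": 0.97, "G": 0.66, "T": 0.72}


@dataclass(frozen=True)
class DensitometryProfile:
    """Band intensity by product length (nt), arbitrary units."""

    lengths: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.intensities) or not self.lengths:
            raise ValueError("profile needs matching, non-empty length/intensity lists")
        if any(i < 0 for i in self.intensities):
            raise ValueError("intensities must be >= 0")
        if not any(i > 0 for i in self.intensities):
            raise ValueError("profile has no positive intensity")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, float]]) -> "DensitometryProfile":
        lengths, intensities = zip(*pairs)
        return cls(tuple(lengths), tuple(intensities))


@dataclass(frozen=True)
class AbsorbanceModel:
    """Two-component absorbance model of a protein-ssDNA adduct.

    The protein contributes fixed absorbances (from molar extinction
    coefficients, or from a measured protein-only A260/A280 ratio plus
    eps280); the DNA contributes ``mean_length * composition-weighted
    per-base eps`` per mole of protein at full occupancy.
    """

    mean_length: float
    composition: Mapping[str, float]
    eps280_protein: float
    eps260_protein: float | None = None
    protein_ratio: float | None = None  # measured protein-only A260/A280
    eps260_per_base: Mapping[str, float] = field(
        default_factory=lambda: dict(EPS260_PER_BASE)
    )
    eps280_over_eps260: Mapping[str, float] = field(
        default_factory=lambda: dict(EPS280_OVER_EPS260)
    )
    hypochromicity: float = 0.0  # fractional reduction of DNA eps260/eps280

    def __post_init__(self) -> None:
        if self.mean_length <= 0:
            raise ValueError("mean DNA length must be positive")
        total = sum(self.composition.get(b, 0.0) for b in "ACGT")
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("base composition must sum to 1")
        if (self.eps260_protein is None) == (self.protein_ratio is None):
            raise ValueError("supply exactly one of eps260_protein or protein_ratio")
        if self.eps280_protein <= 0:
            raise ValueError("protein eps280 must be positive")
        if not 0.0 <= self.hypochromicity < 1.0:
            raise ValueError("hypochromicity must be in [0, 1)")

    # -- per-mole-of-protein absorbance components --------------------------
    @property
    def a260_protein(self) -> float:
        if self.eps260_protein is not None:
            return self.eps260_protein
        return self.protein_ratio * self.eps280_protein

    @property
    def a280_protein(self) -> float:
        return self.eps280_protein

    @property
    def a260_dna(self) -> float:
        per_base = sum(
            self.composition.get(b, 0.0) * self.eps260_per_base[b] for b in "ACGT"
        )
        return self.mean_length * per_base * (1.0 - self.hypochromicity)

    @property
    def a280_dna(self) -> float:
        per_base = sum(
            self.composition.get(b, 0.0)
            * self.eps260_per_base[b]
            * self.eps280_over_eps260[b]
            for b in "ACGT"
        )
        return self.mean_length * per_base * (1.0 - self.hypochromicity)

    def protein_only_ratio(self) -> float:
        return self.a260_protein / self.a280_protein

    def full_adduct_ratio(self) -> float:
        return adduct_ratio(self, 1.0)


@dataclass(frozen=True)
class OccupancyEstimate:
    """DNA occupancy fraction implied by a measured A260/A280 ratio."""

    occupancy: float
    measured_ratio: float
    protein_only_ratio: float
    full_adduct_ratio: float
    clamped: bool = False


def weighted_mean_length(profile: DensitometryProfile) -> float:
    """Intensity-weighted mean product length, sum(I_l * l) / sum(I_l)."""
    weights = np.asarray(profile.intensities, dtype=float)
    lengths = np.asarray(profile.lengths, dtype=float)
    return float(np.sum(weights * lengths) / np.sum(weights))


def adduct_ratio(model: AbsorbanceModel, occupancy: float) -> float:
    """Theoretical A260/A280 of the adduct at DNA occupancy ``occupancy``."""
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must be in [0, 1]")
    num = occupancy * model.a260_dna + model.a260_protein
    den = occupancy * model.a280_dna + model.a280_protein
    if den <= 0:
        raise ValueError("non-positive A280 denominator")
    return num / den


def occupancy(measured_ratio: float, model: AbsorbanceModel) -> OccupancyEstimate:
    """Invert the two-component mixture for the occupancy fraction.

    ``ratio(f) = (f*D260 + P260) / (f*D280 + P280)`` gives the closed form
    ``f = (r*P280 - P260) / (D260 - r*D280)``.  Measured ratios outside the
    [protein-only, full-adduct] interval are clamped with a warning.
    """
    r0 = model.protein_only_ratio()
    r1 = model.full_adduct_ratio()
    if math.isclose(r0, r1, rel_tol=1e-12, abs_tol=1e-12):
        raise ValueError("protein-only and full-adduct ratios coincide; "
                         "occupancy is undefined")
    denom = model.a260_dna - measured_ratio * model.a280_dna
    if denom == 0:
        raise ValueError("measured ratio equals the DNA-only ratio; "
                         "occupancy diverges")
    f = (measured_ratio * model.a280_protein - model.a260_protein) / denom
    clamped = False
    if not 0.0 <= f <= 1.0:
        logger.warning(
            "measured ratio %.4f outside [%.4f, %.4f]; clamping occupancy",
            measured_ratio, min(r0, r1), max(r0, r1),
        )
        f = min(max(f, 0.0), 1.0)
        clamped = True
    return OccupancyEstimate(f, measured_ratio, r0, r1, clamped)


def polymerization_rate(
    mean_length_t0: float, mean_length_t1: float, delta_t_min: float
) -> float:
    """Initial polymerization rate in nt/min from two mean product lengths."""
    if delta_t_min <= 0:
        raise ValueError("delta_t must be positive")
    return (mean_length_t1 - mean_length_t0) / delta_t_min
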