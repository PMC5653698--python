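"""CsCl gradient fractions and the refractive-index <-> buoyant-density map.

The buoyant density rho (g/cm^3) of a CsCl fraction is linear in its
refractive index eta at fixed temperature::

    rho = a * eta - b

with a = 10.9276 and b = 13.593 valid at 20 degC. A gradient run is
divided into fractions collected from the tube bottom, so fraction 1 is the
heaviest; 18 fractions is the usual count but any series of >= 3 is
accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .errors import SchemaError
from .trflp import TRFPeak

#: Plausible refractive-index range for CsCl gradient fractions.
ETA_RANGE = (1.20, 1.50)
#: Plausible DNA buoyant-density range in CsCl (g/cm^3).
RHO_RANGE = (1.60, 1.85)


@dataclass(frozen=True)
class ConversionConstants:
    """Constants of the linear density/refractive-index relation.

    The defaults are valid only at 20 degC; at other temperatures supply
    temperature-appropriate constants.
    """

    a: float = 10.9276
    b: float = 13.593
    temperature_C: float = 20.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"multiplier a must be positive, got {self.a}")


DEFAULT_CONSTANTS = ConversionConstants()


def density_from_refractive_index(
    eta: float, constants: ConversionConstants = DEFAULT_CONSTANTS
) -> float:
    """Buoyant density (g/cm^3) from a refractive-index reading."""
    if not ETA_RANGE[0] <= eta <= ETA_RANGE[1]:
        raise ValueError(
            f"refractive index {eta!r} outside plausible range {ETA_RANGE}"
        )
    return constants.a * eta - constants.b


def refractive_index_from_density(
    rho: float, constants: ConversionConstants = DEFAULT_CONSTANTS
) -> float:
    """Exact inverse of :func:`density_from_refractive_index`.

    Used as the forward model when simulating refractometer readouts.
    """
    if not RHO_RANGE[0] <= rho <= RHO_RANGE[1]:
        raise ValueError(
            f"buoyant density {rho!r} outside plausible range {RHO_RANGE}"
        )
    return (rho + constants.b) / constants.a


@dataclass
class GradientFraction:
    """One CsCl fraction: optical readout, density, 16S load, peak tables.

    ``peaks`` maps enzyme name -> list of :class:`~siptrflp.trflp.TRFPeak`.
    """

    index: int
    refractive_index: float | None = None
    buoyant_density: float | None = None
    total_16S_copies: float = 0.0
    peaks: dict[str, list[TRFPeak]] = field(default_factory=dict)


@dataclass
class FractionSeries:
    """An ordered set of fractions from one gradient run (one condition)."""

    condition_label: str
    fractions: list[GradientFraction]

    def __iter__(self):
        return iter(self.fractions)

    def __len__(self) -> int:
        return len(self.fractions)

    @property
    def densities(self) -> list[float]:
        return [f.buoyant_density for f in self.fractions]


def validate_fraction_series(
    series: FractionSeries,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> FractionSeries:
    """Validate and normalize a fraction series.

    Computes missing densities from the refractive index, checks ranges and
    index uniqueness, and returns a new series sorted heaviest-first.
    Fraction 1 is collected from the tube bottom and should be the heaviest;
    a density inversion relative to the collection order is a warning, not
    an error, because refractometer readings carry noise.
    """
    if len(series.fractions) < 3:
        raise SchemaError(
            f"series {series.condition_label!r} has {len(series.fractions)} "
            "fractions; at least 3 required"
        )
    indices = [f.index for f in series.fractions]
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        raise SchemaError(
            f"series {series.condition_label!r} has duplicate fraction "
            f"indices: {dupes}"
        )
    completed = []
    for frac in series.fractions:
        rho = frac.buoyant_density
        if rho is None:
            if frac.refractive_index is None:
                raise SchemaError(
                    f"fraction {frac.index} of {series.condition_label!r} has "
                    "neither a density nor a refractive index"
                )
            rho = density_from_refractive_index(frac.refractive_index, constants)
        if not RHO_RANGE[0] <= rho <= RHO_RANGE[1]:
            raise SchemaError(
                f"fraction {frac.index} of {series.condition_label!r}: density "
                f"{rho!r} outside plausible range {RHO_RANGE}"
            )
        if frac.total_16S_copies < 0:
            raise SchemaError(
                f"fraction {frac.index} of {series.condition_label!r}: "
                f"negative 16S copy number {frac.total_16S_copies!r}"
            )
        completed.append(replace(frac, buoyant_density=rho))
    by_index = sorted(completed, key=lambda f: f.index)
    rhos = [f.buoyant_density for f in by_index]
    if any(b > a for a, b in zip(rhos, rhos[1:])):
        warnings.warn(
            f"series {series.condition_label!r}: buoyant density is not "
            "non-increasing in collection order; re-sorting by density",
            stacklevel=2,
        )
    ordered = sorted(
        completed, key=lambda f: (-f.buoyant_density, f.index)
    )
    return FractionSeries(series.condition_label, ordered)
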