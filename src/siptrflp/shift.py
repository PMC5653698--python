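"""Per-T-RF buoyant-density distributions and isotope-shift detection.

For each T-RF bin and condition, per-fraction copy numbers are obtained by
scaling the T-RF's fluorescence proportion by the fraction's total 16S
copy number (from qPCR) and then normalizing the resulting series by its
maximum, giving a curve of normalized DNA amount versus buoyant density.
A taxon that assimilated the 13C-labeled substrate shows this curve
displaced toward heavier fractions relative to the unlabeled reference.

A bin is called shifted when the labeled curve's modal fraction is heavier
than the unlabeled one by at least ``min_peak_shift`` AND the labeled curve
carries more normalized mass at or above the heavy-fraction threshold
(default 1.732 g/cm^3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError, PairingError
from .gradient import FractionSeries
from .trflp import EnzymeSpec, TRFBin, peak_proportions


@dataclass(frozen=True)
class StandardCurve:
    """A qPCR calibration line: Cq = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float


def fit_standard_curve(dilution_points) -> StandardCurve:
    """Fit a qPCR standard curve to (copies, Cq) dilution points.

    Ordinary least squares of Cq on log10(copies); requires >= 3 distinct
    dilution levels. Amplification efficiency is ``10**(-1/slope) - 1``
    (a perfect doubling per cycle gives slope -3.3219 and efficiency 1).
    A fit with r^2 < 0.98 triggers a warning.
    """
    pts = [(float(c), float(q)) for c, q in dilution_points]
    if any(not (math.isfinite(c) and math.isfinite(q)) for c, q in pts):
        raise ValueError("non-finite copies or Cq in dilution points")
    if any(c <= 0 for c, _ in pts):
        raise ValueError("copy numbers must be positive")
    if len({c for c, _ in pts}) < 3:
        raise ValueError("at least 3 distinct dilution levels required")
    x = np.log10([c for c, _ in pts])
    y = np.array([q for _, q in pts])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"calibration slope must be negative, got {fit.slope:.4g}"
        )
    r2 = float(fit.rvalue**2)
    if r2 < 0.98:
        warnings.warn(f"standard curve r^2 = {r2:.4f} < 0.98", stacklevel=2)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=10 ** (-1 / float(fit.slope)) - 1,
        r_squared=r2,
    )


def copies_from_cq(cq: float, curve: StandardCurve) -> float:
    """Absolute copy number from a Cq value via the calibration line."""
    if curve.slope >= 0:
        raise ValueError("invalid standard curve: slope must be negative")
    if not math.isfinite(cq):
        raise ValueError(f"non-finite Cq: {cq!r}")
    return 10 ** ((cq - curve.intercept) / curve.slope)


def trf_copy_numbers(
    proportions: dict[int, float], total_copies: float
) -> dict[int, float]:
    """Per-T-RF absolute copy numbers from proportions and the qPCR total."""
    if total_copies < 0:
        raise ValueError(f"total copy number must be >= 0, got {total_copies}")
    s = sum(proportions.values())
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {s!r}, expected 1")
    return {L: p * total_copies for L, p in proportions.items()}


def normalize_by_max(series) -> np.ndarray:
    """Divide a nonnegative series by its maximum (the maximum maps to 1)."""
    arr = np.asarray(series, dtype=float)
    if (arr < 0).any():
        raise ValueError("copy numbers must be >= 0")
    m = arr.max(initial=0.0)
    if m <= 0:
        raise DegenerateInputError(
            "all-zero series: normalized distribution undefined"
        )
    return arr / m


@dataclass
class TRFDistribution:
    """Normalized copy number of one T-RF bin across a density gradient.

    Points are sorted by ascending buoyant density; ``normalized`` attains
    exactly 1 at the modal fraction.
    """

    bin: TRFBin
    condition_label: str
    densities: np.ndarray
    copies: np.ndarray
    normalized: np.ndarray

    @classmethod
    def from_copies(cls, bin, condition_label, densities, copies):
        densities = np.asarray(densities, dtype=float)
        copies = np.asarray(copies, dtype=float)
        order = np.argsort(densities)
        densities, copies = densities[order], copies[order]
        return cls(bin, condition_label, densities, copies, normalize_by_max(copies))

    def __len__(self) -> int:
        return len(self.densities)


def build_distribution(
    series: FractionSeries,
    bin: TRFBin,
    enzyme,
    floor_fraction: float = 0.005,
) -> TRFDistribution:
    """Density distribution of one T-RF bin in one condition.

    Per fraction: fluorescence of peaks falling in the bin -> proportion of
    total T-RFs -> absolute copies via the fraction's 16S total ->
    normalized by the across-fraction maximum. Fractions without a matching
    peak contribute zero; a bin absent from every fraction is degenerate.
    """
    name = enzyme.name if isinstance(enzyme, EnzymeSpec) else str(enzyme)
    if bin.enzyme and bin.enzyme != name:
        raise ConfigurationError(
            f"bin is for enzyme {bin.enzyme!r}, asked to profile {name!r}"
        )
    densities, copies = [], []
    for frac in series.fractions:
        if name not in frac.peaks:
            raise ConfigurationError(
                f"fraction {frac.index} of {series.condition_label!r} has no "
                f"peak table for enzyme {name!r}"
            )
        peaks = frac.peaks[name]
        c = 0.0
        if peaks and any(p.fluorescence > 0 for p in peaks):
            props = peak_proportions(peaks, floor_fraction)
            in_bin = sum(p for L, p in props.items() if bin.contains(L))
            c = in_bin * frac.total_16S_copies
        densities.append(frac.buoyant_density)
        copies.append(c)
    return TRFDistribution.from_copies(bin, series.condition_label, densities, copies)


def weighted_mean_density(dist: TRFDistribution) -> float:
    """Copy-number-weighted mean buoyant density of a distribution."""
    total = float(dist.copies.sum())
    if total <= 0:
        raise DegenerateInputError("all-zero distribution has no mean density")
    return float(np.dot(dist.densities, dist.copies) / total)


def peak_fraction_density(dist: TRFDistribution) -> float:
    """Buoyant density of the modal fraction; ties resolve to the heavier."""
    m = dist.normalized.max(initial=0.0)
    if m <= 0:
        raise DegenerateInputError("all-zero distribution has no peak")
    return float(dist.densities[dist.normalized == m].max())


@dataclass(frozen=True)
class ShiftParams:
    """Thresholds for calling an isotope-driven density shift.

    ``heavy_threshold`` is the density (g/cm^3) above which fractions count
    as heavy; ``min_peak_shift`` (~ one fraction spacing) is the minimum
    modal-density displacement; ``pairing_tolerance`` is how close two
    gradients' fraction densities must come to be considered comparable.
    """

    heavy_threshold: float = 1.732
    min_peak_shift: float = 0.004
    pairing_tolerance: float = 0.002


@dataclass(frozen=True)
class ShiftResult:
    """Labeled-vs-unlabeled comparison for one T-RF bin."""

    bin: TRFBin
    peak_density_labeled: float
    peak_density_unlabeled: float
    weighted_mean_shift: float
    heavy_ratio: float  # may be math.inf
    shifted: bool


def detect_shift(
    labeled: TRFDistribution,
    unlabeled: TRFDistribution,
    params: ShiftParams = ShiftParams(),
) -> ShiftResult:
    """Compare a labeled distribution against its unlabeled reference.

    ``heavy_ratio`` is the summed normalized copy number at densities >=
    ``heavy_threshold`` in the labeled condition divided by the same sum in
    the unlabeled one (inf when only the labeled sum is positive, 1 when
    both are zero). The bin is shifted iff the modal density moved heavier
    by at least ``min_peak_shift`` and ``heavy_ratio`` exceeds 1.

    Density grids from separate runs are never bit-identical, so grids are
    checked for comparability by nearest-density pairing: it is an error if
    no labeled fraction has an unlabeled fraction within
    ``pairing_tolerance``.
    """
    if (
        labeled.bin.enzyme != unlabeled.bin.enzyme
        or labeled.bin.representative_length_bp
        != unlabeled.bin.representative_length_bp
    ):
        raise ConfigurationError(
            "labeled and unlabeled distributions describe different bins"
        )
    gaps = np.abs(labeled.densities[:, None] - unlabeled.densities[None, :])
    if gaps.min(axis=1).min() > params.pairing_tolerance:
        raise PairingError(
            "no labeled fraction has an unlabeled fraction within "
            f"{params.pairing_tolerance} g/cm^3; grids are not comparable"
        )
    heavy_l = float(
        labeled.normalized[labeled.densities >= params.heavy_threshold].sum()
    )
    heavy_u = float(
        unlabeled.normalized[unlabeled.densities >= params.heavy_threshold].sum()
    )
    if heavy_u > 0:
        heavy_ratio = heavy_l / heavy_u
    elif heavy_l > 0:
        heavy_ratio = math.inf
    else:
        heavy_ratio = 1.0
    peak_l = peak_fraction_density(labeled)
    peak_u = peak_fraction_density(unlabeled)
    shifted = (peak_l - peak_u >= params.min_peak_shift) and heavy_ratio > 1
    return ShiftResult(
        bin=labeled.bin,
        peak_density_labeled=peak_l,
        peak_density_unlabeled=peak_u,
        weighted_mean_shift=weighted_mean_density(labeled)
        - weighted_mean_density(unlabeled),
        heavy_ratio=heavy_ratio,
        shifted=shifted,
    )
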