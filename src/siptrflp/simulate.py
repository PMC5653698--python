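"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the four measurement layers of a DNA-SIP/T-RFLP
experiment:

* **Gradient banding** — each taxon's DNA bands as a Gaussian around a
  buoyant density determined by its GC content and the atom-fraction of
  13C it assimilated (``rho = rho_base + rho_gc_slope * GC +
  rho_label_max * atom_frac``). The density-model constants are standard
  SIP-literature values, configurable, not fitted to any one study.
* **Refractometry** — refractive-index readouts are the exact inverse of
  the density conversion plus Gaussian noise.
* **T-RFLP** — each taxon produces one peak per fraction and enzyme with
  fluorescence proportional to its DNA mass; the observed length is the
  true terminal fragment plus a truncated Gaussian capillary error
  (clipped to +/-4 bp so simulated data never violate the 5-bp affiliation
  tolerance by construction); co-migrating peaks merge.
* **qPCR** — per-fraction 16S totals carry lognormal noise; dilution
  series follow a linear Cq/log10(copies) calibration with Gaussian Cq
  noise.

A VOC degradation model (lag phase, then first-order decay) generates the
concentration time series that set the sampling days.

All randomness descends from ``SimulatorParams.seed``; each operation uses
its own fixed substream so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.SeqUtils import gc_fraction as _bio_gc_fraction

from .errors import ConfigurationError, NotReachedError
from .gradient import (
    FractionSeries,
    GradientFraction,
    density_from_refractive_index,
    refractive_index_from_density,
)
from .trflp import HHAI, MSPI, NO_CUT, EnzymeSpec, TRFPeak, terminal_fragment_length


@dataclass
class Taxon:
    """A simulated community member.

    ``gc_fraction`` is derived from ``sequence`` when one is given.
    ``atom_frac_13C`` is the atom-fraction excess of 13C assimilated into
    the taxon's DNA (0 in every unlabeled condition). ``true_trfs`` may
    preassign terminal fragment lengths per enzyme; otherwise they are
    digested from the sequence.
    """

    id: str
    sequence: str | None = None
    gc_fraction: float | None = None
    relative_abundance: float = 0.0
    atom_frac_13C: float = 0.0
    true_trfs: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and self.gc_fraction is None:
            self.gc_fraction = float(_bio_gc_fraction(self.sequence))
        if self.gc_fraction is None:
            raise ValueError(f"taxon {self.id!r} needs a sequence or gc_fraction")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError(f"gc_fraction {self.gc_fraction} outside [0, 1]")
        if not 0 <= self.atom_frac_13C <= 1:
            raise ValueError(f"atom_frac_13C {self.atom_frac_13C} outside [0, 1]")
        if not 0 <= self.relative_abundance <= 1:
            raise ValueError(
                f"relative_abundance {self.relative_abundance} outside [0, 1]"
            )

    def trf(self, enzyme: EnzymeSpec) -> int:
        """True terminal fragment length for ``enzyme``."""
        if self.true_trfs and enzyme.name in self.true_trfs:
            return self.true_trfs[enzyme.name]
        if self.sequence is not None:
            length = terminal_fragment_length(self.sequence, enzyme)
            if length is not NO_CUT:
                return length
        raise ConfigurationError(
            f"taxon {self.id!r} has no terminal fragment for {enzyme.name}"
        )


@dataclass(frozen=True)
class SimulatorParams:
    """All knobs of the synthetic experiment, with field-realistic defaults.

    Densities in g/cm^3. ``rho_base``/``rho_gc_slope``/``rho_label_max``
    define the taxon band-center model; the fraction grid spans
    ``density_min``..``density_max`` in ``n_fractions`` equal steps;
    ``band_sigma`` is the banding width; measurement noise is set by
    ``eta_noise_sd`` (refractometer), ``len_error_sd``/``len_error_clip_bp``
    (capillary sizing), ``qpcr_lognormal_sd``/``cq_noise_sd`` (qPCR).
    """

    rho_base: float = 1.660
    rho_gc_slope: float = 0.098
    rho_label_max: float = 0.036
    band_sigma: float = 0.005
    n_fractions: int = 18
    density_min: float = 1.690
    density_max: float = 1.775
    eta_noise_sd: float = 1e-4
    len_error_sd: float = 1.5
    len_error_clip_bp: int = 4
    qpcr_lognormal_sd: float = 0.1
    cq_noise_sd: float = 0.1
    qpcr_slope: float = -3.3219
    qpcr_intercept: float = 40.0
    total_copies: float = 1e8
    fluorescence_scale: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_min >= self.density_max:
            raise ValueError("density_min must be below density_max")
        if self.n_fractions < 3:
            raise ValueError("n_fractions must be >= 3")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")


def _rng(params: SimulatorParams, stream: int, label: str = "") -> np.random.Generator:
    key = [params.seed & 0x7FFFFFFF, stream]
    if label:
        key.append(zlib.crc32(label.encode()) & 0x7FFFFFFF)
    return np.random.default_rng(key)


def validate_community(community) -> list[Taxon]:
    taxa = list(community)
    if not taxa:
        raise ValueError("empty community")
    total = sum(t.relative_abundance for t in taxa)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"community abundances sum to {total!r}, expected 1")
    return taxa


def taxon_band_center(taxon: Taxon, params: SimulatorParams) -> float:
    """Buoyant density at which a taxon's DNA bands."""
    return (
        params.rho_base
        + params.rho_gc_slope * taxon.gc_fraction
        + params.rho_label_max * taxon.atom_frac_13C
    )


def fraction_centers(params: SimulatorParams) -> np.ndarray:
    """True fraction densities, equally spaced, ascending."""
    return np.linspace(params.density_min, params.density_max, params.n_fractions)


def band_masses(community, params: SimulatorParams, warn: bool = True):
    """DNA mass of each taxon in each fraction (rows: taxa, cols: ascending
    density). Each taxon's Gaussian band is evaluated at the fraction
    centers and renormalized, so mass is conserved exactly."""
    taxa = validate_community(community)
    centers = fraction_centers(params)
    masses = np.zeros((len(taxa), len(centers)))
    for i, taxon in enumerate(taxa):
        c = taxon_band_center(taxon, params)
        if warn and not (
            params.density_min - 3 * params.band_sigma
            <= c
            <= params.density_max + 3 * params.band_sigma
        ):
            warnings.warn(
                f"band center {c:.4f} of taxon {taxon.id!r} lies more than "
                "3 sigma outside the fraction grid; band is truncated",
                stacklevel=2,
            )
        w = np.exp(-0.5 * ((centers - c) / params.band_sigma) ** 2)
        s = w.sum()
        if s == 0:  # degenerate narrow band: all mass to the nearest fraction
            w[np.argmin(np.abs(centers - c))] = 1.0
            s = 1.0
        masses[i] = taxon.relative_abundance * w / s
    return centers, masses


def simulate_gradient(
    community,
    params: SimulatorParams,
    condition_label: str = "simulated",
    rng: np.random.Generator | None = None,
) -> FractionSeries:
    """Simulate one density-gradient fractionation run.

    Returns a series ordered heaviest-first (fraction 1 = tube bottom) with
    noisy refractive indices, densities recomputed from them, and noisy
    per-fraction 16S totals. Peak tables are attached separately by
    :func:`simulate_trflp`.
    """
    rng = rng if rng is not None else _rng(params, 1, condition_label)
    centers, masses = band_masses(community, params)
    n = len(centers)
    total_mass = masses.sum(axis=0)
    copies = (
        total_mass
        * params.total_copies
        * np.exp(rng.normal(0.0, params.qpcr_lognormal_sd, n))
    )
    eta = np.array(
        [refractive_index_from_density(c) for c in centers]
    ) + rng.normal(0.0, params.eta_noise_sd, n)
    rho = np.array([density_from_refractive_index(e) for e in eta])
    fractions = [
        GradientFraction(
            index=i,
            refractive_index=float(eta[n - i]),
            buoyant_density=float(rho[n - i]),
            total_16S_copies=float(copies[n - i]),
            peaks={},
        )
        for i in range(1, n + 1)
    ]
    return FractionSeries(condition_label, fractions)


def simulate_trflp(
    series: FractionSeries,
    community,
    enzymes,
    params: SimulatorParams,
    rng: np.random.Generator | None = None,
) -> FractionSeries:
    """Attach simulated T-RFLP peak tables to a gradient series.

    One peak per taxon, fraction and enzyme, with fluorescence proportional
    to the taxon's DNA mass; observed lengths carry the clipped capillary
    error, and peaks landing on the same length merge their fluorescence.
    """
    rng = rng if rng is not None else _rng(params, 2, series.condition_label)
    taxa = validate_community(community)
    enzymes = list(enzymes)
    true_lengths = {
        (t.id, e.name): t.trf(e) for t in taxa for e in enzymes
    }
    _, masses = band_masses(community, params, warn=False)
    n = params.n_fractions
    for frac in series.fractions:
        col = n - frac.index
        for enzyme in enzymes:
            merged: dict[int, float] = {}
            for i, taxon in enumerate(taxa):
                err = float(
                    np.clip(
                        rng.normal(0.0, params.len_error_sd),
                        -params.len_error_clip_bp,
                        params.len_error_clip_bp,
                    )
                )
                observed = int(true_lengths[(taxon.id, enzyme.name)] + round(err))
                fl = masses[i, col] * params.fluorescence_scale
                if fl > 0:
                    merged[observed] = merged.get(observed, 0.0) + fl
            frac.peaks[enzyme.name] = [
                TRFPeak(L, f) for L, f in sorted(merged.items())
            ]
    return series


def simulate_experiment(
    community,
    params: SimulatorParams,
    condition_label: str,
    enzymes=(HHAI, MSPI),
) -> FractionSeries:
    """Gradient + T-RFLP simulation for one condition, fully seeded."""
    series = simulate_gradient(community, params, condition_label)
    return simulate_trflp(series, community, enzymes, params)


def simulate_qpcr_dilution_series(
    true_copies_top: float,
    n_levels: int,
    params: SimulatorParams,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Serial 10-fold dilution series as (copies, Cq) points."""
    if n_levels < 3:
        raise ValueError("at least 3 dilution levels required")
    rng = rng if rng is not None else _rng(params, 3)
    out = []
    for level in range(n_levels):
        copies = true_copies_top / 10**level
        cq = (
            params.qpcr_intercept
            + params.qpcr_slope * np.log10(copies)
            + float(rng.normal(0.0, params.cq_noise_sd))
        )
        out.append((copies, float(cq)))
    return out


@dataclass(frozen=True)
class CompoundKinetics:
    """Lag-then-first-order degradation of one compound."""

    initial_mg_L: float = 30.0
    lag_days: float = 0.0
    rate_per_day: float = 0.0

    def __post_init__(self) -> None:
        if min(self.initial_mg_L, self.lag_days, self.rate_per_day) < 0:
            raise ValueError("kinetic parameters must be >= 0")


def simulate_degradation(
    kinetics: Mapping[str, CompoundKinetics], times
) -> pd.DataFrame:
    """Deterministic concentration series: constant through the lag, then
    first-order decay. Rows indexed by day, one column per compound."""
    t = np.asarray(times, dtype=float)
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    if len(t) == 0 or t[0] != 0:
        raise ValueError("times must start at 0")
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly ascending")
    data = {}
    for compound, k in kinetics.items():
        c = np.where(
            t < k.lag_days,
            k.initial_mg_L,
            k.initial_mg_L * np.exp(-k.rate_per_day * (t - k.lag_days)),
        )
        data[compound] = c
    return pd.DataFrame(data, index=pd.Index(t, name="day"))


def max_interval_rate(times, concentrations=None) -> tuple[float, tuple[float, float]]:
    """Maximum degradation rate (mg/L/day) over consecutive sampling
    intervals, with the interval over which it occurs."""
    if concentrations is None and isinstance(times, pd.Series):
        times, concentrations = times.index.to_numpy(), times.to_numpy()
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 2:
        raise ValueError("at least 2 time points required")
    rates = (c[:-1] - c[1:]) / np.diff(t)
    i = int(np.argmax(rates))
    best = float(rates[i])
    if best <= 0:
        warnings.warn(
            "series never decreases between samples; maximum rate is "
            f"{best:.3g} mg/L/day",
            stacklevel=2,
        )
    return best, (float(t[i]), float(t[i + 1]))


def sampling_day(
    times,
    concentrations=None,
    target_fraction_range: tuple[float, float] = (0.5, 0.8),
) -> float:
    """First sampled day whose degraded fraction lies in the target range.

    The degraded fraction is ``1 - C(t)/C(0)``. If sampling skips over the
    range entirely, the first day beyond it is returned with a warning.
    """
    if concentrations is None and isinstance(times, pd.Series):
        times, concentrations = times.index.to_numpy(), times.to_numpy()
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    lo, hi = target_fraction_range
    c0 = c[0]
    if c0 <= 0:
        raise ValueError("initial concentration must be positive")
    degraded = 1 - c / c0
    for day, d in zip(t, degraded):
        if lo < d <= hi:
            return float(day)
        if d > hi:
            warnings.warn(
                f"sampling skipped the {lo:.0%}-{hi:.0%} window; first day "
                f"beyond it is day {day:g} ({d:.0%} degraded)",
                stacklevel=2,
            )
            return float(day)
    raise NotReachedError(
        f"series never degrades past {lo:.0%} of the initial concentration"
    )
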