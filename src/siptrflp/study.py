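"""Pre-configured study scenarios and trial runners.

This module pins down the *conditions* under which the synthetic
experiment is run: the default four-taxon enrichment community, the VOC
degradation kinetics, and the observation schedule. The analysis scripts,
the test suite and the acceptance script all draw their simulated data
from here so that "the experiment" means one fixed thing.

The default community mirrors the dominant genera of an aerobic
VOC-degrading enrichment: a Rhodanobacter-like dominant, two
rhizobial-type taxa, and a Hyphomicrobium-like dichloromethane assimilator
that carries the 341 bp (HhaI) / 403 bp (MspI) terminal fragments and, in
labeled scenarios, an atom-fraction-13C of 0.61 — enough to move its DNA
band from ~1.725 to ~1.747 g/cm^3. GC contents are expressed as exact
base counts of the 980 bp synthetic amplicons; they place each unlabeled
band center on a fraction-grid density so that modal fractions are stable
between replicate unlabeled runs.
"""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache

from .pipeline import ShiftRow, compare_conditions
from .sequences import build_amplicon
from .shift import (
    ShiftParams,
    TRFDistribution,
    build_distribution,
    weighted_mean_density,
)
from .simulate import (
    CompoundKinetics,
    SimulatorParams,
    Taxon,
    simulate_experiment,
)
from .trflp import (
    HHAI,
    MSPI,
    AffiliationParams,
    TRFBin,
    affiliate,
    predict_trf_table,
)

#: Length of the synthetic 16S-like amplicons (bp).
AMPLICON_LENGTH = 980

#: id, relative abundance, exact G+C count, true T-RFs, description.
TAXON_TABLE = [
    ("RHO", 0.45, 450, {"HhaI": 95, "MspI": 120}, "Rhodanobacter-like dominant"),
    ("BRA", 0.25, 550, {"HhaI": 205, "MspI": 220}, "Bradyrhizobium-like"),
    ("RHI", 0.18, 600, {"HhaI": 561, "MspI": 490}, "Rhizobium-like"),
    ("HYP", 0.12, 650, {"HhaI": 341, "MspI": 403}, "Hyphomicrobium-like DCM assimilator"),
]

#: The taxon assimilating the labeled substrate in labeled scenarios.
LABELED_TAXON = "HYP"
#: Default atom-fraction excess 13C reached by the assimilator.
DEFAULT_ATOM_FRAC = 0.61

DEFAULT_ENZYMES = (HHAI, MSPI)

#: Degradation kinetics (mg/L, days): fit so that the degraded fractions on
#: the sampling days match the observed 50-80% sampling rule (DCM sampled
#: on day 4 at ~75%, benzene day 6 at ~75%, toluene day 7 at ~51%).
DEFAULT_KINETICS = {
    "DCM": CompoundKinetics(initial_mg_L=30.0, lag_days=2.54, rate_per_day=0.95),
    "benzene": CompoundKinetics(initial_mg_L=30.0, lag_days=3.96, rate_per_day=0.678),
    "toluene": CompoundKinetics(initial_mg_L=30.0, lag_days=5.80, rate_per_day=0.597),
}

#: Days on which VOC concentrations are measured.
MEASUREMENT_DAYS = [0, 1, 2, 3, 4, 6, 7, 8, 9, 11]


@lru_cache(maxsize=1)
def taxon_sequences() -> dict[str, str]:
    """Deterministic synthetic amplicons for the default community."""
    return {
        ident: build_amplicon(trfs, gc_count, AMPLICON_LENGTH, seed=101 + i)
        for i, (ident, _, gc_count, trfs, _) in enumerate(TAXON_TABLE)
    }


def default_community(
    labeled_id: str | None = LABELED_TAXON,
    atom_frac: float = DEFAULT_ATOM_FRAC,
) -> list[Taxon]:
    """The default community; pass ``labeled_id=None`` for fully unlabeled."""
    seqs = taxon_sequences()
    return [
        Taxon(
            id=ident,
            sequence=seqs[ident],
            relative_abundance=abundance,
            atom_frac_13C=atom_frac if ident == labeled_id else 0.0,
            true_trfs=dict(trfs),
        )
        for ident, abundance, _, trfs, _ in TAXON_TABLE
    ]


@lru_cache(maxsize=1)
def community_predictions():
    """In-silico digest table of the default community's amplicons."""
    annotations = {ident: desc for ident, _, _, _, desc in TAXON_TABLE}
    return predict_trf_table(
        taxon_sequences(), DEFAULT_ENZYMES, annotations=annotations
    )


def condition_pair(
    seed: int,
    atom_frac: float = DEFAULT_ATOM_FRAC,
    params: SimulatorParams | None = None,
    labels: tuple[str, str] = ("labeled", "unlabeled"),
):
    """Simulate a labeled run and an independent unlabeled reference run."""
    params = replace(params or SimulatorParams(), seed=seed)
    labeled = simulate_experiment(
        default_community(atom_frac=atom_frac), params, labels[0]
    )
    unlabeled = simulate_experiment(
        default_community(labeled_id=None), params, labels[1]
    )
    return labeled, unlabeled


def label_contrast_trial(
    seed: int,
    atom_frac: float = DEFAULT_ATOM_FRAC,
    params: SimulatorParams | None = None,
    shift_params: ShiftParams = ShiftParams(),
    min_fractions: int = 3,
) -> dict:
    """One full simulated experiment: shift detection plus affiliation.

    Returns per-enzyme shifted bins and whether the trial *succeeded*:
    exactly one shifted bin per enzyme, each affiliated (top-ranked) to the
    labeled taxon.
    """
    labeled, unlabeled = condition_pair(seed, atom_frac, params)
    rows = compare_conditions(
        labeled,
        unlabeled,
        DEFAULT_ENZYMES,
        shift_params,
        min_fractions=min_fractions,
    )
    shifted: dict[str, list[ShiftRow]] = {e.name: [] for e in DEFAULT_ENZYMES}
    for row in rows:
        if row.result.shifted:
            shifted[row.enzyme].append(row)
    success = all(len(v) == 1 for v in shifted.values())
    affiliations: dict[str, str | None] = {}
    if success:
        for enzyme_name, (row,) in shifted.items():
            matches = affiliate(
                {enzyme_name: row.bin.representative_length_bp},
                community_predictions(),
                AffiliationParams(),
            )
            top = matches[0].sequence_id if matches else None
            affiliations[enzyme_name] = top
            if top != LABELED_TAXON:
                success = False
    return {
        "rows": rows,
        "shifted": shifted,
        "affiliations": affiliations,
        "success": success,
    }


def false_positive_trial(
    seed: int,
    params: SimulatorParams | None = None,
    shift_params: ShiftParams = ShiftParams(),
    min_fractions: int = 3,
) -> bool:
    """Compare two independent unlabeled runs; True if any bin is called
    shifted (a false positive)."""
    run_a, run_b = condition_pair(
        seed, atom_frac=0.0, params=params, labels=("unlabeled-a", "unlabeled-b")
    )
    rows = compare_conditions(
        run_a, run_b, DEFAULT_ENZYMES, shift_params, min_fractions=min_fractions
    )
    return any(r.result.shifted for r in rows)


def single_taxon_distribution(
    seed: int,
    atom_frac: float,
    gc: float = 0.684,
    params: SimulatorParams | None = None,
    enzyme=HHAI,
) -> TRFDistribution:
    """Pipeline-recovered density distribution of a lone simulated taxon."""
    params = replace(params or SimulatorParams(), seed=seed)
    taxon = Taxon(
        id="probe",
        gc_fraction=gc,
        relative_abundance=1.0,
        atom_frac_13C=atom_frac,
        true_trfs={"HhaI": 341, "MspI": 403},
    )
    series = simulate_experiment([taxon], params, f"probe-{atom_frac:g}")
    lengths = sorted(
        {
            p.length_bp
            for frac in series.fractions
            for p in frac.peaks[enzyme.name]
        }
    )
    bin_ = TRFBin(enzyme.name, lengths[0], frozenset(lengths))
    return build_distribution(series, bin_, enzyme.name)


def single_taxon_recovery(
    seed: int,
    atom_frac: float,
    gc: float = 0.684,
    params: SimulatorParams | None = None,
) -> float:
    """Weighted-mean buoyant density recovered for a lone simulated taxon."""
    return weighted_mean_density(
        single_taxon_distribution(seed, atom_frac, gc, params)
    )
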