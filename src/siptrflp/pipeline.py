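"""End-to-end orchestration: load inputs, compare conditions, report.

The pipeline pools observed fragment lengths across the labeled and
reference conditions, bins them per enzyme, builds each bin's
buoyant-density distribution in both conditions, and calls shifts. Bins
detected in fewer than ``min_fractions`` fractions in either condition are
not compared: a fragment seen in one or two fractions carries no
distribution to speak of, and demanding reproducible detection suppresses
spurious bins created by capillary sizing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .community import CommunityProfile
from .errors import ConfigurationError, DegenerateInputError
from .gradient import FractionSeries
from .io import (
    RunConfig,
    config_digest,
    read_community_csv,
    read_fasta,
    read_fraction_csv,
    read_observed_csv,
    read_peak_csv,
    read_predictions_tsv,
)
from .shift import (
    ShiftParams,
    ShiftResult,
    TRFDistribution,
    build_distribution,
    detect_shift,
)
from .trflp import (
    AffiliationParams,
    DigestPrediction,
    TRFBin,
    affiliate,
    bin_lengths,
    peak_proportions,
    predict_trf_table,
)


@dataclass
class Dataset:
    """Validated in-memory inputs for one pipeline run."""

    series: dict[str, FractionSeries]
    predictions: list[DigestPrediction] = field(default_factory=list)
    profiles: list[CommunityProfile] = field(default_factory=list)
    observed: dict[str, dict[str, int]] = field(default_factory=dict)


def load_inputs(config: RunConfig) -> Dataset:
    """Load and cross-validate every file referenced by the configuration."""
    paths = config.paths
    if "fractions" not in paths:
        raise ConfigurationError("config.paths must name a 'fractions' CSV")
    series = read_fraction_csv(paths["fractions"], config.constants)
    if "peaks" in paths:
        read_peak_csv(paths["peaks"], series, config.enzymes)
    predictions: list[DigestPrediction] = []
    if "predictions" in paths:
        predictions = read_predictions_tsv(paths["predictions"])
    elif "sequences" in paths:
        predictions = predict_trf_table(
            read_fasta(paths["sequences"]).items(), config.enzymes.values()
        )
    unknown_pred_enzymes = {p.enzyme for p in predictions} - set(config.enzymes)
    if unknown_pred_enzymes:
        raise ConfigurationError(
            "predictions use unknown enzyme(s): "
            + ", ".join(sorted(unknown_pred_enzymes))
        )
    profiles = read_community_csv(paths["community"]) if "community" in paths else []
    observed = read_observed_csv(paths["observed"]) if "observed" in paths else {}
    return Dataset(series, predictions, profiles, observed)


@dataclass
class ShiftRow:
    """One compared T-RF bin with its distributions and verdict."""

    condition: str
    enzyme: str
    bin: TRFBin
    result: ShiftResult
    labeled_dist: TRFDistribution
    unlabeled_dist: TRFDistribution


def merge_bin_chains(bins: list[TRFBin], tolerance_bp: int) -> list[TRFBin]:
    """Merge runs of adjacent bins separated by <= ``tolerance_bp``.

    Greedy smallest-anchor binning splits a fragment whose observed-length
    cloud is wider than the tolerance (capillary error up to +/-4 bp spans
    8 bp) into a dominant bin plus a sibling a base pair or two away. Two
    bins whose nearest members differ by less than the sizing tolerance
    cannot be distinguished at the stated sizing error, so for comparison
    purposes they are one fragment: runs of such bins are merged here (the
    merged member set may span up to twice the tolerance). Bins from
    distinct taxa stay separate as long as their true fragments differ by
    more than the tolerance plus the error spread.
    """
    if not bins:
        return []
    ordered = sorted(bins, key=lambda b: b.representative_length_bp)
    merged: list[TRFBin] = [ordered[0]]
    for b in ordered[1:]:
        last = merged[-1]
        if b.representative_length_bp - last.max_length_bp <= tolerance_bp:
            merged[-1] = TRFBin(
                last.enzyme,
                last.representative_length_bp,
                last.member_lengths | b.member_lengths,
            )
        else:
            merged.append(b)
    return merged


def compare_conditions(
    labeled: FractionSeries,
    unlabeled: FractionSeries,
    enzymes,
    shift_params: ShiftParams = ShiftParams(),
    tolerance_bp: int = 5,
    floor_fraction: float = 0.005,
    min_fractions: int = 3,
) -> list[ShiftRow]:
    """Bin T-RFs across both conditions and test every bin for a shift."""
    rows: list[ShiftRow] = []
    for enzyme in enzymes:
        name = getattr(enzyme, "name", str(enzyme))
        observed = []
        for series in (labeled, unlabeled):
            for frac in series.fractions:
                if name not in frac.peaks:
                    raise ConfigurationError(
                        f"fraction {frac.index} of {series.condition_label!r} "
                        f"has no peak table for enzyme {name!r}"
                    )
                peaks = frac.peaks[name]
                if peaks and any(p.fluorescence > 0 for p in peaks):
                    props = peak_proportions(peaks, floor_fraction)
                    observed.extend(
                        (series.condition_label, L) for L in props
                    )
        bins = merge_bin_chains(
            bin_lengths(observed, tolerance_bp, enzyme=name), tolerance_bp
        )
        for bin_ in bins:
            try:
                dist_l = build_distribution(labeled, bin_, name, floor_fraction)
                dist_u = build_distribution(unlabeled, bin_, name, floor_fraction)
            except DegenerateInputError:
                continue  # bin absent from one condition: nothing to compare
            support = min(
                int((dist_l.copies > 0).sum()), int((dist_u.copies > 0).sum())
            )
            if support < min_fractions:
                continue
            rows.append(
                ShiftRow(
                    condition=labeled.condition_label,
                    enzyme=name,
                    bin=bin_,
                    result=detect_shift(dist_l, dist_u, shift_params),
                    labeled_dist=dist_l,
                    unlabeled_dist=dist_u,
                )
            )
    return rows


@dataclass
class ReportBundle:
    """Tables produced by one pipeline run, plus provenance."""

    shift_table: pd.DataFrame
    affiliation_table: pd.DataFrame
    distributions: pd.DataFrame
    seed: int
    digest: str


def _shift_frame(rows: list[ShiftRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "enzyme": r.enzyme,
                "trf_bp": r.bin.representative_length_bp,
                "peak_density_labeled": r.result.peak_density_labeled,
                "peak_density_unlabeled": r.result.peak_density_unlabeled,
                "weighted_mean_shift": r.result.weighted_mean_shift,
                "heavy_ratio": r.result.heavy_ratio,
                "shifted": r.result.shifted,
            }
            for r in rows
        ],
        columns=[
            "condition",
            "enzyme",
            "trf_bp",
            "peak_density_labeled",
            "peak_density_unlabeled",
            "weighted_mean_shift",
            "heavy_ratio",
            "shifted",
        ],
    )


def _distribution_frame(rows: list[ShiftRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        for dist, label in ((r.labeled_dist, r.condition), (r.unlabeled_dist, r.unlabeled_dist.condition_label)):
            for rho, c, nv in zip(dist.densities, dist.copies, dist.normalized):
                records.append(
                    {
                        "condition": label,
                        "enzyme": r.enzyme,
                        "trf_bp": r.bin.representative_length_bp,
                        "buoyant_density": rho,
                        "copies_per_ml": c,
                        "normalized": nv,
                    }
                )
    return pd.DataFrame(
        records,
        columns=[
            "condition",
            "enzyme",
            "trf_bp",
            "buoyant_density",
            "copies_per_ml",
            "normalized",
        ],
    ).drop_duplicates()


def _affiliation_frame(
    rows: list[ShiftRow],
    predictions: list[DigestPrediction],
    params: AffiliationParams,
) -> pd.DataFrame:
    records = []
    prediction_enzymes = {p.enzyme for p in predictions}
    for r in rows:
        if not r.result.shifted or r.enzyme not in prediction_enzymes:
            continue
        matches = affiliate(
            {r.enzyme: r.bin.representative_length_bp}, predictions, params
        )
        if not matches:
            records.append(
                {
                    "condition": r.condition,
                    "enzyme": r.enzyme,
                    "observed_trf_bp": r.bin.representative_length_bp,
                    "sequence_id": "",
                    "expected_trf_bp": "",
                    "difference_bp": "",
                    "annotation": "unaffiliated",
                    "ambiguous": False,
                }
            )
        for m in matches:
            diff = m.diffs_bp.get(r.enzyme)
            pred = next(
                p
                for p in predictions
                if p.sequence_id == m.sequence_id and p.enzyme == r.enzyme
            )
            records.append(
                {
                    "condition": r.condition,
                    "enzyme": r.enzyme,
                    "observed_trf_bp": r.bin.representative_length_bp,
                    "sequence_id": m.sequence_id,
                    "expected_trf_bp": pred.expected_length_bp,
                    "difference_bp": diff,
                    "annotation": m.annotation,
                    "ambiguous": m.ambiguous,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "condition",
            "enzyme",
            "observed_trf_bp",
            "sequence_id",
            "expected_trf_bp",
            "difference_bp",
            "annotation",
            "ambiguous",
        ],
    )


def run_pipeline(dataset: Dataset, config: RunConfig) -> ReportBundle:
    """Compare every labeled condition against the unlabeled reference."""
    reference = config.reference_condition
    if reference is None or reference not in dataset.series:
        raise ConfigurationError(
            f"reference (unlabeled) condition {reference!r} not found among "
            f"conditions {sorted(dataset.series)}"
        )
    labeled_conditions = [c for c in dataset.series if c != reference]
    if not labeled_conditions:
        raise ConfigurationError("no labeled condition to compare to reference")
    all_rows: list[ShiftRow] = []
    for condition in labeled_conditions:
        all_rows.extend(
            compare_conditions(
                dataset.series[condition],
                dataset.series[reference],
                config.enzymes.values(),
                config.shift,
                config.affiliation.tolerance_bp,
                config.floor_fraction,
                config.min_fractions,
            )
        )
    return ReportBundle(
        shift_table=_shift_frame(all_rows),
        affiliation_table=_affiliation_frame(
            all_rows, dataset.predictions, config.affiliation
        ),
        distributions=_distribution_frame(all_rows),
        seed=config.seed,
        digest=config_digest(config),
    )


def write_report(bundle: ReportBundle, out_dir) -> list[Path]:
    """Write the report tables with a provenance comment header."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# config_digest={bundle.digest} seed={bundle.seed}\n"
    written = []
    for name, frame, sep in (
        ("shift_report.tsv", bundle.shift_table, "\t"),
        ("affiliations.tsv", bundle.affiliation_table, "\t"),
        ("distributions.csv", bundle.distributions, ","),
    ):
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            frame.to_csv(fh, sep=sep, index=False)
        written.append(path)
    return written
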