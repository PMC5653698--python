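"""Tabular and sequence input/output plus run configuration.

All tabular files are comma-separated UTF-8 with a header row and ``.``
decimals (reports are tab-separated). Schemas:

* fraction CSV: ``condition,fraction_index,refractive_index
  [,buoyant_density],total_16S_copies`` — the density column is computed
  from the refractive index when absent; repeated rows for one fraction
  are qPCR replicates and are averaged on the copies scale.
* peak CSV: ``condition,fraction_index,enzyme,length_bp,fluorescence``.
* community CSV: ``otu_id,organism,accession,similarity`` plus one column
  per condition; censored cells are written verbatim as ``<0.1``.
* prediction TSV: ``sequence_id,enzyme,expected_length_bp,annotation``
  with ``NO_CUT`` for sequences lacking the site.
* observed-T-RF CSV: ``condition,enzyme,length_bp``.
* degradation CSV: ``day`` plus one column per compound (mg/L).
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .community import CommunityProfile, parse_abundance
from .errors import ConfigurationError, SchemaError
from .gradient import (
    ConversionConstants,
    DEFAULT_CONSTANTS,
    FractionSeries,
    GradientFraction,
    validate_fraction_series,
)
from .shift import ShiftParams
from .simulate import SimulatorParams
from .trflp import (
    AffiliationParams,
    BUILTIN_ENZYMES,
    DigestPrediction,
    EnzymeSpec,
    NO_CUT,
    TRFPeak,
)

logger = logging.getLogger(__name__)


def _read_csv(path, **kw) -> pd.DataFrame:
    try:
        if kw.get("dtype") is not str:
            kw.setdefault("float_precision", "round_trip")
        return pd.read_csv(path, comment="#", **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_fraction_csv(
    path, constants: ConversionConstants = DEFAULT_CONSTANTS
) -> dict[str, FractionSeries]:
    """Load gradient fractions, one validated series per condition."""
    df = _read_csv(path)
    _require_columns(
        df, ["condition", "fraction_index", "total_16S_copies"], path
    )
    if "refractive_index" not in df.columns and "buoyant_density" not in df.columns:
        raise SchemaError(
            f"{path}: need a refractive_index or buoyant_density column"
        )
    out: dict[str, FractionSeries] = {}
    for condition, group in df.groupby("condition", sort=False):
        fractions = []
        for idx, rows in group.groupby("fraction_index", sort=False):
            copies = rows["total_16S_copies"].astype(float)
            if len(copies) > 1:  # qPCR replicates
                cv = copies.std(ddof=1) / copies.mean() if copies.mean() else 0.0
                logger.info(
                    "%s fraction %s: %d qPCR replicates averaged (CV %.3f)",
                    condition,
                    idx,
                    len(copies),
                    cv,
                )
            eta = (
                float(rows["refractive_index"].astype(float).mean())
                if "refractive_index" in rows
                and rows["refractive_index"].notna().all()
                else None
            )
            rho = (
                float(rows["buoyant_density"].astype(float).mean())
                if "buoyant_density" in rows
                and rows["buoyant_density"].notna().all()
                else None
            )
            fractions.append(
                GradientFraction(
                    index=int(idx),
                    refractive_index=eta,
                    buoyant_density=rho,
                    total_16S_copies=float(copies.mean()),
                )
            )
        out[str(condition)] = validate_fraction_series(
            FractionSeries(str(condition), fractions), constants
        )
    return out


def write_fraction_csv(series_map: dict[str, FractionSeries], path) -> None:
    rows = [
        {
            "condition": label,
            "fraction_index": f.index,
            "refractive_index": f.refractive_index,
            "buoyant_density": f.buoyant_density,
            "total_16S_copies": f.total_16S_copies,
        }
        for label, series in series_map.items()
        for f in series.fractions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def read_peak_csv(
    path,
    series_map: dict[str, FractionSeries],
    enzymes: dict[str, EnzymeSpec] | None = None,
) -> dict[str, FractionSeries]:
    """Attach peak tables from a peak CSV to loaded fraction series.

    Every fraction receives a (possibly empty) peak list for every enzyme
    seen in the file. Unknown enzymes and unknown conditions/fractions are
    schema errors; fractional lengths are rounded half-up with a warning.
    """
    registry = enzymes or BUILTIN_ENZYMES
    df = _read_csv(path)
    _require_columns(
        df, ["condition", "fraction_index", "enzyme", "length_bp", "fluorescence"], path
    )
    unknown = sorted(set(df["enzyme"].astype(str)) - set(registry))
    if unknown:
        raise SchemaError(f"{path}: unknown enzyme(s): {', '.join(unknown)}")
    by_key = {
        (label, f.index): f
        for label, series in series_map.items()
        for f in series.fractions
    }
    seen_enzymes = sorted(set(df["enzyme"].astype(str)))
    for f in by_key.values():
        for name in seen_enzymes:
            f.peaks.setdefault(name, [])
    n_fractional = 0
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        key = (str(row.condition), int(row.fraction_index))
        frac = by_key.get(key)
        if frac is None:
            raise SchemaError(
                f"{path} line {row_number}: unknown condition/fraction "
                f"{key[0]!r}/{key[1]}"
            )
        length = float(row.length_bp)
        if length != int(length):
            n_fractional += 1
            length = _round_half_up(length)
        frac.peaks[str(row.enzyme)].append(
            TRFPeak(int(length), float(row.fluorescence))
        )
    if n_fractional:
        warnings.warn(
            f"{path}: {n_fractional} fractional fragment length(s) rounded "
            "half-up",
            stacklevel=2,
        )
    return series_map


def write_peak_csv(series_map: dict[str, FractionSeries], path) -> None:
    rows = [
        {
            "condition": label,
            "fraction_index": f.index,
            "enzyme": enzyme,
            "length_bp": p.length_bp,
            "fluorescence": p.fluorescence,
        }
        for label, series in series_map.items()
        for f in series.fractions
        for enzyme, peaks in sorted(f.peaks.items())
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


_COMMUNITY_META = ["otu_id", "organism", "accession", "similarity"]


def read_community_csv(path) -> list[CommunityProfile]:
    """Load an OTU table with one percent-abundance column per condition."""
    df = _read_csv(path, dtype=str)
    _require_columns(df, _COMMUNITY_META, path)
    conditions = [c for c in df.columns if c not in _COMMUNITY_META]
    if not conditions:
        raise SchemaError(f"{path}: no condition columns found")
    profiles = []
    for condition in conditions:
        abundances, censored, annotations = {}, set(), {}
        for _, row in df.iterrows():
            otu = str(row["otu_id"])
            value, is_censored = parse_abundance(row[condition])
            abundances[otu] = value
            if is_censored:
                censored.add(otu)
            annotations[otu] = (
                str(row["organism"]),
                str(row["accession"]),
                float(row["similarity"]),
            )
        profiles.append(
            CommunityProfile(condition, abundances, frozenset(censored), annotations)
        )
    return profiles


def write_community_csv(profiles, path) -> None:
    otus = list(profiles[0].abundances)
    rows = []
    for otu in otus:
        organism, accession, similarity = profiles[0].annotations.get(
            otu, ("", "", float("nan"))
        )
        row = {
            "otu_id": otu,
            "organism": organism,
            "accession": accession,
            "similarity": similarity,
        }
        for p in profiles:
            v = p.abundances[otu]
            row[p.condition_label] = "<0.1" if otu in p.censored else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_predictions_tsv(path) -> list[DigestPrediction]:
    df = _read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sequence_id", "enzyme", "expected_length_bp"], path)
    out = []
    for row in df.itertuples(index=False):
        raw = str(row.expected_length_bp)
        length = NO_CUT if raw == "NO_CUT" else int(raw)
        out.append(
            DigestPrediction(
                sequence_id=str(row.sequence_id),
                enzyme=str(row.enzyme),
                expected_length_bp=length,
                annotation=str(getattr(row, "annotation", "") or ""),
            )
        )
    return out


def write_predictions_tsv(predictions, path) -> None:
    rows = [
        {
            "sequence_id": p.sequence_id,
            "enzyme": p.enzyme,
            "expected_length_bp": "NO_CUT"
            if p.expected_length_bp is NO_CUT
            else p.expected_length_bp,
            "annotation": p.annotation,
        }
        for p in predictions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_observed_csv(path) -> dict[str, dict[str, int]]:
    """Observed T-RF lengths as condition -> enzyme -> length_bp."""
    df = _read_csv(path)
    _require_columns(df, ["condition", "enzyme", "length_bp"], path)
    out: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.condition), {})[str(row.enzyme)] = int(row.length_bp)
    return out


def read_fasta(path) -> dict[str, str]:
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise SchemaError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: dict[str, str], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    records = [
        SeqRecord(Seq(seq), id=ident, description=descriptions.get(ident, ""))
        for ident, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    constants: ConversionConstants = DEFAULT_CONSTANTS
    enzymes: dict[str, EnzymeSpec] = field(
        default_factory=lambda: dict(BUILTIN_ENZYMES)
    )
    affiliation: AffiliationParams = AffiliationParams()
    shift: ShiftParams = ShiftParams()
    simulator: SimulatorParams = SimulatorParams()
    floor_fraction: float = 0.005
    min_fractions: int = 3
    reference_condition: str | None = None
    paths: dict[str, str] = field(default_factory=dict)
    seed: int = 0


_CONFIG_SECTIONS = {
    "constants": ConversionConstants,
    "enzymes": None,
    "affiliation": AffiliationParams,
    "shift": ShiftParams,
    "simulator": SimulatorParams,
    "floor_fraction": None,
    "min_fractions": None,
    "reference_condition": None,
    "paths": None,
    "seed": None,
}
_PATH_KEYS = {"fractions", "peaks", "sequences", "predictions", "community", "observed"}


def _build(cls, mapping, context):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {context}: {', '.join(sorted(unknown))}"
        )
    return cls(**mapping)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys and checking
    that every referenced file exists."""
    base = Path(path).parent
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_CONFIG_SECTIONS)
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown top-level key(s): {', '.join(sorted(unknown))}"
        )
    kwargs: dict = {}
    for key, value in raw.items():
        cls = _CONFIG_SECTIONS[key]
        if cls is not None:
            kwargs[key] = _build(cls, value or {}, key)
        elif key == "enzymes":
            kwargs["enzymes"] = {
                e["name"]: EnzymeSpec(e["name"], e["site"], e["cut_offset"])
                for e in value
            }
        elif key == "paths":
            bad = set(value) - _PATH_KEYS
            if bad:
                raise ConfigurationError(
                    f"{path}: unknown path key(s): {', '.join(sorted(bad))}"
                )
            resolved = {}
            for name, p in value.items():
                full = Path(p) if Path(p).is_absolute() else base / p
                if not full.exists():
                    raise ConfigurationError(
                        f"{path}: referenced file does not exist: {full}"
                    )
                resolved[name] = str(full)
            kwargs["paths"] = resolved
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def config_digest(config: RunConfig) -> str:
    """Stable short hash of a configuration, for report provenance."""
    text = repr(config).encode()
    return hashlib.sha1(text).hexdigest()[:12]
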