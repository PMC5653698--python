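"""T-RFLP primitives: in-silico terminal digests, electropherogram peak
tables, cross-sample fragment binning, and phylogenetic affiliation.

Terminal restriction fragment length polymorphism (T-RFLP) fingerprints a
community by digesting fluorescently end-labeled 16S amplicons with a
4-cutter and sizing only the labeled terminal fragment (T-RF) on a
capillary. The T-RF length of a sequence for an enzyme is therefore the
position of the first cut, measured from base 1 of the labeled strand.

Capillary sizing carries a few base pairs of error, so observed lengths are
grouped into bins and compared against in-silico predictions with a length
tolerance (default 5 bp, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ConfigurationError, DegenerateInputError

logger = logging.getLogger(__name__)

#: Sentinel returned when a sequence contains no recognition site.
NO_CUT = None

_DNA = frozenset("ACGT")
_IUPAC = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme as seen by T-RFLP.

    ``cut_offset`` is the number of bases of the recognition site that stay
    attached to the labeled (5') fragment: HhaI cuts GCG^C (offset 3), MspI
    cuts C^CGG (offset 1).
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        if not site or set(site) - _DNA:
            raise ValueError(
                f"recognition site {self.recognition_site!r} must be a "
                "non-empty string over A/C/G/T"
            )
        object.__setattr__(self, "recognition_site", site)
        if not 0 < self.cut_offset <= len(site):
            raise ValueError(
                f"cut_offset {self.cut_offset} must lie in (0, {len(site)}]"
            )


HHAI = EnzymeSpec("HhaI", "GCGC", 3)
MSPI = EnzymeSpec("MspI", "CCGG", 1)
BUILTIN_ENZYMES: dict[str, EnzymeSpec] = {e.name: e for e in (HHAI, MSPI)}


@dataclass(frozen=True)
class TRFPeak:
    """One electropherogram peak: fragment length (bp) and fluorescence."""

    length_bp: int
    fluorescence: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"peak length {self.length_bp} must be positive")
        if self.fluorescence < 0:
            raise ValueError(f"fluorescence {self.fluorescence} must be >= 0")


@dataclass(frozen=True)
class DigestPrediction:
    """Expected terminal fragment of one sequence for one enzyme."""

    sequence_id: str
    enzyme: str
    expected_length_bp: int | None  # NO_CUT when the site is absent
    annotation: str = ""


@dataclass(frozen=True)
class TRFBin:
    """A group of observed T-RF lengths treated as one fragment.

    The representative length is the smallest member; members never span
    more than the binning tolerance.
    """

    enzyme: str
    representative_length_bp: int
    member_lengths: frozenset[int]

    @property
    def max_length_bp(self) -> int:
        return max(self.member_lengths)

    def contains(self, length_bp: int) -> bool:
        return self.representative_length_bp <= length_bp <= self.max_length_bp


@dataclass(frozen=True)
class AffiliationParams:
    """Matching rule for observed vs predicted fragment lengths."""

    tolerance_bp: int = 5
    require_both_enzymes: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.tolerance_bp <= 10:
            raise ValueError(f"tolerance_bp {self.tolerance_bp} outside [0, 10]")


def terminal_fragment_length(seq: str, enzyme: EnzymeSpec) -> int | None:
    """Length of the labeled terminal fragment of ``seq`` for ``enzyme``.

    ``seq`` is the 5'->3' sequence of the strand carrying the labeled primer
    at position 1. Returns the 1-based cut position (= fragment length
    including the primer) of the first exact occurrence of the recognition
    site, or :data:`NO_CUT` when the site is absent. IUPAC ambiguity codes
    are legal in the query but never match a site (a window containing one
    is skipped; the count of skipped windows is logged).
    """
    s = seq.upper()
    bad = set(s) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters {sorted(bad)} in sequence")
    site = enzyme.recognition_site
    if len(s) < len(site):
        raise ValueError(
            f"sequence of length {len(s)} shorter than recognition site {site}"
        )
    if set(s) - _DNA:  # only then can ambiguous windows exist
        k = len(site)
        n_ambiguous = sum(
            1 for i in range(len(s) - k + 1) if set(s[i : i + k]) - _DNA
        )
        if n_ambiguous:
            logger.debug(
                "%d window(s) with ambiguity codes skipped while scanning for %s",
                n_ambiguous,
                enzyme.name,
            )
    pos = s.find(site)
    if pos == -1:
        return NO_CUT
    return pos + enzyme.cut_offset


def predict_trf_table(
    sequences,
    enzymes,
    annotations: dict[str, str] | None = None,
) -> list[DigestPrediction]:
    """In-silico digest of every sequence with every enzyme.

    ``sequences`` may be a mapping id -> sequence, an iterable of
    ``(id, sequence)`` pairs, or Biopython ``SeqRecord`` objects. Sequences
    without a site are recorded with :data:`NO_CUT`, never dropped.
    """
    if isinstance(sequences, dict):
        items = list(sequences.items())
    else:
        items = []
        for entry in sequences:
            if hasattr(entry, "id") and hasattr(entry, "seq"):
                items.append((entry.id, str(entry.seq)))
            else:
                ident, seq = entry
                items.append((ident, str(seq)))
    if not items:
        raise ValueError("no sequences supplied")
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("no enzymes supplied")
    annotations = annotations or {}
    out = []
    for ident, seq in items:
        for enzyme in enzymes:
            out.append(
                DigestPrediction(
                    sequence_id=ident,
                    enzyme=enzyme.name,
                    expected_length_bp=terminal_fragment_length(seq, enzyme),
                    annotation=annotations.get(ident, ""),
                )
            )
    return out


def peak_proportions(
    peaks, floor_fraction: float = 0.005
) -> dict[int, float]:
    """Relative abundance of each T-RF in one sample from peak fluorescence.

    Peaks sharing a length are merged. Peaks below ``floor_fraction`` of the
    total fluorescence are discarded (a peak at exactly the floor is kept)
    before renormalizing, so the returned proportions sum to 1.
    """
    merged: dict[int, float] = {}
    for p in peaks:
        merged[p.length_bp] = merged.get(p.length_bp, 0.0) + p.fluorescence
    total = sum(merged.values())
    if total <= 0:
        raise DegenerateInputError("all peaks have zero fluorescence")
    kept = {L: f for L, f in merged.items() if f / total >= floor_fraction}
    if not kept:  # every peak below the floor: keep the largest one
        L = max(merged, key=merged.get)
        kept = {L: merged[L]}
    kept_total = sum(kept.values())
    return {L: f / kept_total for L, f in sorted(kept.items())}


def bin_lengths(observed, tolerance_bp: int, enzyme: str = "") -> list[TRFBin]:
    """Group observed fragment lengths into bins of width <= ``tolerance_bp``.

    Deterministic greedy rule anchored at the smallest member: unique
    lengths are sorted ascending and a new bin opens whenever
    ``length - bin_minimum > tolerance_bp``. The result is independent of
    input order. Lengths may be given bare or as ``(sample_id, length)``.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    lengths = set()
    for item in observed:
        value = item[1] if isinstance(item, tuple) else item
        if value != int(value):
            raise ValueError(f"fragment length {value!r} is not an integer")
        lengths.add(int(value))
    bins: list[TRFBin] = []
    current: list[int] = []
    for length in sorted(lengths):
        if current and length - current[0] > tolerance_bp:
            bins.append(TRFBin(enzyme, current[0], frozenset(current)))
            current = []
        current.append(length)
    if current:
        bins.append(TRFBin(enzyme, current[0], frozenset(current)))
    return bins


@dataclass(frozen=True)
class AffiliationMatch:
    """One candidate sequence matching an observed T-RF pattern."""

    sequence_id: str
    annotation: str
    diffs_bp: dict[str, int] = field(compare=False)
    total_diff_bp: int = 0
    ambiguous: bool = False


def affiliate(
    observed: dict[str, int],
    predictions,
    params: AffiliationParams = AffiliationParams(),
) -> list[AffiliationMatch]:
    """Candidate sequences whose predicted T-RFs match the observed lengths.

    ``observed`` maps enzyme name -> observed fragment length. A candidate
    matches when every observed enzyme's predicted fragment is within the
    tolerance (inclusive); with ``require_both_enzymes=False`` a single
    matching enzyme suffices. Matches are ranked by total absolute
    difference; exact ties are flagged ambiguous, not broken. An empty list
    means the fragment is unaffiliated.
    """
    if not observed:
        raise ValueError("observed must contain at least one enzyme")
    by_seq: dict[str, dict[str, DigestPrediction]] = {}
    annotations: dict[str, str] = {}
    covered: set[str] = set()
    for pred in predictions:
        covered.add(pred.enzyme)
        by_seq.setdefault(pred.sequence_id, {})[pred.enzyme] = pred
        if pred.annotation:
            annotations[pred.sequence_id] = pred.annotation
    missing = set(observed) - covered
    if missing:
        raise ConfigurationError(
            f"no predictions for enzyme(s): {', '.join(sorted(missing))}"
        )
    matches: list[AffiliationMatch] = []
    for seq_id in sorted(by_seq):
        preds = by_seq[seq_id]
        diffs: dict[str, int] = {}
        for enz, obs_len in observed.items():
            pred = preds.get(enz)
            if pred is None or pred.expected_length_bp is NO_CUT:
                continue
            d = abs(obs_len - pred.expected_length_bp)
            if d <= params.tolerance_bp:
                diffs[enz] = d
        if params.require_both_enzymes:
            ok = set(diffs) == set(observed)
        else:
            ok = bool(diffs)
        if ok:
            matches.append(
                AffiliationMatch(
                    sequence_id=seq_id,
                    annotation=annotations.get(seq_id, ""),
                    diffs_bp=diffs,
                    total_diff_bp=sum(diffs.values()),
                )
            )
    matches.sort(key=lambda m: (m.total_diff_bp, m.sequence_id))
    totals = [m.total_diff_bp for m in matches]
    return [
        AffiliationMatch(
            m.sequence_id,
            m.annotation,
            m.diffs_bp,
            m.total_diff_bp,
            ambiguous=totals.count(m.total_diff_bp) > 1,
        )
        for m in matches
    ]
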