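"""OTU relative-abundance tables and their summary arithmetic.

A community profile lists the percent abundance of each OTU in one
condition. Published tables report low-abundance cells as a censoring
string (``"<0.1"``); such cells are stored censored-at-0.1 with an
imputation value of half the limit (0.05) for arithmetic, never silently
as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SchemaError

#: Reporting limit below which table cells are censored.
CENSOR_LIMIT = 0.1
#: Value imputed for censored cells in sums (half the reporting limit).
CENSOR_IMPUTE = CENSOR_LIMIT / 2


def parse_abundance(text) -> tuple[float, bool]:
    """Parse a table cell into ``(percent, censored)``.

    Accepts plain numbers and the verbatim censoring form ``"<0.1"``.
    """
    s = str(text).strip()
    if s.startswith("<"):
        try:
            limit = float(s[1:])
        except ValueError:
            raise SchemaError(f"unparseable abundance cell {text!r}") from None
        return limit / 2, True
    try:
        return float(s), False
    except ValueError:
        raise SchemaError(f"unparseable abundance cell {text!r}") from None


@dataclass
class CommunityProfile:
    """Percent abundances of OTUs in one condition.

    ``abundances`` holds the arithmetic values (imputed for censored
    cells); ``censored`` names the OTUs whose cells were below the
    reporting limit; ``annotations`` maps OTU id to
    ``(closest organism, accession, similarity_percent)``.
    """

    condition_label: str
    abundances: dict[str, float]
    censored: frozenset[str] = frozenset()
    annotations: dict[str, tuple[str, str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {o: v for o, v in self.abundances.items() if v < 0}
        if bad:
            raise ValueError(f"negative abundances: {bad}")
        total = sum(self.abundances.values())
        if total > 100 + 1e-6:
            raise ValueError(
                f"abundances in {self.condition_label!r} sum to {total:.3f} > 100"
            )


def filter_min_abundance(profiles, floor_percent: float):
    """Keep OTUs exceeding ``floor_percent`` in at least one condition.

    Censored cells cannot certify exceedance of a floor at or above their
    imputed value, but an OTU censored in one condition is retained when it
    exceeds the floor elsewhere (the any-condition rule). Accepts a single
    profile or a list; returns the same shape. Idempotent at a fixed floor.
    """
    if floor_percent < 0:
        raise ValueError("floor_percent must be >= 0")
    single = isinstance(profiles, CommunityProfile)
    plist = [profiles] if single else list(profiles)
    keep = {
        otu
        for p in plist
        for otu, v in p.abundances.items()
        if v > floor_percent
    }
    out = [
        CommunityProfile(
            condition_label=p.condition_label,
            abundances={o: v for o, v in p.abundances.items() if o in keep},
            censored=frozenset(o for o in p.censored if o in keep),
            annotations={o: a for o, a in p.annotations.items() if o in keep},
        )
        for p in plist
    ]
    return out[0] if single else out


def top_k_sum(profile: CommunityProfile, k: int) -> float:
    """Summed percent abundance of the ``k`` most abundant OTUs."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(profile.abundances.values(), reverse=True)
    return float(sum(ranked[:k]))


def dominant_abundance_range(profiles, otu_id: str) -> tuple[float, float]:
    """(min, max) percent abundance of one OTU across conditions."""
    values = []
    for p in profiles:
        if otu_id not in p.abundances:
            raise KeyError(
                f"OTU {otu_id!r} missing from condition {p.condition_label!r}"
            )
        values.append(p.abundances[otu_id])
    return (min(values), max(values))
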