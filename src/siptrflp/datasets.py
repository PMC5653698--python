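"""Bundled reference tables from the VOC-degrading enrichment study.

Three small published tables ship with the package:

* OTU relative-abundance profiles of the enrichment under the four
  incubation conditions (13C-DCM, 13C-benzene, 13C-toluene, unlabeled);
* in-silico digest predictions for the two clone sequences recovered from
  the heavy gradient fractions;
* the T-RF lengths observed by capillary electrophoresis in the shifted
  fractions.
"""

from __future__ import annotations

from importlib.resources import files

from .community import CommunityProfile
from .io import read_community_csv, read_observed_csv, read_predictions_tsv
from .trflp import DigestPrediction

_DATA = files("siptrflp") / "data"

#: Condition labels of the enrichment incubations (labeled substrate noted).
CONDITIONS = ("AE/AE-13D", "AE/AE-13B", "AE/AE-13T", "AE/AE-13N")
#: The unlabeled reference condition.
REFERENCE_CONDITION = "AE/AE-13N"


def reference_profiles() -> list[CommunityProfile]:
    """OTU percent-abundance profiles, one per incubation condition."""
    return read_community_csv(_DATA / "community_profiles.csv")


def clone_predictions() -> list[DigestPrediction]:
    """Expected T-RFs of the clones sequenced from heavy fractions."""
    return read_predictions_tsv(_DATA / "clone_trf_predictions.tsv")


def observed_trfs() -> dict[str, dict[str, int]]:
    """Observed shifted T-RF lengths per condition and enzyme."""
    return read_observed_csv(_DATA / "observed_trfs.csv")
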