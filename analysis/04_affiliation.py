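"""Affiliate the published observed T-RFs with the clone predictions.

The capillary-observed fragment lengths from the shifted heavy fractions
(337/398 bp under the 13C-DCM condition; 352/154 bp under the 13C-benzene
condition) are matched against the in-silico digests of the clone
sequences recovered from those fractions, at the 5 bp tolerance. Also
reports the smallest tolerance at which every pair still matches. Writes
results/affiliation_report.tsv.
"""

from pathlib import Path

from siptrflp import datasets
from siptrflp.trflp import AffiliationParams, affiliate

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    observed = datasets.observed_trfs()
    predictions = datasets.clone_predictions()

    lines = [
        "condition\tenzyme\tobserved_bp\tclone_id\texpected_bp\t"
        "difference_bp\tannotation"
    ]
    for condition, lengths in observed.items():
        matches = affiliate(lengths, predictions, AffiliationParams(tolerance_bp=5))
        for m in matches:
            for enzyme, diff in sorted(m.diffs_bp.items()):
                expected = next(
                    p.expected_length_bp
                    for p in predictions
                    if p.sequence_id == m.sequence_id and p.enzyme == enzyme
                )
                lines.append(
                    f"{condition}\t{enzyme}\t{lengths[enzyme]}\t{m.sequence_id}"
                    f"\t{expected}\t{diff}\t{m.annotation}"
                )
                print(
                    f"{condition}: {enzyme} {lengths[enzyme]} bp -> "
                    f"{m.sequence_id} (expected {expected} bp, off by {diff})"
                )
    (OUT / "affiliation_report.tsv").write_text("\n".join(lines) + "\n")

    def all_match(tol: int) -> bool:
        return all(
            affiliate(lengths, predictions, AffiliationParams(tolerance_bp=tol))
            for lengths in observed.values()
        )

    smallest = min(t for t in range(0, 11) if all_match(t))
    print(
        f"\nsmallest tolerance affiliating all observed/expected pairs: "
        f"{smallest} bp"
    )
    print(f"report written to {OUT / 'affiliation_report.tsv'}")


if __name__ == "__main__":
    main()
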