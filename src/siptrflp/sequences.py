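"""Synthetic 16S-like amplicon construction with planted restriction sites.

The simulator needs amplicon sequences whose terminal restriction
fragments and GC content are exactly known. These are synthetic stand-ins
for real 16S rRNA gene amplicons: a background sequence free of the CG
dinucleotide (both HhaI's GCGC and MspI's CCGG contain CG, so a CG-free
background can never harbour an accidental site) into which one
recognition site per enzyme is spliced at the position that yields the
requested T-RF length. The exact GC count is preserved, and the result is
verified against the digest function itself.
"""

from __future__ import annotations

import numpy as np

from .trflp import BUILTIN_ENZYMES, EnzymeSpec, terminal_fragment_length

_BASES = "ACGT"


def _cg_free_background(n_gc: int, n_at: int, rng: np.random.Generator) -> str | None:
    """Random sequence with exact base counts and no CG dinucleotide.

    Greedy sequential draw weighted by remaining counts, forbidding G after
    C; returns None when the draw jams (caller retries).
    """
    remaining = {
        "G": n_gc // 2,
        "C": n_gc - n_gc // 2,
        "A": n_at // 2,
        "T": n_at - n_at // 2,
    }
    seq = []
    prev = ""
    for _ in range(n_gc + n_at):
        choices = [
            b
            for b in _BASES
            if remaining[b] > 0 and not (prev == "C" and b == "G")
        ]
        if not choices:
            return None
        weights = np.array([remaining[b] for b in choices], dtype=float)
        b = choices[rng.choice(len(choices), p=weights / weights.sum())]
        remaining[b] -= 1
        seq.append(b)
        prev = b
    return "".join(seq)


def build_amplicon(
    trfs: dict[str, int],
    gc_count: int,
    length: int = 980,
    seed: int = 0,
    enzymes: dict[str, EnzymeSpec] | None = None,
) -> str:
    """Deterministic synthetic amplicon with prescribed T-RFs and GC count.

    Parameters
    ----------
    trfs
        Enzyme name -> desired terminal fragment length (bp). The first
        occurrence of each enzyme's site will sit exactly where it produces
        this fragment.
    gc_count
        Exact number of G+C bases in the final sequence.
    length
        Total amplicon length (bp).
    seed
        Seed for the background draw; the same arguments always return the
        same sequence.
    """
    registry = enzymes or BUILTIN_ENZYMES
    specs = []
    for name in sorted(trfs):
        enz = registry[name]
        if "CG" not in enz.recognition_site:
            raise NotImplementedError(
                f"site {enz.recognition_site} lacks CG; the CG-free "
                "background guarantee does not apply"
            )
        start = trfs[name] - enz.cut_offset
        specs.append((start, enz))
    specs.sort()
    site_len = sum(len(e.recognition_site) for _, e in specs)
    for (s0, e0), (s1, e1) in zip(specs, specs[1:]):
        if s0 + len(e0.recognition_site) + 2 > s1:
            raise ValueError(
                f"sites for {e0.name} and {e1.name} overlap or nearly touch"
            )
    if specs and (specs[0][0] < 0 or specs[-1][0] + 4 > length):
        raise ValueError("a requested T-RF places its site outside the amplicon")
    site_gc = sum(
        sum(b in "GC" for b in e.recognition_site) for _, e in specs
    )
    bg_gc = gc_count - site_gc
    bg_at = (length - site_len) - bg_gc
    if bg_gc < 0 or bg_at < 0:
        raise ValueError("gc_count incompatible with length and planted sites")

    for attempt in range(200):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, attempt])
        bg = _cg_free_background(bg_gc, bg_at, rng)
        if bg is None:
            continue
        seq_parts = []
        bg_pos = 0
        final_pos = 0
        for start, enz in specs:
            chunk = bg[bg_pos : bg_pos + (start - final_pos)]
            seq_parts.append(chunk)
            bg_pos += len(chunk)
            final_pos = start + len(enz.recognition_site)
            seq_parts.append(enz.recognition_site)
        seq_parts.append(bg[bg_pos:])
        seq = "".join(seq_parts)
        if len(seq) != length:
            raise AssertionError("internal splice length mismatch")
        if all(
            terminal_fragment_length(seq, registry[name]) == trfs[name]
            for name in trfs
        ) and sum(b in "GC" for b in seq) == gc_count:
            return seq
    raise RuntimeError(
        f"could not build an amplicon for trfs={trfs}, gc_count={gc_count}"
    )
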