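# Methods

## Model and assumptions

**Density conversion.** Buoyant density is linear in refractive index at
fixed temperature, ρ = a·η − b with a = 10.9276 and b = 13.593 valid at
20 °C. The constants live in a config object (`ConversionConstants`)
rather than being hard-coded because they are temperature-specific.
Plausibility windows (η ∈ [1.20, 1.50], ρ ∈ [1.60, 1.85] g/cm³) reject
readings that cannot be CsCl gradient fractions.

**Fraction ordering.** Fractions are collected from the tube bottom, so
index 1 is the heaviest. Validation computes missing densities from η,
re-sorts heaviest-first, and treats a density inversion relative to the
collection order as a warning, not an error — refractometer readings
carry noise and real gradients are never perfectly monotone.

**T-RF length.** The terminal fragment runs from base 1 of the labeled
strand through the first cut: the length equals the 0-based position of
the first recognition-site occurrence plus the enzyme's cut offset
(*Hha*I GCG^C → offset 3; *Msp*I C^CGG → offset 1). IUPAC ambiguity codes
are legal in queries but never match a site: a phantom cut inferred from
an uncertain base would mislocate the terminal fragment, so ambiguous
windows are skipped (and counted in the debug log).

**Peak arithmetic.** Within one electropherogram, peaks sharing a length
merge; peaks below 0.5 % of total fluorescence are treated as noise and
removed before renormalization (a peak at exactly the floor is kept; the
floor is configurable). Per-T-RF copy numbers are the fluorescence
proportions scaled by the fraction's total 16S copy number from qPCR;
when replicate qPCR rows are supplied they are averaged on the copies
scale and the replicate CV is logged.

**Normalization scope.** Each T-RF's copy-number series is normalized by
its own maximum *within one condition*, so every curve peaks at exactly 1.
Cross-condition normalization would make the shift statistics depend on
absolute DNA recovery, which differs between gradients for reasons
unrelated to labeling.

**Shift rule.** For a T-RF bin with labeled distribution ℓ and unlabeled
reference u:

* *peak shift* = modal-fraction density of ℓ minus that of u (modal ties
  resolve to the heavier fraction, since labeling only ever moves mass
  heavier);
* *heavy ratio* = Σ normalized ℓ at ρ ≥ 1.732 ÷ Σ normalized u at
  ρ ≥ 1.732 (∞ if only the labeled sum is positive; 1 if both are zero);
* the bin is **shifted** iff peak shift ≥ 0.004 g/cm³ (≈ one fraction
  spacing) *and* heavy ratio > 1.

Two gradients never land on bit-identical densities, so grids are checked
for comparability by nearest-density pairing (tolerance 0.002 g/cm³); the
comparison is refused only when *no* labeled fraction has an unlabeled
neighbour that close. The heavy sums and modal densities themselves are
computed on each full distribution and need no pointwise pairing.

**Binning and affiliation.** Observed lengths are binned by a
deterministic greedy rule anchored at the smallest member: sorted unique
lengths open a new bin whenever the distance to the current bin's
smallest member exceeds the tolerance (default 5 bp). The rule is
order-independent but splits a fragment whose observed-length cloud is
wider than the tolerance; see *Chain merging* below. Affiliation matches
an observed length pattern against in-silico digests with an **inclusive**
tolerance (|observed − expected| ≤ 5): the observed 398 bp fragment and
its 403 bp prediction differ by exactly 5 and belong together, which an
exclusive rule would refuse. Candidates are ranked by total absolute
difference; exact ties are reported as ambiguous, never broken silently.
No correction for systematic capillary size-calling bias is applied — the
tolerance absorbs it.

**qPCR calibration.** Cq is regressed on log₁₀(copies) by ordinary least
squares (≥ 3 distinct dilution levels); efficiency = 10^(−1/slope) − 1;
r² < 0.98 warns. The inverse map 10^((Cq − intercept)/slope) converts Cq
to absolute copies.

**Community tables.** Censored cells ("<0.1") are stored censored with an
imputation value of half the reporting limit (0.05) for sums — treating
them as zero would understate row totals, and using the limit itself
would overstate them. The abundance filter keeps an OTU that exceeds the
floor in *any* condition, which is why censored cells still appear in
filtered tables.

## The simulator

`siptrflp.simulate` generates data with the statistical structure the
analysis assumes, layer by layer:

| parameter | default | meaning |
|---|---|---|
| `rho_base` | 1.660 g/cm³ | density of GC-free unlabeled DNA |
| `rho_gc_slope` | 0.098 g/cm³ | density increase per unit GC fraction |
| `rho_label_max` | 0.036 g/cm³ | density increase at full ¹³C labeling |
| `band_sigma` | 0.005 g/cm³ | Gaussian banding width |
| `n_fractions` | 18 | fractions per gradient |
| `density_min/max` | 1.690 / 1.775 g/cm³ | equally spaced fraction grid |
| `eta_noise_sd` | 1e-4 | refractometer noise (≈ 0.0011 g/cm³) |
| `len_error_sd` | 1.5 bp | capillary sizing error, clipped at ±4 bp |
| `qpcr_lognormal_sd` | 0.1 | per-fraction 16S total noise |
| `cq_noise_sd` | 0.1 | Cq noise in dilution series |
| `total_copies` | 1e8 /mL | community 16S load |

The band-center model ρ = 1.660 + 0.098·GC + 0.036·atom-fraction-¹³C uses
standard SIP-literature constants; they are simulator assumptions, not
fitted values, and are configurable. Each taxon's band is a Gaussian
evaluated at the fraction centers and renormalized, so DNA mass is
conserved exactly. The length error is hard-clipped at ±4 bp so simulated
data never violate the 5 bp affiliation tolerance by construction; an
unclipped mode (`len_error_clip_bp`) is available for robustness testing.
All randomness descends from a single seed; each operation and condition
label uses its own substream, making every run reproducible bit-for-bit.

**Default study conditions** (`siptrflp.study`): four taxa with
abundances 0.45/0.25/0.18/0.12 mirroring the enrichment's dominant genera
(a Rhodanobacter-like dominant, two rhizobial-type taxa, and a
Hyphomicrobium-like DCM assimilator carrying the 341/403 bp fragments).
GC contents are exact base counts of 980 bp synthetic amplicons (450,
550, 600, 650 of 980), chosen so each unlabeled band center falls on a
fraction-grid density — band centers halfway between fractions would make
the modal fraction flip between replicate runs, an instability of the
*grid*, not of the method. The labeled taxon assimilates at atom-fraction
0.61, moving its band by ≈ 0.022 g/cm³ (about 4½ fraction spacings).
Synthetic amplicons are built on a CG-dinucleotide-free background (both
recognition sites contain CG, so only the planted sites can cut) and are
verified against the digest function itself; they are synthetic
stand-ins, not real 16S sequences.

**Degradation kinetics** are lag-then-first-order,
C(t) = C₀·e^(−k·(t−lag)) after the lag, with all three VOCs starting at
30 mg/L. Defaults (lag 2.54/3.96/5.80 d, k 0.95/0.678/0.597 d⁻¹ for DCM,
benzene, toluene) were fit so the degraded fractions on the sampling days
match the 50–80 % sampling rule: DCM sampled on day 4 at 75 %, benzene on
day 6 at 75 %, toluene on day 7 at 51 %, on a measurement schedule of
days 0–4, 6–9, 11.

**What the simulator does not emulate:** rRNA operon copy-number
variation, PCR primer/amplification bias, isotope fractionation
chemistry, non-linear gradient formation (real CsCl gradients are not
equally spaced in density; the grid is caller-overridable), diffusive
smearing of the interface, and cross-contamination between fractions.
Passing tests therefore show the *analysis* is correct under its stated
noise model, not that the noise model captures every failure mode of real
gradients.

## Pipeline-level choices

**Minimum support.** A bin is compared between conditions only if its
T-RF is detected (positive copies after the fluorescence floor) in at
least 3 fractions in *both* conditions. One or two detections carry no
distribution worth comparing, and the rule suppresses spurious sparse
bins created by sizing error.

**Chain merging.** The greedy binning rule splits a single fragment's
±4 bp observed-length cloud (span up to 8 bp) into a dominant bin plus a
sibling 1–2 bp away. Two bins whose nearest members differ by no more
than the sizing tolerance cannot be distinguished at the stated sizing
error — by the same 5 bp rule that groups observed and expected lengths —
so, before shift evaluation, runs of such adjacent bins are merged into
one fragment (`merge_bin_chains`). The merged member set may span up to
twice the tolerance; this is deliberate and applies only to the
cross-condition comparison, not to `bin_lengths` itself. Without the
merge, roughly one simulated experiment in ten reports the labeled taxon
twice under one enzyme.

**Degenerate inputs.** All-zero peak tables, all-zero copy series and
empty distributions raise explicit degenerate-input errors rather than
returning NaNs; bins absent from one condition are skipped in the
comparison (there is nothing to compare), never treated as infinite
shifts.

**Determinism.** Reports carry a config digest and the seed in a comment
header; rerunning with the same config and seed reproduces every output
byte-for-byte.

## Problem sizes

The test suite and `scripts/acceptance.py` use 18-fraction gradients with
the four-taxon community throughout; stochastic checks use 20 seeds for
band-density recovery, 50 for end-to-end detection, and 100 for the
false-positive rate — sizes at which the binomial uncertainty on the
reported rates is a few percent, adequate for the pass criteria they
feed.

## Known limitations

* The shift call is a threshold rule, not a significance test; no
  uncertainty is attached to a single experiment's verdict.
* Refractometer noise (≈ 0.0011 g/cm³) occasionally displaces two runs'
  measured densities of the same modal fraction by more than the 0.004
  g/cm³ peak-shift threshold; with the default community this produces a
  false positive in roughly 1–2 % of unlabeled-vs-unlabeled comparisons.
* Co-migrating fragments from different taxa (same length under both
  enzymes) are indistinguishable by construction of T-RFLP; the simulator
  can create such collisions, and the affiliation report flags exact ties
  as ambiguous rather than resolving them.
* The greedy binning anchor depends on the smallest observed length, so
  bin representatives sit up to 4 bp below the true fragment length; the
  inclusive 5 bp affiliation tolerance absorbs this.
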