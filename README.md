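# siptrflp

DNA stable-isotope probing (DNA-SIP) analysis with T-RFLP community
fingerprints, for microbiologists who identify which community members
assimilate a ¹³C-labeled substrate — here, volatile organic compounds
(dichloromethane, benzene, toluene) degraded by an aerobic enrichment
culture.

## The method

In DNA-SIP, organisms that assimilate a ¹³C-labeled substrate synthesize
heavier DNA. After isopycnic CsCl ultracentrifugation the gradient is
divided into fractions (18 by default, collected heaviest-first); each
fraction's refractive index η is converted to buoyant density by

    ρ = a·η − b        (a = 10.9276, b = 13.593 at 20 °C)

Each fraction is fingerprinted by T-RFLP: fluorescently end-labeled 16S
rRNA amplicons are digested with the 4-cutters *Hha*I (GCG^C) and *Msp*I
(C^CGG) and only the labeled terminal fragment (T-RF) is sized. For a
T-RF of length *L* under enzyme *e*, the package computes per fraction

    copies(L) = proportion of total fluorescence in L × total 16S copies (qPCR)

and normalizes each T-RF's copy-number series by its maximum across
fractions, giving the normalized buoyant-density distribution of that
fragment. A fragment is called **shifted** — i.e., its carriers assimilated
the labeled substrate — when, relative to the unlabeled reference
incubation, its modal density moved heavier by at least 0.004 g/cm³ *and*
it carries more normalized mass in the heavy fractions (ρ ≥ 1.732 g/cm³).

Shifted T-RFs are affiliated phylogenetically by comparing their lengths
against in-silico digests of clone or reference 16S sequences, grouping
lengths within a 5 bp sizing tolerance (the documented maximum T-RFLP
sizing error).

Because no raw gradient data are public, the package includes a fully
seeded simulator (`siptrflp.simulate`) producing gradient, T-RFLP, qPCR
and VOC-degradation data with the statistical structure the analysis
assumes; `siptrflp.study` pins the default study conditions.

## Worked example

The numbered scripts under `analysis/` run the full study; each writes
its tables under `results/`.

```
$ python analysis/01_simulate_experiment.py
seed 1: simulated 18 fractions per condition
labeled condition density range: 1.6908-1.7739 g/cm^3

$ python analysis/03_shift_analysis.py
2/8 compared T-RF bins shifted:
  HhaI 339 bp: modal density 1.7243 -> 1.7451 g/cm^3 (heavy ratio 259.0)
  MspI 402 bp: modal density 1.7243 -> 1.7451 g/cm^3 (heavy ratio 19.9)
  HhaI 339 bp affiliated to HYP (Hyphomicrobium-like DCM assimilator), expected 341 bp, difference 2 bp
  MspI 402 bp affiliated to HYP (Hyphomicrobium-like DCM assimilator), expected 403 bp, difference 1 bp
```

Of the eight T-RF bins compared between the labeled and unlabeled
gradients, exactly one per enzyme shifted heavier — the fragments of the
one simulated taxon that assimilated the labeled substrate (its band
moved ~0.021 g/cm³, matching 0.036 g/cm³ × atom-fraction 0.61) — and both
were affiliated to that taxon within the 5 bp tolerance.

The published-table arithmetic runs the same way:

```
$ python analysis/02_community_summary.py
condition  n_otus_listed  n_otus_above_0.1pct  top4_sum_percent  dominant_otu_percent
AE/AE-13D             19                   14              79.8                  43.0
AE/AE-13B             19                   13              86.2                  51.4
...
OTU1 (Rhodanobacter-like) spans 43.0-55.2% across conditions

$ python analysis/04_affiliation.py
AE/AE-13D: HhaI 337 bp -> AE/AE-13D-05-001 (expected 341 bp, off by 4)
AE/AE-13D: MspI 398 bp -> AE/AE-13D-05-001 (expected 403 bp, off by 5)
...
smallest tolerance affiliating all observed/expected pairs: 5 bp

$ python analysis/05_degradation_kinetics.py
DCM: max rate 11.9 mg/L/day (days 3-4); sampled day 4 at 75% degraded
benzene: max rate 10.8 mg/L/day (days 4-6); sampled day 6 at 75% degraded
toluene: max rate 12.0 mg/L/day (days 6-7); sampled day 7 at 51% degraded
```

A `siptrflp` command-line tool exposes the same stages
(`simulate`, `digest`, `profile`, `shift`, `affiliate`, `report`); run
`siptrflp --help`.

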