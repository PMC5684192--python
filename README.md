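# temra-repertoire

Analysis of T-cell receptor (TCR-beta) repertoire structure in human CD4
T-cell subsets, centred on the observation that GPR56+ CD4 TEMRA cells
(effector memory T cells re-expressing CD45RA) are clonally expanded.
The package is aimed at immunologists working with clonotype tables from
AIRR-seq experiments (AIRR-Rearrangement or immunoSEQ-style TSV exports)
together with flow-cytometry subset frequencies.

It implements four connected computations:

1. **Clonotype aggregation** — a clonotype is a group of T cells with the
   same CDR3 amino-acid sequence; rows sharing (donor, subset, CDR3) are
   merged by summing template/cell counts (V/J calls are annotation only).
2. **Normalized clonality** — for clonotype frequencies *f₁ … fₙ*,

   normalized Shannon entropy  H = −Σᵢ fᵢ·log₂(fᵢ) / log₂(n)

   normalized clonality  C = 1 − H

   so C = 0 for a perfectly polyclonal (uniform) repertoire and C = 1 for
   a monoclonal one. Samples of different sequencing depths are made
   comparable by resampling each to 1000 cells with replacement
   (seeded bootstrap; mean, SD and percentile 95% CI over replicates).
3. **Clonotype sharing** — the source-relative fraction of a subset's
   distinct clonotypes found in a reference subset, overall and
   restricted to *highly represented* clonotypes (≥ 10 cells), plus the
   fraction of source cells those carry.
4. **Subset-composition model** — the constant-plus-variable model of
   TEMRA composition: a constant absolute frequency *c* of
   GPR56−Perforin− TEMRA cells among CD4 T cells plus a variable
   GPR56+/Perforin+ component, predicting the within-TEMRA
   double-negative proportion p(f) = min(1, c / f); *c* is fitted by
   bounded 1-D least squares.

A seeded synthetic-cohort generator (Zipf clone sizes per subset,
controlled cross-subset clonotype sharing, lognormal composition noise)
replaces raw sequencing data, so the whole pipeline is testable offline.

## Worked example

```sh
python analysis/01_simulate_cohort.py   # 11 donors x 5 subsets -> results/cohort/
python analysis/02_clonality.py
python analysis/03_overlap.py
python analysis/04_fit_composition.py
```

On the default seed the clonality step prints

```
median bootstrap-normalized clonality (1000 cells):
subset
TEMRA_GPR56pos    0.372392
TEM               0.069161
TEMRA_GPR56neg    0.031423
TCM               0.021060
TN                0.020936
```

i.e. GPR56+ TEMRA repertoires are dominated by a few large clones while
naive and central-memory repertoires are near-uniform. The overlap step
prints

```
mean GPR56+ TEMRA sharing across donors:
                  fraction_shared  fraction_shared_high  cell_mass_fraction_high
TCM                      0.070978              0.092309                 0.793182
TEM                      0.551378              0.506100                 0.793182
```

about 55% of GPR56+ TEMRA clonotypes also occur in the same donor's TEM
repertoire versus ~7% in TCM (TEM as the likelier precursor), and the
≥ 10-cell clonotypes hold ~79% of the GPR56+ TEMRA cell mass. The
composition step fits the constant double-negative fraction

```
fitted constant double-negative fraction c = 0.9948% over 11 donors
(generator truth 0.8%; RSS 0.01815)
```

recovering the generator's 0.8% to within the 20% measurement noise it
injected. The same pipeline is exposed as a CLI
(`temra-repertoire simulate|diversity|overlap|fit-composition|report`)
for use on real clonotype tables.

## Acceptance script

`scripts/acceptance.py` reruns the full pipeline from scratch on the
default synthetic cohort — simulation, bootstrap diversity, overlap and
the composition fit — printing the per-subset/overlap/fit summaries and
writing the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
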