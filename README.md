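# retidiv

Barcode-anchored species assignment and biodiversity statistics for
statewide surveys of *Reticulitermes* subterranean termites (and any survey
with the same shape: labeled reference haplotypes, unlabeled query reads,
and georeferenced multi-species detection records).

*Reticulitermes* species are morphologically cryptic; reliable distribution
data depend on assigning each sampled colony to a species by its mtDNA
barcode (~685 bp COII amplicons) against a reference panel validated by
integrative taxonomy. `retidiv` implements that assignment and the survey
statistics built on top of it:

* **Classification** — nearest-reference distance assignment under p,
  Jukes–Cantor or Kimura 2-parameter models with pairwise deletion;
  barcode-gap verification (`panel_separability`); neighbour-joining trees
  with species-monophyly checks; column-resampling bootstrap support; and
  label audits that flag records (e.g. GenBank accessions) whose assignment
  contradicts their claimed species.
* **Tabulation** — per-species counts and percentages of counties, sites and
  samples, statewide and split at a fall line into north/south strata, plus
  the per-site species co-occurrence histogram.
* **Diversity** — Hill numbers in effective species:
  N0 (richness), N1 = exp(−Σ p_i ln p_i) (exponential Shannon),
  N2 = 1/(Σ n_i(n_i−1)/(N(N−1))) (finite-sample inverse Simpson), and
  N∞ = 1/max p_i, with p_i the species' share of site-level detections.
* **Spatial statistics** — Clark–Evans aggregation index
  R = observed mean nearest-neighbour distance / (1/(2√λ)) with guard-buffer
  edge correction and a two-sided CSR z-test, and Gaussian kernel density
  surfaces of per-species site patterns.
* **Synthetic data** — generators for reference panels with an enforced
  barcode gap and for survey datasets with stratum-restricted and
  Thomas-clustered species, so the full chain runs and is tested without any
  unreleased field data.

## Worked example

Hill-number profiles from a survey's per-species site-detection counts
(statewide, and north/south of the fall line):

```python
from retidiv.diversity import DetectionCounts, HillProfile

site_counts = {
    "statewide": (1131, 559, 323, 318, 21),
    "north":     (504, 130, 313, 97, 21),
    "south":     (627, 429, 10, 221),
}
for stratum, counts in site_counts.items():
    p = HillProfile.from_counts(DetectionCounts(counts, stratum), stratum)
    n0, n1, n2, ninf = p.rounded()
    print(f"{stratum:10s} N0={n0} N1={n1:.2f} N2={n2:.2f} Ninf={ninf:.2f}")
```

prints

```
statewide  N0=5 N1=3.59 N2=3.08 Ninf=2.08
north      N0=5 N1=3.55 N2=3.00 Ninf=2.11
south      N0=4 N1=2.88 N2=2.65 Ninf=2.05
```

Reading: the state hosts five species, but unevenness (one dominant species
at 1131 of 2352 site detections) reduces the effective number to ~3.6 by
Shannon weighting and ~3.1 by Simpson weighting; the south stratum lacks one
species outright (N0 = 4) and is less even (N1 = 2.88). N∞ ≈ 2.1 says the
dominant species alone accounts for nearly half of all detections.

An end-to-end run on synthetic data (simulate → classify → tabulate →
diversity → spatial, with a reproducibility manifest):

```sh
cat > run.yaml <<EOF
seed: 7
outdir: out
sim_survey:
  n_sites: 400
EOF
retidiv run --config run.yaml
```

which leaves `out/assignments.csv`, `out/panel_nj.nwk`, `out/table1.csv`,
`out/table2.csv`, `out/table3.csv`, per-species KDE grids and
`out/manifest.json` with per-output SHA-256 checksums (identical across
reruns with the same seed). Individual stages are available as
`retidiv simulate | classify | tabulate | diversity | spatial | validate`.

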