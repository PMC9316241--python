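# Methods

`retidiv` implements the analysis chain of a statewide barcode-based
biodiversity survey of *Reticulitermes* subterranean termites: species
assignment of mtDNA barcode reads against a taxonomically validated reference
panel, stratified tabulation of detections, Hill-number diversity profiles,
and point-pattern statistics of per-species site distributions. This note
records the models, the defaults and why they were chosen, and what the
synthetic data generator does and does not emulate.

## Species assignment

The field practice this package supports identifies a query haplotype by
where it falls among reference clades in a phylogenetic tree. We implement
the decision rule as **nearest-reference distance assignment**: the species
distance of a query is the minimum distance to any of that species'
references, and the query takes the species with the smallest such distance.
Whenever the panel exhibits a *barcode gap* — maximum within-species distance
strictly below minimum between-species distance — the nearest-reference label
coincides with the clade label, so the package computes and reports that gap
(`panel_separability`) as the precondition for trusting any assignment.
Maximum-likelihood tree inference (GTR+G+I class models) is deliberately not
reimplemented: it adds nothing to the label outcome under a verified gap, and
the distance rule is deterministic and auditable.

Distances are p, Jukes–Cantor, or Kimura 2-parameter
(d = ½ ln 1/(1−2P−Q) + ¼ ln 1/(1−2Q) with transition and transversion
proportions P, Q), always with **pairwise deletion** of columns containing
`N` or `-` — partial reads keep their informative sites. A pair whose
correction log-argument reaches zero is *saturated* and carries distance
`inf`; saturated queries are flagged, never guessed. Assignment ties (species
distances within 1e−12) are flagged `ambiguous`. Support is a
column-resampling bootstrap (default 1000 replicates, matching standard
practice for the tree analogue): resample alignment columns with replacement,
reassign, and report the agreeing fraction.

Neighbour-joining (Q-criterion, two-taxon branch split, matrix reduction) is
implemented in-package and cross-checked in the test suite against an
independent library implementation. Negative branch lengths are clamped to
zero and logged — standard practice that keeps newick consumers content.
Species monophyly on the unrooted NJ tree is a bipartition test: a species is
monophyletic iff one edge separates exactly its leaves.

`audit_labels` screens any labeled collection (e.g. public-database
accessions) by re-assigning every record and reporting disagreements; an
empty report is exactly the statement that assignment agrees with every
label.

## Survey tabulation

Sites carry planar-km coordinates, a county id, and a stratum determined by a
horizontal fall line: **north iff y ≥ fall line** (on-line sites are north; a
documented tie rule, not a claim about geology). A species counts once per
sample, once per site (presence), and once per county (≥ 1 sample at ≥ 1 site
of the county). Percentages use the stratum's own totals and round half-up to
one decimal, the convention of printed survey tables. Within a stratum the
sample percentages of all species sum to 100 (each sample has one species);
site and county percentages may exceed 100 in aggregate because multi-species
sites are counted once per species. A county's stratum is the majority
stratum of its sites (ties north) — with grid-cell counties and a fall line
on cell boundaries this is exact.

## Hill numbers

Diversity is reported in effective species at orders r = 0, 1, 2, ∞:

* N0 — richness;
* N1 = exp(−Σ p_i ln p_i), the exponential Shannon entropy;
* N2 = 1 / (Σ n_i(n_i−1) / (N(N−1))), the finite-sample inverse Simpson
  with n_i the per-species site-detection count and N = Σ n_i the total
  detections;
* N∞ = 1 / max p_i, the inverse Berger–Parker dominance.

p_i is a species' share of **site-level detections** within the stratum (not
samples, not counties): the number of sites where the species was found over
the total of those counts. N2's finite-sample form requires integer counts
and N ≥ 2; when every species is a singleton the unbiased Simpson sum is zero
and N2 is reported as `inf` rather than a number. 0·ln 0 is treated as 0.
Display rounding is half-up to two decimals; full precision is kept
internally.

One ordering caveat is worth recording: the asymptotic Hill ordering
N0 ≥ N1 ≥ N2 ≥ N∞ holds for proportions, but the finite-sample N2 is
inflated relative to its asymptotic value by the factor (N−1)/(N−A) with
A = N²/Σn², so N2 can slightly exceed N1 for near-even counts at any finite
N (e.g. counts [21, 29]: N1 = 1.974, finite-sample N2 = 1.989). The test
suite asserts the exact bound N2 ≤ N1·(N−1)/(N−N1) instead of the naive
ordering.

## Point-pattern statistics

**Clark–Evans index.** R = observed mean nearest-neighbour distance over the
CSR expectation 1/(2√λ), with λ = n/|window| estimated from the full
pattern. Edge bias is removed by a **guard buffer**: points within
`guard_width` of the window boundary still serve as neighbours but contribute
no nearest-neighbour distance of their own. The default guard width is the
full pattern's mean nearest-neighbour distance, computed once — a
scale-adaptive choice of the classical buffer method; any fixed width can be
passed instead. The two-sided z-test uses the classical standard error
0.26136/√(n_focal·λ). Under CSR (n = 500, 500 replicates) the implementation
shows mean R within 1% of 1 and empirical size ≈ 5–7% at α = 0.05 — the
classical test ignores the weak dependence among nearest-neighbour distances
and is known to run slightly liberal; the guard correction keeps R itself
unbiased.

**Kernel density estimation.** Isotropic Gaussian kernels on a cell-centre
lattice over the window bounds, on the intensity scale (integrates to n over
the plane). No boundary correction is applied, so intensity mass within a few
bandwidths of the border is knowingly underestimated; the surfaces are for
visual comparison of species prevalence, not for edge-corrected inference.
The default bandwidth is the Silverman-style rule 0.9·min(sd_x, sd_y)·n^(−1/5).

## Synthetic data

The generator produces datasets with the statistical structure the analysis
assumes, so the full chain is testable without any sequence download or
released coordinates.

*Sequences.* A random root sequence; per-species ancestors at a configurable
between-species divergence (default 0.05 substitutions/site); reference and
query haplotypes star-like around each ancestor at a within-species
divergence (default 0.005). Substitution is equal-rate (Jukes–Cantor style):
each site flips with probability ¾(1−e^(−4d/3)) to a uniform other base —
the simplest model whose pairwise distances have closed forms to test
against. Defaults mirror the study scale: 5 species × 11 references (55
anchors), 685 bp. The config enforces the barcode-gap invariant
(between > 2·within). A star phylogeny is used within species rather than a
coalescent genealogy because only the gap matters for classifier testing;
real haplotype genealogies, rate variation among sites, indels and
sequencing error are *not* emulated, so classifier tests demonstrate
correctness of the decision rule, not robustness to those real-data
features.

*Survey.* The default window is 450 × 342 km = 153 900 km² (the surveyed
land area) with 1570 sites — one per ~98 km² — and a fall line at y = 192 km
reproducing the survey's north/south site split under uniform placement.
Counties are a 12 × 13 grid of cells (156 ≈ the real 159; only the partition
structure matters to the statistics, not polygon shapes). Per-species,
per-stratum occupancy defaults follow the surveyed site proportions (three
statewide species, two restricted to the north stratum). Clustered species
are realized by a Thomas process — Poisson parents, Gaussian-scattered
offspring — thinned to the nearest survey sites, which yields
Clark–Evans R < 1; CSR species use independent per-site occupancy draws.
Samples per site are uniform on a configurable range (default 1–7, the
survey's observed range; the study's underlying sampling intensity is
unpublished, so it is a parameter, not an assertion). Every site yields at
least one sample: a site whose presence draws all come up empty is backfilled
with one species drawn proportionally to its stratum occupancy, mirroring a
survey design that kept collecting until a site produced a sample.

## Pipeline

`run_pipeline` executes simulate → classify → tabulate → diversity → spatial
from one declarative YAML config. All randomness flows from a single root
seed split per stage by hashing the stage name (each derived seed < 2³¹);
identical config + seed gives byte-identical outputs, which the manifest
proves with per-output SHA-256 checksums. A stage failure short-circuits the
run and leaves a partial manifest naming the failed stage. CLI exit codes:
0 ok, 2 config error, 3 stage failure.

## Numerical and scale choices

* Rounding of displayed percentages and Hill numbers is half-up (`Decimal`
  quantization / explicit floor(x·100+0.5)), since banker's rounding would
  disagree with printed survey tables on exact halves.
* Test problem sizes: classifier checks run a 55-reference, 200-query panel;
  Clark–Evans calibration uses 500 CSR replicates of n = 500 and 200 Thomas
  replicates — sizes at which binomial noise on the checked rates is well
  inside the asserted bands while the whole suite stays interactive
  (seconds, not minutes).
* Queries are required to match the panel's aligned length; optional
  end-trim/pad to length (`--coerce-length`) exists on the CLI only, because
  silent coercion hides misalignment.

## Known limitations

* No multiple sequence alignment: inputs must be pre-aligned homologous
  reads (true for fixed-primer amplicons).
* No maximum-likelihood or Bayesian tree inference; NJ trees are for
  monophyly checks, not phylogenetic publication.
* The published per-species R scores and density maps cannot be reproduced
  numerically without the study's site coordinates, which were not released;
  the spatial suite instead verifies calibration and power of the
  implementation on generated patterns.
* Planar coordinates only; longitude/latitude must be pre-projected.
* Percentage agreement with printed tables is at one decimal; two printed
  cells sit on the wrong side of a rounding boundary from their exact
  quotients and one printed county percentage is inconsistent with its own
  count — the package always reports what the data yield.
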