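# Methods

## Problem setting

Untargeted LC-MS profiling of a collection of related bacterial strains
produces a *bucket table*: rows are analyses (strains or replicates),
columns are (retention time, *m/z*) buckets, cells are summed ion
intensities. With a permissive S/N threshold — desirable, because poorly
ionizing unique compounds are exactly the interesting ones — such tables
reach 10⁵–10⁶ features, of which only a handful per strain are
strain-exclusive chemistry. The package automates the triage: PCA
identifies, for each strain, the component plane in which it separates
from all others, and the raw table identifies which masses are exclusively
its own; the loading distance in the selected plane ranks them.

## Pipeline and its assumptions

Order of operations (fixed):

    replicate averaging → RT/mass range filter → row-sum normalization →
    Pareto scaling → PCA → per strain: plane search → uniqueness filter →
    ranking → optional dereplication

Rationale for the two places where a choice had to be made:

* **Normalization is row-wise** (each analysis divided by its own total
  signal). Strains genuinely differ in overall ion yield; without row
  normalization a weakly ionizing strain would appear to have few unique
  features simply because its signals are small. Column-wise
  interpretation of "sum normalization" would not correct this and was
  rejected.
* **Uniqueness is judged on the raw, range-filtered table**, not on the
  normalized or scaled one. Presence/absence is an instrument-level fact;
  scaling exists only to shape the PCA. With the default α = 0 the two
  choices coincide (row scaling preserves zero patterns); for α > 0 the
  raw table keeps the tolerance in instrument-intensity units.

PCA assumptions worth stating: buckets are treated as independent columns
(no isotope/adduct grouping), and "unique to a strain" is defined against
the *collection analysed*, not against nature — changing the group changes
the model, though not, in practice, the unique sets (this invariance is
tested).

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `delta_rt` | 0.33 | min | bucketing RT tolerance |
| `delta_ppm` | 4 | ppm | bucketing mass tolerance |
| `rt_min, rt_max` | 2, 14 | min | trusted chromatographic window |
| `mz_min, mz_max` | 150, 1500 | Th | trusted mass window |
| `alpha` | 0 | — | max other-strain intensity fraction for uniqueness |
| `top_n` | 60 | — | report length per strain |
| `tol_ppm` | 5 | ppm | dereplication mass tolerance |
| adducts | [M+H]⁺ | — | positive-ESI default; Na/NH₄/2H⁺ available |
| proton mass | 1.007276 | Da | fixed constant of the adduct arithmetic |

The bucketing and window defaults are the standard acquisition settings
for this kind of screen; the dereplication tolerance of 5 ppm is a
conventional choice for a well-calibrated TOF (the bucketing tolerance of
4 ppm is about measurement reproducibility between runs, a different
quantity — the two are deliberately independent knobs).

## Algorithmic choices

**Bucketing** is a greedy sweep over all features of all samples in
ascending *m/z*: a feature joins an open bucket if it is within
`delta_ppm` of the bucket's intensity-weighted *m/z* centroid *and*
within `delta_rt` of its RT centroid (the two tolerances gate
independently); among several admissible buckets it takes the nearest in
ppm, ties toward the lower-*m/z* centroid; otherwise it opens a new
bucket. Input is canonically sorted first, so the result is deterministic
and invariant to sample/feature order; same-sample collisions are summed,
conserving total signal. Complexity O(F log F). The sweep cannot resolve
two true compounds closer than the tolerance — a limitation of the
tolerance, not the implementation, and asserted as such in the tests.

**Pareto scaling** uses the n−1 (sample) standard deviation. Zero-variance
columns are set to zero rather than dropped so feature indices stay
aligned with the table. Consequence used by the tests: post-scaling column
variance equals the pre-scaling standard deviation.

**PCA** is a plain SVD of the centered matrix; retained components are the
numerical rank (singular values above 1e−10 of the largest), which after
centering is at most n−1 — a collection of n strains has at most n−1
informative components, not n. Sign indeterminacy is fixed by making each
component's largest-magnitude loading positive, so reports are
reproducible across LAPACK builds. Scores/loadings planes are labelled
1-based ("PC13 vs PC15") as users expect.

**Plane search.** The per-component gap is the nearest-neighbor score
distance: a strain stands out only if it is separated from *all* other
strains, and a difference-from-mean statistic would reward planes where a
second outlier inflates the mean. (An `abs_deviation_from_median` metric
is available, since which statistic vendor overview plots use is not
documented.) The best plane takes the two components with the largest
gaps; this equals the exhaustive optimum over all K(K−1)/2 pairs under
the natural pair objective (maximize the weaker gap, then the stronger),
which is kept as `exhaustive_best_plane` and as a test oracle. Ties break
toward lower component index, favouring higher-variance components. When
the model has fewer than two components (e.g. all strains identical)
there is no plane to search and all reports are empty by construction.

**Dereplication** converts each query ion to a neutral mass per adduct
(`M = m/z·charge − shift`), then takes all database entries within
`tol_ppm` via binary search on the mass-sorted database; ppm error is
relative to the database (theoretical) mass, per MS convention. Matches
sort by |ppm error|; a record with no match under any adduct is flagged
putatively novel. Annotation never reorders the ranking.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of a strain-collection screen:

* `n_background` features shared by all strains, with log-normal
  intensities centred at ~5×10³ counts (σ = 1 in log space) — the minor,
  noise-threshold features a permissive S/N cutoff admits in bulk;
* `n_unique_per_strain` exclusive features per strain at ~5×10⁵ counts
  (σ = 0.5) — genuine metabolite peaks, ~two orders of magnitude above the
  noise floor, as real secondary-metabolite peaks are;
* a per-strain ion-yield factor, uniform in [0.5, 2] — the between-strain
  intensity disparity that sum normalization corrects;
* optional Bernoulli dropout of background features (default 10 %),
  optional replicates with multiplicative log-normal noise of a given CV
  (default 5 %), *m/z* keys drawn ≥ 20 ppm apart so bucketing ground
  truth is unambiguous, and full reproducibility from the seed.

The two intensity scales matter: if background and unique features were
drawn from one distribution, noise-level background loadings would be
commensurate with the weakest unique loadings and no ranking method could
cleanly separate them — nor does real data look like that.

Not emulated: chromatographic peak shapes, isotope envelopes, multiple
adducts of one compound, RT drift beyond small jitter, and features shared
by strain subgroups. Passing tests therefore demonstrate correctness of
the algorithmic chain under the stated noise model, not that every real
collection will separate this cleanly — on real data the outcome depends
on peak-list quality, as it must.

## Numerical conventions

* Rank tolerance 1e−10 (relative to the largest singular value).
* All ranking ties (gaps, distances, top-N) break toward the lower index,
  making every output deterministic.
* CSV output writes floats with `repr` (round-trip exact); table reads use
  round-trip float parsing, so write→read reproduces matrices bit-exactly.
* Excel sheet names truncate to the format's 31-character limit with
  numeric deduplication.
* Empty/NA cells read as intensity 0 (dense absence encoding).
* Degenerate inputs: single-row matrices are rejected by scaling/PCA;
  all-zero strain rows are rejected by normalization with the strain
  named; an empty compound database flags every query novel with a
  warning.

## Problem sizes used in the checks

The acceptance checks run the reference conditions — 20 strains × 2
replicates, 2,000 background + 100 planted features, 5 % noise — plus 100
random 10×50 models for the plane-search oracle, random matrices up to
20×5,000 for the PCA invariants, and a 10⁴-entry database for the
dereplication oracle. These sizes exercise every code path at the scale
of a realistic screening batch while keeping the whole suite in seconds;
the workflow itself is O(n·p) + one SVD and handles larger tables without
structural change.

## Known limitations

* Uniqueness is binary per feature; a compound appearing as different
  adducts in different strains is not recognised as shared.
* The gap statistic has no null model: "most separated" is descriptive,
  not a significance claim.
* Group composition still shapes the PCA model (which plane is chosen),
  even though the unique-feature *sets* are group-invariant; reports from
  collections above ~50 strains become progressively less informative as
  intergroup and intragroup variance converge.
* Dereplication is exact-mass only: no formula generation, isotope-pattern
  scoring, or RT matching against standards.
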