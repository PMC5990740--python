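# Methods

## Forward model of incremental growth

A section lives in a 2-D longitudinal plane (µm), cusp tip at the origin,
cervix toward +u, enamel on the +v side of the EDJ. The activation front
of ameloblasts advances along the EDJ according to the extension schedule
c(t) (constant or piecewise constant), reaching arc position
s(t) = ∫₀ᵗ c dτ. Each activated EDJ point secretes enamel at the daily
rate d for at most `secretion_duration` days.

Ameloblasts retreat perpendicular to their own flat secretory surface, so
in the quasi-steady wedge the forming front meets the EDJ at the angle
sin θ = d/c and the secretory path is tilted cervix-ward by θ from the
EDJ normal. This construction makes the perpendicular spacing of
consecutive daily fronts exactly d — the property the daily-increment
estimators rely on — while the spacing measured along the EDJ normal is
d/cos θ (indistinguishable from d when d ≪ c, which holds across the
realistic range of roughly 5–100 µm/day extension against 1–4 µm/day
secretion). For piecewise extension schedules the tilt is set from the
rate at each point's activation time, which is exact within each constant
piece and a first-order approximation at transitions. The construction
requires d < c; configurations with secretion outrunning extension are
rejected rather than silently mis-modelled.

The forming front at the end of each day t is emitted as a short-period
(daily) incremental line; every R-th front is emitted as an accentuated
long-period line instead, where R is the repeat interval (2 in the
cynodont condition; any R ≥ 1 is supported). Every line touches the EDJ
exactly at s(t), carries its ground-truth `day_index`, and the generating
`SectionConfig` rides along as `truth`.

Dentine is modelled schematically near the EDJ only: the daily von Ebner
line for day t shares the enamel front's EDJ intersection at s(t)
(reciprocal induction of ameloblast and odontoblast differentiation) and
extends straight inward with daily apposition `dentine_rate`, clipped at
`dentine_max_depth` (default 60 µm). Inward spacing between consecutive
von Ebner lines therefore equals `dentine_rate` exactly; no pulp geometry
is modelled.

Digitization error is modelled as i.i.d. Gaussian displacement of line
vertices along the local EDJ normal (`jitter_sd`, µm); it perturbs every
incremental line but not the EDJ or outer surface, which a tracer anchors
far more reliably. All randomness flows from a single seed per call.

**What the generator does not emulate:** prismatic enamel and decussation,
enamel maturation, sub-daily (intradian) lines, wear and damage,
illumination artefacts of real micrographs, and cusp-to-cervix variation
in secretion rate along a single ameloblast path (depth-varying schedules
are supported but default constant). Passing tests therefore demonstrate
correctness of the measurement algorithms on idealized but ground-truthed
geometry, not robustness to every failure mode of real histology.

### Defaults

| parameter | default | meaning |
|---|---|---|
| `cer_schedule` | 20 µm/day | extension (activation-front) rate |
| `dsr_schedule` | 1.5 µm/day | daily secretion rate |
| `repeat_interval` | 2 | daily increments per long-period line |
| `secretion_duration` | 30 days | secretion lifetime of a front point |
| `dentine_rate` | 11.9 µm/day | von Ebner width (measured Diademodon value) |
| `jitter_sd` | 0 µm | vertex tracing noise |
| `step` | 0.5 µm | EDJ discretization |

The `cynodont_section_config()` preset uses extension 88.3 µm/day — the
dentine-measured EDJ extension rate of the Diademodon specimen that
anchors the periodicity comparison — with 12 days of growth.

## Measurement algorithms

**DSR.** Rays are cast through the enamel either along local normals to
the outer enamel surface (`prismless` mode, the likely ameloblast path in
prismless enamel) or along trajectories orthogonal to the forming fronts
(`prism_path` mode); for parallel-front enamel the two coincide. Gaps
between consecutive daily-line crossings are pooled into bins of `window`
µm of EDJ arc (default 50 µm); the grand mean over all gaps is the
tooth's average DSR. When ground-truth day indices are present, only
day-adjacent pairs contribute, guarding against misconfigured fixtures.

**Cumulative-length CER.** Anchors are the accentuated lines ordered by
their EDJ intersections; the first segment starts at the cusp tip. For
each anchor the trajectory direction is estimated as the normal of the
nearest increment line (principal direction over a local vertex window,
robust to tracing noise), and the ray is nudged cervix-ward when it would
only graze front endpoints — legitimate because days x = A / spacing is
invariant to ray obliqueness across locally parallel fronts. The local
daily spacing under assumption p is (long-period spacing along the
ray)/p, with the long-period spacing measured as span/gaps between the
outermost long-period crossings; when fewer than two long-period lines
cross the ray it falls back to R × (mean daily gap) with R the modal
counted repeat interval. Both forms scale exactly as 1/p, which makes
CER(p=1) = 2 × CER(p=2) an algebraic identity on any section — jittered
or not — mirroring how halving the assumed number of days doubles the
inferred rate. Segments whose anchor cannot be reached are skipped with a
warning and never interpolated; gaps shorten the measured EDJ.

**Dentine extension rate.** Arc distance between the first and last von
Ebner EDJ intersection divided by the daily intervals spanned (day
indices when available, else count − 1).

**Periodicity.** `count_repeat_interval` takes the modal number of daily
increments between adjacent long-period lines (short lines strictly
between, plus one). `periodicity_concordance` computes the enamel CER
over the dentine-covered EDJ span for each candidate p and picks the
argmin of |CER_p − dentine| / dentine. Ties break toward the smaller p
(conservative toward faster growth) with a warning. Dentine increment
widths outside the 4–20 µm plausibility band for daily von Ebner lines
warn but do not abort, since the band is a survey heuristic, not a law.

**Rendering and image profiles.** Lines are rasterized and turned into
dark bands via a Euclidean distance transform with a Gaussian
cross-profile (σ default 0.35 µm); long-period bands are rendered darker
than short-period bands, both darker than the matrix. Band spacing is
recovered as distances between prominence-selected intensity minima along
bilinear-sampled transects; prominence-based selection is robust to
illumination gradients where fixed thresholds are not. Spacings below
2 px at the chosen resolution are flagged as merge-prone.

## Comparative statistics

The chain follows standard practice for mass-corrected growth-rate
comparison: log₁₀ rates and log₁₀ body mass (base 10 throughout; the base
cancels in residual-based group tests), PGLS with pure Brownian
covariance C (no branch-length transformation parameter is estimated),
raw residuals as the mass-corrected rates, per-variable Box-Cox with a
shift of (−min + 1) when residuals are non-positive and a λ grid of
[−3, 3] in steps of 0.01, then:

* Wilks' Λ MANOVA with Rao's F (exact for two responses);
  multivariate partial η² = 1 − Λ^(1/s), s = min(q, ν_h);
* pairwise two-group MANOVAs (equivalent to Hotelling's T²);
* univariate one-way ANOVAs and two-group pairwise ANOVAs;
* tie-corrected Kruskal–Wallis and Dunn post-hocs (midranks, two-sided);
* Benjamini–Hochberg adjustment applied within each pairwise family.

Species can be excluded or reassigned between groups at the pipeline
surface, supporting sensitivity analyses for taxa of uncertain affinity;
species labelled `unassigned` are dropped.

### The species-data generator

`simulate_species_dataset` draws log₁₀ body mass by Brownian motion on
the tree (root 3.0 = 1 kg, sd 1.0 per unit depth) and sets
log₁₀ rate = group intercept + 0.1·log₁₀ mass + Brownian deviation
(sd 0.08) + i.i.d. noise (sd 0.08). The default tree holds the five
comparison groups as clades in an amniote-shaped topology (diapsids
outside, non-probainognathians stemward of mammaliamorphs, crown mammals
split into non-hypsodont and hypsodont clades), normalized to unit depth,
with 4 + 2 + 3 + 27 + 3 = 39 tips so the univariate error df is 34. The
`published_means` preset targets the reported group mean rates — CER 86.0
(non-probainognathian), 10.1 (mammaliamorph) µm/day, with the remaining
groups at realistic magnitudes — and gives both cynodont groups the same
DSR mean, encoding the reported absence of a secretion-rate difference
between them.

### Calibration and known limitations

Two properties of the published chain deserve explicit statement, both
reproduced and quantified by this package's tests:

1. **Residual-projection inflation.** Testing PGLS residuals as if they
   were raw data ignores the degrees of freedom absorbed by the mass
   regression. On an exchangeable null (no group effect, no phylogenetic
   structure in mass or traits) the full chain's type-I error at nominal
   5% is about 6.3% (±0.4%, estimated at 3000 replicates). The
   acceptance test estimates this rate over 2000 replicates so that
   Monte-Carlo noise (se ≈ 0.5%) does not dominate the 7% bound it is
   checked against.
2. **Clade-aligned confounding.** When trait deviations are Brownian and
   the comparison groups are clades, clade-level deviations are
   indistinguishable from group effects to the non-phylogenetic MANOVA
   stage; under that coherent Brownian null the chain rejects ~11% at
   nominal 5%, and in the calibrated pattern check it produces spurious
   pairwise DSR differences in roughly one replicate in eight. This is
   inherent to applying non-phylogenetic group tests to
   phylogenetically structured residuals with few species per group; a
   phylogenetic MANOVA would address it but is outside this package's
   scope.

Label-permutation calibration (shuffling group labels on null data) shows
the MANOVA p-value uniform, confirming the chain is well behaved when
group membership is not confounded with phylogeny.

## Numerical choices

* Geometry tolerance 10⁻⁶ µm for clean digitized input; measurement
  functions snap line–EDJ contacts within 1 µm to absorb tracing noise.
* Polyline intersections, projections and distances go through shapely;
  intersections returning multiple crossings keep the most cervical one
  with a warning.
* Simulated problem sizes in tests and the acceptance script (10–12 day
  sections, 0.5 µm EDJ step, 100-replicate Monte Carlos) were chosen as
  the smallest sizes at which the estimators' asymptotic behaviour is
  already visible.
* MANOVA requires every group ≥ 2 members and n > groups + responses;
  degenerate zero-within-variance ANOVAs flag F as infinite rather than
  erroring.
* Box-Cox λ is reported to grid resolution (0.01), which exceeds any
  reporting precision needed downstream.
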