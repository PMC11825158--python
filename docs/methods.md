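# Methods

## Input model

The package consumes annotation exports, not images. One *section* is a
testicular region of interest (ROI) polygon, a set of tubule outline
polygons and a set of germ-cell point marks, each mark labelled AP2G
(gonocyte, nuclear AP2γ stain) or MAGEA4 ((pre)spermatogonium,
cytoplasmic MAGE-A4 stain). Coordinates are continuous Cartesian
millimetres, y increasing downward as in image exports; a
`scale_mm_per_unit` factor applied at read time converts pixel-unit
exports. Polygons must be simple with at least 3 vertices and nonzero
area; identifiers are opaque strings, unique within a section. When an
export carries no ROI, the convex hull of all tubule outlines stands in
(edge exclusion needs *some* boundary), and the substitution is logged.
Features with unmapped classification labels are skipped with logged
counts rather than failing: annotation projects accumulate stray classes.

## Per-tubule morphometry

- **Area**: shoelace area of the true outline polygon (orientation
  independent).
- **Longest/shortest diameter**: maximum and minimum Feret diameters of
  the outline's *convex hull* — the computational analogue of manual
  caliper/grid measurement, which spans a shape rather than its
  concavities. The maximum is the largest hull vertex-pair distance; the
  minimum width is attained perpendicular to a hull edge, so an exact
  rotating-calipers sweep over hull edges suffices. Both are
  rotation-invariant to ≤1e-9 relative and scale linearly with the
  coordinates.
- **Roundness**: ratio = longest/shortest diameter; a tubule is round iff
  ratio < 1.5, *strictly* — a ratio of exactly 1.5 is non-round. The
  threshold is configurable (`roundness_threshold`, default 1.5,
  dimensionless).
- **Intactness**: an annotator-provided flag always wins; otherwise a
  tubule is excluded as edge-clipped when any outline vertex leaves the
  ROI or comes within `edge_tolerance_mm` (default 0.002 mm) of the ROI
  boundary. The tolerance is configurable because the original
  intactness call is visual and operator-dependent.
- **Cell assignment**: closed-region point-in-polygon (boundary cells
  count as inside — annotators click nuclei straddling the outline).
  Cells inside several overlapping outlines go to the lowest tubule_id,
  deterministically, with a warning; overlap is annotation noise, not a
  modelled situation. Cells in no tubule are reported unassigned and
  enter no metric.

## The four metrics and aggregation

Only intact tubules contribute counts and areas. Per section:
`method1 = cells / total area`, `method2 = cells-in-round / n_round`,
`method3 = 100 · round-with-≥1-cell / n_round`,
`method4 = cells-in-round / round area`. Any metric with a zero
denominator is *missing* (empty CSV cell), never an exception, so
sparse sections flow through the pipeline. Useful identities, enforced
by tests: `method2 = method4 × (round area / n_round)` whenever both are
defined; `method1 = method4` exactly when every analysed tubule is
round; rescaling coordinates by *s* leaves Methods 2–3 unchanged and
multiplies Methods 1 and 4 by 1/s².

Both markers count as germ cells (double-positive resolution happens at
annotation time); per-marker counts are also emitted.

Sample-level aggregation defaults to the unweighted mean of each
metric's defined per-section values (`per_section_mean`), matching how
per-individual means over tissue fragments are usually reported;
`pooled_counts` instead sums counts and areas across sections and
re-applies the formulas, which weights sections by size. The two agree
trivially for single-section samples.

Two QC flags mark reliability floors without excluding anything:
`few_round_tubules` when fewer than `min_round_tubules` (default 25)
round cross-sections are available, and `small_total_area` when total
tubular area falls below `min_total_area_mm2` (default by tissue type:
0.015 mm² fetal, 0.003 mm² prepubertal). Exclusion is left to
reporting-time judgement because sub-threshold samples are often
analysed separately rather than discarded.

## Statistics

`compare_groups` reproduces a normality-gated workflow: Shapiro–Wilk per
condition at the analysis alpha (default 0.05); when every group is
consistent with normality, an additive two-factor ANOVA with condition
and subject as crossed factors (randomized block — justified because
each subject contributes tissue to every condition), with Tukey–Kramer
pairwise tests on condition built from the blocked model's residual mean
square and the studentized-range distribution; otherwise Kruskal–Wallis
on condition followed by Dunn's rank test with Bonferroni adjustment
over all pairs. The branch taken is recorded in the result. Groups
smaller than 3 cannot be assessed for normality and take the
nonparametric branch; zero-range groups pass the gate (a constant sample
cannot reject normality). The blocked-ANOVA factor choice is an
assumption recorded in the result metadata, not an inevitability.

`pearson_correlation` is the standard product-moment r with the
two-sided t-transform p (n−2 df) and a least-squares fit line.
`correlate_methods` computes it for Methods 2–4 against Method 1 on
sample-level values (one point per subject × condition), overall and in
two strata: samples with `< 25` and `≥ 25` round tubules (strict `<` /
`≥`, threshold configurable). Strata with fewer than 3 complete pairs
yield undefined r/p rather than an error.

## Synthetic sections

The simulator exists so every stage is testable against known truth.
Tubule profiles are ellipse-shaped 64-gons — the round/elongated
dichotomy is an axis-ratio statement, and ellipses make the truth
analytic (a 64-gon's measured axis ratio deviates from the ellipse's by
under 0.2%). Defaults, chosen to emulate immature-testis sections and
fixed once:

| parameter | default | meaning |
|---|---|---|
| section | 1.2 × 1.2 mm | one tissue fragment cross-section |
| n_tubules | Poisson, mean 15 | tubule profiles per section |
| sample_size_sigma | 0.5 | lognormal spread of a per-sample abundance multiplier (fragment size varies) |
| tubule area | lognormal(ln 0.003, 0.5) mm² | ≈55–70 µm diameters |
| log axis ratio | Normal(0.25, 0.25) truncated ≥ 0 | ≈⅔ of profiles round at the 1.5 threshold |
| density λ | 690.2 cells/mm² (fetal preset) | cells per mm² of *tubular* area, Method 1's denominator |
| subject_sigma | 0.25 | mean-one lognormal subject effect on λ |
| ap2g_fraction | 0.3 fetal / 0.0 prepubertal | marker mix |

Placement is dart-throwing with a conservative circumcircle overlap
test (up to 10,000 attempts per tubule; a shortfall beyond 50% is a
simulation error advising fewer tubules or a larger section). Tubules
crossing the section boundary are clipped against it and ground-truth
flagged not intact. Cell counts are Poisson(λ · polygon area), optionally
gamma-mixed to a negative binomial (`overdispersion` = gamma shape);
cells are placed uniformly in the tubule polygon by rejection sampling.
Cell position within a tubule is uniform — no basement-membrane bias is
modelled.

Studies draw one subject effect per subject, multiply per-condition
factors onto it, and use one RNG stream per (seed, subject, condition,
section), so enlarging a study never perturbs existing sections and a
fixed seed reproduces files byte-identically. Two presets bundle
realistic regimes: `fetal_chemo` (control/cisplatin/carboplatin
multipliers 1.0/0.705/0.721 on base 690.2) and `prepubertal_cryo`
(control/cryopreserved/fresh-cultured/cryo-cultured multipliers
1.0/0.799/0.530/0.514 on base 1175). The prepubertal multiplier set is
completed from round-tubular-density group means because all-shape
density means are reported for only two of the four arms; the presets
are starting points for estimator testing, not claims of distributional
fidelity. With the defaults, roughly 30% of simulated samples fall short
of 25 round tubules — the scarcity regime that motivates an all-shape
density metric.

What the simulator does **not** emulate: spatial clustering of germ
cells, within-section density gradients, tubule shape irregularity
beyond ellipses, annotation errors (missed cells, double clicks,
mis-drawn outlines), and section-to-section autocorrelation within a
block. Passing recovery tests therefore demonstrates correctness of the
computational pipeline under the stated generative model, not robustness
to annotation noise in real tissue.

## Numerical and design choices

- Zero denominators yield missing values; missing values propagate as
  empty CSV cells and are dropped pairwise (with logged counts) in
  statistics.
- Metric CSVs round-trip losslessly at 12 significant digits; geometry
  CSVs/GeoJSON write full-precision floats so the two export formats are
  bit-equivalent.
- Manifests record command, config, input checksums, seed and version —
  but no wall-clock timestamp, so fixed-seed pipelines are byte-exactly
  reproducible end to end.
- Tie-breaks: round threshold strict `<`; stratification strict `<` vs
  `≥`; overlapping-tubule assignment by ascending tubule_id.
- Test problem sizes (300-section recovery runs, 20×200-section variance
  experiments, 400–500-replicate calibration loops) were chosen so the
  statistical assertions have comfortable margins while the whole suite
  runs in about two minutes.

## Limitations

- The intactness heuristic only sees vertex-to-boundary distance; an
  outline that crosses the ROI between vertices could escape it (not
  possible for the convex ROIs and dense outlines produced here).
- Dunn's adjustment is Bonferroni over all pairs; other adjustment
  variants exist and give larger power.
- The blocked two-factor ANOVA assumes additive subject effects and no
  subject × condition interaction; with 5–6 subjects there is little
  power to check that assumption.
- QC thresholds (25 round tubules; 0.015/0.003 mm²) are conventions
  carried from the literature, not derived quantities; the package only
  flags them.
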