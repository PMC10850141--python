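# Methods

## The measurement model

Copepodamides are taurine-conjugated lipids made by copepods. All share one
of two scaffolds that differ by two hydrogens at C3: the copepodamides
proper (CA) and the dihydro-copepodamides (dhCA). Under collision-induced
dissociation the scaffold survives as a charged diagnostic fragment —
C22H40NO5S (m/z 430.26) for CA, C22H42NO5S (m/z 432.28) for dhCA — while
the variable fatty acyl esterified at C5 leaves as a neutral free fatty
acid, C\_n H\_(2n−2d) O\_2 for an n-carbon acyl with d double bonds. Two
consequences drive the whole package:

1. **Class detection.** A precursor-ion scan over 600–1000 m/z for product
   430.3 or 432.3 finds every member of the class in a bulk extract,
   whatever its acyl group.
2. **Acyl annotation.** The neutral loss (precursor − product) equals the
   free fatty-acid mass, so the acyl is identified by matching the loss
   against an enumerated homolog library. The [M+H]+ precursor m/z of a
   species is exactly the fragment cation mass plus the neutral fatty-acid
   mass.

Species are named acyl-then-scaffold, e.g. "22:6 dhCA".

### Mass arithmetic

Monoisotopic atomic masses (CODATA/AME values, C = 12 exactly) are summed
per formula; cation masses subtract one electron (0.000549 Da). The printed
fragment compositions are treated as the *charged* fragment compositions:
summing C22H42NO5S and removing an electron reproduces m/z 432.28, whereas
protonating a neutral of that composition would land ~1 Da high. m/z is
carried at full precision internally and rounded (4 decimals in tables, 1
decimal for display) only at the I/O boundary.

The packaged reference table stores the 35 reported compounds with their
*printed* precursor values, which are unit-resolution measurements.
Validation compares them with formula-derived theory at a 0.2 Da bound:
32 of 35 agree within 0.15 Da and three printed values (17:0 dhCA 702.7,
20:3 dhCA 738.7, 22:6 CA 758.7) sit 0.17–0.20 Da above theory, consistent
with unit-resolution rounding of measured peaks. Tightening the bound below
0.2 Da therefore fails honest entries; the screening tolerance itself is a
separate knob.

### Library and matching defaults

| parameter | default | rationale |
|---|---|---|
| chain range | 12–24 carbons | covers every reported acyl (14–22) with margin |
| double bonds | 0–6 | covers 0–6 observed; within ≤6 no two acyls are closer than 1.9 Da, so unit-resolution assignment is collision-free |
| matching tolerance | 0.3 Da | unit-resolution triple-quadrupole data |
| scan window | [600, 1000) m/z, half-open | inclusivity is unstated in practice; half-open keeps binning unambiguous |

Odd chains and polyunsaturated acyls are enumerated uniformly; no
biological plausibility filter is applied (odd-chain C15/C17 species are
real observations). Collisions — multiple library species within tolerance
of one observed pair — are all reported, sorted by |mass error|, never
silently dropped.

## Screening and MRM target selection

Each in-window peak is matched by product channel to a scaffold and by
neutral loss to an acyl; unannotated peaks are retained with an empty
annotation for QC. MRM targets are the most abundant annotated compounds
whose cumulative intensity reaches ≥ 80 % of the total *annotated* ion
count (interpreting "total ion counts" as the class-specific transitions,
not the raw spectrum), unioned with the previously described reference
compounds. The rule runs per bulk sample by default, with target lists
unioned across samples; a pooled mode exists behind a switch since the
operational wording is ambiguous. Ties in intensity break by ascending
precursor m/z so selection is deterministic. Note the rule is *not*
idempotent in the strict sense: a selected set can cover ≥ 80 % of its own
total with a shorter prefix; re-selection never adds compounds and always
returns a prefix of the abundance ranking, and that is the property tested.

Presence classification needs one detection in one sample: a compound seen
only in freshwater samples is classed F, only marine M, both B, so
F + M + B equals the total. Compounds detected nowhere are excluded (they
cannot be classified). The one compound flagged as single-sample is carried
as an output column; no filter uses it.

## Quantification

Single-point external calibration through the origin: amount = area /
(standard area / standard amount), with the same response factor for every
compound (the equal-ionisation-efficiency assumption that a single
authentic standard forces). pmol→ng conversion uses the neutral
monoisotopic mass (precursor − proton); for these ~660–760 Da species the
monoisotopic/average difference is below 0.1 %.

Dry mass comes from power-law length–weight regressions W = a·L^b (W in
µg, L the prosome length in mm, converted from µm input). The shipped
default (a = 30, b = 2.5, taxon "default") is a synthetic placeholder on
the right order of magnitude for adult copepods and is labelled
non-authoritative; real analyses must supply collated per-taxon
coefficients. Content metrics per individual: total pmol, total ng, and
mass fraction in parts per thousand, ppt = total ng / dry mass µg (10 ng in
a 100 µg copepod = 0.1 ppt). The ln–ln allometric regression of total pmol
on dry mass is ordinary least squares, with optional extra covariate (e.g.
handling time); non-positive records cannot be log-transformed and are
dropped with a logged count.

## Statistics

All multivariate machinery is implemented here from first principles;
scikit-bio and vegan-style implementations are used only as independent
oracles in the test suite.

* **Bray–Curtis**: d = Σ|x−y| / Σ(x+y) per compound, computed on relative
  abundances by default. Symmetric, zero diagonal, range [0, 1]; the
  triangle inequality does not hold in general and nothing assumes it.
  A pair of all-zero samples has undefined distance (NaN, warned).
* **PERMANOVA** (one-way): SS_total = Σ d²/n over pairs, SS_within the
  per-group analogue, pseudo-F = (SS_A/(a−1))/(SS_W/(n−a)), R² =
  SS_A/SS_total. p by free label permutation with the observed statistic
  counted in both numerator and denominator, p = (#{F* ≥ F}+1)/(n_perm+1),
  so p ≥ 1/(n_perm+1). When the number of distinct label assignments is
  below the requested permutation count the test switches to exhaustive
  enumeration (p = #{F* ≥ F}/#assignments) — for the 6+4-site design that
  is 210 assignments and a p floor of 1/210 ≈ 0.0048.
* **PERMDISP**: principal-coordinates embedding of the distance matrix
  (Gower-centred −d²/2; negative eigenvalues truncated at zero with a
  warning when substantial), Euclidean distance of each sample to its
  group *mean* (centroids, not spatial medians), ANOVA F on those
  distances, label-permutation p on the distance scores.
* **nMDS**: SMACOF majorisation with Kruskal's primary approach to ties:
  disparities from monotone regression of configuration distances on
  dissimilarities using pool-adjacent-violators with tied blocks averaged.
  Quality is Kruskal stress-1 = √(Σ(d−d̂)²/Σd²), invariant to rotation,
  translation and uniform scaling. Restart 0 starts from the PCoA
  embedding (exact data converges immediately), later restarts are random;
  best final stress wins. The Guttman step guarantees descent of raw
  stress, not stress-1; on the rare stress-1 uptick the previous
  configuration is kept, so the reported history is non-increasing.
  Defaults: k = 2, 4 restarts, 300 iterations, tol 1e-7 on stress change.
* **ANCOVA**: statsmodels OLS with type-II sums of squares for
  response ~ group + covariate; partial η² = SS_term/(SS_term+SS_resid).
  Slope homogeneity is the group×covariate interaction p from a separate
  model; conditional normality is the Shapiro–Wilk test on residuals
  (reported, not enforced — the F tests are robust at the sample sizes
  involved). A single group degrades to simple linear regression; a
  constant covariate is dropped with a warning.
* **Centroid ellipses**: group mean with the ellipse of the centroid's
  standard-error covariance (sample covariance / n) scaled by the χ²(2)
  quantile at the requested level (default 95 %); groups under 3 samples
  get a bare centroid.

Defaults follow the field's conventions: 9999 permutations, α = 0.05,
Bray–Curtis throughout.

## The synthetic-data generator

The generator emulates the study design the statistics expect: 6
freshwater + 4 marine sites, each with one bulk precursor-ion scan and ~12
individually extracted copepods; a calibration standard; and a ground-truth
ledger kept separate from the observables. What it reproduces:

* **Habitat profiles.** Freshwater compositions are ≥ 98 % dhCA by default
  (dhCA-dominance is the defining freshwater feature), with varied
  saturation and odd-chain acyls; marine compositions mix CA/dhCA 40/60
  and lean on long-chain polyunsaturates. Exact fractions are config, not
  claims.
* **Taxon signatures.** Each taxon carries a fixed lognormal reweighting of
  its habitat profile (strength 0.5 by default), seeded from the dataset
  seed and the taxon name only — so the same taxon has the same signature
  at every site, the feature the taxon-consistency analyses look for.
* **Size structure.** Prosome lengths are Gaussian per taxon (0.75–2.5 mm
  across the default taxon pools — small cyclopoids to Calanus), dry mass
  follows the configured power law, and ln(total content) = 0.25 +
  0.3·ln(dry mass) + N(0, 0.5) by default, i.e. larger copepods carry more
  but proportionally less. Per-compound amounts split the total by the
  blended profile and sum to it exactly before measurement noise.
* **Noise.** Lognormal multiplicative noise on intensities and MRM areas
  (σ 0.3 / 0.2 — standard behaviour of MS peak areas), Gaussian m/z error
  (σ 0.02 Da), and uniform background peaks (2 per 100 Da) that avoid
  library masses by twice the screening tolerance. The magnitudes are
  engineering choices; no instrument noise model was available to fit.

One seed drives everything through deterministically derived per-site /
per-individual substreams, so regeneration is byte-identical and partial
regeneration is stable. `SimulationConfig.noiseless()` switches every
stochastic nuisance off, which makes the end-to-end identity — screening
recovers the designed presence matrix exactly; quantification returns the
ledger to float precision — a meaningful test.

What the generator does **not** emulate: chromatographic peak shapes,
retention times, detector saturation, matrix effects, isotope patterns,
adducts beyond [M+H]+, or correlated noise between compounds. Tests passing
on synthetic data therefore demonstrate the correctness of the pipeline's
logic and its statistical calibration, not robustness to those real-data
complications.

## Problem sizes in the routine checks

The statistical calibration studies run at sizes chosen to give decisive
binomial margins: the PERMANOVA null calibration uses 1000 simulated
datasets of 10 samples with exhaustive 252-assignment enumeration each
(expected rejection 12/252 ≈ 0.048); the habitat power study uses 60
replicates of the 5+5-site design; allometric slope recovery uses 100 seeds
at 200 individuals each. The full pipeline checks use 3–12 individuals per
site. All of these complete in seconds to a couple of minutes on one CPU.

## Known limitations

* The length–weight defaults are placeholders; ppt values on synthetic data
  are only order-of-magnitude realistic.
* The published data-dependent statistics (specific p-values, stress
  values, η², regression coefficients) depend on the original raw
  measurements and are not reproduced here; the package reproduces the
  printed chemistry, the reference-table reconstruction, and the
  qualitative statistical findings on synthetic data with matched design.
* PERMANOVA is one-way; nested or multi-factor designs (site within
  habitat) are out of scope, as are alternative dissimilarities and
  constrained ordination.
* Quantification assumes equal ionisation efficiency across homologs, as
  single-standard calibration forces; no LOD/LOQ or matrix-effect
  modelling.
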