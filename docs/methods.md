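# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of the `durumpanel` pipeline.  The package
re-implements, over fully synthetic data with known ground truth, the
analysis chain used for diversity panels of inbred durum wheat: field-trait
derivation → augmented-design BLUPs → structure-aware GWAS → LD-window QTL
hotspots → subpopulation haplotype blocks.

## Trait derivation

Twenty-one traits are derived per plot from raw records (schema in
`plot_records_schema.md`).

* **Phenology** — durations in calendar days between Zadoks stages:
  D_EH = GS55 − GS11, D_HA = GS65 − GS55, D_AM = GS87 − GS65.  Dates are
  integer day offsets from sowing; out-of-order stages are an error,
  missing stages propagate to missing durations.  No thermal-time scale is
  used.
* **Radiation** — a ceptometer triplet gives the intercepted fraction
  IPAR = 100·(PARᵢ − PARₜ − PARᵣ)/PARᵢ (percent, in [0, 100]).  Cumulated
  absorbed PAR over a growth period (cPAR, MJ m⁻²) sums, over the integer
  days of the half-open interval [start, end), the daily IPAR fraction —
  linearly interpolated between sampling days, held constant outside the
  sampled range — times daily incident PAR.  The half-open convention makes
  cPAR exactly additive over adjacent periods.  The interpolation rule is a
  package choice: field protocols sample IPAR roughly every three weeks and
  do not prescribe an integration scheme; daily linear interpolation
  mirrors the rule used for accumulated green area.
* **RUE** = (DMₙ − DMₙ₋₁)/(cPARₙ − cPARₙ₋₁), g MJ⁻¹; undefined (missing,
  logged) when the two cPAR values coincide.
* **CTD** = Tₐ − mean of three canopy readings; positive means the canopy
  is cooler than the air.
* **GA_90d** sums daily linearly-interpolated green area over days 1–90
  from emergence; a single sample degrades to constant extrapolation with
  a warning; samples that all fall after day 90 are an error.
* **Yield components** — NS = spikes / sampled area; NGS = grains/spike;
  W = 1000 · subsample mass / subsample grain count (mg grain⁻¹);
  HI = grain mass / total mass; GFR = W / D_AM; plot yield is scaled to
  kg ha⁻¹ with a configurable multiplicative moisture factor (the 12 %
  standardization is treated as a pass-through because per-plot moisture
  measurements are not part of the record).
* Aboveground dry matter: DM_A from the 0.5 m anthesis cut, DM_M from the
  1 m pre-harvest sample, both divided by sampled area (row length ×
  0.15 m spacing).

Missing-data policy throughout: a missing raw input yields a missing trait
value, never an imputed zero; missing values reach the BLUP step as absent
observations.

## Synthetic panel generator

The generator emulates a 372-entry panel (172 landraces + 200 modern
cultivars) in five admixed subpopulations.

* **Markers** — allocated near-evenly over the 14 durum chromosomes
  (1A–7B), positions uniform on a per-chromosome cM map (default 150 cM),
  ~77.6 % PAVs (coded "1"/"0") and the rest SNPs (homozygous IUPAC letters;
  the panel is inbred, heterozygote codes are accepted on read but never
  generated).
* **Subpopulation frequencies** — Balding–Nichols draws around an ancestral
  frequency p₀ ~ U(0.10, 0.90): p_s ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with
  a divergence parameter F per subpopulation (default 0.10–0.15).  This is
  the simplest standard model producing between-subpopulation
  allele-frequency differences; it makes no claim about the real panel's
  demography.
* **Admixture** — one Dirichlet draw per genotype with concentration
  `admixture_concentration` (default 3.0) on a home subpopulation and 0.35
  elsewhere; landrace homes are the first three subpopulations, modern
  homes the last two.  At the defaults roughly a third of genotypes exceed
  the q > 0.80 assignment threshold, matching the proportion the analysis
  expects (120 of 372).
* **Calls** — one Bernoulli draw per line × marker from the
  admixture-weighted frequency (inbred: a line is homozygous), then
  missingness at the configured rate (default 3 %).
* **Planted structure** — `high_divergence` boosts F at chosen markers;
  `SpPrivateRun` plants a run of consecutive markers fixed for a private
  allele in one subpopulation (frequency 0 there, 1 elsewhere) and
  compresses the run into a tight span (default 1.2 cM) so it behaves like
  a real haplotype block on the map.

## Field-trial generator

Each year lays out every test genotype once plus two replicated checks
after every fifth test entry (the 1:5 check:test ratio), serpentine-filled
into a near-square grid (the grid shape is a package choice; any augmented
layout with the stated ratio is equivalent for the model).  For every
independently measurable trait,

    plot value = baseline + Σ QTL effects · dosage [+ polygenic] + row + col + residual

with independent normal row, column and residual effects (per-trait SDs;
scalar arguments scale realistic per-trait defaults whose baselines sit at
typical Mediterranean durum values, e.g. yield 4 250 kg ha⁻¹ with a
250 kg ha⁻¹ plot residual SD).  The optional polygenic term (default off)
adds a genotype-level normal effect for realistic heritabilities.  The four
ratio traits (GFR, DM_M, RUE_EA, RUE_AM) follow arithmetically from the
others and cannot carry their own QTLs — planting on them raises an error.

**Raw-record inversion.**  The generator works backwards from each plot's
target trait values to raw measurements so that running the derivation step
reproduces the targets exactly (to float round-off) when noise SDs are
zero:

* phenology targets are rounded to whole days (each period ≥ 1 day) and
  the truth table records the rounded values;
* per growth period the IPAR fraction is constant at
  cPAR_target/(incident · days), emitted as PAR triplets at fractional
  sample days straddling the period boundaries so integer-day
  interpolation returns the period constant exactly (interior samples
  every ~3 weeks keep the cadence realistic); fractions are clipped to
  [0.001, 0.97], which only binds for extreme noise draws;
* green area is a constant profile GA_90d/90 sampled every 14 days;
* canopy temperatures are three identical readings at Tₐ − CTD;
* the harvest sample is reconstructed from NS, NGS, W and HI (counts kept
  as floats), which makes DM_M = total sample mass / area a derived value;
* plot yield mass = Yield · area / 10⁴ at moisture factor 1.

The truth table stores the realized per-plot targets and the per-year
genotype genetic values.

## Augmented-design REML/BLUP

Single year: y = μ + check + u_genotype + u_row + u_col + e with check
cultivars fixed and independent random intercepts for genotype (test
entries only), row and column — no spatial correlation beyond that.
Across years: year joins the fixed effects, genotype stays a single random
effect across years, row/column effects are nested within year, and a
genotype×year interaction component is added.  The across-year joint fit
(rather than averaging per-year BLUPs) is the package's choice because it
uses all data and handles imbalance; averaging is available via
`combine_years(method="average")`.

REML profiles out the residual variance and maximizes the restricted
likelihood over the variance ratios γᵢ = σᵢ²/σₑ² with L-BFGS-B under
γᵢ ≥ 0 (components are clamped non-negative by construction; convergence
tolerance 1e-10 on the profiled deviance).  Each evaluation builds
V₀ = I + Σ γᵢZᵢZᵢᵀ densely and factorizes it — exact and fast to a few
thousand plots, which covers the emulated design (~450 plots/year, ~1 350
across years).  BLUPs solve the mixed-model equations at the estimates;
the reported genotypic value is the mean fixed-effect prediction over test
plots plus the genotype effect.  Perfectly noiseless data (residual
variance ≤ 1e-10 of the total) short-circuits to fixed-effect-adjusted
genotype means, the exact BLUP limit, instead of factorizing an
ill-conditioned V.  A fit with no replicated check is refused: without
replication the residual and genotypic variances are not separable.

## Structure analyses

Assignment uses strict q > 0.80 (a genotype exactly at the threshold stays
admixed).  The structure regression drops one q column (rows sum to one)
and reports OLS R² per trait; R² is invariant to the dropped column.  The
partitioned ANOVA splits the genotype sum of squares into between-group
and within-group parts and tests F = MS(between)/MS(genotypes within
groups) — the within-group genotypic variance is the error term, so no
mixed-model degrees-of-freedom correction is involved.  Tukey–Kramer
letters use the studentized range with df = N − k and the unbalanced-n
standard error; letters come from exhaustive maximal non-significant
subsets (group counts are small), so the display can never contradict a
pairwise decision.  Trait PCA eigendecomposes the correlation matrix with
the sign convention that each loading vector's largest-magnitude element
is positive; Ward clustering runs on standardized traits; correlations are
pairwise-complete Pearson.

## GWAS

* **QC** order: MAF < 5 % → missingness > 30 % → exact duplicate call
  vectors (the earlier marker in map order is kept); each marker is
  counted once, in the first rule that removes it.
* **Dosage** coding: PAV 1/0 directly; SNPs 0/1 by minor-allele presence
  (ties to the lexicographically smaller base); heterozygote codes count
  0.5 with a warning; missing dosages are marker-mean imputed both for K
  and in the scan, so every genotype contributes to every test.
* **Kinship** is the VanRaden-style centered cross-product scaled by
  Σ2p(1−p).  Tools differ in kinship flavor (centered-IBS is common); the
  choice only rescales σᵤ² and does not change the tests' calibration.
* **Scan**: y = Xβ + Zu + e with X = [1 | 6 genotype PCs | marker dosage],
  u ~ N(0, σᵤ²K).  Variance components are estimated once per trait×scope
  by 1-D REML over h² = σᵤ²/(σᵤ²+σₑ²) in the eigenbasis of K (bounded
  search, explicit boundary check at h² = 0) and reused for every marker —
  the P3D/EMMAX convention; `p3d=False` refits per marker for small
  panels.  The marker coefficient is tested by weighted least squares in
  the rotated space against t with n − p df; with ĥ² = 0 this reduces
  exactly to the plain fixed-effects regression test.  No compression /
  genotype clustering is applied: compression is a speed approximation of
  the individual-level model, and the uncompressed model is exact.
* **Significance**: suggestive threshold −log10 p ≥ 3, applied per
  trait×scope family; Benjamini–Hochberg FDR flags at q = 0.05 per family
  (per-year scans are separate families, matching per-year MTA
  accounting).

One caveat observed in calibration: when K ≈ c·I plus a few structured
directions that the PCs already span, the restricted likelihood in h² is
nearly flat and the estimate can land anywhere on [0, ~0.5) for an
unstructured phenotype.  This does not affect calibration (the flat
directions change all marker tests identically) but means the OLS
equivalence holds exactly only when the estimate hits the boundary.

## Hotspots and haplotype blocks

MTAs are chained per chromosome by single linkage at the 1 cM LD-decay
window with transitive closure, so a chain of sub-window steps can produce
a block much wider than 1 cM.  A block is a QTL hotspot when it holds ≥ 2
MTAs from ≥ 2 distinct trial years; across-years-scope MTAs do not count
toward the year requirement (configurable).  Hotspots are numbered per
chromosome in ascending cM order ("2A.1", "2A.2", …).

Within a hotspot, the modal allele per marker × subpopulation is computed
over assigned genotypes; a major allele below 60 % frequency (or with no
calls) is NA — a 50/50 tie can therefore never be called.  A marker
differentiates when at least one subpopulation's called allele differs
from the called allele of every other *called* subpopulation (a marker
with fewer than two called subpopulations cannot differentiate); an HB is
a maximal run of consecutive differentiating markers sharing the same
differentiating set, with no minimum length by default.  Contiguity in map
order is assumed.  HBs inherit trait links from MTAs on their own markers,
falling back to hotspot-level traits flagged as indirect.

Because differentiation is judged against *called* subpopulations, raising
the calling threshold is guaranteed to shrink the differentiating-marker
set only for one-subpopulation-private variation (the pattern the rule
targets); with balanced multi-way patterns, silencing one subpopulation
can create a new 1-vs-1 contrast.  The property suite exercises the
monotone regime.

## Standing studies and problem sizes

`durumpanel.studies` fixes the package's three standing experiments, which
both the acceptance script and the test suite run:

* **Type-I calibration** — 300 genotypes, ~2 200 markers at F ≈ 0.15, trait
  = linear function of q + unit noise (no causal marker); the PCA + K scan
  must hold its empirical size at α = 0.05 within 3 binomial SDs while the
  unstructured scan is inflated several-fold.
* **Power** — the same panel scale, a planted additive QTL of one
  phenotypic SD at n = 300, 100 replicates, detection at −log10 p ≥ 3;
  plus a two-year planting whose per-year MTAs must chain into a called
  hotspot.
* **End-to-end round trip** — 150 genotypes, 400 markers, three noise-free
  trial years, QTLs on Yield and W, and a 4-marker SP3-private run: trait
  derivation must reproduce the truth table to float precision, BLUPs the
  planted genotypic values, the scans the causal markers in every year,
  and the haplotype step exactly the planted run with SP3 differentiating.

These sizes (and the 3 000-marker panel in `analysis/`) are scaled-down
emulations of the 46 k-marker study design; the package's algorithms are
exact, so scale only affects runtime and Monte-Carlo precision.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the pipeline assumes:
admixed subpopulations with frequency differentiation, an unreplicated
augmented layout with row/column noise, additive QTLs, and raw records
consistent with their derived traits.  It deliberately omits
linkage-disequilibrium decay along the map (LD enters only through the
1 cM chaining rule), epistasis, G×E beyond year-specific QTL activity,
spatially correlated field trends, assay artifacts, and any real weather
or soil signal.  Passing tests therefore demonstrate correctness of the
implementations and calibration under the stated model — not robustness to
real-data violations of it.
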