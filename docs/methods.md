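# Methods

This note records the models, conventions and design choices behind
`lipichrom`, and what the shipped tests do and do not establish.

## Index arithmetic

**CHI calibration.** The Chromatographic Hydrophobicity Index is defined
operationally: gradient retention times of a standard mixture with known
CHI values are regressed on retention time (ordinary least squares, via
`scipy.stats.linregress`), and analyte retention times are mapped through
the fitted line. The nominal scale is 0–100 but extrapolation is
physically meaningful for very lipophilic analytes and is permitted;
`apply_calibration` flags any value outside the nominal range rather than
clipping it. At least two standards with distinct retention times are
required; the standards' literature CHI values must be supplied by the
user (an example standards file would be instrument-specific, so none is
treated as authoritative).

**CHI → CHI LogP.** The linear map `CHI LogP = 0.054·CHI − 1.467` is
applied to CHI measured on the nonionized form — for a basic library, the
pH 10.6 run. The slope and intercept are treated as given constants of
the protocol, not refit. A rounded variant (2 decimals) exists solely for
reproducing printed tables; computation always uses the unrounded value.

**%HSA ↔ logK_HSA.** The plasma-protein-binding transform is
`logK = log10(pct / (101 − pct))` with inverse
`pct = 101·10^logk / (1 + 10^logk)`. The 101-denominator form is the one
used in biomimetic HSA chromatography and is verified by a shipped test to
reproduce every non-censored pair in the bundled table to 2 decimals; a
100-denominator variant misses the high binders by ~1%. The inverse can
exceed 100% for strong binders (logK ≳ 2.0); such values are not
quantitatively meaningful and are reported censored as ">99.8"
(`format_pct_hsa`). One bundled compound (18, logK_HSA = 2.27) carries a
censored %HSA cell for exactly this reason; it is stored as
censored-above at 99.80, preserving the monotone %HSA–logK relationship
without inventing a value.

**Rounding.** Table reproduction uses round-half-away-from-zero at 2
decimals (the convention of printed index tables), implemented with
`decimal` to avoid float-tie artifacts. Python's built-in banker's
rounding is never used for reporting.

**Acid/base calls.** Ionization suppresses reversed-phase retention, so
the CHI profile across pH 2.6 / 7.4 / 10.6 encodes acid/base character.
Define the acid-end suppression `s_a = CHI(7.4) − CHI(2.6)` and the
basic-end suppression `s_b = CHI(7.4) − CHI(10.6)`. With threshold *t*
(default 10 CHI units, configurable — the protocol offers no number, only
"significantly lower"):

- **basic** if `s_a > t` and `s_b ≤ t`;
- **acidic** if `s_b > t` and `s_a ≤ t`;
- **neutral** if neither suppression exceeds *t*;
- both exceed *t*: the dominant suppression decides, and the call is
  flagged ambiguous (zwitterionic pattern).

The conditions are deliberately one-sided: a compound whose CHI *rises*
from pH 7.4 to 10.6 (a strong base still partly ionized at 7.4 — two
bundled compounds show this by ~12 CHI units) has negative `s_b` and is
classified basic, not ambiguous. A symmetric "CHI(7.4) ≈ CHI(10.6)"
condition would misread exactly the strongest bases. On the bundled
library the rule calls 25 of 26 compounds basic; compound 8's printed
pH 2.6 CHI (97.99) sits within 3.4 units of its pH 7.4 value, so it is
honestly neutral under any threshold near the default — the package
reports what the numbers say rather than forcing the expected blanket
conclusion (the value is a wild outlier in its column and may simply be a
misprint).

## Descriptor pre-filtering

Molecular descriptors arrive as an externally computed compounds × names
matrix (descriptor computation itself — AlvaDesc, Chemicalize, SwissADME,
geometry optimization — is out of scope). Pre-filtering:

1. **(Near-)constant removal** — columns with zero variance, or whose
   modal value covers ≥ 95% of compounds (configurable; 0.95 is the
   conventional descriptor-software default, since "almost constant" has
   no standard definition).
2. **Correlation pruning** — for every pair with |Pearson r| ≥ 0.95, the
   later column in matrix order is dropped; earlier columns always
   survive. Absolute correlation is used (a descriptor and its negation
   are equally redundant) and keep-first-in-order is the tie-break,
   chosen for determinism; after the scan no surviving pair violates the
   threshold (asserted by exhaustive pair scan in tests).
3. **Standardization** — column z-scores (ddof = 1), required before
   clustering and advisable before regression across heterogeneous
   descriptor blocks.

Missing entries are rejected at load, never silently imputed.

## GA-MLR descriptor selection

Chromosomes are descriptor subsets of exactly `model_size` (default
exploration 1–3; three-descriptor models are the practical ceiling for
~19 training compounds). Defaults mirror the QSARINS-style protocol:
population 10, 500 generations per model size, mutation "rate 20"
interpreted as a 0.20 per-gene replacement probability (the percentage
convention). Operators: size-2 tournament selection, uniform crossover
implemented as sampling the child from the parents' gene union repaired
to fixed size, per-gene mutation to a random non-member, and elitism
(best individual carried forward), which makes best-so-far fitness
non-decreasing. The exact operators of the original selection software
are not published; these are standard choices and are configurable.

**Fitness** is leave-one-out Q² of the OLS fit on the *training*
compounds only (R² available as an alternative); validation data never
touch selection. Q² is computed by the exact hat-matrix shortcut
(PRESS residual = residual/(1 − leverage)), so each subset costs one
least-squares solve; fitness values are cached per subset, bounding the
cost of a run by the number of distinct subsets visited. Singular designs
get fitness −∞.

**Train/validation split** (default 19/7 as used with 26-compound
libraries): the default "systematic" strategy ranks compounds by response
and sends every (n/n_val)-th rank to validation, spreading the validation
set across the response range; a seeded random strategy is available. The
systematic split is a reconstruction of common practice, not a published
membership list.

**MLR fitting** solves the normal equations by `numpy.linalg.lstsq`
with an explicit intercept column; coefficient uncertainties are the
usual standard errors from σ²(XᵀX)⁻¹ with n − p − 1 degrees of freedom
(cross-checked against `statsmodels` OLS in the test suite). Rank
deficiency raises an error naming the collinear columns (pivoted QR
diagnosis).

## Validation statistics and applicability domain

On the training set: R², RMSE_tr, Q²_LOO (both literal-refit and
hat-matrix routes are implemented and must agree to 1e−8 — a two-oracle
consistency check shipped as a test). On the external set: R²_EXT,
RMSE_P, and Lin's concordance correlation coefficient
`CCC = 2·cov(o,p) / (var(o) + var(p) + (mean(o) − mean(p))²)` with sample
(n-denominator) moments, the standard Lin definition. RMSE uses the
n-denominator by default (the convention of QSAR reporting software),
with an n − p − 1 variant available since published tables rarely state
which was used.

Applicability domain: leverage `h_i = x_iᵀ(XᵀX)⁻¹x_i` with the intercept
column included (training leverages therefore sum to p + 1, and a point
at the descriptor centroid has leverage 1/n), critical leverage
`h* = 3(p+1)/n_train`, standardized residuals = residual / RMSE_train,
outside-domain iff `h > h*` or |standardized residual| > 3. These
cut-offs are the conventional Williams-plot choices. An optional plot
(leverage vs standardized residual, training/validation distinguished,
h* and ±3 lines) is produced with matplotlib.

## Chemometric scale comparison

The objects compared are the *index columns* (lipophilicity scales and
chromatographic indices), each represented by its standardized vector of
values over the compounds; compounds-as-objects clustering is available
as an option. Hierarchical clustering uses Ward linkage on Euclidean
distances (`scipy.cluster.hierarchy`, i.e. the Ward.D2 convention —
Euclidean input with squared update — the common modern reading of
"Ward's rule"); merge heights are monotone non-decreasing. PCA is
SVD-based on standardized columns, with orthonormal loadings and a fixed
sign convention (largest-magnitude loading element positive) for
reproducibility; a full-rank reconstruction identity and a
loadingsᵀ·loadings = I check pin the implementation. The minimum-
descriptor census counts, per scale, the compounds for which that scale
gives the smallest LogP, splitting exact ties fractionally so counts
always sum to the compound count (no ties occur in the bundled data; the
census there is MLogP 16, Silicos-IT 10).

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, as pure functions of their parameters and a seed:

- **Descriptor matrices**: standard-normal marginals (real descriptor
  blocks are heavier-tailed; a lognormal mode exists but normality keeps
  the exhaustive-search oracles exact and simple), optional within-pool
  equicorrelation via a shared latent factor, and a planted sparse linear
  response `y = β₀ + Σ βⱼxⱼ + N(0, σ)`. Default shape 26 × 200 — the
  library size of the reference campaign with a descriptor pool small
  enough that exhaustive subset enumeration remains feasible as a test
  oracle (a realistic pruned pool is ~3 000 columns; nothing in the
  implementation depends on the pool size). Default noise σ = 0.5
  response units, a signal-to-noise ratio comparable to a well-fitting
  QSRR model.
- **Calibration runs**: uniform retention times over a configurable
  window (default 0.5–5 min, a fast-gradient elution window) with
  Gaussian index noise.
- **Index tables**: groups of equicorrelated columns
  (`x = √r·latent + √(1−r)·ε`), emulating the computed-vs-experimental
  two-block structure.

What passing on synthetic data shows: the selection machinery finds
planted optima (GA best = exhaustive best on enumerable pools; a planted
2-descriptor signal among 100 decoys is recovered at n = 26, σ = 0.5)
and the statistics are internally consistent. What it does not show:
performance under heavy-tailed, blockwise-redundant real descriptor
distributions, or that any particular real model is correct.

## Numerical choices and degenerate inputs

- Calibration with < 2 standards or all-equal retention times: error.
- Two-point calibration: exact line, r² = 1.
- %HSA domain strictly (0, 101); endpoints rejected.
- Q²_LOO requires n > p + 2 and finite leverages (< 1); a leverage of 1
  means a compound its own sole determinant and is rejected.
- R² undefined for a constant observed response: error, not NaN.
- Fitness caching keys are sorted index tuples, so subset identity is
  order-free.
- GA reproducibility: a single `numpy.random.Generator` seeded from the
  config drives initialization, selection, crossover and mutation.

## Known limitations

- The bundled library is small (26 compounds) and chemically homogeneous
  (organic bases); the acid/base classifier's default threshold has been
  exercised mainly on that regime.
- Censoring is handled for the one pattern that occurs (%HSA bounded
  above); there is no general censored-data machinery.
- The GA explores fixed-size subsets; it does not trade off model size
  within a run (run it per size and compare, as the validation battery
  supports).
- No y-scrambling or bootstrap validation is implemented.
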