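# Methods

This note documents the statistical procedures, the numerical choices and
the synthetic-experiment model behind `spentmed`, in the order the
pipeline runs them.

## Significance-gated fold changes

For each metabolite *m* and isolate *r*, the relative fold change is

    FC_m,r = mean(spent replicates) / mean(matched control replicates) − 1

and is reported only when the comparison is significant at level `alpha`
(default 0.05); otherwise it is exactly 0. The gate keeps replicate noise
out of the downstream utilization profiles: a non-significant cell cannot
contribute to any overlap or diversity computation.

Comparison families are formed **per control group and per metabolite**:
all isolates sampled against the same uninoculated control (early control
for fast growers, late control for slow growers, supplied explicitly in
the sample metadata as `control_group`) form one Dunnett many-to-one
family for each metabolite, controlling the familywise error across
isolates that share a control. The alternative family layout (per isolate
across metabolites) was considered and rejected: the shared-control
structure is what induces dependence between comparisons, while
metabolites are measured on distinct chromatographic peaks.

Tests run on raw peak heights by default; `log_transform=True` tests
log10(height + 1) instead (the fold change itself is always computed from
raw group means). Missing heights are empty cells, never zeros; the
default policy drops a metabolite with any missing value, and
`missing_policy="impute"` substitutes half the metabolite's observed
minimum instead.

Degenerate cells: a control mean of exactly 0 with nonzero spent signal
leaves the ratio undefined — the cell is flagged, not forced. Groups whose
pooled variance is zero to rounding fall back to an exact-equality rule
(p = 1 if the means agree, else 0), so noiseless data gate cleanly.

## Dunnett p-values by exact quadrature

Many-to-one comparisons against a shared control have test statistics with
product-structure correlation ρ_ij = λ_i λ_j, λ_i = √(n_i/(n_i+n_c)).
Conditioning on the standardized control mean *z* and the pooled
standard-deviation factor *u* = s/σ (ν u² ~ χ²_ν) factorizes the joint
two-sided probability into a product of normal interval probabilities, so

    p_j = 1 − P(max_i |T_i| ≤ |t_j|)

is a two-dimensional integral evaluated with Gauss–Hermite (64 nodes in
*z*) × Gauss–Legendre (40 nodes in *u*) quadrature. For batches of more
than 384 statistics sharing one family design, the smooth monotone CDF is
evaluated on a 384-point grid and cubic-spline interpolated. Agreement
with `scipy.stats.dunnett` (randomized-QMC multivariate *t*) is within
~2·10⁻⁴ on random families; unlike the QMC route the quadrature is
deterministic and its cost is flat in the number of groups, which matters
for background filtering where a single family can hold 60+ sample groups.

## Utilization profiles and metrics

Depletion fractions are p_m,r = −FC_m,r where FC < 0, else 0; production
is excluded from the profile. Three per-isolate summaries:

- **richness** — count of substrates with p_m,r > 0;
- **abundance** — 100 · Σ_m p_m,r (percent units, so one fully depleted
  substrate contributes 100);
- **diversity** — inverse Simpson index D = 1/Σ_m π_m² with π_m the
  depletion fractions normalized over the significant support. D = 1 for
  single-substrate use, D = richness for perfectly even use, and is
  reported missing on an empty support. Normalizing over the support is
  the standard construction and makes D invariant to common rescaling of
  the profile (fractions vs. percentages).

## Predicted interactions and competitive ranks

    PIS_ri = − Σ_m p_m,r p_m,i / Σ_m p_m,r²     (≤ 0)
    R_r    = Σ_{i≠r} (PIS_ri − PIS_ir)           (Σ_r R_r = 0)

PIS is 0 iff the two supports are disjoint, −1 when the influencer's
profile matches (or covers, in the normalized sense) the recipient's, and
is invariant under common positive rescaling of all profiles. Recipients
with empty support make the defining ratio 0/0; their rows are flagged
undefined and excluded from ranking rather than set to 0 — isolates that
grow too poorly to profile should drop out of the analysis, not enter it
as zeros. The diagonal is excluded from both sums ("all the *other*
isolates"). Ranks are reported unnormalized; no per-partner normalization
is applied. Substrates are treated as equally important and independent —
no weighting by substrate identity or growth value is attempted.

The PIS heatmap ordering uses average-linkage clustering on Euclidean
distances; this is presentation only and no analysis depends on it.

## Growth analysis

Logistic fits use N(t) = K / (1 + ((K−N0)/N0) e^(−rt)) with least squares
(`scipy.optimize.curve_fit`), initialized at N0 = first observation,
K = max observation and r from a log-linear regression on the early phase,
with bounds K ∈ (0, 10·max], N0 ∈ (0, max], r ∈ [10⁻⁴, 20] h⁻¹. Doubling
time is ln 2 / r. A series whose total rise is below 0.02 OD is flagged
no-growth and left unparameterized; non-convergence is reported, never
silently defaulted.

Growth metrics entering MIS:

- **final OD** — mean of the series' last time point minus the matched
  uninoculated-medium control at the same time, clamped at 0 (the clamp
  preserves MIS ≥ −1 after blank correction);
- **cumulative respiration** — (A570 initial − final) of the sample minus
  the mean drop over uninoculated controls of the same medium, clamped
  at 0 for the same reason.

MIS_ri = mean growth in spent medium / mean growth in fresh medium − 1,
per recipient, with one Dunnett family per recipient (its spent media
against its fresh-medium reference). Insignificant entries are retained
but flagged, mirroring how weak edges are usually drawn dashed rather than
dropped. Control correction uses the mean over control replicates; per-well
pairing is not attempted because the plate layout is not part of the data
model.

## Untargeted features and cross-feeding

Background filtering keeps features significantly **higher** than the
extraction blanks in at least one replicated sample group (one Dunnett
family per feature over all biological groups; direction read from the
mean). Production calls compare each isolate's spent medium against its
matched defined-medium control among retained features.

Cross-feeding classification tests two legs per (influencer i, recipient
r) pair and feature: leg 1 = spent_i vs. defined-medium control; leg 2 =
double_spent_ri vs. the abiotic (uninoculated, incubated) spent-i control
when present, else the spent_i samples themselves. Leg tests are two-sided
Welch t-tests with direction from the sign of the mean difference;
"unchanged" iff p > alpha. Classes are assigned with this precedence, which
makes them mutually exclusive and exhaustive:

1. `cross_fed` — up on leg 1 and down on leg 2;
2. `sequentially_depleted` — down on both legs;
3. `recipient_produced` — up on leg 2 (any leg-1 outcome not already
   cross_fed);
4. `produced_not_consumed` — up on leg 1 with leg 2 unchanged;
5. `unchanged` — everything else (including down-then-unchanged).

Only the first two classes are biologically canonical (cross-feeding;
sequential depletion as competition evidence); the remaining three are
closure classes defined by this package so that per-pair percentages sum
to 100. A leg-2 decrease does not need to return the feature to its
pre-influencer baseline — any significant decrease counts. Ionization
modes are analyzed as separate tables and can be averaged downstream.

## Synthetic experiments

The generator emulates the experimental design end to end with known
ground truth; its defaults describe the reference community used
throughout the tests:

| parameter | default | meaning |
|---|---|---|
| isolates / metabolites | 8 / 60 | community and tracked-panel size |
| archetypes | half generalist, half specialist | support 2/3 vs. 1/6 of the panel; fractions U(0.3, 1) vs. U(0.1, 0.7) |
| replicates | 3 | spent, controls, blanks, growth |
| noise | log-normal, cv = 0.1, mean-one | multiplicative replicate noise |
| baselines | log-normal, median 10⁵, σ_ln = 1.15 | ~2 orders of magnitude across metabolites |
| blank floor | 50 | extraction-control background |
| secretion | 6 features/isolate, amounts ~10⁵·lognormal(0, 0.5) | consumable by other isolates w.p. 0.3; consumed fraction 0.9 |
| growth | logistic; K = N0 + yield · Σ consumed; yield U(0.010, 0.030) OD/unit; r U(0.4, 0.7) (generalists) or U(0.15, 0.35) h⁻¹; N0 = 0.01 | sampled every 0.5 h for 48 h |
| respiration | drop = 0.02 + resp_frac · consumed · 0.02; resp_frac U(0.2, 0.5) | A570 from 1.0; uninoculated drift 0.02 |

Spent peak expectation is baseline · (1 − C[i,m]); double-spent multiplies
by (1 − C[r,m]) again; consumable secreted features lose 90% of their
amount to the recipient and the recipient's own secretions are added.
Sequential growth is linear in total substrate obtained (residual
metabolites plus consumable secretions), so the ground-truth interaction
strength is −Σ_m C_r C_i / Σ_m C_r for pure competition and can be
positive when secretion exceeds substrate loss (facilitation). With
`n_secreted_per_isolate = 0` the community is pure competition and every
true interaction is ≤ 0.

What the generator does **not** emulate: substrate kinetics (no Monod
terms or stoichiometry), diauxie or substrate preference ordering,
metabolite degradation in controls, retention-time drift, ionization
suppression, or missing peaks. Passing recovery tests therefore show that
the statistical chain is correct under multiplicative replicate noise and
the linear yield model — not that it is robust to every artifact of real
LC-MS data.

## Problem sizes and tolerances in the test suite

Recovery tests use the reference community (8 isolates × 60 metabolites,
triplicates): noiseless runs must recover the consumption matrix to
machine precision (≤ 10⁻¹²); at cv = 0.1, fractions ≥ 0.3 must be detected
with sensitivity ≥ 0.9 and median absolute error ≤ 0.1 (medians over 10
seeds). Logistic recovery uses the canonical (K, r, N0) = (1.2, 0.6, 0.02)
curve: 10⁻³ relative noiseless, ≤ 10% median relative error at 5% noise
over 20 seeds. The competition-structure test requires ≥ 90% of
significant measured interactions negative in a pure-competition community
and a median predicted-vs-measured Pearson r > 0.4 over 10 seeds. The
cross-feeding recall test plants changes that are at least 3-fold on the
weaker leg (secretion amount 5× the blank floor, consumed fraction 0.8)
and requires recall ≥ 0.8 at cv = 0.1, perfect precision and recall at
cv = 0. These sizes keep the whole suite under a minute while leaving
each statistic comfortably powered.

## Known limitations

- The Dunnett quadrature assumes homoscedastic groups within a family
  (the classical test's assumption); strongly heteroscedastic peak
  heights are better served by the log10 transform switch.
- Fold changes use replicate means; no shrinkage or variance moderation
  across metabolites is applied.
- The untargeted taxonomy's closure classes absorb alpha-level false
  positives on the second leg (a non-planted feature has a ~2.5% chance
  of a spurious "down" call per pair at alpha = 0.05); interpret per-pair
  cross-feeding percentages with that base rate in mind.
- Group-level inferential statistics on real study designs (ANCOVA,
  PERMANOVA, post hoc letters) are out of scope; the pipeline emits tidy
  tables suitable for those analyses in external tools.
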