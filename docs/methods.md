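# Methods

## The model

The hematopoietic stem-cell compartment is modelled as a Moran process on
a fixed population of N cells. At each iteration one cell is chosen to
divide with probability proportional to its fitness (f_i / Σ_j f_j) and
one cell is chosen to die uniformly (probability 1/N); divider and dier
may coincide, so every iteration — including such self-replacements —
advances the clock by one unit. Calendar time attaches by assuming the
whole compartment turns over in 1/(division rate), so one iteration spans
1/(division rate · N) years.

With a single mutant type of relative fitness r against wild-type fitness
1, the process reduces *exactly* to a birth–death chain on the mutant
count k with absorbing states 0 and N:

    p_up(k)   = [r k / (r k + N − k)] · [(N − k)/N]
    p_down(k) = [(N − k) / (r k + N − k)] · [k/N]

so p_up/p_down = r at every interior state. All production simulation runs
on this reduced chain; the literal N-cell implementation (explicit fitness
vector, divider sampled by fitness, dier uniformly) is distributionally
identical and kept only as a small-N test oracle (N ≤ 64), because the
reduction is exact and orders of magnitude faster.

### Fixation probability

For a single founder the takeover (fixation) probability is the standard
birth–death hitting probability φ = (1 − 1/r)/(1 − 1/r^N), φ = 1/N when
r = 1; general starting counts use the ratio of partial geometric sums.
It is evaluated via `expm1` identities in log-r space so that values
remain accurate for r within 10⁻⁷ of 1 and N above 10⁶.

### Conditional fixation time, exactly

The quantity of biological interest is the expected number of iterations
for a clone that *does* take over — the fixation time conditioned on
fixation, since a barely-advantageous founder usually goes extinct. The
exact value comes from first-step analysis on the Doob h-transform of the
k-chain: conditioned transition probabilities p̃_up(k) = p_up(k)·φ(k+1)/φ(k)
and p̃_down(k) = p_down(k)·φ(k−1)/φ(k) (the k = 1 → 0 move vanishes because
φ(0) = 0), giving a tridiagonal linear system solved with a banded solver.
Self-replacement iterations are counted (they carry p̃_stay = p_stay and
add to the expected time through the diagonal). The solver is limited to
N ≤ 2,000 — far above the accuracy cross-check range and well below memory
limits, but large N is better served by the closed form below. An
unconditional absorption-time solver is included for comparison only.

### Closed-form fixation time

For large compartments the conditional fixation time of an advantageous
single founder (r > 1) is evaluated with

    T(N, r) = N · ln N · (r + 1)/(r − 1)   iterations,

the deterministic-sweep approximation obtained by integrating the expected
per-iteration frequency change E[Δx] = (r − 1)·x(1 − x)/(N·(r x + 1 − x))
from x = 1/N to 1 − 1/N. The formula demands r > 1 and one founder;
neutral or deleterious clones raise a domain error ("no takeover
predicted" at the reporting layer), since their conditional times are
governed by different asymptotics and, biologically, such clones are not
expected to fix.

Which expectation does it approximate? The approximation-quality report
(`fixation.approximation_quality_report`) computes its signed relative
deviation from both exact solvers over N ≤ 500, r ∈ [1.1, 2]: the
deviation from the *conditional* time is uniformly the smaller one, is
positive (the sweep formula overshoots because it linearises the
stochastic boundary layers), and decreases smoothly and monotonically in
both r and N — from ≈ +42% at (N = 500, r = 1.1) to ≈ +2% at (N = 500,
r = 2), with no sign changes. The closed form therefore approximates the
conditional fixation time, with relative error shrinking like
1/((r − 1)·ln N). Because the with/without-CXCL8 comparison is a ratio of
two such times at the same N, much of this bias cancels in the
speedup factor.

### Default method switching

`fixation_years(..., method="auto")` uses the exact conditional solver up
to N = 2,000 and the closed form above it; Monte-Carlo (`method="mc"`) is
available as a spot check at any N where runtime permits.

## Growth rates and relative fitness

Cultures are summarised by an exponential model. The default convention
is the daily fold change g = (C_t/C₀)^(1/t_days): a non-growing culture
has g = 1, and the healthy-marrow cohort means the generator targets
(≈1.54/day without CXCL8, ≈1.17/day with 10 ng/mL CXCL8) correspond to
1.6–3.7-fold expansion over the 72-hour culture. An exponential
rate-constant convention g = ln(C_t/C₀)/t_days is selectable in the
configuration; it changes units, not ordering. Estimation defaults to the
two endpoint counts (matching a day-0/day-3 design); a log-linear
least-squares fit across all timepoints is available when more are
present. Rates are invariant to rescaling all counts (only the ratio to
the seed enters).

Relative fitness is the ratio of a sample's rate to the *arithmetic mean*
rate of the healthy samples cultured under the same CXCL8 condition —
condition mismatches are errors, not warnings, because CXCL8 changes the
denominator by ~25%. The advantageous subset uses the strict inequality
r > 1; samples exactly at the healthy mean are not eligible for the
fixation formula. The fitness report carries min/max over all CMML
samples and over the advantageous subset separately, since the two
conventions give slightly different lower ends on real cohorts.

The per-sample CXCL8 scenario (`fixation_for_sample`) takes one measured
CMML growth rate and normalises it by each condition's healthy mean:
CXCL8 suppresses wild-type but not CMML cells, so the mutant rate is
unchanged while its relative fitness rises, shortening the predicted
takeover. The pipeline's per-sample scenarios instead use each
condition's own measured rate when both are present (required for exact
recovery of generator truth); the two coincide whenever the CMML rate is
condition-independent.

## Synthetic cohorts

The generator emulates the study design the estimators assume: 3 healthy
donors and 19 CMML patients per CXCL8 condition, 72-hour cultures seeded
at 0.75 × 10⁵ cells/mL, counted at 0 and 72 h. Healthy rates are drawn
per condition from a normal distribution truncated at zero (defaults
1.54 ± 0.09 and 1.17 ± 0.13 per day; the ± values are treated as SD — if
they are instead SEM of n = 3 the spread is understated, which only makes
the recovery tests easier, and both are exposed in the configuration).
Each CMML sample draws one relative fitness uniformly from [1.08, 1.67]
and its rate under each condition is that fitness times the condition's
mean healthy rate, so generating fitness is recoverable exactly from
noise-free data and the truth table needs no re-derivation.

Counts carry independent multiplicative lognormal noise per post-seed
timepoint, parameterised by its coefficient of variation (default
CV = 0.1, a typical hemocytometer/Trypan-blue counting variability);
counts are therefore always positive and error scales with magnitude.
The time-0 count is the seed density exactly.

What the generator does *not* emulate: death/apoptosis as a process
separate from net growth, saturation or medium exhaustion (the growth law
is purely exponential over 72 h), inter-replicate correlation within a
donor, and any CXCL8 dose–response (conditions are categorical). Passing
recovery tests therefore show the estimators are correct under the
exponential-growth, independent-noise model — not that real cultures obey
it.

## Sensitivity analysis

The sensitivity grid evaluates fixation years over (r, N, division rate)
— defaults r ∈ (1, 2] in steps of 0.05, N ∈ {25,000; 100,000; 1,300,000},
division rate 1/year — and reports |dT/dr| by central finite differences
(one-sided at the edges). Because T ∝ (r + 1)/(r − 1), |dT/dr| ∝
2/(r − 1)², so sensitivity is maximal just above r = 1 for every N and
division rate: in the empirically observed fitness range (all measured
CMML fitness < 2) fixation times respond far more strongly to fitness
changes than anywhere else, which is what makes the CXCL8-induced fitness
shift consequential.

## Numerical and design choices

- **Iteration accounting.** Self-replacement events count as iterations;
  simulators collapse runs of stays into a single geometric draw
  (exact in distribution, large speedup for large N where p_stay → 1).
- **Stability.** Hitting probabilities use `expm1`/`log` identities;
  the conditioned linear system is solved in banded form.
- **Reproducibility.** Every stochastic routine takes an explicit seed or
  numpy Generator; batch runs derive per-task seeds deterministically and
  record them in the run manifest together with SHA-256 digests of all
  inputs and outputs, so any table can be regenerated bit-identically.
- **Ties and degenerate inputs.** r = 1 exactly uses the neutral closed
  forms; boundary starting counts absorb in zero iterations; a Monte-Carlo
  batch with no fixing replicate reports an undefined conditional time
  with a warning rather than NaN arithmetic; single-point sensitivity axes
  warn and return NaN sensitivities; r ≤ 1 scenario branches report a
  "no takeover predicted" sentinel to keep tables finite.
- **Configuration.** One nested YAML file; unknown keys are errors so
  parameter-name typos cannot silently fall back to defaults.
- **Problem sizes in the test suite.** Monte-Carlo cross-checks run 2 × 10⁴
  replicates on N ≤ 50 lattices and the recovery study uses 500 synthetic
  cohorts; these sizes put 3-standard-error agreement bands in the
  sub-percent range while keeping the full suite around ten seconds.

## Known limitations

- Two clone types only: no mutation during growth, no multi-clone
  competition, no spatial structure, and N is constant — takeover times in
  an expanding or hierarchically structured compartment would differ.
- The closed-form fixation time overshoots the exact conditional time by
  up to tens of percent for r barely above 1 at small N; absolute times
  at the baseline N = 10⁵ inherit some of this bias (the recorded
  deviation trend suggests ≈ +20% at r = 1.1), while speedup ratios are
  less affected.
- Fitness measured over 72 h in culture is assumed to transfer to
  per-division fitness in the stem-cell compartment over years; this is a
  modelling assumption, not an inference the data can test.
- The division rate and N are literature-derived constants, not estimated
  from data; conclusions should be read against the sensitivity grid.
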