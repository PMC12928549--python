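# Methods

## Model structure

The engine is a time-homogeneous Markov cohort model with four states —
not pregnant without IUD (the initial state), not pregnant with IUD,
pregnant without IUD, pregnant with IUD — updated by monthly cycles over a
three-month horizon (the period over which a training effect on provision
can plausibly be asserted without long-term follow-up data). Cohort
fractions, not individuals, move between states, so the model is
deterministic given its parameters; all occupancy rows sum to 1 by
construction and this is asserted at run time.

Transition flows, composed in this order within a cycle:

1. an eligible non-user receives an IUD with probability `p_provision`
   (scenario-specific);
2. the remainder becomes pregnant with probability `p_preg_no_iud`;
3. IUD users become pregnant with the method-failure probability
   `p_preg_iud`;
4. pregnant fractions return to a non-pregnant state with probability
   `p_loss`, to the with-IUD state only when `retain_iud_after_loss` is set.

Uptake-before-risk (1 before 2) reflects that insertion presupposes a
non-pregnant consultation: a woman who receives the device this month faces
the failure rate only from next month. The pregnancy-loss transition exists
in the matrix but defaults to 0 — over a three-month horizon a pregnancy
outlasts the model — and `retain_iud_after_loss` defaults to false.

## Rewards and accrual conventions

QALYs accrue as occupancy-weighted utilities x cycle length (1/12 year) on
the state occupied at the **start** of each cycle; an optional half-cycle
correction instead averages start- and end-of-cycle occupancy (off by
default, matching the common default of commercial cohort-model tools).
One-time costs are charged on the transition **into** a state during the
cycle (insertion on uptake, pregnancy cost on conception), which prevents
double-charging a persistent state; recurring costs (the consultation
without insertion) are charged on occupancy like utilities. Discounting is a
per-cycle geometric factor `(1+r)^(-(t-1)/12)`; the default annual rate is 0
because the horizon is under one year. Scenario totals scale per-person
results by the eligible-user cohort size and add the one-off training cost
(`n_professionals` x unit training cost).

These conventions are exactly mirrored by an independent path-enumeration
oracle in the test suite (every state path, weighted by its probability),
which agrees with the matrix engine to 1e-10 at horizons up to 4 cycles.

## Parameters

| parameter | default | unit | provenance |
|---|---|---|---|
| provision probability | 0.0024 / 0.02 / 0.032 / 0.04 | per month | published scenarios |
| cohort sizes | 600 / 734 / 1,226 / 1,532 | users | published (stored as printed constants; they are not consistent with a single population denominator, so no N is derived) |
| utility, IUD no pregnancy | 1.0 | — | published |
| utility, no IUD no pregnancy | 0.8 | — | published |
| disutility, pregnancy on IUD | -0.1 | — | published |
| utility, pregnancy without IUD | 0.7 | — | **assumed**: base utility plus the same pregnancy disutility applied symmetrically |
| p_preg_no_iud | 0.1462 | per month | **assumed**: 85%/year typical-use no-method pregnancy rate, converted 1-(1-p)^(1/12) |
| p_preg_iud | 0.000669 | per month | **assumed**: 0.8%/year copper-IUD typical-use failure rate, same conversion |
| training cost | 1,820.38 | BRL/professional | published |
| insertion cost | 91.02 | BRL | published |
| consultation (no insertion) | 10.00 | BRL | **assumed** order of magnitude of the SUS outpatient schedule |
| unintended-pregnancy cost | 3,000.00 | BRL | **assumed** order of magnitude of Brazilian SUS costing literature |
| professionals trained | 1 per scenario | — | **assumed** (only the per-professional cost is published) |
| WTP threshold | 40,000 (primary), 120,000 (max) | BRL/QALY | published |

Assumed entries carry an `assumed` flag through serialization and a
validation warning; they must be replaced with local values for policy use.

## Ranking rules

Strategies are sorted by ascending cost. Strong dominance is exhaustive and
pairwise (no more costly and no less effective, one strict). Extended
dominance is an iterative sweep over the survivors in effectiveness order:
a strategy whose ICER against its lower neighbour exceeds the ICER of its
upper neighbour lies above the lower convex hull of the (effectiveness,
cost) frontier and is removed; exact ties in both coordinates collapse to a
single frontier point and share its label (both kept when nothing separates
them, ordered alphabetically in output). Incremental columns compare each
row with the nearest non-dominated row above it — the convention used in
published CEA rankings, where dominated rows are still contrasted with the
last efficient strategy. A zero incremental effectiveness yields a signed
infinite ICER flagged not interpretable rather than an exception, and the
negative ICERs of dominated rows are likewise reported but flagged.

## Sensitivity analysis

**Tornado (one-way).** Each parameter in turn is set to its low and high
bound with everything else at base; both comparator scenarios are rerun and
the ICER recomputed. Candidate parameter sets are validated *before* any
model run so an out-of-domain bound fails fast with a field-named error.
Rows are sorted by descending ICER swing. The shipped fixture uses +/-20%
ranges on costs and utilities (clipped to [0, 1] for utilities) because the
study's exact bounds are not published; they are flagged as assumptions.

**Probabilistic (Monte Carlo).** Following standard PSA practice,
probabilities and utilities are sampled from beta distributions and costs
from gamma distributions, each matched by the method of moments to a stated
mean and standard deviation (beta: alpha = m*nu, beta = (1-m)*nu with
nu = m(1-m)/sd^2 - 1, infeasible moments rejected; gamma: shape = m^2/sd^2,
scale = sd^2/m). The disutility is sampled as a beta on its magnitude and
negated, keeping draws in [-1, 0]. A `fixed` family gives degenerate draws,
as does sd = 0. Normal draws are truncated to the parameter's domain by
resampling; resampled draws are counted and reported (always 0 for
beta/gamma, whose support is the domain). The fixture's relative sd of 10%
is an assumption (the study reports only that means and sds were used). All
sampling flows from a single `numpy.random.Generator` (PCG64) seeded once,
recorded in output metadata; runs are byte-reproducible from the seed.

**Summaries.** The CEAC reports, along a willingness-to-pay grid from 0 to
120,000 BRL/QALY in steps of 2,000 (61 points, containing the 40,000
primary threshold), the fraction of iterations in which each strategy has
the strictly highest net monetary benefit, with exact ties splitting the
iteration's weight equally, so the curves sum to 1 at every grid point. The
ICE scatter reports per-iteration (deltaE, deltaC) for a strategy pair plus a 95%
confidence ellipse from the sample mean and covariance at the chi-square(2
df) 0.95 quantile, and the fraction of iterations below a given WTP line.

## Synthetic parameter generation

`generate_params(seed, spread)` emulates an unpublished study parameter
table: means jittered within a relative `spread` of the fixture values
(clipped to their domains; exact 0/1 boundary values stay fixed, since a
beta cannot centre there), sds of `spread` x mean with beta feasibility
enforced by shrinking (logged), and one-way ranges of mean +/- 2 sd clipped
to the domain. Generated sets always satisfy every container invariant
(fuzzed over 1,000 seeds in the suite). What the generator does **not**
emulate: correlation between parameters, skewed or heavy-tailed cost
uncertainty beyond the gamma family, and time-varying probabilities — so
passing tests demonstrate internal consistency of the pipeline, not
calibration of any real parameter table.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script: the path-enumeration
cross-check uses 200 random parameter sets at horizons up to 4 cycles (256
paths each); dominance is cross-checked on 200+ random strategy sets of up
to 6 strategies, including small-integer grids that provoke exact ties and
collinear frontiers; the PSA runs the study's 10,000 iterations over all
four scenarios. Row-stochasticity is enforced to 1e-12, occupancy
conservation to 1e-9, oracle agreement to 1e-10, CEAC normalisation to
1e-9. Monetary output is serialized with 2 decimals, probabilities and
utilities with 6.

## Known limitations

- The published table's absolute cost, effectiveness and NMB magnitudes rest
  on an unprinted population-scaling convention (e.g. per-person three-month
  QALYs cannot reach the printed 4.3, and cohort x insertion cost does not
  give the printed 3,813); the package reproduces per-person and
  cohort-total quantities, the incremental-column arithmetic and the
  dominance labels, and makes no claim about the absolute magnitudes.
- Cohort-level modelling ignores individual heterogeneity, device expulsion,
  discontinuation and side effects; the three-month horizon excludes
  longer-term savings from averted pregnancies.
- PSA parameters are sampled independently (no correlation structure), and
  expected value of perfect information is out of scope.
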