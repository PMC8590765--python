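# Methods

This note records the statistical model implemented by `trialanon`, the
provenance of its fixed parameters, what the synthetic-data generator does
and does not cover, the numerical choices made in the implementation, and
the known limitations.

## 1. Data risk

Let a table of *n* records be partitioned into equivalence classes by exact
match on a quasi-identifier (QI) set; class *j* has size *f\_j*. Missing
values are treated as a regular value (all-missing records form their own
class) so that missingness can never silently lower measured risk.

- **Prosecutor risk** (adversary knows the target is in the sample):
  per-record risk 1/*f\_j*; average = (1/n) Σ\_j f\_j · (1/f\_j) = K/n where
  K is the number of classes; maximum = 1/min\_j f\_j.
- **Journalist risk** (target known only to be in a population sampled at
  fraction π): per-record risk min(1, π/f\_j); averaged the same way. At
  π = 1 it equals prosecutor risk; it is monotone in π and never exceeds
  prosecutor risk.

Two QI sets are assessed per release: the *public* set (registry-findable
attributes) and the *acquaintance* superset (additionally what friends,
relatives, and colleagues know). The package enforces public ⊆ acquaintance
at the codebook level.

## 2. Context risk and the three attacks

| attack | data-risk term | context term |
|---|---|---|
| T1 deliberate | avg. journalist risk on public QIs | P(attempt) from control checklist |
| T2 acquaintance | avg. journalist risk on acquaintance QIs | 1 − (1 − v)¹⁵⁰ |
| T3 breach | avg. journalist risk on public QIs | P(breach) |

**Overall risk = max(T1, T2, T3).**

- *P(attempt)* is looked up from a three-group checklist (security,
  privacy, contractual controls). Each item is answered high/medium/low;
  the weakest answer across all items selects P(attempt) from
  {high: 0.05, medium: 0.2, low: 0.4}. Strengthening any single control can
  therefore never increase the modelled risk (verified by property-based
  test).
- *T2*: an analyst is modelled as personally knowing ~150 people (the
  Dunbar number). If a fraction *v* of the therapeutic-area population is
  enrolled in the pooled studies, the chance that at least one acquaintance
  is in the data is 1 − (1 − v)¹⁵⁰ under independence. *v* doubles as the
  sampling fraction π of the journalist model: both describe the same
  sample-of-population relationship.
- *P(breach)* defaults to 0.14, a published annualised rate of significant
  breaches among health-data custodians.

## 3. Certification

A release is certified when overall risk ≤ **0.09** — the per-record
equivalence-class-size-of-11 threshold recommended in European regulatory
guidance for proactive clinical-data publication and adopted by the
Canadian regulator — *and*, under the strict-average criterion, the
estimated number of sample records that are unique in the *population* is
below 0.1 (i.e. statistically indistinguishable from zero). The strict
check runs on the public-QI partition: population uniqueness concerns
adversaries matching against exterior data sources, which is the public-QI
threat surface.

## 4. Population-uniqueness estimation

The certification needs E[# sample records whose population equivalence
class has size 1], observing only the sample.

**Default estimator (independence log-linear).** For each sample singleton
with QI tuple *t*, estimate its cell probability as the product of the
sample marginal proportions of its component values,
p̂(t) = Π\_k (m\_k(t\_k)/n), the independence log-linear model of the QI
cross-classification. With population size N = n/π, the probability that
none of the N − n unsampled individuals falls in that cell — i.e. that the
sample unique is a population unique — is (1 − p̂(t))^(N−n). Summing over
sample singletons gives the estimate. Properties: it reduces *exactly* to
the singleton count at π = 1 (the exponent vanishes); it is deterministic;
it is clamped to [0, sample uniques]; it returns 0 when there are no sample
uniques.

**Alternative (`method="pitman"`).** A two-parameter Ewens–Pitman species
model fitted by method of moments to (number of classes, number of
singletons), with the population singleton count E[K₁,N] evaluated under
the fitted model and thinned by π. It is retained because it uses only the
class-size spectrum (no access to the QI tuples), but its power-law tail
systematically over-extrapolates singleton counts on product-categorical
data, and benchmarking on the package's own synthetic worlds (50 seeds,
N = 2000, π = 0.1, exact truth by enumeration) showed ~23% mean absolute
error against ~15% for the log-linear estimator, with higher variance.
The log-linear estimator is therefore the default.

The acceptance suite asserts mean absolute error ≤ 20% of the mean true
count over 50 seeded worlds; that tolerance characterises this generator at
these settings and is a harness choice, not a literature claim.

## 5. Transformations

- **Pseudonymisation**: seed-shuffled sequential zero-padded ids; the
  original↔pseudonym bijection is returned as a protected link file kept
  outside the release. The id range is deterministically bumped until no
  original id (of length ≥ 3) appears as a substring of any pseudonym.
- **Relative study days**: each subject's earliest recorded date becomes
  day 1; earlier days count from −1 (no day 0). All date columns are
  replaced by integer `*_day` columns; unparseable dates are suppressed
  with a logged finding.
- **Generalization**: numeric banding into left-closed intervals labelled
  `lo-hi` (5-year age bands by default convention), and categorical ladders
  (e.g. country → region → continent) declared in the codebook, validated
  to be true coarsenings (a later level may never split an earlier one).
- **Suppression**: whole columns (e.g. site id, which would expose site
  geography through public trial registries) or individual cells; suppressed
  cells are logged with their (table, subject, variable) coordinates so QC
  can later distinguish them from source missingness.
- **Noise**: bounded uniform perturbation with clipping to the declared
  valid range, seeded.
- **Sidecar scrubbing**: image-header key/value metadata is reduced to a
  keep-list (default-deny); kept values are additionally screened against
  date- and name-like patterns so identifying content typed into retained
  acquisition fields is still dropped.

Every transform writes a log entry; replaying the log with the link file
reproduces the release byte-for-byte (asserted in the acceptance suite).

## 6. The engine

Mandatory steps (pseudonymise, relative days, suppress direct identifiers)
run first. The search then proceeds over per-variable *ladders* — ordered
weak coarsenings ending in suppression (defaults: numeric width 5/10/20
then suppress; categorical hierarchy levels then suppress). The state is
the ladder index per variable; each candidate state is evaluated by
re-applying the selected rungs to the pristine post-mandatory tables, so
successive generalizations never operate on already-banded strings. The
greedy rule takes the step with the lowest resulting overall risk, breaking
ties toward the variable with the lower utility weight, then codebook
order. Because each rung weakly coarsens its predecessor, the recorded risk
trajectory is non-increasing. If the ladders exhaust before certification
the run fails with the partial report attached. Per-step RNG seeds are
derived from the run seed by SHA-256 and reduced below 2³¹.

Risk is computed on a one-row-per-subject view of the QI columns joined
across tables (first value per subject). When every QI has been suppressed
the partition degenerates to a single class of size *n* — which still fails
strict certification at *n* = 1, as it should.

## 7. Wrangling, QC and releases

Per-study tables are validated against the codebook (aliases resolved,
types, categories, ranges and key uniqueness checked), then melted into a
long entity–attribute–value store (SQLite) carrying (source table, source
row) provenance on every observation; an observation referencing an
unregistered subject is a referential error. QC reports per-variable
missingness and out-of-range/out-of-category anomalies, and — given the
anonymisation report plus the source tables' missing-cell coordinates —
classifies every missing cell as *suppressed*, *source-missing* or
*unexplained* (the acceptance suite requires zero unexplained). A release
snapshot hashes a canonical serialisation (sorted, provenance row numbers
excluded) so the version is independent of input row order, and carries the
codebook version and an optional parent pointer forming a provenance chain.

## 8. Synthetic worlds and generator scope

The generator materialises the full therapeutic-area population
(default N = 2000): age from a clipped normal (38 ± 10 on 18–60), sex 70/30
F/M, country from a Zipf(s = 1) margin over 12 countries with a shipped
region/continent ladder. Three disjoint cohorts (80/60/60) are sampled
without replacement, giving v = 0.1 exactly. Each subject gets quarterly
visits with ±3-day jitter, an EDSS-like score (0–10 in 0.5 steps, bounded
random walk), Poisson relapse events (0.5/patient-year) and an integer
disease-duration acquaintance QI. Missingness (5%) is injected only into
the score column, keeping QI columns complete so population-uniqueness
ground truth remains exact; the truth record carries v, population and
in-sample unique counts (by enumeration), and the exact coordinates of
every injected missing cell.

Scope: the generator covers cross-sectional categorical/integer QIs with a
single-level (non-hierarchical) population; it does not model household or
longitudinal correlation between QIs, free-text fields, genomic data, or
real-world census margins. Estimator-accuracy statements in this repository
are with respect to this generator.

## 9. Numerical choices

- Probabilities are validated to [0, 1] with tolerance 1e-12; formula tests
  assert 1e-12 absolute agreement.
- `log1p`/`expm1` forms are used where 1 − v is near 1 (the exponent
  recovery in `scripts/acceptance.py` uses log1p).
- Rising factorials in the Pitman alternative are computed via `gammaln`
  differences to avoid overflow at N in the thousands.
- Content hashes are SHA-256; codebook and snapshot versions are the first
  12 hex digits.
- All RNG use goes through `numpy.random.default_rng` with explicit seeds;
  derived seeds are reduced modulo 2³¹.

## 10. Limitations

- The risk model assumes exact matching on QIs; fuzzy or probabilistic
  record linkage by an adversary is out of scope.
- The independence log-linear estimator ignores QI dependence; strong
  positive association between QI values can bias population-uniqueness
  estimates (downward or upward depending on the dependence structure). Its
  accuracy is characterised only on the shipped generator.
- P(attempt), P(breach), the Dunbar exponent and the 0.09 threshold are
  fixed policy parameters taken from the governing guidance, not fitted
  quantities; the package treats them as configuration.
- The greedy ladder search is locally optimal per step; it does not claim
  minimal information loss among all certifying transformations.
- Utility is modelled only as per-variable tie-breaking weights, not as an
  analytic loss function.
- The engine's subject-level QI view takes the first value per subject;
  time-varying quasi-identifiers are not modelled.
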