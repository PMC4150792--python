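# Methods

`rhoterm` models Rho-dependent transcription termination as a race between a
translocating RNA polymerase and the termination factor Rho, and packages the
downstream analyses that the termination field applies around that model:
empirical fitting of release/ATPase kinetics, rut-site sequence scanning,
a distance-based terminator-strength metric, and WT-vs-mutant expression
comparison. This note records the model assumptions, the parameter choices
and their rationale, the numerical conventions, and the limits of what the
synthetic benchmarks demonstrate.

## Recruitment kinetics

The recruitment scheme is a linear continuous-time Markov chain

```
Free  <=>  Bound(OH)  ->  ...  ->  Committed(CH)  ->  Step_1 ... Step_n  ->  Released
     k_on/k_off          k_iso (n_iso_stages)        k_step per stage      k_dislodge
```

Binding of Rho's primary site to the rut RNA is the only reversible stage;
once the open hexamer (OH) begins closing into the translocase-competent
closed hexamer (CH) the chain is irreversible. The closed form for the mean
first-passage time Free -> Committed with a single isomerization stage,

```
E[T] = (k_off + k_iso) / (k_on * k_iso) + 1/k_iso ,
```

is exact and is cross-checked against the stochastic sampler; it decreases
monotonically in `k_iso` and in the NusG multiplier.

**Multi-stage isomerization.** `ChainSpec.n_iso_stages` resolves the OH -> CH
transition into n sequential sub-stages at rate `n * k_iso` each, keeping the
mean at `1/k_iso` while reducing its coefficient of variation to ~`1/sqrt(n)`.
This is not cosmetic: a single exponential stage has CV ~ 1, and a CV-1 waiting
time cannot produce a lag phase in the release curve — the curve it generates
is indistinguishable from a (shifted) exponential rise no matter how slow the
stage is. A lag requires a low-variance delay, i.e. several comparable
sub-steps, which is also the natural kinetic signature of a large concerted
conformational change such as hexamer ring closure. The default is 1 (the
minimal scheme, for which the closed form above is exact); the release-assay
benchmarks use 5. With n stages and reversible binding the generalized mean
`(k_off + n*k_iso)/(k_on*n*k_iso) + 1/k_iso` is used, which reduces to the
single-stage form at n = 1.

**NusG** enters exclusively as a multiplier on `k_iso` (`nusg_factor`,
default 100): it accelerates the isomerization allosterically and does
nothing else in this model. Its observed modest effect on release amplitude
is deliberately not modeled.

**ATP hydrolysis** runs at `k_cat` per committed Rho against a pool
`atp_pool`, f(t) = min(1, (k_cat/atp_pool) * integral of P(committed)).
The linear asymptote of f extrapolates back to the mean commitment time, so
a slow isomerization shows up as an ATPase lag; translocation stoichiometry
is not resolved because the emulated assay uses stalled complexes.

**Solvers.** The master equation is integrated with LSODA at relative
tolerance 1e-8 with the (constant) generator matrix supplied as the exact
Jacobian. The stochastic oracle does not integrate anything: it samples
exact first-passage times from the renewal structure of the chain (geometric
number of binding attempts, gamma sojourn sums, Erlang isomerization and
translocation, exponential dislodging), so agreement between the two routes
tests both the solver and the model algebra.

## Termination-zone model

When the commitment clock starts, the polymerase is `start_offset` nt past
the rut 3' end (default 0) and elongates at `rnap_speed`; after the random
commitment time T, Rho translocates at `rho_speed > rnap_speed` and catches
the polymerase at `(start_offset + rnap_speed*T) * rho_speed/(rho_speed -
rnap_speed)`, then dislodges it after an Exp(`k_dislodge`) wait. Speeds are
constant and sequence-independent. The mean distance separates into the two
interpretable terms — time to form a translocase-competent Rho, time to
dislodge the EC — and `infer_commitment_time` inverts the mean formula
exactly, so forward/inverse round trips are limited only by arithmetic.
Because no speeds have been measured for this system, inferred commitment
times are always conditional on the supplied speeds.

Terminator classification uses the distance from the rut 3' end to the
termination-zone midpoint, with the class boundary at 265 nt — the midpoint
between the short-distance class (roughly 70–145 nt, classical "tR1-like"
terminators) and the long-distance class (roughly 385–425 nt, "trac-like"
terminators). Distances are measured from the rut 3' end because that is
where translocation starts.

## Rate-constant defaults

No rate constants have been measured for this system; every default is an
order-of-magnitude choice and is labeled illustrative:

| parameter | default | rationale |
|---|---|---|
| `k_on` | 0.05 /s | ~50 nM Rho at a ~1e6 /M/s association rate |
| `k_off` | 0.01 /s | stable engagement of a good rut site |
| `k_iso` | 0.5 /s (0.05 slow / 5 fast in benchmarks) | spans the weak/strong terminator contrast |
| `k_step` | 60 /s | Rho translocation of tens of nt/s |
| `k_dislodge` | 2 /s | sub-second to seconds once Rho reaches the EC |
| `nusg_factor` | 100 | large acceleration consistent with complete lag removal |
| `k_cat/atp_pool` | 0.01 /s | puts pool exhaustion on the assay timescale |

The reference release-assay conditions (`RELEASE_ASSAY_*`) add a 200-nt
rut-to-roadblock distance, five isomerization sub-stages, and 20 samples on
[10, 180] s — sampling starts after a 10 s dead time, as in manual gel
sampling, and stays within the informative part of the curve.

## Release fractions and curve fitting

The released fraction from one gel time point is `2S / (S + (S+P))`: the
supernatant was split in half, so 2S is the full released signal and
S + (S+P) the total. The printed form of this formula is typographically
ambiguous; the alternative reading `2S / (2(S+P))` is available via
`denominator="twice_total"`. Fractions outside [0, 1] are clipped and the
clipping logged.

Three candidate forms are fitted by multi-start nonlinear least squares
(five deterministic starts derived from the data: amplitude from the span,
rate from the half-rise time):

* `y = a (1 - exp(-b x))` — 2 parameters;
* `y = y0 + a (1 - exp(-b x))` — 3 parameters;
* `y = y0 + a / (1 + (x/x0)^b)` — 4 parameters. Under this
  parameterization a rising curve has `b < 0`; both signs are accepted. At
  x = 0 the curve is evaluated by its limit (y0 for b < 0), so the sigmoid
  fits the same points as the exponential candidates and the information
  criteria are comparable.

Selection uses AICc (small-sample corrected, error variance counted as a
parameter). Candidates within 2 AICc units of the minimum are treated as
statistically indistinguishable and the simplest is returned; consequently
the sigmoid — and a lag — is declared only when it beats every exponential
form by at least 2 units. The lag itself is the standard growth-curve
tangent construction: the tangent at the inflection (x0, y0 + a/2), slope
`-ab/(4 x0)`, intersects the baseline y0 at `lag = x0 (1 + 2/b)`, clamped
to >= 0. Exponential selections report lag = 0 by construction.

Known behaviour: on data whose true shape is exponential, the sigmoid is
still selected in a few percent of noisy replicates (AIC optimism under
multiplicative noise); the package targets and verifies a < 10% type-I rate
rather than zero.

## rut-site scanning

A rut site is operationally defined as C-rich and weakly structured. The
scanner computes, per sliding window (default 60 nt, step 1):

* `cg_ratio` = C count / max(G count, 1) — the G pseudocount avoids
  division by zero on G-free windows;
* `delta_g` — minimum folding energy under a deliberately self-contained
  pair-energy model: GC -3, AU -2, GU -1 kcal/mol, hairpin loops >= 3 nt,
  nested structures only, optional minimum helix run length (default 1).
  The O(n^3) dynamic program is verified exactly against a brute-force
  enumeration oracle on short sequences. These energies are comparative
  scores, not thermodynamic free energies: they rank windows of equal
  length but will not match values from nearest-neighbour folding tools.

Windows with `cg_ratio >= cg_min` (default 1.5) and `delta_g >= dg_min` are
flagged and merged into maximal intervals. The default `dg_min = -55`
kcal/mol was calibrated once against the synthetic generator: 60-nt windows
drawn from the planted rut composition score about -37 (range -46 to -21)
under this energy model while hairpin-cassette background windows score
about -70 (range -75 to -63), and -55 sits in the gap. The threshold scales
with window length and energy model and must be recalibrated if either
changes. Coordinates are 0-based half-open throughout, single-strand
(transcript sense); BED output scores are interval ranks scaled to 0–1000.

## Expression comparison

Fold changes are `log2(mut/wt)`; a gene is affected when `|log2 FC| >=
log2(fold_threshold)` with the default threshold of 5 — a 5-fold change
reported on the log2 scale (cutoff ~2.32). The alternative literal reading
(5 log2 units, i.e. 32-fold) is selectable with `scale="log2"`. Replicate
tables are combined by the arithmetic mean of log2 FC before thresholding.
Overlay classification inner-joins the PBS- and SBS-mutant profiles and
partitions genes into `sbs_only` / `pbs_and_sbs` / `pbs_only` / `neither`;
the four classes always partition the joined set. qRT-PCR quantification is
the 2^-ddCt estimator against an internal control gene; the control cancels
exactly, so equal inputs give exactly 1.

No significance testing or multiple-testing correction is applied: the
emulated comparison is a pure fold-change cutoff, and input tables are
assumed normalized.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of `SynthConfig` (same seed, byte-identical
output); distinct experimental conditions fold a CRC of their inputs into the
stream key so they receive independent noise.

* **Release time courses.** True curve from the master equation, scaled by
  `release_amplitude` (default 0.8 — release assays saturate below 1), then
  multiplicative lognormal noise (`noise_sd`, default 0.02, so the expected
  relative deviation is `sigma*sqrt(2/pi)` ~ 1.6%), then band intensities
  back-computed from a fixed 100-unit total.
* **Expression tables.** 4294 genes (chip scale) with 550 planted affected
  genes in the SBS profile, of which 20% (110) also respond to PBS mutants
  (`frac_pbs_insensitive = 0.8`, matching the ~5-fold contrast between the
  two mutant classes). Planted |log2 FC| ~ Normal(4.0, 0.6) truncated at
  the cutoff (every planted gene is a true positive by construction); 70%
  up-regulated; null genes scatter as Normal(0, 0.3) in log2, which makes
  false positives at the 5-fold cutoff essentially impossible (7.7 sigma).
* **rut sequences.** Background concatenated from perfect G/C stem-loops
  (8–12 bp stems, 4–6 nt loops), one planted 60-nt window per 300-nt
  sequence with base probabilities C .45 / A .25 / U .20 / G .10 (expected
  C/G count ratio 4.5).
* **Ct tables.** `ct_target_mut = ct_target_wt - log2(fold) + N(0,
  sigma_ct)`, constant controls, so the ddCt estimator is unbiased on the
  log scale.

These generators reproduce the *statistical* structure each analysis stage
assumes — not instrument physics. There are no probe or dye effects, no gel
background or smile, no PCR efficiency below 2, no sequence-dependent
translocation, and planted effects are cleanly separated from the null.
Passing the benchmarks therefore demonstrates internal consistency of the
pipeline (each stage recovers what the model that motivated it planted), not
performance on real arrays, gels or sequencing data.

## Numerical conventions and degenerate inputs

* Master equation: LSODA, rtol 1e-8, atol 1e-12, exact Jacobian; caller
  supplies the grid, which must be strictly increasing and non-negative.
* `k_off = 0` is legal (pure hypoexponential chain); all other rates must be
  strictly positive. `rho_speed <= rnap_speed` raises (no catch-up), and a
  distance explained entirely by dislodging makes the inversion infeasible
  rather than returning a negative time.
* Fits: bounds keep amplitudes in (0, 2] and rates positive; a failed fit
  from all starts raises `FitError` with per-start diagnostics; AICc is
  +inf when a form is underdetermined, which silently removes it from
  selection. Zero residual is floored at 1e-300 before the log.
* Both band intensities zero -> `UndefinedFractionError`; fractions are
  clipped to [0, 1] with a logged warning otherwise.
* Folding: T and U are interchangeable on input; the empty sequence is an
  error; windows longer than the sequence are an error.

## Known limitations

* The kinetic parameters are unmeasured; all quantitative outputs are
  conditional on user-supplied rates and speeds, and defaults only encode
  order-of-magnitude reasoning.
* The folding score is a toy energy model by design; it supports ranking
  and the planted-site benchmarks, not thermodynamic prediction.
* Model selection retains a few-percent false-sigmoid rate on
  exponential-truth data; single noisy curves near the decision boundary
  can be misclassified.
* The termination-zone model assumes constant speeds and a single
  dislodging rate; polymerase pausing and sequence-dependent translocation
  are out of scope.
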