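# rhoterm

Kinetic modelling and sequence analysis of **Rho-dependent transcription
termination** in bacteria.

Rho is a hexameric RNA translocase that terminates roughly half of *E. coli*
operons. It loads onto a C-rich, weakly structured *rut* segment of the
nascent mRNA through its primary binding site (PBS), isomerizes from an open
(OH) to a closed (CH) hexamer — the translocase-competent form — then
threads mRNA through its secondary binding site (SBS), hydrolyses ATP,
chases the elongation complex (EC) and dislodges it. Terminators differ in
how fast Rho completes this recruitment: on weak-recruitment terminators the
slow OH→CH isomerization produces a visible **lag** in RNA-release and
ATPase kinetics and pushes the termination zone hundreds of nucleotides
downstream of the rut site, and the elongation factor **NusG** erases both
effects by accelerating the isomerization.

`rhoterm` implements that picture quantitatively, for anyone who wants to
reason about termination kinetics or reanalyse termination-style data:

* **`kinetic_model`** — the recruitment scheme as a linear CTMC
  (Free ⇌ Bound(OH) → Committed(CH) → translocation → Released), with the
  closed-form mean commitment time
  `E[T] = (k_off + k₂)/(k_on·k₂) + 1/k₂`, a master-equation solver, an
  exact stochastic sampler as independent oracle, ATP-hydrolysis traces,
  and a catch-up model that converts commitment times into termination
  distances.
* **`kinetics_fitting`** — released fractions from gel bands
  (`2S/(S+(S+P))`), exponential-rise `y = a(1−e^{−bx})` vs sigmoid
  `y = y₀ + a/(1+(x/x₀)^b)` fits, AICc model selection, tangent-intercept
  lag extraction.
* **`rut_scan`** — sliding-window rut-site discovery by C/G ratio and a
  self-contained minimum-free-energy dynamic program, with BED output.
* **`terminator_strength`** — rut-to-termination-zone distances,
  tR1-like vs trac-like classification, and inversion of the distance back
  into a mean commitment time.
* **`expression_compare`** — log2 fold changes, the 5-fold affected-gene
  cutoff, PBS/SBS overlay classification, and 2^−ΔΔCt qPCR quantification.
* **`synthetic_data`** — seeded generators for all four input kinds, so the
  whole pipeline is testable without any external data.

No rate constants have been measured for this system; all defaults are
illustrative order-of-magnitude choices (see `docs/methods.md`).

## Worked example

```python
import rhoterm as rt

slow = rt.RELEASE_ASSAY_SLOW          # weak-recruitment terminator, k_iso = 0.05/s
chain, times = rt.RELEASE_ASSAY_CHAIN, rt.RELEASE_ASSAY_TIMES

print(rt.mean_commitment_time(slow, n_iso_stages=5))              # 40.8 s
print(rt.mean_commitment_time(slow, nusg=True, n_iso_stages=5))   # 20.2 s

# simulate a noisy release assay and ask whether the curve has a lag
cfg = rt.SynthConfig(seed=1, noise_sd=0.02)
ms, _ = rt.gen_release_timecourse(slow, chain, times, cfg)
fit = rt.select_model_and_lag(rt.timecourse_from_measurements(ms))
print(fit.form, round(fit.lag, 1))    # sigmoid 17.0

# NusG accelerates the isomerization 100x: the lag disappears
ms, _ = rt.gen_release_timecourse(slow, chain, times, cfg, nusg=True)
fit = rt.select_model_and_lag(rt.timecourse_from_measurements(ms))
print(fit.form, round(fit.lag, 1))    # exp_rise_offset 0.0
```

The printed numbers mean: forming a translocase-competent Rho on this
terminator takes ~41 s on average, and NusG halves that (the remainder is
binding-limited). The simulated gel time course is classified as sigmoidal
with a ~17 s lag — the kinetic signature of slow isomerization — and the
NusG curve is a plain exponential rise with no lag.

The same contrast drives terminator strength: with RNAP at 20 nt/s and Rho
at 60 nt/s, `predict_termination_zone(slow, 20, 60, n_iso_stages=5,
seed=1)` puts the mean termination distance at ~1234 nt versus ~616 nt with
NusG, and `classify_terminator` labels distances ≥ 265 nt "trac-like"
(weak-recruitment) and shorter ones "tR1-like" (classical).

A command-line interface mirrors the library:

```bash
rhoterm simulate --mode release --out tc.tsv
rhoterm fit --in tc.tsv --out fit.json
rhoterm synth sequences --out-dir synth/ --seed 4
rhoterm rutscan --fasta synth/regions.fa --out rut.bed --table windows.tsv
rhoterm strength --zones zones.tsv --out strength.tsv
rhoterm degenes --pbs pbs.tsv --sbs sbs.tsv --out classes.tsv
```

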