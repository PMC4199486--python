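# cadwave

Frequency-gradient segmentation-clock modelling for the *Tribolium castaneum*
blastoderm.

## The problem

In the short-germ beetle *Tribolium*, stripes of the pair-rule gene
*even-skipped* (*Tc-eve*) are not laid down simultaneously as in *Drosophila*:
waves of expression sweep from the posterior pole toward the anterior and
freeze into stable stripes, even though the blastoderm does not elongate.
These kinematic waves can be produced without any cell-to-cell signalling if
every nucleus carries an independent oscillator whose frequency is set by a
posterior-to-anterior gradient — and the posterior gradient of *Tc-caudal*
(*Tc-cad*) expression is the prime candidate for that frequency gradient.

`cadwave` is for quantitative developmental biologists who want to work with
this model computationally: fit measured *Tc-cad* profiles, simulate the
oscillator array for wild type and RNAi knockdowns of *Tc-cad* regulators
(*Tc-lgs*, *Tc-pan*, *Tc-apc1*, *Tc-zen1* and the *lgs;zen1* double), infer
oscillation-cycle durations from staged egg collections, and ask whether a
*graded* frequency profile buffers a clock-and-wavefront mechanism against
gradient noise better than a sharp threshold does.

## The model

**Gradient.** The *Tc-cad* profile along the AP axis (fraction $x \in [0,1]$,
anterior at 0) is linear-with-plateau, summarised by three descriptors —
plateau $P$, anterior border $b$ and slope $m$:

$$g(x) = \mathrm{clip}\big(m\,(x - b),\; 0,\; P\big)$$

In time, the profile scales with an exponential buildup
$B(t) = 1 - e^{-(t - t_\mathrm{on})/\tau}$ and, late in the blastoderm, the
border retracts posteriorly at speed $v$.

**Clock.** Each cell is a phase oscillator,
$\dot\varphi(x,t) = \omega_\mathrm{ref}\,
\min\!\big(g(x,t),\, g_\mathrm{ref}\big)/g_\mathrm{ref}$, with
$\omega_\mathrm{ref} = 1/3$ cycles per hour (the ~3 h *Tc-eve* period).
Expression is high during the first half of each cycle, and only where the
clock has ever run — abolishing the gradient abolishes expression.  Phase
runs faster posteriorly, so iso-phase contours travel anteriorly and shrink:
kinematic waves.

**Quantification.** Measured profiles are fitted by least squares over the
two knots of the curve with the slope profiled out in closed form
(`LinearPlateauModel.fit()`); group statistics use an embryo-level percentile
bootstrap and permutation tests.  Cycle durations are inferred from staged
egg collections by an interval-censored multinomial maximum-likelihood model
(`CycleTimingModel.fit()`), with parametric-bootstrap confidence intervals.

## Worked example

```python
import cadwave as cw

# wild-type blastoderm, 13.5-23 h after egg lay (AEL)
pattern = cw.simulate_1d(cw.SimConfig1D(), cw.condition_preset("WT"))
print([round(d, 3) for d in cw.posterior_cycle_durations(pattern)])
stripes, border = cw.detect_stripes(pattern.expr[-1])
print(sum(s.complete for s in stripes), cw.classify_stage(pattern, 18.0).label)

# graded vs thresholded arrest under per-cell gradient noise
summary = cw.compare_models(cw.SimConfig2D(), sigma=0.15, n_seeds=20, seed=42)
print(summary.summary())
```

prints

```
[3.5, 3.0, 3.0]
3 II.1
Robustness over 20 matched noise fields
  threshold_free  : roughness 0.1225 ± 0.0016
  threshold_based : roughness 0.1830 ± 0.0034
```

Reading: the first posterior oscillation cycle lasts 3.5 h (slowed by the
gradient's exponential buildup), later cycles run at the 3 h reference
period, and exactly three stripes complete before the end of the blastoderm
stage; at 18 h AEL the posterior end is in the high phase of cycle II
("II.1").  Under 15% frozen multiplicative noise in the gradient, the
threshold-free (graded-arrest) model corrupts ~12% of lattice cells versus
~18% for the threshold-based arrest front: the graded profile is the more
robust wavefront.

The same operations are available from the shell:

```bash
cadwave synth profiles --preset WT --n-embryos 30 --seed 1 --out profiles.csv
cadwave fit-gradient --in profiles.csv --out descriptors.csv --boot 2000 --seed 1
cadwave simulate-1d --preset lgs --out lgs_run/
cadwave synth cohort --n-per-window 50 --seed 2 --out cohort.csv
cadwave infer-timing --in cohort.csv --boot 1000 --seed 7 --out timing.csv
cadwave compare-robustness --sigma 0.15 --seeds 20 --out robustness/
```

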