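# flapflow

Quantitative analysis of indocyanine-green (ICG) fluorescence angiography for
DIEP-flap perfusion assessment.

In autologous breast reconstruction with a deep inferior epigastric
perforator (DIEP) flap, perfusion-related complications (partial or total
flap necrosis) are the main locoregional concern. Intra-operative ICG
angiography films the flap's fluorescence after an intravenous dye bolus;
the shape of the regional time–intensity curve tracks tissue perfusion.
Commercial systems quantify these videos with closed, proprietary software.
`flapflow` is an open, fully testable implementation of that analysis chain
for surgeons and imaging researchers:

* **frame-stack I/O** — multi-page TIFF + JSON-sidecar video container with
  the standard 20-second cut that makes recordings comparable across flaps;
* **zone geometry** — partition of the flap into four regions of interest
  mapped onto the Hartrampf perfusion zones (ROI 2 = zone I over the
  perforator, ROI 3 = zone II across the midline, ROI 1 = zone III, ROI 4 =
  zone IV), plus the "bright zone" (top-quantile fluorescence subregion) on
  which whole-flap parameters are estimated;
* **perfusion quantification** — for a region with mean fluorescence curve
  F(t): *ingress* = max F − F̄(baseline window), in absolute perfusion units
  (APU), and *ingress rate* = ingress / (t_peak − t_onset), in APU/s; plus
  per-pixel ingress and time-to-peak maps (the "dynamic color analysis");
* **pattern classification** — a deterministic, scale-invariant rule that
  assigns each flap one of three perfusion patterns (1: confined to the
  perforator half without crossing the midline; 2: confined to the
  perforator emergence area; 3: crossing the midline with poor peripheral
  ends) from zone-ingress ratios and a midline-crossing index;
* **cohort statistics** — median/IQR and count/percent summaries, pooled
  t test / one-way ANOVA for continuous outcomes, chi-square or Fisher's
  exact test selected by the expected-count validity rule, and the
  outcome-by-covariate univariate report (deliberately uncorrected,
  exploratory design);
* **synthetic data** — a flap-video generator with peak-normalized
  gamma-variate bolus kinetics per pixel (true ingress known in closed
  form), presets producing the three perfusion patterns, and a per-patient
  cohort generator with configurable multiplicative covariate effects.

The kinetic model for a pixel at distance *d* from the perforator is

    F(t) = B + A(d) · x^α e^{α(1−x)},   x = (t − t₀ − d/v)/t_p  (0 for x < 0)
    A(d) = A₀ e^{−d/λ} · m^{[crosses midline]} · p^{[peripheral end band]}

so the curve peaks at exactly B + A(d): the amplitude field *is* the true
per-pixel ingress, which is what makes every downstream stage testable
without clinical data.

## Worked example

```bash
python examples/simulate_and_quantify.py
```

```
whole flap (bright zone): ingress  132.1 APU, rate 12.89 APU/s
roi1: ingress  113.8 APU (truth  113.8), rate 10.84 APU/s, onset  3.2 s, peak 13.8 s
roi2: ingress  126.0 APU (truth  126.0), rate 11.72 APU/s, onset  2.5 s, peak 13.2 s
roi3: ingress   31.3 APU (truth   31.2), rate  2.98 APU/s, onset  4.0 s, peak 14.5 s
roi4: ingress   24.4 APU (truth   24.4), rate  2.44 APU/s, onset  6.0 s, peak 16.0 s
```

This is a pattern-1 flap: the perforator zone (ROI2) and the ipsilateral
periphery (ROI1) are well perfused, while the two contralateral zones are
attenuated by the midline block; regional estimates match the closed-form
truth to well under 1 APU at realistic noise. `examples/classify_patterns.py`
shows the classifier recovering all three preset patterns
(`preset 1 -> label 1 ... crossing=0.29`, etc.), and
`examples/cohort_analysis.py` prints the cohort summaries (e.g. whole-flap
ingress "median 113 APU (IQR 83–139)" at n = 40) and the univariate
perfusion-vs-covariate table in Markdown.

A thin CLI wraps the same functions (`flapflow simulate`, `trim`,
`quantify`, `classify`, `simulate-cohort`, `cohort`).

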