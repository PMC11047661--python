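# ocuscreen

Probability-based **in vitro eye-irritation screening** analysis for
micropatterned human corneal epithelial cell (hCEC) assays.

Eye irritation has multiple mechanisms, and no single in vitro readout
predicts it reliably. This package implements an analysis strategy that
combines two mechanistic assays measured on arrays of 80 µm circular cell
micropatterns:

* **apoptosis** — caspase-3/7 fluorescence per cell after 24 h compound
  exposure, and
* **nociceptor (TRPV1) activation** — Fluo-4 calcium influx per cell during
  compound induction,

each digitized to a binary micropattern outcome and fitted to a binary
logistic dose-response model. The per-assay probabilities are then combined
into a single eye-irritation probability. It is aimed at in vitro
toxicologists and high-content screening analysts who want a quantitative,
statistics-backed alternative to single-endpoint cutoff assays.

## Model

Each micropattern (a small colony of ~4.5 ± 2 cells) yields one binary
outcome per assay:

* a cell is **apoptotic** when its caspase intensity exceeds the matched
  vehicle-control mean by more than 20 %:
  (I − Ī_ctrl)/Ī_ctrl > 0.20;
* a cell is a **TRPV1 responder** when the integrated peak area of its
  baseline-subtracted Fluo-4 trace over the 20 frames after induction is
  positive;
* a micropattern scores 1 when ≥ 50 % of its cells score 1.

Pattern outcomes y ∈ {0, 1} at concentration C (nM) follow a logistic law

    P(C) = 1 / (1 + exp(−(β₀ + β₁·C)))

fitted by maximum likelihood (Newton/IRLS), with IC50 = −β₀/β₁ and
pointwise Wald confidence bands. The combined eye-irritation probability
treats the two mechanisms as non-mutually-exclusive events:

    P_irritation(C) = P_apoptosis(C) + P_TRPV1(C) − P_apoptosis(C)·P_TRPV1(C)

(the intersection is modelled as an independence product; other rules can be
plugged in).

A first-class synthetic-data module renders two-channel chips (DAPI +
caspase), Fluo-4 time-lapse stacks and binary dose tables with known ground
truth, so the whole image pipeline — ROI-grid registration, Otsu
auto-threshold nuclei segmentation, 2 px-dilated per-cell intensity
measurement, trace extraction — is testable end to end without any
microscope data.

## Worked example

```python
from ocuscreen import LogisticFit, combine_probabilities, ic50, predict

# published logistic dose-response models (logit intercept, per-nM slope)
sls = LogisticFit.from_coefficients(-1.1057, 1e-6)   # strong surfactant
ema = LogisticFit.from_coefficients(-0.9490, 0.0)    # mild irritant

print(f"SLS apoptosis P at 1.73e7 nM: {predict(sls, 1.73e7):.4f}")
print(f"SLS IC50: {ic50(sls):.4g} nM")
print(f"EMA combined P: {combine_probabilities(predict(ema, 5e5), 0.8):.4f}")
print(f"SLS combined P at 1e5 nM: {combine_probabilities(predict(sls, 1e5), 0.5):.4f}")
```

prints

```
SLS apoptosis P at 1.73e7 nM: 1.0000
SLS IC50: 1.106e+06 nM
EMA combined P: 0.8558
SLS combined P at 1e5 nM: 0.6339
```

SLS (a GHS category 1 irritant) is overwhelmingly cytotoxic at the 0.05 %
w/w exposure level (probability ≈ 1) with an IC50 of about 1 mM, while below
its cytotoxic range its combined irritation probability is only ~0.63. EMA
(category 2B) is barely cytotoxic at any tested dose, but its strong TRPV1
activation (P ≈ 0.8) pushes the combined irritation probability to ~0.86 —
the two compounds are separated by mechanism, not just by magnitude.

An end-to-end synthetic run (simulate chips → segment → digitize → fit →
combine):

```bash
ocuscreen run config.json        # see RunConfig for the schema
ocuscreen simulate --kind chip --out scratch/demo --rows 4 --cols 4
ocuscreen validate-layout scratch/demo.layout.json
```

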