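# respcal

Calibration of respiratory effort belts against spirometer airflow with a
least-squares-trained MISO FIR filter bank.

Respiratory effort belts — elastic transducers around the rib cage and
abdomen — are the workhorse of unobtrusive breathing monitoring, but the
classical calibration, a two-coefficient multiple linear regression

> y = β₁·x₁ + β₂·x₂ + ε,

assumes the belt waveforms already match the airflow waveform.  They do
not, and the mismatch worsens whenever breathing style or body position
changes, or when the rib cage and abdomen move asynchronously.  `respcal`
implements an improved calibration that replaces each scalar coefficient
with an N-tap FIR filter and adds an integer device delay z⁻ᴰ:

> y[i + D] = **β₁**ᵀ **x₁**[i:i+N] + **β₂**ᵀ **x₂**[i:i+N] + ε,

with the taps estimated by least squares on the lagged design matrix and D
by a sliding grid search.  The filters transform each belt's waveform into
the spirometer's, so both the flow waveform and quantities derived from it
(tidal volume, minute ventilation) transfer far better across breathing
rates and postures.  The package also provides the standard regression and
a five-feature minute-ventilation model as baselines, the evaluation
metrics (R², relative RMSE, relative volume error, Bland–Altman data), a
synthetic two-compartment recording generator with protocol presets, and
cross-step / leave-one-subject-out experiment runners.  See
`docs/methods.md` for the model details and modelling choices.

## Worked example

Train on metronome-guided 0.33 Hz breathing and predict 0.10 Hz breathing —
a three-fold rate change, the hardest transfer case:

```python
import respcal as rc

presets = rc.protocol_presets()
train = rc.generate(presets["step8"]).recording   # controlled 0.33 Hz, sitting
test = rc.generate(presets["step9"]).recording    # controlled 0.10 Hz, sitting

model = rc.fit_proposed(train, window_s=0.3, delay_search_s=1.0)
print(f"N = {model.N} taps, D = {model.D} samples")

for name, m in [("standard", rc.fit_standard(train)), ("FIR N=16", model)]:
    rep = rc.compute_report(rc.evaluate(m, test))
    print(f"{name:9s}  R2 = {rep.r_squared:6.3f}   "
          f"relRMSE = {rep.relative_rmse_pct:6.1f} %   "
          f"volume error = {rep.relative_volume_error_pct:+5.1f} %")
```

prints

```
N = 16 taps, D = 12 samples
standard   R2 = -0.728   relRMSE =  131.5 %   volume error = -23.0 %
FIR N=16   R2 =  0.992   relRMSE =    9.0 %   volume error =  +2.1 %
```

The standard calibration, trained at one rate, predicts worse than the mean
at the other (negative R², errors larger than the signal), while the FIR
bank keeps the waveform error below 10 % and the integrated-volume error
within a few percent.

The same workflow is available from the shell:

```sh
respcal simulate --scenario step8 --seed 3 --out rec.csv
respcal fit --input rec.csv --window 0.3 --delay-search 1.0 --out model.json
respcal predict --model model.json --input rec.csv --out pred.csv
respcal evaluate --model model.json --input rec.csv --report report.json
respcal crosstest --config protocol.yaml --out results/
```

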