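# bilicomp

Two-wavelength reflectance bilirubinometry with hemoglobin-interference
compensation — a simulation and analysis toolkit.

## The problem

Total serum bilirubin (TSB) is the diagnostic quantity for neonatal
hyperbilirubinemia. Simple reagent-free reflectance photometers estimate TSB
from the light a plasma-loaded test strip reflects at 465 nm, near the
bilirubin absorption peak. Free hemoglobin from hemolysis — common with
capillary heel-stick collection — also absorbs at 465 nm, so hemolyzed
samples read several mg/dL too high, risking misdiagnosis and overtreatment.
A second channel at 590 nm, where bilirubin absorption is negligible and
hemoglobin dominates, carries a pure hemolysis signal that can be used to
subtract the interference.

`bilicomp` implements that two-wavelength measurement pipeline end to end,
together with a virtual photometer (a seeded optical forward model) so that
every stage can be exercised, tested, and reproduced without laboratory data.
It is intended for people developing or evaluating point-of-care optical
bilirubinometers: it lets you study how hemolysis corrupts the estimate, how
well a linear two-wavelength correction repairs it, and how the accuracy
statistics behave.

## The method

Reflectances are blank-normalized (dimensionless; the 465 nm channel sits
above 100 because both channels are normalized to the dimmer 590 nm blank).

1. **Calibration.** Non-hemolyzed samples at six bilirubin levels
   (0.56–28.00 mg/dL, five replicates each) fit the exponential law

       R₄₆₅ = a · exp(−b · C),

   inverted analytically as C = −ln(R₄₆₅/a)/b.

2. **Compensation.** On a 5 bilirubin-level × 5 hemolysis-level × 5-replicate
   panel (125 tests), the least-hemolyzed group provides references
   R₄₆₅,ref (per bilirubin level) and a pooled R₅₉₀,ref. Per-sample mean
   deficits

       ΔR₅₉₀ = R₅₉₀,ref − R₅₉₀,    ΔR₄₆₅ = R₄₆₅,ref − R₄₆₅

   are related by ordinary least squares, ΔR₄₆₅ = m·ΔR₅₉₀ + c. For an
   individual test the hemoglobin-induced deficit predicted from its own
   ΔR₅₉₀ is added back before inverting the calibration:

       R₄₆₅,corrected = R₄₆₅ + m·(R₅₉₀,ref − R₅₉₀) + c.

3. **Evaluation.** Per-level mean ± SD and RMSE, pooled RMSE, and
   Bland–Altman bias with 1.96·SD limits of agreement, for the compensated
   and uncompensated arms side by side.

## Worked example

```python
from bilicomp import run_pipeline
print(run_pipeline(seed=42).report.to_text())
```

```
  Nominal         Non-compensated    RMSE             Compensated    RMSE
  [mg/dL]       mean ± SD [mg/dL]               mean ± SD [mg/dL]
---------------------------------------------------------------------------
     4.96             8.96 ± 2.91    4.91             5.60 ± 0.59    0.86
     9.67            13.68 ± 3.08    5.02             9.95 ± 0.49    0.55
    14.47            18.52 ± 2.96    4.98            14.44 ± 0.37    0.36
    19.33            23.34 ± 3.05    5.01            18.91 ± 0.47    0.62
    28.00            32.03 ± 3.09    5.04            26.82 ± 0.92    1.48
---------------------------------------------------------------------------
   pooled                            4.99                            0.87
RMSE ratio (comp/non-comp): 0.174   n = 125
Bias (est − nominal): +4.02 → -0.14 mg/dL; LoA non-comp [-1.80, +9.84], comp [-1.83, +1.54]
```

Each row is one nominal bilirubin level of the 125-test synthetic panel.
Uncompensated estimates run ~4–6 mg/dL high — hemolysis read as bilirubin —
with pooled RMSE 4.99 mg/dL; the two-wavelength correction removes the
systematic excess, cutting pooled RMSE to 0.87 mg/dL and bias to
−0.14 mg/dL. The `examples/` directory walks through each capability
(forward model, calibration, compensation, evaluation) as a short narrative
script.

The same workflow is available from the shell:

```sh
bilicomp reproduce --seed 42 --out run/
```

which writes the simulated panels, fitted model JSONs, both estimate CSVs,
and the text/JSON report, byte-reproducibly for a given seed. The
`simulate`, `calibrate`, `fit-comp`, `estimate`, and `evaluate` subcommands
expose the individual stages for work with externally supplied CSVs.

## Documentation

`docs/methods.md` describes the optical forward model, the default
parameters and what they emulate, the numerical choices, and the known
limitations of the synthetic study.
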