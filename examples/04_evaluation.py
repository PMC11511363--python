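"""End-to-end accuracy study: per-level errors and Bland–Altman agreement.

Runs the seeded pipeline (simulate calibration series + 125-test panel, fit
both models, estimate each test with and without compensation) and prints
the comparison report.
"""

from bilicomp import run_pipeline

result = run_pipeline(seed=42)
print(result.report.to_text())
print()
ba = result.report.agreement_comp
print(
    "Reading the table: uncompensated estimates overestimate by several\n"
    "mg/dL (hemolysis read as bilirubin); compensation cuts the pooled RMSE\n"
    f"by {100 * (1 - result.report.rmse_ratio):.0f}% and brings the bias to "
    f"{ba.bias:+.2f} mg/dL with limits of agreement\n"
    f"[{ba.loa_lower:+.2f}, {ba.loa_upper:+.2f}] mg/dL."
)
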