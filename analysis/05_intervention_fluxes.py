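"""In silico G6PD inhibition (DHEA, 20%) across the condition grid.

Compares the 60-min time-integrated semiquinone-formation flux (CPR
reduction, R1) and NADPH-dependent superoxide flux (NOX, R4) with and
without DHEA for both cell lines at both doses.

Finding: DHEA measurably lowers the superoxide flux at 10 uM — most in
the NADPH-poor EU1-Res line (ratio ~0.989) and only marginally in
EU3-Sens (~0.996) — and leaves the semiquinone flux within 0.01%
everywhere: with the printed constants the G6PD supply always
re-equilibrates NADPH before the CPR cycle becomes substrate-limited.
"""

import csv
from pathlib import Path

from doxcycle import compare_intervention_fluxes

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    print("cell line  dose   semiquinone ratio  superoxide ratio")
    for c in compare_intervention_fluxes():
        rows.append([c.cell_line, c.dose, c.intervention,
                     f"{c.semiquinone_control:.12g}",
                     f"{c.semiquinone_intervention:.12g}",
                     f"{c.superoxide_control:.12g}",
                     f"{c.superoxide_intervention:.12g}",
                     f"{c.ratio('semiquinone'):.6f}",
                     f"{c.ratio('superoxide'):.6f}"])
        print(f"{c.cell_line:10s} {c.dose:5s}  "
              f"{c.ratio('semiquinone'):.6f}           "
              f"{c.ratio('superoxide'):.6f}")
    out = RESULTS / "intervention_fluxes.csv"
    with open(out, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_line", "dose", "intervention",
                        "semiquinone_control_M", "semiquinone_dhea_M",
                        "superoxide_control_M", "superoxide_dhea_M",
                        "semiquinone_ratio", "superoxide_ratio"])
        writer.writerows(rows)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
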