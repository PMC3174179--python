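"""Refit the cell-free rate constants from synthetic assay data.

Generates the three stage datasets (redox cycling, reductive conversion,
SOD-induced redox cycling) from the tabulated model — noiseless and with
2% replicate noise — and runs the staged single-parameter fits for k1
(CPR reduction of quinone), k4 (non-enzymatic NADPH/O2) and k5
(superoxide reduction of quinone), each started one decade off the truth.

Finding: noiseless refits recover all three constants to <0.1%.  Under 2%
noise k1 and k4 stay within ~5-15%, while k5 is structurally
non-identifiable (its flux is production-limited, so the time courses are
insensitive to the constant over two decades).
"""

import json
from pathlib import Path

from doxcycle import (NoiseModel, pipeline_datasets, run_invitro_pipeline)

RESULTS = Path(__file__).resolve().parents[1] / "results"
TRUTH = {"k1": 1.2e4, "k4": 2.9e1, "k5": 5.5e7}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    report = {}
    for label, noise in [
        ("noiseless", NoiseModel(sigma=0.0, replicates=1, seed=0)),
        ("noise_2pct", NoiseModel(sigma=0.02, replicates=3, seed=1)),
    ]:
        results = run_invitro_pipeline(pipeline_datasets("invitro", noise))
        report[label] = {}
        print(f"-- {label}")
        for r in results:
            err = 100.0 * abs(r.value / TRUTH[r.target] - 1.0)
            report[label][r.target] = {
                "fitted": r.value, "truth": TRUTH[r.target],
                "error_pct": err, "cost": r.cost,
                "evaluations": r.n_evaluations, "converged": r.converged,
            }
            print(f"   {r.target}: fitted {r.value:.4g} "
                  f"(truth {TRUTH[r.target]:.3g}, error {err:.2f}%)")
    out = RESULTS / "fits_invitro.json"
    out.write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
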