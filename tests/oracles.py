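"""Independent hand-transcribed right-hand sides for oracle comparisons.

These derivative functions are written directly from the model's reaction
tables, species by species, without using the network engine — they are
the brute-force reference the engine is checked against.
"""

from __future__ import annotations


def invitro_rhs(conc: dict, p: dict, sod: bool = False,
                k_sod: float = 0.0, sod_conc: float = 0.0) -> dict:
    """9-equation cell-free derivative, hand-coded reaction by reaction."""
    r1 = p["k1"] * conc["CPR_red"] * conc["Dox_q"]
    r2 = p["k2"] * conc["CPR_ox"] * conc["NADPH"]
    r3 = p["k3"] * conc["O2"] * conc["Dox_sq"]
    r4 = p["k4"] * conc["NADPH"] * conc["O2"]
    r5 = p["k5"] * conc["O2minus"] * conc["Dox_q"]
    r6 = p["k6"] * conc["O2minus"] * conc["O2minus"]
    rs = k_sod * sod_conc * conc["O2minus"] if sod else 0.0
    return {
        "CPR_red": -r1 + r2,
        "CPR_ox": r1 - r2,
        "Dox_q": -r1 + r3 - r5,
        "Dox_sq": r1 - r3 + r5,
        "NADPH": -r2 - r4,
        "NADP": r2 + r4,
        "O2": -r3 - r4 + r5 + 0.5 * rs,
        "O2minus": r3 + r4 - r5 - 2.0 * r6 - rs,
        "H2O2": r6 + 0.5 * rs,
    }


def invivo_rhs(conc: dict, p: dict, rho: float, k_dox: float,
               modulated: bool = True, clamp_o2: bool = False) -> dict:
    """10-equation cellular derivative, hand-coded reaction by reaction."""
    r1 = p["k1"] * conc["CPR_red"] * conc["In_Dox_q"]
    r2 = p["k2"] * conc["CPR_ox"] * conc["NADPH"]
    r3 = p["k3"] * conc["O2"] * conc["In_Dox_sq"]
    r4 = p["k4"] * conc["NADPH"] * conc["O2"]
    if modulated:
        r4 *= conc["In_Dox_q"] / (conc["In_Dox_q"] + k_dox)
    r5 = p["k5"] * conc["O2minus"] * conc["In_Dox_q"]
    r6 = p["k6"] * conc["O2minus"] * conc["O2minus"]
    r7 = p["k7"] * p["A"] * conc["Ex_Dox_q"]
    r8 = p["k8"] * conc["NADP"] / (p["k9"] + conc["NADP"])
    d = {
        "CPR_red": -r1 + r2,
        "CPR_ox": r1 - r2,
        "Ex_Dox_q": -r7,
        "In_Dox_q": -r1 + r3 - r5 + r7 / rho,
        "In_Dox_sq": r1 - r3 + r5,
        "NADPH": -r2 - r4 + r8,
        "NADP": r2 + r4 - r8,
        "O2": -r3 - r4 + r5 + r6,
        "O2minus": r3 + r4 - r5 - 2.0 * r6,
        "H2O2": r6,
    }
    if clamp_o2:
        d["O2"] = 0.0
    return d
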