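"""Independent hand-written right-hand side for the 33-variable model.

Every differential equation is written out literally from the reaction
scheme, species by species, without using the package's stoichiometry
machinery. Serves as the oracle for `evaluate_derivatives`.
"""

from __future__ import annotations


def oracle_rhs(c: dict[str, float], k: dict[str, float], ras: float) -> dict[str, float]:
    """dx/dt for every species, by name. `c` maps species name to
    concentration, `k` maps rate symbol to value, `ras` is the momentary
    Ras-GTP activity."""
    # cytosolic fluxes
    b1 = k["a1"] * ras * c["Raf"]
    u1 = k["d1"] * c["Ras:Raf"]
    c1 = k["k1"] * c["Ras:Raf"]
    b2 = k["a2"] * c["P_Raf"] * c["Raf*"]
    u2 = k["d2"] * c["Raf*:P_Raf"]
    c2 = k["k2"] * c["Raf*:P_Raf"]
    b3 = k["a3"] * c["Raf*"] * c["MEK"]
    u3 = k["d3"] * c["Raf*:MEK"]
    c3 = k["k3"] * c["Raf*:MEK"]
    c4 = k["k4"] * c["Raf*:MEKp"]
    b4 = k["a4"] * c["MEKpp"] * c["P_MEK"]
    u4 = k["d4"] * c["P_MEK:MEKpp"]
    c5 = k["k5"] * c["P_MEK:MEKpp"]
    c6 = k["k6"] * c["P_MEK:MEKp"]
    b5 = k["a5"] * c["MEKpp"] * c["ERK"]
    u5 = k["d5"] * c["MEKpp:ERK"]
    c7 = k["k7"] * c["MEKpp:ERK"]
    b6 = k["a6"] * c["MEKpp"] * c["ERKp"]
    u6 = k["d6"] * c["MEKpp:ERKp"]
    c8 = k["k8"] * c["MEKpp:ERKp"]
    b7 = k["a7"] * c["P_ERK"] * c["ERKpp"]
    u7 = k["d7"] * c["P_ERK:ERKpp"]
    c9 = k["k9"] * c["P_ERK:ERKpp"]
    b8 = k["a8"] * c["P_ERK"] * c["ERKp"]
    u8 = k["d8"] * c["P_ERK:ERKp"]
    c10 = k["k10"] * c["P_ERK:ERKp"]
    # shuttling (in: cytosol -> nucleus)
    s_mek_i = k["kin_MEK"] * c["MEK"]
    s_mek_o = k["kout_MEK"] * c["N-MEK"]
    s_mpp_i = k["kin_MEKpp"] * c["MEKpp"]
    s_mpp_o = k["kout_MEKpp"] * c["N-MEKpp"]
    s_erk_i = k["kin_ERK"] * c["ERK"]
    s_erk_o = k["kout_ERK"] * c["N-ERK"]
    s_ekp_i = k["kin_ERKp"] * c["ERKp"]
    s_ekp_o = k["kout_ERKp"] * c["N-ERKp"]
    s_epp_i = k["kin_ERKpp"] * c["ERKpp"]
    s_epp_o = k["kout_ERKpp"] * c["N-ERKpp"]
    # nuclear fluxes
    b9 = k["a9"] * c["N-MEKpp"] * c["N-ERK"]
    u9 = k["d9"] * c["N-MEKpp:N-ERK"]
    c11 = k["k11"] * c["N-MEKpp:N-ERK"]
    b10 = k["a10"] * c["N-MEKpp"] * c["N-ERKp"]
    u10 = k["d10"] * c["N-MEKpp:N-ERKp"]
    c12 = k["k12"] * c["N-MEKpp:N-ERKp"]
    b11 = k["a11"] * c["N-MEKpp"] * c["N-P_MEK"]
    u11 = k["d11"] * c["N-P_MEK:N-MEKpp"]
    c13 = k["k13"] * c["N-P_MEK:N-MEKpp"]
    c14 = k["k14"] * c["N-P_MEK:N-MEKp"]
    b12 = k["a12"] * c["N-ERKpp"] * c["N-P_ERK"]
    u12 = k["d12"] * c["N-P_ERK:N-ERKpp"]
    c15 = k["k15"] * c["N-P_ERK:N-ERKpp"]
    b13 = k["a13"] * c["N-ERKp"] * c["N-P_ERK"]
    u13 = k["d13"] * c["N-P_ERK:N-ERKp"]
    c16 = k["k16"] * c["N-P_ERK:N-ERKp"]

    return {
        "Raf": -b1 + u1 + c2,
        "Ras:Raf": b1 - u1 - c1,
        "Raf*": c1 - b2 + u2 - b3 + u3 + c4,
        "Raf*:P_Raf": b2 - u2 - c2,
        "P_Raf": -b2 + u2 + c2,
        "MEK": -b3 + u3 + c6 - s_mek_i + s_mek_o,
        "Raf*:MEK": b3 - u3 - c3,
        "Raf*:MEKp": c3 - c4,
        "MEKpp": c4 - b4 + u4 - b5 + u5 + c7 - b6 + u6 + c8 - s_mpp_i + s_mpp_o,
        "P_MEK:MEKpp": b4 - u4 - c5,
        "P_MEK:MEKp": c5 - c6,
        "P_MEK": -b4 + u4 + c6,
        "ERK": -b5 + u5 + c10 - s_erk_i + s_erk_o,
        "MEKpp:ERK": b5 - u5 - c7,
        "ERKp": c7 - b6 + u6 + c9 - b8 + u8 - s_ekp_i + s_ekp_o,
        "MEKpp:ERKp": b6 - u6 - c8,
        "ERKpp": c8 - b7 + u7 - s_epp_i + s_epp_o,
        "P_ERK:ERKpp": b7 - u7 - c9,
        "P_ERK:ERKp": b8 - u8 - c10,
        "P_ERK": -b7 + u7 + c9 - b8 + u8 + c10,
        "N-MEK": s_mek_i - s_mek_o + c14,
        "N-MEKpp": s_mpp_i - s_mpp_o - b9 + u9 + c11 - b10 + u10 + c12 - b11 + u11,
        "N-ERK": s_erk_i - s_erk_o - b9 + u9 + c16,
        "N-MEKpp:N-ERK": b9 - u9 - c11,
        "N-ERKp": s_ekp_i - s_ekp_o + c11 - b10 + u10 + c15 - b13 + u13,
        "N-MEKpp:N-ERKp": b10 - u10 - c12,
        "N-ERKpp": s_epp_i - s_epp_o + c12 - b12 + u12,
        "N-P_MEK": -b11 + u11 + c14,
        "N-P_MEK:N-MEKpp": b11 - u11 - c13,
        "N-P_MEK:N-MEKp": c13 - c14,
        "N-P_ERK": -b12 + u12 + c15 - b13 + u13 + c16,
        "N-P_ERK:N-ERKpp": b12 - u12 - c15,
        "N-P_ERK:N-ERKp": b13 - u13 - c16,
    }
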