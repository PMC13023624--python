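"""Theoretical methane potential (Buswell stoichiometry) and biodegradability.

A substrate CnHaObNc digested anaerobically with water yields CH4, CO2 and
NH3 according to the Buswell total reaction:

    CnHaObNc + (n - a/4 - b/2 + 3c/4) H2O ->
        (n/2 + a/8 - b/4 - 3c/8) CH4 + (n/2 - a/8 + b/4 + 3c/8) CO2 + c NH3

so the theoretical methane potential on a mass basis is

    TMP = 22.4 * 1000 * (n/2 + a/8 - b/4 - 3c/8) / (12n + a + 16b + 14c)   [mL/g]

using a 22.4 L/mol molar volume and nominal atomic masses 12/1/16/14 (the
conventional form of the formula, kept verbatim rather than CODATA values so
results match the standard printed expression).  Biodegradability is the
ratio of experimental to theoretical methane production, BD = EMP/TMP * 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MOLAR_VOLUME_ML = 22.4 * 1000.0  # mL CH4 per mol at STP, nominal
ATOMIC_MASS = {"C": 12.0, "H": 1.0, "O": 16.0, "N": 14.0}  # nominal


@dataclass
class ElementalComposition:
    """Dry-basis elemental mass percentages."""

    c_pct: float
    h_pct: float
    o_pct: float
    n_pct: float = 0.0
    vs_fraction: float | None = None

    def __post_init__(self) -> None:
        for name in ("c_pct", "h_pct", "o_pct", "n_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = self.c_pct + self.h_pct + self.o_pct + self.n_pct
        if total > 101.0:
            raise ValueError(f"element percentages sum to {total:.2f} > 101%")


@dataclass
class MolecularSubscripts:
    """Molar subscripts (n, a, b, c) of CnHaObNc; scale is arbitrary."""

    n: float
    a: float
    b: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("carbon subscript n must be > 0")
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("subscripts must be >= 0")


@dataclass
class StoichResult:
    tmp: float  # mL CH4 per g substrate
    ch4_coeff: float
    co2_coeff: float
    nh3_coeff: float
    h2o_coeff: float
    basis: str = "per_g_dry"


@dataclass
class BiodegradabilityResult:
    emp: float
    tmp: float
    bd: float  # percent
    basis: str = "emp_per_g_vs__tmp_per_g_dry"


def composition_to_subscripts(comp: ElementalComposition) -> MolecularSubscripts:
    """Molar subscripts from mass percentages (per 100 g dry matter).

    Subscripts are mass% / nominal atomic mass; TMP is invariant to their
    overall scale so no normalization is applied.
    """
    if comp.c_pct <= 0:
        raise ValueError("carbon content must be > 0")
    return MolecularSubscripts(
        n=comp.c_pct / ATOMIC_MASS["C"],
        a=comp.h_pct / ATOMIC_MASS["H"],
        b=comp.o_pct / ATOMIC_MASS["O"],
        c=comp.n_pct / ATOMIC_MASS["N"],
    )


def buswell(subs: MolecularSubscripts) -> StoichResult:
    """Buswell reaction coefficients and theoretical methane potential.

    Raises if the methane coefficient is non-positive (a fully oxidized
    substrate cannot be methanized).
    """
    n, a, b, c = subs.n, subs.a, subs.b, subs.c
    ch4 = n / 2 + a / 8 - b / 4 - 3 * c / 8
    if ch4 <= 0:
        raise ValueError("substrate is not methanogenic: CH4 coefficient <= 0")
    co2 = n / 2 - a / 8 + b / 4 + 3 * c / 8
    h2o = n - a / 4 - b / 2 + 3 * c / 4
    mass = 12 * n + a + 16 * b + 14 * c
    tmp = MOLAR_VOLUME_ML * ch4 / mass
    return StoichResult(tmp=float(tmp), ch4_coeff=float(ch4), co2_coeff=float(co2),
                        nh3_coeff=float(c), h2o_coeff=float(h2o))


def element_balance_check(subs: MolecularSubscripts, result: StoichResult,
                          rel_tol: float = 1e-9) -> dict[str, dict[str, float | bool]]:
    """Per-element closure report for the total reaction.

    Compares atoms on the left (substrate + water) with the right
    (CH4 + CO2 + NH3) for C, H, O and N; each must balance to within
    ``rel_tol`` relative to the larger side.
    """
    left = {
        "C": subs.n,
        "H": subs.a + 2 * result.h2o_coeff,
        "O": subs.b + result.h2o_coeff,
        "N": subs.c,
    }
    right = {
        "C": result.ch4_coeff + result.co2_coeff,
        "H": 4 * result.ch4_coeff + 3 * result.nh3_coeff,
        "O": 2 * result.co2_coeff,
        "N": result.nh3_coeff,
    }
    report = {}
    for el in "CHON":
        scale = max(abs(left[el]), abs(right[el]), 1.0)
        imbalance = abs(left[el] - right[el]) / scale
        report[el] = {"imbalance": float(imbalance), "pass": bool(imbalance <= rel_tol)}
    return report


def biodegradability(
    emp: float,
    tmp: float,
    emp_basis: str = "per_g_vs",
    tmp_basis: str = "per_g_dry",
    vs_fraction: float | None = None,
    align_basis: bool = False,
) -> BiodegradabilityResult:
    """BD = 100 * EMP / TMP, with an explicit basis flag.

    EMP is conventionally per g VS while elemental TMP is per g dry matter.
    By default the ratio is taken as-is and the mixed basis recorded; with
    ``align_basis=True`` the TMP is converted to per-g-VS using
    ``vs_fraction`` (VS/TS) before dividing.
    """
    if tmp <= 0:
        raise ValueError("tmp must be > 0")
    if emp < 0:
        raise ValueError("emp must be >= 0")
    basis = f"emp_{emp_basis}__tmp_{tmp_basis}"
    if align_basis and emp_basis != tmp_basis:
        if vs_fraction is None:
            raise ValueError("basis alignment requested but vs_fraction not supplied")
        if not 0 < vs_fraction <= 1:
            raise ValueError("vs_fraction must lie in (0, 1]")
        tmp = tmp / vs_fraction  # per g dry -> per g VS
        basis = f"emp_{emp_basis}__tmp_{emp_basis}"
    return BiodegradabilityResult(emp=emp, tmp=tmp, bd=100.0 * emp / tmp, basis=basis)


def tmp_from_composition(comp: ElementalComposition) -> StoichResult:
    """Convenience chain: mass percentages -> subscripts -> Buswell TMP."""
    return buswell(composition_to_subscripts(comp))
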