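"""Generalized environmental decomposition of the NN free energies.

Each NN parameter under a crowding condition is composed as

    ΔG°_NN = ΔG°_NN,bulk + ΔG°_NN,cation + ΔG°_NN,ev + ΔG°_NN,wa

where the excluded-volume term follows the cylinder/polymer-chain model

    ΔG°₃₇,ev,dup / (C·N) = −0.019·n − 0.070        (6–12 bp fit)
    ΔG°₃₇,NN,ev          = ΔG°₃₇,ev,dup / n

(C: cosolute molality in mol per kg water, N: monomers per cosolute
molecule, n: base pairs) and the water-activity term is linear in the
water-activity depression Δa_w = a_no-cosolute − a_cosolute:

    ΔG°₃₇,NN,wa = m_cs·Δa_w

with the prefactor m_cs set by the cosolute's chemical class: cosolutes
without vicinal hydroxyls (PEGs, 2-methoxyethanol, 1,2-dimethoxyethane)
destabilize more strongly than vicinal-diol-like ones (ethylene glycol,
glycerol, 1,3-propanediol), whose prefactors are the PEG column scaled by
the common slope ratio (≈0.411).

Conventions (documented assumptions):

* wt% means grams of cosolute per 100 g of water, so C = 10·w/M.  This
  convention — not mass fraction — reproduces the tabled worked examples.
* PEG monomer counts are round((M − 18)/44) (PEG200 → 4); the small
  cosolutes count as a single monomer.
* Composed sets are ΔG°₃₇-only: the decomposition exists for ΔG°₃₇, so no
  ΔH°/ΔS° (and hence no Tm) is available under arbitrary crowding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from . import cations
from .tables import (
    DecomposedGibbs,
    FREE_PARAMETERS,
    NNParameterSet,
    T37,
    ThermoTriple,
    _data_path,
)
from .thermo import R_KCAL

N_AVOGADRO = 6.022e23
M_WATER_KG = 0.018  # kg/mol
R_J = 8.314  # J/mol/K
RHO_WATER = 1.0  # kg/L, density of water in the ev relation

PEG_CLASS = "peg_class"
DIOL_CLASS = "diol_class"
CUSTOM_CLASS = "custom"

EV_FIT_RANGE = (6, 12)  # bp range of the excluded-volume linear fit


class CrowdingError(ValueError):
    pass


def peg_monomer_count(molar_mass: float) -> int:
    """Ethylene-oxide monomer count of a PEG: round((M − 18)/44), min 1."""
    return max(1, round((molar_mass - 18.0) / 44.0))


@dataclass(frozen=True)
class Cosolute:
    """A crowding cosolute: identity, size and water-activity class."""

    name: str
    molar_mass: float  # g/mol
    n_monomers: int = 1
    cls: str = CUSTOM_CLASS
    slope_ratio: float | None = None  # S_CS/S_PEG, required iff cls=custom

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise CrowdingError("molar mass must be positive")
        if self.n_monomers < 1:
            raise CrowdingError("monomer count must be >= 1")
        if self.cls not in (PEG_CLASS, DIOL_CLASS, CUSTOM_CLASS):
            raise CrowdingError(f"unknown cosolute class {self.cls!r}")


#: Bundled cosolutes of the two calibrated chemical classes.
COSOLUTES: dict[str, Cosolute] = {
    "PEG200": Cosolute("PEG200", 200.0, peg_monomer_count(200.0), PEG_CLASS),
    "PEG400": Cosolute("PEG400", 400.0, peg_monomer_count(400.0), PEG_CLASS),
    "PEG600": Cosolute("PEG600", 600.0, peg_monomer_count(600.0), PEG_CLASS),
    "2-methoxyethanol": Cosolute("2-methoxyethanol", 76.09, 1, PEG_CLASS),
    "1,2-dimethoxyethane": Cosolute("1,2-dimethoxyethane", 90.12, 1, PEG_CLASS),
    "ethylene glycol": Cosolute("ethylene glycol", 62.07, 1, DIOL_CLASS),
    "glycerol": Cosolute("glycerol", 92.09, 1, DIOL_CLASS),
    "1,3-propanediol": Cosolute("1,3-propanediol", 76.09, 1, DIOL_CLASS),
}
_ALIASES = {
    "EG": "ethylene glycol",
    "Gly": "glycerol",
    "1,3-PDO": "1,3-propanediol",
    "2-ME": "2-methoxyethanol",
    "1,2-DME": "1,2-dimethoxyethane",
}


def get_cosolute(name: str) -> Cosolute:
    key = _ALIASES.get(name, name)
    try:
        return COSOLUTES[key]
    except KeyError:
        raise CrowdingError(
            f"unknown cosolute {name!r}; bundled: {sorted(COSOLUTES)}; "
            "build a Cosolute(...) for anything else"
        ) from None


@dataclass(frozen=True)
class SolutionCondition:
    """A solution environment for composing condition-specific parameters.

    ``delta_aw`` is the water-activity depression caused by the cosolute
    (a_no-cosolute − a_cosolute).  It may be given directly, derived from a
    measured osmolality of the cosolute solution, or looked up from the
    small bundled table; a missing value is an error, never silently zero.
    """

    cosolute: Cosolute | None = None
    wt_pct: float = 0.0
    delta_aw: float | None = None
    osmolality_mmol_kg: float | None = None
    na_mM: float = 122.0
    cation_mode: str = "sodium"  # sodium | potassium | intracellular
    na_model: str | None = None
    temperature: float = T37

    def __post_init__(self) -> None:
        if self.wt_pct < 0:
            raise CrowdingError("wt_pct must be >= 0")
        if self.delta_aw is not None and not (0 <= self.delta_aw < 1):
            raise CrowdingError("delta_aw must be in [0, 1)")
        if self.cation_mode not in ("sodium", "potassium", "intracellular"):
            raise CrowdingError(f"unknown cation_mode {self.cation_mode!r}")
        if self.cation_mode == "sodium" and self.na_mM <= 0:
            raise CrowdingError("na_mM must be positive in sodium mode")


# --- water activity ---------------------------------------------------------

def water_activity_from_osmolality(
    osmolality_mmol_kg: float, T: float = 298.15
) -> float:
    """Water activity from osmometer readout.

    Water potential Ψ = osmolality(mmol/kg)·10³/(−400), interpreted in kPa
    (the only reading dimensionally consistent with Ψ = (RT/M_w)·ln a_w;
    it reproduces the physical benchmark a_w ≈ 0.982 at 1 osmol/kg).
    """
    if osmolality_mmol_kg < 0:
        raise CrowdingError("osmolality must be non-negative")
    psi_pa = osmolality_mmol_kg * 1e3 / (-400.0) * 1e3  # kPa -> Pa
    ln_aw = psi_pa * M_WATER_KG / (R_J * T * 1000.0 * RHO_WATER)
    return math.exp(ln_aw)


_AW_LOOKUP: dict[tuple[str, float], float] | None = None


def _aw_lookup() -> dict[tuple[str, float], float]:
    global _AW_LOOKUP
    if _AW_LOOKUP is None:
        df = pd.read_csv(_data_path("water_activity.tsv"), sep="\t")
        _AW_LOOKUP = {
            (str(r.cosolute), float(r.wt_pct)): float(r.delta_aw)
            for r in df.itertuples()
        }
    return _AW_LOOKUP


def resolve_delta_aw(solution: SolutionCondition) -> float:
    """Δa_w of a condition: direct value, osmometry, or bundled lookup."""
    if solution.cosolute is None and solution.wt_pct == 0:
        return 0.0
    if solution.delta_aw is not None:
        return solution.delta_aw
    if solution.osmolality_mmol_kg is not None:
        aw = water_activity_from_osmolality(
            solution.osmolality_mmol_kg, solution.temperature
        )
        return 1.0 - aw
    if solution.cosolute is not None:
        key = (solution.cosolute.name, float(solution.wt_pct))
        table = _aw_lookup()
        if key in table:
            return table[key]
    raise CrowdingError(
        "delta_aw unknown for this condition: supply delta_aw directly, an "
        "osmolality, or a (cosolute, wt%) pair present in the bundled lookup"
    )


# --- excluded volume --------------------------------------------------------

def molality(wt_pct: float, cosolute: Cosolute) -> float:
    """Cosolute molality C (mol per kg water) from wt% = g per 100 g water."""
    if wt_pct < 0:
        raise CrowdingError("wt_pct must be >= 0")
    return 10.0 * wt_pct / cosolute.molar_mass


def excluded_volume_generic(N: float, l: float, k: float) -> float:
    """Excluded volume V = N·l²·N_A·k·10⁻²⁷ (L/mol).

    N: monomers per cosolute; l: statistical segment length (Å); k:
    geometrical factor from the RNA cylinder's length and radius (Å).
    """
    if N <= 0 or l <= 0 or k <= 0:
        raise CrowdingError("N, l and k must all be positive")
    return N * l**2 * N_AVOGADRO * k * 1e-27


def delta_excluded_volume(v_dup: float, v_ss: float) -> float:
    """ΔV = V_dup − 2·V_ss (L/mol) for bimolecular duplex formation."""
    return v_dup - 2.0 * v_ss


def ev_free_energy(delta_v: float, C: float, T: float = T37) -> float:
    """ΔG°_ev = R·T·ρ·ΔV·C (kcal/mol) from a generic excluded-volume change."""
    return R_KCAL * T * RHO_WATER * delta_v * C


def excluded_volume_duplex(n_bp: int, C: float, N: float) -> float:
    """Duplex-level excluded-volume term, ΔG°₃₇,ev,dup (kcal/mol).

    (−0.019·n − 0.070)·C·N from the linear length fit; always ≤ 0.  Warns
    outside the 6–12 bp range the fit was established on.
    """
    if n_bp < 2:
        raise CrowdingError("need at least 2 base pairs")
    if C < 0:
        raise CrowdingError("molality must be >= 0")
    if C > 0 and not (EV_FIT_RANGE[0] <= n_bp <= EV_FIT_RANGE[1]):
        warnings.warn(
            f"excluded-volume length fit was established for "
            f"{EV_FIT_RANGE[0]}-{EV_FIT_RANGE[1]} bp; n={n_bp} extrapolates",
            stacklevel=2,
        )
    return (-0.019 * n_bp - 0.070) * C * N


def excluded_volume_per_nn(dG_ev_dup: float, n_bp: int) -> float:
    """Per-parameter share of the duplex excluded-volume term (÷ n).

    Applied to each propagating stack and to initiation — n terms in
    total for an n-bp duplex — but never to the terminal A·U penalty
    (its share is already inside initiation).
    """
    if n_bp < 1:
        raise CrowdingError("n_bp must be >= 1")
    return dG_ev_dup / n_bp


# --- water-activity prefactors and composition ------------------------------

def wa_contribution(m_cs: float, delta_aw: float) -> float:
    """ΔG°₃₇,NN,wa = m_cs·Δa_w (kcal/mol)."""
    return m_cs * delta_aw


def m_cs_for(
    cosolute: Cosolute, decomposition: DecomposedGibbs
) -> dict[str, float]:
    """Per-parameter water-activity prefactors for a cosolute.

    PEG-class cosolutes use the m_PEG column as is; diol-class ones the
    m_diol column; a custom cosolute scales m_PEG by its slope ratio
    S_CS/S_PEG.
    """
    if cosolute.cls == PEG_CLASS:
        return dict(decomposition.m_peg_class)
    if cosolute.cls == DIOL_CLASS:
        return dict(decomposition.m_diol_class)
    if cosolute.slope_ratio is None:
        raise CrowdingError(
            f"custom cosolute {cosolute.name!r} needs slope_ratio (S_CS/S_PEG)"
        )
    return {
        p: cosolute.slope_ratio * m
        for p, m in decomposition.m_peg_class.items()
    }


def compose_condition_parameters(
    decomposition: DecomposedGibbs,
    solution: SolutionCondition,
    n_bp: int,
) -> NNParameterSet:
    """Compose a ΔG°₃₇-only NN parameter set for a crowding condition.

    Propagating stacks and initiation get bulk + cation + per-NN excluded
    volume + m_cs·Δa_w; the terminal A·U penalty gets bulk + m_cs·Δa_w
    only (no cation, no excluded-volume term).  The symmetry correction is
    condition-independent.  The result feeds ``predict_duplex`` but carries
    no ΔH°/ΔS°, so Tm prediction under composed conditions is refused.

    ``n_bp`` is the duplex length the per-NN excluded-volume share is
    computed for: predicting an n-bp duplex with a set composed at the same
    n reconstitutes the duplex-level term exactly (n − 1 stacks plus
    initiation = n shares).
    """
    if solution.temperature != T37:
        warnings.warn(
            "composition is defined at 310.15 K; temperature adjustment "
            "requires a full dH/dS parameter set",
            stacklevel=2,
        )
    cat = cations.cation_term(solution.na_mM, decomposition, solution.na_model)
    if solution.cosolute is not None and solution.wt_pct > 0:
        delta_aw = resolve_delta_aw(solution)
        C = molality(solution.wt_pct, solution.cosolute)
        ev_dup = excluded_volume_duplex(n_bp, C, solution.cosolute.n_monomers)
        ev_nn = excluded_volume_per_nn(ev_dup, n_bp)
        m = m_cs_for(solution.cosolute, decomposition)
        cos_label = f"{solution.wt_pct:g} wt% {solution.cosolute.name}"
    else:
        delta_aw = 0.0
        ev_nn = 0.0
        m = {p: 0.0 for p in FREE_PARAMETERS}
        cos_label = "no cosolute"

    values: dict[str, ThermoTriple] = {}
    for p in FREE_PARAMETERS:
        total = decomposition.dG_bulk[p] + cat[p] + wa_contribution(m[p], delta_aw)
        if p != "terminal_AU":
            total += ev_nn
        values[p] = ThermoTriple(dH=None, dS=None, dG37=total)
    values["symmetry"] = ThermoTriple(dH=0.0, dS=-1.4e-3, dG37=0.43)
    return NNParameterSet(
        condition_label=(
            f"composed: {cos_label}, {solution.na_mM:g} mM Na+, "
            f"n_bp={n_bp}, delta_aw={delta_aw:g}"
        ),
        values=values,
        source=decomposition.source,
        source_sha256=decomposition.source_sha256,
    )


def predict_in_condition(duplex, solution: SolutionCondition, decomposition: DecomposedGibbs):
    """End-to-end ΔG°₃₇ prediction for a duplex in a crowding condition.

    Composes a parameter set at the duplex's own length, runs the NN sum,
    then — for potassium or intracellular cation modes — applies the
    whole-duplex affine transfer to the Na⁺ prediction, recorded as a
    single ``cation_mode`` breakdown term.
    """
    from dataclasses import replace as _replace

    from .thermo import predict_duplex

    params = compose_condition_parameters(decomposition, solution, duplex.n_bp)
    thermo = predict_duplex(duplex, params)
    if solution.cation_mode == "sodium":
        return thermo
    if solution.cation_mode == "potassium":
        corrected = cations.potassium_correction(thermo.dG37)
    else:
        corrected = cations.intracellular_correction(thermo.dG37)
    breakdown = dict(thermo.breakdown)
    breakdown[f"cation_mode:{solution.cation_mode}"] = corrected - thermo.dG37
    notes = thermo.warnings + (
        f"{solution.cation_mode} transfer applied to the whole-duplex "
        "Na+ prediction (regression fitted under 40 wt% PEG200 crowding)",
    )
    return _replace(
        thermo, dG37=corrected, breakdown=breakdown, warnings=notes
    )
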