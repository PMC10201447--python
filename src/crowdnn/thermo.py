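"""Core duplex thermodynamics.

Nearest-neighbor summation, free energy at temperature, two-state
bimolecular melting temperature, and the inverse van't Hoff analysis
(Tm⁻¹ versus ln(Ct/s) regression).

Conventions
-----------
* ΔG°₃₇ = ΔH° − 310.15·ΔS° with ΔS° in kcal·mol⁻¹·K⁻¹ (ΔCp = 0
  throughout; the zero-ΔCp approximation is only justified near 37 °C, so
  :func:`free_energy_at` warns for |T − 310.15| > 25 K).
* Tm⁻¹ = R·ln(Ct/s)/ΔH° + ΔS°/ΔH° with Ct the *total* strand
  concentration and s the symmetry factor: 1 for self-complementary
  duplexes, 4 for non-self-complementary ones.
* R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sequences import DuplexSpec, count_terminal_au, nn_steps
from .tables import NNParameterSet, T37

R_KCAL = 1.9872e-3
"""Gas constant, kcal·mol⁻¹·K⁻¹."""


class ThermoError(ValueError):
    pass


@dataclass(frozen=True)
class DuplexThermo:
    """Predicted duplex formation thermodynamics with term provenance.

    ``breakdown`` maps each contributing term (one entry per NN-stack
    occurrence, plus initiation, terminal A·U and, for self-complementary
    duplexes, the symmetry correction) to its ΔG°₃₇ contribution in
    kcal·mol⁻¹; the entries sum exactly to ``dG37``.  ``dH``/``dS`` are
    ``None`` when the parameter set is ΔG-only (composed crowding
    conditions), in which case no Tm can be computed.
    """

    dG37: float
    dH: float | None
    dS: float | None
    breakdown: dict[str, float]
    condition_label: str = ""
    warnings: tuple[str, ...] = ()

    @property
    def has_enthalpy(self) -> bool:
        return self.dH is not None and self.dS is not None


def predict_duplex(duplex: DuplexSpec, params: NNParameterSet) -> DuplexThermo:
    """NN prediction: ΔG°₃₇ = Σ stacks + initiation + terminal A·U + symmetry.

    G·U wobbles (declared on the duplex) are treated as A·U for lookup;
    ΔH° and ΔS° are summed alongside ΔG°₃₇ when the set provides them.
    """
    steps = nn_steps(duplex)
    n_term_au = count_terminal_au(duplex)
    notes: list[str] = []
    if duplex.wobble_positions:
        notes.append(
            f"{len(duplex.wobble_positions)} G-U wobble pair(s) scored as A-U"
        )
        if any(i in (0, duplex.n_bp - 1) for i in duplex.wobble_positions):
            notes.append(
                "G-U at a duplex terminus counted as a terminal A-U "
                "(two-hydrogen-bond equivalence; extrapolation)"
            )

    breakdown: dict[str, float] = {}
    counts: Counter[str] = Counter()
    terms: list[str] = []
    for s in steps:
        counts[s] += 1
        key = s if counts[s] == 1 else f"{s}#{counts[s]}"
        breakdown[key] = params[s].dG37
        terms.append(s)
    breakdown["initiation"] = params["initiation"].dG37
    terms.append("initiation")
    if n_term_au:
        breakdown[f"terminal_AU x{n_term_au}"] = (
            n_term_au * params["terminal_AU"].dG37
        )
        terms.extend(["terminal_AU"] * n_term_au)
    if duplex.self_complementary:
        breakdown["symmetry"] = params["symmetry"].dG37
        terms.append("symmetry")

    dG37 = math.fsum(breakdown.values())
    triples = [params[t] for t in terms]
    if all(t.has_enthalpy for t in triples):
        dH = math.fsum(t.dH for t in triples)  # type: ignore[misc]
        dS = math.fsum(t.dS for t in triples)  # type: ignore[misc]
    else:
        dH = dS = None
        notes.append(
            "dH/dS unavailable for this parameter set (dG37-only composition); "
            "Tm prediction is refused"
        )
    return DuplexThermo(
        dG37=dG37,
        dH=dH,
        dS=dS,
        breakdown=breakdown,
        condition_label=params.condition_label,
        warnings=tuple(notes),
    )


def free_energy_at(thermo: DuplexThermo, T: float) -> float:
    """ΔG°(T) = ΔH° − T·ΔS° (K), under the ΔCp = 0 approximation."""
    if T <= 0:
        raise ThermoError("temperature must be positive (kelvin)")
    if not thermo.has_enthalpy:
        raise ThermoError("dH/dS unavailable; cannot extrapolate in temperature")
    if abs(T - T37) > 25.0:
        warnings.warn(
            f"extrapolating {abs(T - T37):.0f} K from 37 C with dCp = 0; "
            "treat the result with caution",
            stacklevel=2,
        )
    return thermo.dH - T * thermo.dS  # type: ignore[operator]


def melting_temperature(thermo: DuplexThermo, Ct: float, s: int) -> float:
    """Two-state bimolecular Tm (K) at total strand concentration Ct (M).

    Tm = 1 / (R·ln(Ct/s)/ΔH° + ΔS°/ΔH°); s = 1 (self-complementary)
    or 4.  Requires ΔH° < 0.
    """
    if s not in (1, 4):
        raise ThermoError("symmetry factor s must be 1 or 4")
    if Ct <= 0:
        raise ThermoError("total strand concentration must be positive")
    if not thermo.has_enthalpy:
        raise ThermoError(
            "Tm undefined: this prediction has no dH/dS "
            "(dG37-only composed condition)"
        )
    dH, dS = thermo.dH, thermo.dS
    assert dH is not None and dS is not None
    if dH >= 0:
        raise ThermoError("no bimolecular melting defined for dH >= 0")
    inv = R_KCAL * math.log(Ct / s) / dH + dS / dH
    if inv <= 0:
        raise ThermoError("non-physical parameters: 1/Tm <= 0")
    return 1.0 / inv


@dataclass(frozen=True)
class MeltingDataset:
    """Tm-versus-concentration data for one duplex.

    ``ct``: total strand concentrations (mol/L); ``tm``: melting
    temperatures (K); ``s``: symmetry factor (1 or 4).
    """

    ct: tuple[float, ...]
    tm: tuple[float, ...]
    s: int

    def __post_init__(self) -> None:
        if self.s not in (1, 4):
            raise ThermoError("symmetry factor s must be 1 or 4")
        if len(self.ct) != len(self.tm):
            raise ThermoError("ct and tm lengths differ")
        if any(c <= 0 for c in self.ct):
            raise ThermoError("all concentrations must be positive")
        if any(t <= 0 for t in self.tm):
            raise ThermoError("all melting temperatures must be positive (K)")
        if len(set(self.ct)) < 2:
            raise ThermoError("need at least 2 distinct concentrations to fit")


@dataclass(frozen=True)
class VantHoffResult:
    dH: float
    dS: float
    dG37: float
    se_dH: float
    se_dS: float
    se_dG37: float
    r_squared: float

    def as_thermo(self) -> DuplexThermo:
        return DuplexThermo(
            dG37=self.dG37,
            dH=self.dH,
            dS=self.dS,
            breakdown={"vant_hoff_fit": self.dG37},
            condition_label="vant_hoff_fit",
        )


def vant_hoff_fit(data: MeltingDataset) -> VantHoffResult:
    """Two-state van't Hoff analysis of Tm versus total strand concentration.

    Ordinary least squares of Tm⁻¹ on ln(Ct/s); ΔH° = R/slope,
    ΔS° = intercept·ΔH°, ΔG°₃₇ from the 310.15 K relation.  Standard
    errors are first-order propagations of the slope/intercept errors
    (covariance neglected — adequate for the centered designs used here).
    Exact inverse of :func:`melting_temperature` on noiseless input.
    """
    x = np.log(np.asarray(data.ct, dtype=float) / data.s)
    y = 1.0 / np.asarray(data.tm, dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope == 0 or not np.isfinite(fit.slope):
        raise ThermoError("degenerate fit: zero or non-finite slope")
    dH = R_KCAL / fit.slope
    dS = fit.intercept * dH
    dG37 = dH - T37 * dS
    se_dH = abs(R_KCAL / fit.slope**2) * fit.stderr
    se_dS = math.hypot(fit.intercept * se_dH, dH * fit.intercept_stderr)
    se_dG37 = math.hypot(se_dH, T37 * se_dS)
    return VantHoffResult(
        dH=dH,
        dS=dS,
        dG37=dG37,
        se_dH=se_dH,
        se_dS=se_dS,
        se_dG37=se_dG37,
        r_squared=fit.rvalue**2,
    )
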