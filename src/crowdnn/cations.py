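"""Cation contributions to the NN free energies.

The decomposition anchors ΔG°_NN,cation at exactly two Na⁺ concentrations:
zero at 10 mM (where ΔG°_NN ≈ ΔG°_NN,bulk by construction) and the tabled
column at 122 mM.  Other Na⁺ concentrations require a user-registered
per-parameter model — the tool never interpolates silently.

K⁺ and intracellular cation mixes are handled at the whole-duplex level by
the affine regressions fitted under 40 wt% PEG200 crowding:

    ΔG°₃₇(K⁺)            = 0.93·ΔG°₃₇(Na⁺ prediction) + 0.45
    ΔG°₃₇(intracellular) = 0.92·ΔG°₃₇(Na⁺ prediction) − 0.12

Both corrections apply to a completed Na⁺ prediction, never per-NN stack;
outside PEG200-like crowding they extrapolate and a warning is emitted.
"""

from __future__ import annotations

import warnings
from typing import Callable

from .tables import DecomposedGibbs, FREE_PARAMETERS

#: Registered per-parameter Na⁺ dependence models:
#: name -> callable(parameter_label, na_mM) -> kcal/mol.
NaModel = Callable[[str, float], float]
_NA_MODELS: dict[str, NaModel] = {}

K_SLOPE, K_INTERCEPT = 0.93, 0.45
IC_SLOPE, IC_INTERCEPT = 0.92, -0.12


class CationError(ValueError):
    pass


def register_na_model(name: str, fn: NaModel) -> None:
    """Register a per-parameter ΔG°_NN,cation(Na⁺) model under ``name``."""
    _NA_MODELS[name] = fn


def registered_na_models() -> tuple[str, ...]:
    return tuple(sorted(_NA_MODELS))


def cation_term(
    na_mM: float,
    decomposition: DecomposedGibbs,
    model: str | None = None,
) -> dict[str, float]:
    """Per-parameter ΔG°_NN,cation (kcal·mol⁻¹) at the given Na⁺ level.

    10 mM → all zeros; 122 mM → the tabled column (terminal A·U always 0);
    anything else requires ``model`` to name a registered Na⁺ model.
    """
    if na_mM <= 0:
        raise CationError("Na+ concentration must be positive (mM)")
    if model is not None:
        try:
            fn = _NA_MODELS[model]
        except KeyError:
            raise CationError(
                f"no registered Na+ model named {model!r}; "
                f"available: {registered_na_models()}"
            ) from None
        out = {p: float(fn(p, na_mM)) for p in FREE_PARAMETERS}
        out["terminal_AU"] = 0.0  # terminal pairs are Na+-independent
        return out
    if na_mM == 10:
        return {p: 0.0 for p in FREE_PARAMETERS}
    if na_mM == 122:
        return dict(decomposition.dG_cation_122mM)
    raise CationError(
        f"no cation term available at {na_mM:g} mM Na+: only the 10 mM and "
        "122 mM anchors are tabled; register a Na+ dependence model via "
        "register_na_model() (interpolation is refused)"
    )


def _affine(dg: float, slope: float, intercept: float) -> float:
    return slope * dg + intercept


def potassium_correction(
    dG37_pred_Na: float, *, warn_domain: bool = False
) -> float:
    """Whole-duplex ΔG°₃₇ in 100 mM K⁺ from the matched Na⁺ prediction.

    Slope 0.93: ~7% weaker charge screening by K⁺; intercept +0.45:
    average terminal destabilization (kcal·mol⁻¹).
    """
    if warn_domain:
        warnings.warn(
            "K+ regression was fitted under 40 wt% PEG200 crowding; "
            "applying it elsewhere is an extrapolation",
            stacklevel=2,
        )
    return _affine(dG37_pred_Na, K_SLOPE, K_INTERCEPT)


def potassium_correction_inverse(dG37_K: float) -> float:
    """Exact inverse of :func:`potassium_correction`."""
    return (dG37_K - K_INTERCEPT) / K_SLOPE


def intracellular_correction(
    dG37_pred_Na: float, *, warn_domain: bool = False
) -> float:
    """Whole-duplex ΔG°₃₇ at intracellular cation composition.

    (140 mM K⁺, 10 mM Na⁺, 0.5 mM Mg²⁺, trace Ca²⁺.)  Slope 0.92 mirrors
    the K⁺ screening; the slightly negative intercept (−0.12 kcal·mol⁻¹)
    reflects terminal stabilization by Mg²⁺.
    """
    if warn_domain:
        warnings.warn(
            "intracellular regression was fitted under 40 wt% PEG200 "
            "crowding; applying it elsewhere is an extrapolation",
            stacklevel=2,
        )
    return _affine(dG37_pred_Na, IC_SLOPE, IC_INTERCEPT)
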