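"""Crowding-aware rules for motifs beyond perfect duplexes.

Loop penalties measured in dilute solution are rescaled for a crowding
condition by the empirical water-activity relation

    ΔG°₃₇,loop,cosolute = ΔG°₃₇,loop,no-cosolute · (1 − 11.8·Δa_w)

(at 40 wt% PEG200, Δa_w ≈ 0.0489, the loop destabilization shrinks by
~58%).  Hairpin stability assembles a wobble-normalized stem scored with
condition-composed NN parameters, the rescaled hairpin/internal-loop
penalties, one helix-initiation term, and — if the user supplies the
folded/unfolded cylinder geometry — a unimolecular excluded-volume term.

Dilute-condition loop penalties are user inputs (classical Turner-style
loop tables are not bundled); bulges, non-wobble mismatches, dangling
ends and coaxial stacking are out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .crowding import (
    SolutionCondition,
    compose_condition_parameters,
    ev_free_energy,
    excluded_volume_generic,
    molality,
    resolve_delta_aw,
)
from .sequences import DuplexSpec, nn_steps, wobble_normalize
from .tables import DecomposedGibbs

LOOP_AW_SLOPE = 11.8  # per unit delta_aw


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class HairpinGeometry:
    """Cylinder-model geometry for the unimolecular excluded-volume term.

    ``l``: statistical segment length of the cosolute (Å); ``k_folded`` /
    ``k_unfolded``: geometrical factors of the folded hairpin and the
    unfolded strand (Å-derived, as in the excluded-volume relation).
    """

    l: float
    k_folded: float
    k_unfolded: float


@dataclass(frozen=True)
class HairpinSpec:
    """A hairpin: stem duplex (wobbles allowed) + dilute-condition loops."""

    stem: DuplexSpec
    loop_penalty_dilute: float  # kcal/mol, >= 0 (destabilizing)
    internal_loop_penalties_dilute: tuple[float, ...] = ()
    geometry: HairpinGeometry | None = None

    def __post_init__(self) -> None:
        if self.stem.n_bp < 2:
            raise MotifError("hairpin stem needs at least 2 base pairs")
        if self.loop_penalty_dilute < 0 or any(
            p < 0 for p in self.internal_loop_penalties_dilute
        ):
            raise MotifError(
                "loop penalties are destabilizing by convention (>= 0)"
            )


def loop_penalty_crowded(loop_dilute: float, delta_aw: float) -> float:
    """Rescale a dilute-solution loop penalty for a crowding condition.

    Linear in both arguments; for Δa_w ≥ 1/11.8 the factor changes sign
    (loops would become stabilizing), which is outside the calibrated
    domain — a warning is emitted.
    """
    if delta_aw >= 1.0 / LOOP_AW_SLOPE:
        warnings.warn(
            f"delta_aw={delta_aw:g} is beyond 1/11.8; the loop rescaling "
            "changes sign and extrapolates outside its calibration",
            stacklevel=2,
        )
    return loop_dilute * (1.0 - LOOP_AW_SLOPE * delta_aw)


def hairpin_stability(
    hairpin: HairpinSpec,
    solution: SolutionCondition,
    decomposition: DecomposedGibbs,
) -> tuple[float, dict[str, float]]:
    """ΔG°₃₇ (kcal/mol) of hairpin formation, with a term breakdown.

    Stem stacks use parameters composed for the condition *without* the
    bimolecular per-NN excluded-volume share (a hairpin folds
    unimolecularly); the excluded-volume term instead comes from the
    generic cylinder relation with the user-supplied geometry, or is
    omitted with a warning.  Helix initiation is charged once (the first
    stem pair must still form); no symmetry term and no concentration
    dependence apply to a unimolecular fold.  The terminal A·U penalty is
    applied at the open terminus only, never at the loop-closing pair.
    """
    stem = wobble_normalize(hairpin.stem)
    delta_aw = resolve_delta_aw(solution)

    # Compose without cosolute geometry so no duplex ev share leaks in:
    # bulk + cation + wa only.
    no_ev = SolutionCondition(
        cosolute=solution.cosolute,
        wt_pct=solution.wt_pct,
        delta_aw=delta_aw,
        na_mM=solution.na_mM,
        na_model=solution.na_model,
    )
    params = compose_condition_parameters(decomposition, no_ev, stem.n_bp)
    # strip the duplex-level ev share the composer added
    if solution.cosolute is not None and solution.wt_pct > 0:
        from .crowding import excluded_volume_duplex, excluded_volume_per_nn

        C = molality(solution.wt_pct, solution.cosolute)
        ev_nn = excluded_volume_per_nn(
            excluded_volume_duplex(stem.n_bp, C, solution.cosolute.n_monomers),
            stem.n_bp,
        )
    else:
        C = 0.0
        ev_nn = 0.0

    breakdown: dict[str, float] = {}
    for i, step in enumerate(nn_steps(stem)):
        breakdown[f"stem:{step}#{i + 1}"] = params[step].dG37 - ev_nn
    breakdown["initiation"] = params["initiation"].dG37 - ev_nn

    open_pair = stem.pair(0)
    if open_pair in {("A", "U"), ("U", "A")}:
        breakdown["terminal_AU(open end)"] = params["terminal_AU"].dG37

    breakdown["hairpin_loop"] = loop_penalty_crowded(
        hairpin.loop_penalty_dilute, delta_aw
    )
    for j, pen in enumerate(hairpin.internal_loop_penalties_dilute):
        breakdown[f"internal_loop#{j + 1}"] = loop_penalty_crowded(pen, delta_aw)

    if C > 0:
        if hairpin.geometry is not None:
            g = hairpin.geometry
            N = solution.cosolute.n_monomers  # type: ignore[union-attr]
            dv = excluded_volume_generic(
                N, g.l, g.k_folded
            ) - excluded_volume_generic(N, g.l, g.k_unfolded)
            breakdown["excluded_volume(hairpin)"] = ev_free_energy(dv, C)
        else:
            warnings.warn(
                "no hairpin geometry supplied; the unimolecular "
                "excluded-volume term is omitted",
                stacklevel=2,
            )
    total = math.fsum(breakdown.values())
    return total, breakdown
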