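"""Nearest-neighbor parameter tables and their data model.

Two assets ship with the package, both for RNA duplexes in 40 wt% PEG200
with 100 mM NaCl (122 mM total Na⁺ counting buffer sodium):

* the full 13-parameter thermodynamic table (per-stack ΔH°, ΔS°, ΔG°₃₇
  plus helix initiation, the per-terminal-A·U penalty and the
  self-complementarity correction), and
* its ΔG°₃₇ decomposition into bulk, cation (122 mM Na⁺), excluded-volume
  and water-activity components, with the two cosolute-class water-activity
  prefactors m_cs.

Tables are plain TSV transcriptions; nothing is hard-coded so a user can
load an alternative set (e.g. the classical 1 M NaCl parameters) through
the same format.  Validation enforces Hess-law closure
ΔG°₃₇ = ΔH° − 310.15·ΔS° on every row at load time, and, for the
decomposition, that the four components sum back to the full-table value.

Entropies are converted from the printed cal·mol⁻¹·K⁻¹ to
kcal·mol⁻¹·K⁻¹ exactly once, here at load.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .sequences import CANONICAL_STEPS

T37 = 310.15
"""Reference temperature, K (37 °C)."""

#: The 12 freely fitted parameters, in canonical order.
FREE_PARAMETERS: tuple[str, ...] = CANONICAL_STEPS + ("initiation", "terminal_AU")
#: All 13 parameters (symmetry is condition-independent, never refit).
ALL_PARAMETERS: tuple[str, ...] = FREE_PARAMETERS + ("symmetry",)

HESS_TOL = 0.015  # kcal/mol; rounding slack of the printed 2-decimal columns

_BUNDLED = {
    "peg200_40wt_100mM_Na": "peg200_40wt_100mM_Na.tsv",
}


class TableError(ValueError):
    """A parameter table failed validation."""


@dataclass(frozen=True)
class ThermoTriple:
    """ΔH° (kcal·mol⁻¹), ΔS° (kcal·mol⁻¹·K⁻¹), ΔG°₃₇ (kcal·mol⁻¹).

    ΔH°/ΔS° are ``None`` for ΔG-only sets composed for arbitrary crowding
    conditions (the decomposition is defined for ΔG°₃₇ only).
    """

    dH: float | None
    dS: float | None
    dG37: float

    @property
    def has_enthalpy(self) -> bool:
        return self.dH is not None and self.dS is not None


@dataclass(frozen=True)
class NNParameterSet:
    """A complete NN parameter set tagged with its solution condition."""

    condition_label: str
    values: dict[str, ThermoTriple]
    source: str | None = None
    source_sha256: str | None = None

    def __post_init__(self) -> None:
        missing = [p for p in ALL_PARAMETERS if p not in self.values]
        if missing:
            raise TableError(f"parameter set incomplete, missing: {missing}")

    def __getitem__(self, param: str) -> ThermoTriple:
        return self.values[param]

    @property
    def has_enthalpy(self) -> bool:
        return all(self.values[p].has_enthalpy for p in ALL_PARAMETERS)

    def validate(self, tol: float = HESS_TOL) -> None:
        """Enforce ΔG°₃₇ = ΔH° − 310.15·ΔS° on every enthalpy-bearing row."""
        for name, t in self.values.items():
            if not t.has_enthalpy:
                continue
            closure = t.dH - T37 * t.dS
            if abs(closure - t.dG37) > tol:
                raise TableError(
                    f"row {name!r} violates dG37 = dH - 310.15*dS: "
                    f"{t.dG37:+.3f} vs {closure:+.3f} kcal/mol"
                )

    def to_frame(self) -> pd.DataFrame:
        """Table as a DataFrame with printed units (dS in cal·mol⁻¹·K⁻¹)."""
        rows = []
        for name in ALL_PARAMETERS:
            t = self.values[name]
            rows.append(
                {
                    "parameter": name,
                    "dH_kcal": t.dH,
                    "dS_cal": None if t.dS is None else t.dS * 1000.0,
                    "dG37_kcal": t.dG37,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DecomposedGibbs:
    """Per-parameter ΔG°₃₇ components and cosolute-class prefactors.

    ``dG_ev_ref`` is the sequence-averaged excluded-volume component for
    40 wt% PEG200 (−0.22 kcal·mol⁻¹); it is ``None`` for the terminal A·U
    row, which carries no excluded-volume term (already counted in
    initiation) and no cation term (terminal pairs are taken to be
    Na⁺-independent).
    """

    dG_bulk: dict[str, float]
    dG_cation_122mM: dict[str, float]
    dG_ev_ref: dict[str, float | None]
    dG_wa_ref: dict[str, float]
    m_peg_class: dict[str, float]
    m_diol_class: dict[str, float]
    source: str | None = None
    source_sha256: str | None = None

    @property
    def parameters(self) -> tuple[str, ...]:
        return FREE_PARAMETERS

    def slope_ratio(self) -> float:
        """Mean m_diol/m_peg ratio (= S_CS/S_PEG of the two-class model)."""
        ratios = [
            self.m_diol_class[p] / self.m_peg_class[p] for p in FREE_PARAMETERS
        ]
        return sum(ratios) / len(ratios)

    def implied_delta_aw(self) -> dict[str, float]:
        """Δa_w of the reference condition back-inferred per row (wa/m_peg)."""
        return {
            p: self.dG_wa_ref[p] / self.m_peg_class[p] for p in FREE_PARAMETERS
        }


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("crowdnn").joinpath("data", filename)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_parameter_set(condition_id: str | Path) -> NNParameterSet:
    """Load a bundled (by id) or user (by path) NN parameter table.

    The table is validated on load; a row breaking Hess-law closure is a
    hard failure naming the row.
    """
    cid = str(condition_id)
    if cid in _BUNDLED:
        path = _data_path(_BUNDLED[cid])
        label = cid
    else:
        path = Path(cid)
        if not path.exists():
            raise TableError(
                f"unknown condition id or missing file: {cid!r} "
                f"(bundled ids: {sorted(_BUNDLED)})"
            )
        label = path.stem
    df = pd.read_csv(path, sep="\t")
    required = {"parameter", "dH_kcal", "dS_cal", "dG37_kcal"}
    if not required.issubset(df.columns):
        raise TableError(f"{path}: missing columns {required - set(df.columns)}")
    values: dict[str, ThermoTriple] = {}
    for _, row in df.iterrows():
        name = str(row["parameter"])
        dH = row["dH_kcal"]
        dS = row["dS_cal"]
        values[name] = ThermoTriple(
            dH=None if pd.isna(dH) else float(dH),
            dS=None if pd.isna(dS) else float(dS) / 1000.0,
            dG37=float(row["dG37_kcal"]),
        )
    pset = NNParameterSet(
        condition_label=label,
        values=values,
        source=str(path),
        source_sha256=_sha256(path),
    )
    pset.validate()
    return pset


def load_decomposition(path: str | Path | None = None) -> DecomposedGibbs:
    """Load the ΔG°₃₇ decomposition table (default: bundled 40 wt% PEG200 set).

    Load-time checks: the four components of every propagating stack and of
    initiation sum to the full-table ΔG°₃₇ within 0.015 kcal·mol⁻¹, and the
    m_diol/m_peg ratio is constant across rows within ±0.01.
    """
    p = _data_path("decomposition_peg200.tsv") if path is None else Path(path)
    df = pd.read_csv(p, sep="\t")
    cols = {"parameter", "dG_bulk", "dG_cat_122", "dG_ev", "dG_wa", "m_peg", "m_diol"}
    if not cols.issubset(df.columns):
        raise TableError(f"{p}: missing columns {cols - set(df.columns)}")
    df = df.set_index("parameter")
    missing = [q for q in FREE_PARAMETERS if q not in df.index]
    if missing:
        raise TableError(f"{p}: missing rows {missing}")

    def col(name: str, allow_na: bool = False) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for q in FREE_PARAMETERS:
            v = df.loc[q, name]
            out[q] = None if (allow_na and pd.isna(v)) else float(v)
        return out

    decomp = DecomposedGibbs(
        dG_bulk=col("dG_bulk"),  # type: ignore[arg-type]
        dG_cation_122mM=col("dG_cat_122"),  # type: ignore[arg-type]
        dG_ev_ref=col("dG_ev", allow_na=True),
        dG_wa_ref=col("dG_wa"),  # type: ignore[arg-type]
        m_peg_class=col("m_peg"),  # type: ignore[arg-type]
        m_diol_class=col("m_diol"),  # type: ignore[arg-type]
        source=str(p),
        source_sha256=_sha256(p),
    )

    # closure against the full table at the same condition
    full = load_parameter_set("peg200_40wt_100mM_Na")
    for q in FREE_PARAMETERS:
        ev = decomp.dG_ev_ref[q] or 0.0
        total = (
            decomp.dG_bulk[q]
            + decomp.dG_cation_122mM[q]
            + ev
            + decomp.dG_wa_ref[q]
        )
        if abs(total - full[q].dG37) > HESS_TOL:
            raise TableError(
                f"decomposition row {q!r} sums to {total:+.3f}, full table "
                f"says {full[q].dG37:+.3f} kcal/mol"
            )
    if decomp.dG_ev_ref["terminal_AU"] is not None:
        raise TableError("terminal_AU must not carry an excluded-volume term")
    if decomp.dG_cation_122mM["terminal_AU"] != 0.0:
        raise TableError("terminal_AU must not carry a cation term")

    ratios = [
        decomp.m_diol_class[q] / decomp.m_peg_class[q] for q in FREE_PARAMETERS
    ]
    mean_ratio = sum(ratios) / len(ratios)
    for q, r in zip(FREE_PARAMETERS, ratios):
        if abs(r - mean_ratio) > 0.01:
            raise TableError(
                f"m_diol/m_peg ratio of row {q!r} ({r:.4f}) deviates from the "
                f"across-row mean ({mean_ratio:.4f}) by more than 0.01"
            )
    return decomp


def stability_order(pset: NNParameterSet) -> list[str]:
    """Propagating stacks sorted by increasing stability (−ΔG°₃₇)."""
    return sorted(CANONICAL_STEPS, key=lambda s: -pset[s].dG37)
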