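"""Readers and writers tying the modules together.

Formats
-------
* melting TSV: columns ``Ct_molar`` (total strand concentration, mol/L)
  and ``Tm_C`` (melting temperature, °C).
* thermodynamics TSV: ``sequence``, ``dH_kcal``, optional ``dS_cal``,
  ``dG37_kcal``, ``self_complementary`` — one row per measured duplex,
  the layout a transcribed measured panel would use for refitting.
* parameter TSV: the same layout as the bundled tables
  (``parameter``, ``dH_kcal``, ``dS_cal``, ``dG37_kcal``).
* prediction records: TSV or JSON, one record per sequence, units in the
  header, the full term breakdown and any warnings always present.

Every prediction record echoes the parameter-set provenance (file path
and SHA-256) — the parameter tables are the scientific payload, so their
identity travels with every number derived from them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .tables import ALL_PARAMETERS, NNParameterSet
from .thermo import DuplexThermo, MeltingDataset


class IOError_(ValueError):
    pass


@dataclass(frozen=True)
class PredictionRecord:
    """One prediction for one sequence, fully self-describing."""

    sequence_id: str
    top_strand: str
    bottom_strand: str
    n_bp: int
    condition: str
    dG37_kcal: float
    dH_kcal: float | None
    dS_cal: float | None
    tm_K: float | None
    tm_C: float | None
    breakdown_kcal: dict[str, float]
    warnings: tuple[str, ...] = ()
    params_source: str | None = None
    params_sha256: str | None = None

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["warnings"] = list(self.warnings)
        return d


def make_record(
    sequence_id: str,
    duplex,
    thermo: DuplexThermo,
    params: NNParameterSet,
    tm_K: float | None = None,
    extra_warnings: tuple[str, ...] = (),
) -> PredictionRecord:
    return PredictionRecord(
        sequence_id=sequence_id,
        top_strand=duplex.top_strand,
        bottom_strand=duplex.bottom_strand,
        n_bp=duplex.n_bp,
        condition=thermo.condition_label,
        dG37_kcal=thermo.dG37,
        dH_kcal=thermo.dH,
        dS_cal=None if thermo.dS is None else thermo.dS * 1000.0,
        tm_K=tm_K,
        tm_C=None if tm_K is None else tm_K - 273.15,
        breakdown_kcal=dict(thermo.breakdown),
        warnings=thermo.warnings + extra_warnings,
        params_source=params.source,
        params_sha256=params.source_sha256,
    )


def write_records(records: list[PredictionRecord], path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "json":
        path.write_text(
            json.dumps([r.to_json_dict() for r in records], indent=2) + "\n"
        )
        return
    rows = []
    for r in records:
        d = r.to_json_dict()
        d["breakdown_kcal"] = json.dumps(d["breakdown_kcal"])
        d["warnings"] = "; ".join(d["warnings"])
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> list[PredictionRecord]:
    """Inverse of :func:`write_records` for both formats."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("["):
        raw = json.loads(text)
    else:
        df = pd.read_csv(path, sep="\t")
        raw = df.to_dict(orient="records")
        for d in raw:
            d["breakdown_kcal"] = json.loads(d["breakdown_kcal"])
            w = d.get("warnings")
            d["warnings"] = (
                [] if (not isinstance(w, str) or not w) else w.split("; ")
            )
    out = []
    for d in raw:
        d = dict(d)
        d["warnings"] = tuple(d.get("warnings") or ())
        for k in ("dH_kcal", "dS_cal", "tm_K", "tm_C", "params_source", "params_sha256"):
            if k in d and pd.isna(pd.Series([d[k]])).iloc[0]:
                d[k] = None
        out.append(PredictionRecord(**d))
    return out


def read_melting_tsv(path: str | Path, s: int) -> MeltingDataset:
    df = pd.read_csv(path, sep="\t")
    for col in ("Ct_molar", "Tm_C"):
        if col not in df.columns:
            raise IOError_(f"{path}: missing column {col!r}")
    return MeltingDataset(
        ct=tuple(df["Ct_molar"].astype(float)),
        tm=tuple(df["Tm_C"].astype(float) + 273.15),
        s=s,
    )


def write_melting_tsv(data: MeltingDataset, path: str | Path) -> None:
    pd.DataFrame(
        {"Ct_molar": data.ct, "Tm_C": [t - 273.15 for t in data.tm]}
    ).to_csv(path, sep="\t", index=False)


def read_thermo_tsv(path: str | Path) -> pd.DataFrame:
    """Measured per-duplex thermodynamics for refitting."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sequence", "dH_kcal", "dG37_kcal", "self_complementary"}
    missing = needed - set(df.columns)
    if missing:
        raise IOError_(f"{path}: missing columns {sorted(missing)}")
    return df


def write_parameter_tsv(params: NNParameterSet, path: str | Path) -> None:
    params.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def parameter_set_complete(params: NNParameterSet) -> bool:
    return all(p in params.values for p in ALL_PARAMETERS)
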