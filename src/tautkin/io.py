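"""Reading and writing reaction sets in the JSON and TSV interchange dialects.

JSON dialect: one file with a ``units`` declaration, ``reference_label``,
``structures`` (each with embedded contacts), ``reactions`` and ``metadata``.

TSV dialect: a directory of four UTF-8 tab-separated tables —
``meta.tsv`` (key/value: units, reference label, metadata),
``structures.tsv``, ``contacts.tsv`` (one row per contact, keyed by
structure label) and ``reactions.tsv``.  Scientific notation uses the plain
``3.09e-58`` form and "." as decimal separator.  An informational
``name_ascii``/``label_ascii`` column carries the portable alias; readers
accept either spelling.

Readers verify the declared units against the package convention
(energies kcal·mol⁻¹, wavenumbers cm⁻¹, densities a.u.) and reject files
declaring anything else.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Optional

import pandas as pd
from pydantic import ValidationError

from .types import ReactionSet, StationaryPoint, TautomericReaction, to_ascii

UNITS = {"energy": "kcal/mol", "wavenumber": "cm-1", "rho": "au"}

_STRUCTURE_COLS = [
    "label", "label_ascii", "role", "rel_gibbs", "rel_electronic",
    "dipole", "dihedral_C3C2C1pC6p",
]
_CONTACT_COLS = [
    "structure_label", "donor_label", "acceptor_label", "contact_class",
    "rho", "lap_rho", "ellipticity", "d_AB", "d_HB", "angle_AHB", "V_bcp",
    "ref_energy", "ref_formula", "ref_inconsistent",
]
_REACTION_COLS = [
    "name", "name_ascii", "reactant", "ts", "product", "nu_imag",
    "dG_reaction", "dE_reaction", "ddG_forward", "ddE_forward", "temperature",
    "ref_k_forward", "ref_k_reverse", "ref_tau_999", "ref_tau_lifetime",
    "ref_ddG_reverse", "ref_ddE_reverse",
]


def _check_units(declared: dict[str, str]) -> None:
    for key, expected in UNITS.items():
        got = declared.get(key)
        if got != expected:
            raise ValueError(
                f"unit mismatch for {key!r}: file declares {got!r}, "
                f"this package stores {expected!r}"
            )


def _wrap_validation(err: ValidationError, context: str) -> ValueError:
    details = "; ".join(
        f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
    )
    return ValueError(f"{context}: {details}")


# --------------------------------------------------------------------------
# JSON dialect
# --------------------------------------------------------------------------


def _rs_to_payload(rs: ReactionSet) -> dict[str, Any]:
    payload = {
        "units": dict(UNITS),
        "reference_label": rs.reference_label,
        "structures": [s.model_dump(mode="json") for s in rs.structures],
        "reactions": [r.model_dump(mode="json") for r in rs.reactions],
        "metadata": dict(rs.metadata),
    }
    return payload


def _rs_from_payload(payload: dict[str, Any], context: str) -> ReactionSet:
    _check_units(payload.get("units", {}))
    body = {k: payload.get(k) for k in ("reference_label", "structures", "reactions", "metadata")}
    body = {k: v for k, v in body.items() if v is not None}
    try:
        return ReactionSet.model_validate(body)
    except ValidationError as err:
        raise _wrap_validation(err, context) from err


# --------------------------------------------------------------------------
# TSV dialect helpers
# --------------------------------------------------------------------------


def _cell(value: Any) -> Any:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    return value


def _opt_float(value: Any) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _opt_str(value: Any) -> Optional[str]:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return str(value)


def _structure_rows(rs: ReactionSet) -> tuple[list[dict], list[dict]]:
    srows, crows = [], []
    for s in rs.structures:
        srows.append({
            "label": s.label,
            "label_ascii": to_ascii(s.label),
            "role": s.role.value,
            "rel_gibbs": _cell(s.rel_gibbs),
            "rel_electronic": _cell(s.rel_electronic),
            "dipole": _cell(s.dipole),
            "dihedral_C3C2C1pC6p": _cell(s.dihedral_C3C2C1pC6p),
        })
        for c in s.contacts:
            ref = c.reference
            crows.append({
                "structure_label": s.label,
                "donor_label": c.donor_label,
                "acceptor_label": c.acceptor_label,
                "contact_class": c.contact_class.value,
                "rho": c.rho,
                "lap_rho": c.lap_rho,
                "ellipticity": c.ellipticity,
                "d_AB": c.d_AB,
                "d_HB": _cell(c.d_HB),
                "angle_AHB": _cell(c.angle_AHB),
                "V_bcp": _cell(c.V_bcp),
                "ref_energy": _cell(ref.energy if ref else None),
                "ref_formula": _cell(ref.formula.value if ref else None),
                "ref_inconsistent": _cell(ref.inconsistent if ref else None),
            })
    return srows, crows


def _reaction_rows(rs: ReactionSet) -> list[dict]:
    rows = []
    for r in rs.reactions:
        ref = r.reference
        rows.append({
            "name": r.name,
            "name_ascii": to_ascii(r.name),
            "reactant": r.reactant,
            "ts": r.ts,
            "product": r.product,
            "nu_imag": r.nu_imag,
            "dG_reaction": r.dG_reaction,
            "dE_reaction": _cell(r.dE_reaction),
            "ddG_forward": r.ddG_forward,
            "ddE_forward": _cell(r.ddE_forward),
            "temperature": r.temperature,
            "ref_k_forward": _cell(ref.k_forward if ref else None),
            "ref_k_reverse": _cell(ref.k_reverse if ref else None),
            "ref_tau_999": _cell(ref.tau_999 if ref else None),
            "ref_tau_lifetime": _cell(ref.tau_lifetime if ref else None),
            "ref_ddG_reverse": _cell(ref.ddG_reverse if ref else None),
            "ref_ddE_reverse": _cell(ref.ddE_reverse if ref else None),
        })
    return rows


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=object, keep_default_na=False, na_values=[])


def _write_reaction_set_tsv(rs: ReactionSet, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    meta = [("units.energy", UNITS["energy"]),
            ("units.wavenumber", UNITS["wavenumber"]),
            ("units.rho", UNITS["rho"]),
            ("reference_label", rs.reference_label)]
    meta += [(f"metadata.{k}", v) for k, v in sorted(rs.metadata.items())]
    _write_tsv(pd.DataFrame(meta, columns=["key", "value"]), path / "meta.tsv")
    srows, crows = _structure_rows(rs)
    _write_tsv(pd.DataFrame(srows, columns=_STRUCTURE_COLS), path / "structures.tsv")
    _write_tsv(pd.DataFrame(crows, columns=_CONTACT_COLS), path / "contacts.tsv")
    _write_tsv(pd.DataFrame(_reaction_rows(rs), columns=_REACTION_COLS), path / "reactions.tsv")


def _read_reaction_set_tsv(path: Path) -> ReactionSet:
    meta_df = _read_tsv(path / "meta.tsv")
    meta = dict(zip(meta_df["key"], meta_df["value"]))
    _check_units({
        "energy": meta.get("units.energy"),
        "wavenumber": meta.get("units.wavenumber"),
        "rho": meta.get("units.rho"),
    })
    metadata = {
        k.removeprefix("metadata."): str(v)
        for k, v in meta.items() if k.startswith("metadata.")
    }

    contacts_by_structure: dict[str, list[dict]] = {}
    cpath = path / "contacts.tsv"
    if cpath.exists():
        for _, row in _read_tsv(cpath).iterrows():
            ref = None
            if _opt_str(row["ref_energy"]) is not None:
                ref = {
                    "energy": float(row["ref_energy"]),
                    "formula": row["ref_formula"],
                    "inconsistent": str(row["ref_inconsistent"]).lower() == "true",
                }
            contacts_by_structure.setdefault(str(row["structure_label"]), []).append({
                "donor_label": row["donor_label"],
                "acceptor_label": row["acceptor_label"],
                "contact_class": row["contact_class"],
                "rho": float(row["rho"]),
                "lap_rho": float(row["lap_rho"]),
                "ellipticity": float(row["ellipticity"]),
                "d_AB": float(row["d_AB"]),
                "d_HB": _opt_float(row["d_HB"]),
                "angle_AHB": _opt_float(row["angle_AHB"]),
                "V_bcp": _opt_float(row["V_bcp"]),
                "reference": ref,
            })

    structures = []
    for _, row in _read_tsv(path / "structures.tsv").iterrows():
        structures.append({
            "label": row["label"],
            "role": row["role"],
            "rel_gibbs": _opt_float(row["rel_gibbs"]),
            "rel_electronic": _opt_float(row["rel_electronic"]),
            "dipole": _opt_float(row["dipole"]),
            "dihedral_C3C2C1pC6p": _opt_float(row["dihedral_C3C2C1pC6p"]),
            "contacts": contacts_by_structure.get(str(row["label"]), []),
        })

    reactions = []
    rpath = path / "reactions.tsv"
    if rpath.exists():
        for _, row in _read_tsv(rpath).iterrows():
            ref = None
            if _opt_str(row["ref_k_forward"]) is not None:
                ref = {
                    "k_forward": float(row["ref_k_forward"]),
                    "k_reverse": float(row["ref_k_reverse"]),
                    "tau_999": float(row["ref_tau_999"]),
                    "tau_lifetime": float(row["ref_tau_lifetime"]),
                    "ddG_reverse": _opt_float(row["ref_ddG_reverse"]),
                    "ddE_reverse": _opt_float(row["ref_ddE_reverse"]),
                }
            reactions.append({
                "name": row["name"],
                "reactant": row["reactant"],
                "ts": row["ts"],
                "product": row["product"],
                "nu_imag": float(row["nu_imag"]),
                "dG_reaction": float(row["dG_reaction"]),
                "dE_reaction": _opt_float(row["dE_reaction"]),
                "ddG_forward": float(row["ddG_forward"]),
                "ddE_forward": _opt_float(row["ddE_forward"]),
                "temperature": float(row["temperature"]),
                "reference": ref,
            })

    try:
        return ReactionSet.model_validate({
            "reference_label": str(meta.get("reference_label", "")),
            "structures": structures,
            "reactions": reactions,
            "metadata": metadata,
        })
    except ValidationError as err:
        raise _wrap_validation(err, f"TSV reaction set at {path}") from err


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------


def _infer_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("json", "tsv"):
            raise ValueError(f"unknown dialect {dialect!r}; expected 'json' or 'tsv'")
        return dialect
    if path.suffix == ".json":
        return "json"
    if path.is_dir() or path.suffix == "":
        return "tsv"
    raise ValueError(f"cannot infer dialect from path {path}")


def write_reaction_set(rs: ReactionSet, path: str | Path, dialect: Optional[str] = None) -> None:
    """Serialize a reaction set (JSON file, or directory of TSV tables)."""
    path = Path(path)
    if _infer_dialect(path, dialect) == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_rs_to_payload(rs), fh, ensure_ascii=False, indent=1)
            fh.write("\n")
    else:
        _write_reaction_set_tsv(rs, path)


def read_reaction_set(path: str | Path, dialect: Optional[str] = None) -> ReactionSet:
    """Read and validate a reaction set written by :func:`write_reaction_set`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _infer_dialect(path, dialect) == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return _rs_from_payload(payload, f"JSON reaction set at {path}")
    return _read_reaction_set_tsv(path)
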