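"""Empirical QTAIM energies of intramolecular H-bonds and vdW contacts.

Three published mappings from (3,−1) bond-critical-point descriptors to
interaction energies (kcal·mol⁻¹) are implemented:

* **EML** (Espinosa–Molins–Lecomte): E = 0.5·|V(r)| where V(r) is the local
  potential energy density at the BCP (a.u., converted to kcal·mol⁻¹).
  General-purpose; used here for weak CH⋯O, OH⋯C and van der Waals contacts.
* **BYH** (Brovarets'–Yurenko–Hovorun): E = 248.501·ρ − 0.367, calibrated
  for *strong* CH⋯O bonds (energy above 10 kcal·mol⁻¹), such as the
  HCH⋯O contacts of a freshly formed CH₂ group at a proton-transfer TS.
* **NBH** (Nikolaienko–Bulavin–Hovorun): E = −3.09 + 239·ρ, for classical
  OH⋯O hydrogen bonds.

A contact counts as a genuine attractive interaction only when a BCP exists
(implied by the record), ρ > 0 and the Laplacian at the BCP is positive.

Dispatch resolves the strong/weak CH⋯O circularity by evaluating the BYH
estimate itself against the 10 kcal·mol⁻¹ threshold (equivalently
ρ ≥ 0.04173 a.u.): only contacts BYH itself places above the threshold are
BYH-scored, everything else falls through to EML.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .constants import HARTREE_TO_KCAL_PER_MOL
from .types import ContactClass, ContactRecord, Formula, StationaryPoint

NBH_INTERCEPT = -3.09
NBH_SLOPE = 239.0
BYH_SLOPE = 248.501
BYH_INTERCEPT = -0.367
#: BYH applies only to CH⋯O bonds stronger than this, kcal·mol⁻¹.
STRONG_CH_O_THRESHOLD = 10.0

_CH_TYPE = frozenset({ContactClass.CH_O, ContactClass.CH2_O})


@dataclass(frozen=True)
class ContactEnergy:
    """Energy assignment for one contact.

    ``energy`` is ``None`` when the contact is invalid (failed the QTAIM
    criteria) or unscorable (EML-routed but the record carries no V(r)).
    """

    contact: ContactRecord
    energy: Optional[float]
    formula_used: Optional[Formula]
    valid: bool

    def __post_init__(self) -> None:
        if self.formula_used is Formula.BYH and (
            self.energy is None or self.energy <= STRONG_CH_O_THRESHOLD
        ):
            raise ValueError("BYH assignments require energy > 10 kcal/mol")
        if (
            self.formula_used is Formula.NBH
            and self.contact.contact_class is not ContactClass.OH_O
        ):
            raise ValueError("NBH applies only to OH_O contacts")

    @property
    def unscorable(self) -> bool:
        return self.valid and self.energy is None


def is_valid_contact(c: ContactRecord) -> bool:
    """True iff the record satisfies the H-bond/vdW criteria: ρ > 0 and Δρ > 0."""
    return c.rho > 0 and c.lap_rho > 0


def nbh_energy(rho: float) -> float:
    """Classical OH⋯O H-bond energy, −3.09 + 239·ρ, kcal·mol⁻¹."""
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    return NBH_INTERCEPT + NBH_SLOPE * rho


def byh_energy(rho: float) -> float:
    """Strong CH⋯O H-bond energy, 248.501·ρ − 0.367, kcal·mol⁻¹."""
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    return BYH_SLOPE * rho + BYH_INTERCEPT


def eml_energy(V_bcp: Optional[float]) -> float:
    """EML contact energy 0.5·|V(r)| converted from a.u. to kcal·mol⁻¹."""
    if V_bcp is None:
        raise ValueError(
            "record carries no V(r) at the BCP; table-style inputs that omit "
            "the local potential energy density cannot be EML-scored"
        )
    return 0.5 * abs(V_bcp) * HARTREE_TO_KCAL_PER_MOL


def dispatch_energy(c: ContactRecord) -> ContactEnergy:
    """Route a valid contact to the appropriate empirical formula.

    OH⋯O → NBH; CH⋯O-type (including CH₂ donors) whose BYH estimate exceeds
    10 kcal·mol⁻¹ → BYH; everything else (weak CH⋯O, OH⋯C, vdW) → EML when
    V(r) is available, otherwise an explicit unscorable EML outcome.
    """
    if not is_valid_contact(c):
        raise ValueError(
            f"contact {c.label} fails the QTAIM criteria (rho={c.rho}, "
            f"lap_rho={c.lap_rho}); cannot assign an energy"
        )
    if c.contact_class is ContactClass.OH_O:
        return ContactEnergy(c, nbh_energy(c.rho), Formula.NBH, True)
    if c.contact_class in _CH_TYPE:
        e = byh_energy(c.rho)
        if e > STRONG_CH_O_THRESHOLD:
            return ContactEnergy(c, e, Formula.BYH, True)
    if c.V_bcp is not None:
        return ContactEnergy(c, eml_energy(c.V_bcp), Formula.EML, True)
    return ContactEnergy(c, None, Formula.EML, True)


def score_structure(s: StationaryPoint) -> list[ContactEnergy]:
    """One :class:`ContactEnergy` per contact, order preserved.

    Contacts failing the QTAIM criteria are flagged (``valid=False``), not
    dropped.
    """
    out: list[ContactEnergy] = []
    for c in s.contacts:
        if is_valid_contact(c):
            out.append(dispatch_energy(c))
        else:
            out.append(ContactEnergy(c, None, None, False))
    return out


# --------------------------------------------------------------------------
# standalone BCP list reader
# --------------------------------------------------------------------------

_CSV_COLUMNS = [
    "contact_label", "class", "rho", "lap_rho", "ellipticity",
    "d_AB", "d_HB", "angle", "V_bcp",
]


def read_bcp_csv(path: str | Path) -> list[ContactRecord]:
    """Read a bare BCP contact list from CSV (blank d_HB/angle/V_bcp allowed).

    Columns: contact_label (``donor...acceptor``), class, rho, lap_rho,
    ellipticity, d_AB, d_HB, angle, V_bcp.
    """
    records: list[ContactRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"BCP CSV missing columns: {sorted(missing)}")
        for i, row in enumerate(reader):
            try:
                donor, _, acceptor = row["contact_label"].partition("...")
                records.append(
                    ContactRecord(
                        donor_label=donor,
                        acceptor_label=acceptor,
                        contact_class=ContactClass(row["class"]),
                        rho=float(row["rho"]),
                        lap_rho=float(row["lap_rho"]),
                        ellipticity=float(row["ellipticity"]),
                        d_AB=float(row["d_AB"]),
                        d_HB=float(row["d_HB"]) if row["d_HB"] else None,
                        angle_AHB=float(row["angle"]) if row["angle"] else None,
                        V_bcp=float(row["V_bcp"]) if row["V_bcp"] else None,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"BCP CSV row {i + 1}: {exc}") from exc
    return records
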