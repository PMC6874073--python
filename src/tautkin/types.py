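"""Domain model for tautomerization reaction networks and QTAIM contact records.

The in-memory containers are pydantic models so that every file read is
validated against the same invariants the computational code assumes
(positive densities, positive imaginary wavenumbers, resolvable structure
references, ...).

Printed reference values (rate constants, lifetimes, contact energies taken
from published tables) live in dedicated ``reference`` annotation blocks.
Compute paths never read them; only the comparison harness in
:mod:`tautkin.report` does.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

# --------------------------------------------------------------------------
# naming helpers
# --------------------------------------------------------------------------

_ASCII_MAP = {
    "↔": "__",   # ↔
    "*": "s",
    "′": "p",    # prime
    "'": "p",
    "’": "p",
    "/": "-",
    "⋯": "...",  # ⋯
}


def to_ascii(name: str) -> str:
    """ASCII-safe alias for a structure/reaction name (e.g. ``1↔1*_O1H`` → ``1__1s_O1H``)."""
    out = name
    for src, dst in _ASCII_MAP.items():
        out = out.replace(src, dst)
    return out


def match_key(name: str) -> str:
    """Normalization used to match names across display/ASCII spellings."""
    return to_ascii(name).replace("_", "")


# --------------------------------------------------------------------------
# enumerations
# --------------------------------------------------------------------------


class Role(str, enum.Enum):
    MINIMUM = "minimum"
    TRANSITION_STATE = "transition_state"


class ContactClass(str, enum.Enum):
    """Closed enumeration of intramolecular specific-contact types."""

    OH_O = "OH_O"      # classical OH⋯O hydrogen bond
    CH_O = "CH_O"      # weak CH⋯O hydrogen bond
    OH_C = "OH_C"      # OH⋯C hydrogen bond
    VDW_OO = "vdW_OO"  # attractive O⋯O van der Waals contact
    VDW_CO = "vdW_CO"  # attractive C⋯O van der Waals contact
    CH2_O = "CH2_O"    # HCH⋯O bond of a freshly formed CH2 group


class Formula(str, enum.Enum):
    """Empirical BCP-to-energy formulas."""

    EML = "EML"  # Espinosa–Molins–Lecomte, 0.5·|V(r)|
    BYH = "BYH"  # Brovarets'–Yurenko–Hovorun, 248.501·ρ − 0.367
    NBH = "NBH"  # Nikolaienko–Bulavin–Hovorun, −3.09 + 239·ρ


class Stability(str, enum.Enum):
    STABLE = "stable"
    DYNAMICALLY_UNSTABLE = "dynamically_unstable"
    BARRIERLESS_REVERSE = "barrierless_reverse"


# --------------------------------------------------------------------------
# reference annotations (published expected values; never read by compute paths)
# --------------------------------------------------------------------------


class ContactReference(BaseModel):
    """Published energy for one contact, with the formula marker it was printed with."""

    model_config = ConfigDict(frozen=True)

    energy: float
    formula: Formula
    inconsistent: bool = False  # printed value known not to follow its own formula


class ReactionReference(BaseModel):
    """Published kinetic quantities for one reaction."""

    model_config = ConfigDict(frozen=True)

    k_forward: float
    k_reverse: float
    tau_999: float
    tau_lifetime: float
    ddG_reverse: Optional[float] = None
    ddE_reverse: Optional[float] = None


# --------------------------------------------------------------------------
# core records
# --------------------------------------------------------------------------


class ContactRecord(BaseModel):
    """One AH⋯B hydrogen bond or A⋯B van der Waals contact at a (3,−1) BCP.

    Densities and Laplacians are in atomic units, distances in Å, the
    AH⋯B angle in degrees.  ``ellipticity`` is the bare ε (tables often
    print 100·ε).  ``V_bcp`` is the local potential energy density at the
    BCP in a.u. (≤ 0 by definition); it is optional because published
    tables frequently omit it.
    """

    model_config = ConfigDict(frozen=True)

    donor_label: str
    acceptor_label: str
    contact_class: ContactClass
    rho: float = Field(gt=0, description="electron density at the BCP, a.u.")
    lap_rho: float = Field(description="Laplacian of the density at the BCP, a.u.")
    ellipticity: float = Field(ge=0)
    d_AB: float = Field(gt=0, description="donor–acceptor distance, Å")
    d_HB: Optional[float] = Field(default=None, gt=0, description="H⋯B distance, Å")
    angle_AHB: Optional[float] = Field(default=None, description="AH⋯B angle, degrees")
    V_bcp: Optional[float] = Field(default=None, le=0.0)
    reference: Optional[ContactReference] = None

    @model_validator(mode="after")
    def _geometry(self) -> "ContactRecord":
        if self.d_HB is not None and not self.d_AB > self.d_HB:
            raise ValueError(
                f"d_AB ({self.d_AB}) must exceed d_HB ({self.d_HB}) "
                f"for contact {self.donor_label}...{self.acceptor_label}"
            )
        return self

    @property
    def label(self) -> str:
        return f"{self.donor_label}...{self.acceptor_label}"


class StationaryPoint(BaseModel):
    """A tautomer/conformer minimum or a transition state on the PES.

    Energies are relative to the declared reference structure of the owning
    :class:`ReactionSet`, kcal·mol⁻¹.  The dihedral is the inter-ring
    ∠C3-C2-C1′-C6′ torsion in degrees, (−180, 180].
    """

    model_config = ConfigDict(frozen=True)

    label: str
    role: Role
    rel_gibbs: Optional[float] = None
    rel_electronic: Optional[float] = None
    dipole: Optional[float] = Field(default=None, ge=0, description="Debye")
    dihedral_C3C2C1pC6p: Optional[float] = None
    contacts: tuple[ContactRecord, ...] = ()

    @field_validator("dihedral_C3C2C1pC6p")
    @classmethod
    def _dihedral_range(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (-180.0 < v <= 180.0):
            raise ValueError(f"dihedral_C3C2C1pC6p must lie in (-180, 180], got {v}")
        return v


class TautomericReaction(BaseModel):
    """One reactant ↔ TS ↔ product proton-transfer step.

    ``dG_reaction``/``dE_reaction`` are product-minus-reactant energies
    (positive when the product lies above the reactant).  ``ddG_forward`` /
    ``ddE_forward`` are the forward activation barriers (TS relative to the
    reactant).  ``nu_imag`` is the magnitude of the single imaginary
    wavenumber of the TS, cm⁻¹.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    reactant: str
    ts: str
    product: str
    nu_imag: float = Field(gt=0)
    dG_reaction: float
    dE_reaction: Optional[float] = None
    ddG_forward: float
    ddE_forward: Optional[float] = None
    temperature: float = Field(default=298.15, gt=0)
    reference: Optional[ReactionReference] = None

    @property
    def ascii_name(self) -> str:
        return to_ascii(self.name)


class ReactionSet(BaseModel):
    """A collection of reactions plus the stationary points they reference."""

    model_config = ConfigDict(frozen=True)

    reference_label: str = ""
    structures: tuple[StationaryPoint, ...] = ()
    reactions: tuple[TautomericReaction, ...] = ()
    metadata: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _consistency(self) -> "ReactionSet":
        names = [match_key(r.name) for r in self.reactions]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"reaction names not unique: {dup}")
        labels = [match_key(s.label) for s in self.structures]
        if len(set(labels)) != len(labels):
            dup = sorted({n for n in labels if labels.count(n) > 1})
            raise ValueError(f"structure labels not unique: {dup}")
        by_key = {match_key(s.label): s for s in self.structures}
        for r in self.reactions:
            for ref in (r.reactant, r.ts, r.product):
                if match_key(ref) not in by_key:
                    raise ValueError(
                        f"reaction {r.name!r} references unknown structure {ref!r}"
                    )
            # a TS carries exactly one imaginary mode: the reaction's nu_imag
            if by_key[match_key(r.ts)].role is not Role.TRANSITION_STATE:
                raise ValueError(
                    f"reaction {r.name!r}: ts {r.ts!r} is not a transition_state"
                )
        return self

    # -- lookup ------------------------------------------------------------

    def get_structure(self, label: str) -> StationaryPoint:
        key = match_key(label)
        for s in self.structures:
            if match_key(s.label) == key:
                return s
        raise KeyError(f"no structure labelled {label!r}")

    def get_reaction(self, name: str) -> TautomericReaction:
        key = match_key(name)
        for r in self.reactions:
            if match_key(r.name) == key:
                return r
        raise KeyError(f"no reaction named {name!r}")
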