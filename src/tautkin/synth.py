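"""Seeded generator of synthetic tautomerization reaction sets.

The generator emulates the statistical structure of the reference dataset:
forward Gibbs barriers spanning roughly 0.9–96.5 kcal·mol⁻¹, TS imaginary
wavenumbers of 800–2200 cm⁻¹, and per-class BCP density windows (classical
OH⋯O around 0.02–0.06 a.u., strong HCH⋯O contacts at a proton-transfer TS
around 0.10–0.13 a.u., weak CH⋯O/OH⋯C and vdW contacts at or below
~0.03 a.u.).  Values are drawn uniformly within each window — the reference
tables state ranges, not distributions, so no distributional shape is
invented.

Randomness is organized as one global seed with a per-record counter-derived
substream (``numpy`` ``SeedSequence(seed, spawn_key=(i,))``), so the draws
for record *i* never depend on how many records precede it.
"""

from __future__ import annotations


import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .types import (
    ContactClass,
    ContactRecord,
    ReactionSet,
    Role,
    StationaryPoint,
    TautomericReaction,
)

_DEFAULT_RHO_BY_CLASS: dict[ContactClass, tuple[float, float]] = {
    ContactClass.OH_O: (0.020, 0.060),
    ContactClass.CH2_O: (0.100, 0.130),
    ContactClass.CH_O: (0.010, 0.022),
    ContactClass.OH_C: (0.010, 0.022),
    ContactClass.VDW_OO: (0.010, 0.030),
    ContactClass.VDW_CO: (0.010, 0.030),
}

_DONOR_BY_CLASS = {
    ContactClass.OH_O: ("O5H", "O4"),
    ContactClass.CH2_O: ("HC6H", "O7"),
    ContactClass.CH_O: ("C2'H", "O3"),
    ContactClass.OH_C: ("O3H", "C2'"),
    ContactClass.VDW_OO: ("O5", "O4"),
    ContactClass.VDW_CO: ("C9", "O1"),
}


class SynthSpec(BaseModel):
    """Specification of a synthetic reaction set.

    ``dG_fraction_range`` controls how much of the forward barrier is spent
    as reaction free energy; fractions below 1 leave a positive reverse
    barrier.  ``exothermic_reverse`` forces at least one reaction with
    ΔG above the forward barrier, i.e. a negative reverse barrier.
    ``contaminant_fraction`` is the probability that a contact is emitted
    with a nonpositive Laplacian, for validator testing.
    """

    model_config = ConfigDict(frozen=True)

    n_reactions: int = Field(gt=0)
    seed: int = 0
    barrier_range: tuple[float, float] = (0.9, 96.5)
    dG_fraction_range: tuple[float, float] = (0.0, 0.99)
    nu_range: tuple[float, float] = (800.0, 2200.0)
    rho_by_class: dict[ContactClass, tuple[float, float]] = Field(
        default_factory=lambda: dict(_DEFAULT_RHO_BY_CLASS)
    )
    temperature: float = Field(default=298.15, gt=0)
    exothermic_reverse: bool = False
    contaminant_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    max_contacts: int = Field(default=4, ge=1)

    @model_validator(mode="after")
    def _intervals(self) -> "SynthSpec":
        for name, (lo, hi) in (
            ("barrier_range", self.barrier_range),
            ("dG_fraction_range", self.dG_fraction_range),
            ("nu_range", self.nu_range),
        ):
            if not lo <= hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if self.nu_range[0] <= 0:
            raise ValueError("nu_range must be strictly positive")
        for cls, (lo, hi) in self.rho_by_class.items():
            if not 0 < lo <= hi:
                raise ValueError(f"rho_by_class[{cls.value}] must be positive and nonempty")
        return self


def _rng_for(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _synth_contacts(spec: SynthSpec, rng: np.random.Generator) -> tuple[ContactRecord, ...]:
    classes = list(spec.rho_by_class)
    n = int(rng.integers(1, spec.max_contacts + 1))
    out = []
    for _ in range(n):
        cls = classes[int(rng.integers(len(classes)))]
        lo, hi = spec.rho_by_class[cls]
        rho = float(rng.uniform(lo, hi))
        lap = float(rng.uniform(0.03, 0.15))
        if spec.contaminant_fraction > 0 and rng.random() < spec.contaminant_fraction:
            lap = -float(rng.uniform(0.001, 0.05))
        d_ab = float(rng.uniform(2.2, 3.0))
        hydrogenic = cls in (ContactClass.OH_O, ContactClass.CH_O,
                             ContactClass.OH_C, ContactClass.CH2_O)
        donor, acceptor = _DONOR_BY_CLASS[cls]
        v_bcp = None
        if cls not in (ContactClass.OH_O, ContactClass.CH2_O) and rng.random() < 0.5:
            v_bcp = -float(rng.uniform(0.005, 0.05))
        out.append(ContactRecord(
            donor_label=donor,
            acceptor_label=acceptor,
            contact_class=cls,
            rho=rho,
            lap_rho=lap,
            ellipticity=float(rng.uniform(0.0, 1.0)),
            d_AB=d_ab,
            d_HB=float(d_ab - rng.uniform(0.7, 1.0)) if hydrogenic else None,
            angle_AHB=float(rng.uniform(100.0, 150.0)) if hydrogenic else None,
            V_bcp=v_bcp,
        ))
    return tuple(out)


def generate(spec: SynthSpec) -> ReactionSet:
    """Generate a validated synthetic reaction set, deterministic in the seed."""
    structures: list[StationaryPoint] = []
    reactions: list[TautomericReaction] = []
    for i in range(spec.n_reactions):
        rng = _rng_for(spec.seed, i)
        barrier = float(rng.uniform(*spec.barrier_range))
        if spec.exothermic_reverse and i == 0:
            frac = float(rng.uniform(1.02, 1.30))
        else:
            frac = float(rng.uniform(*spec.dG_fraction_range))
        dg = barrier * frac
        nu = float(rng.uniform(*spec.nu_range))
        labels = (f"R{i}", f"TS{i}", f"P{i}")
        roles = (Role.MINIMUM, Role.TRANSITION_STATE, Role.MINIMUM)
        for label, role in zip(labels, roles):
            structures.append(StationaryPoint(
                label=label,
                role=role,
                dipole=float(rng.uniform(0.3, 10.0)),
                dihedral_C3C2C1pC6p=float(rng.uniform(-179.0, 180.0)),
                contacts=_synth_contacts(spec, rng),
            ))
        reactions.append(TautomericReaction(
            name=f"rx{i:03d}",
            reactant=labels[0],
            ts=labels[1],
            product=labels[2],
            nu_imag=nu,
            dG_reaction=dg,
            ddG_forward=barrier,
            temperature=spec.temperature,
        ))
    return ReactionSet(
        reference_label=structures[0].label if structures else "",
        structures=tuple(structures),
        reactions=tuple(reactions),
        metadata={"generator": "tautkin.synth", "seed": str(spec.seed)},
    )


def perturb_fixture(
    rs: ReactionSet, noise_sd: float, seed: int = 0
) -> ReactionSet:
    """Add Gaussian noise (kcal·mol⁻¹) to forward barriers and reaction energies.

    The reverse barrier is a derived quantity (ΔΔG_f − ΔG), so the
    bookkeeping identity holds for the perturbed set by construction.
    ``noise_sd = 0`` returns an identical set.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    if noise_sd == 0:
        return rs.model_copy(deep=True)
    reactions = []
    for i, r in enumerate(rs.reactions):
        rng = _rng_for(seed, i)
        reactions.append(r.model_copy(update={
            "ddG_forward": r.ddG_forward + float(rng.normal(0.0, noise_sd)),
            "dG_reaction": r.dG_reaction + float(rng.normal(0.0, noise_sd)),
        }))
    return rs.model_copy(update={"reactions": tuple(reactions)})
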