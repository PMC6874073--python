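"""Transition-state-theory kinetics with Wigner tunneling.

For a reversible unimolecular step R ⇌ P over a single first-order saddle
point, the forward and reverse rate constants are

    k_{f,r} = Γ · (k_B T / h) · exp(−ΔΔG_{f,r} / RT)

with a common Wigner tunneling factor

    Γ = 1 + (1/24) · (h·c·ν̃_i / k_B T)²

built from the magnitude ν̃_i of the TS imaginary wavenumber.  Derived
observables: the product lifetime τ = 1/k_r, the time to reach 99.9 % of the
equilibrium composition τ₉₉.₉% = ln(10³)/(k_f + k_r), and the equilibrium
constant K = exp(−ΔG/RT) (the prefactor and Γ cancel in k_f/k_r).

A tautomer is *dynamically unstable* when its lifetime is shorter than the
period 1/(c·ν̃) of its lowest-frequency (torsional) vibration — the minimum
cannot develop vibrational structure before decaying.  A negative reverse
barrier is classified ``barrierless_reverse``: the "product" well is not
kinetically bounded at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .constants import CODATA2018, STANDARD_TEMPERATURE, ConstantsConvention
from .types import Stability, TautomericReaction

LN_1000 = math.log(1000.0)

#: Recommended harmonic-frequency scaling factor for the level of theory
#: used to produce the inputs.
DEFAULT_FREQUENCY_SCALE = 0.9668


@dataclass(frozen=True)
class KineticsResult:
    """Kinetic characterization of one reversible tautomerization step."""

    reaction_name: str
    gamma: float
    k_forward: float
    k_reverse: float
    K_eq: float
    tau_lifetime: float
    tau_999: float
    ddG_forward: float
    ddG_reverse: float
    stability: Stability


def wigner_correction(
    nu_imag: float,
    temperature: float = STANDARD_TEMPERATURE,
    constants: ConstantsConvention = CODATA2018,
) -> float:
    """Wigner tunneling factor Γ = 1 + (h·c·ν̃/k_BT)²/24 (dimensionless, ≥ 1)."""
    if nu_imag < 0:
        raise ValueError(f"nu_imag must be nonnegative, got {nu_imag}")
    x = nu_imag / constants.kBT_in_wavenumbers(temperature)
    return 1.0 + x * x / 24.0


def eyring_rate(
    barrier_kcal: float,
    temperature: float = STANDARD_TEMPERATURE,
    gamma: float = 1.0,
    constants: ConstantsConvention = CODATA2018,
) -> float:
    """Tunneling-corrected Eyring rate Γ·(k_BT/h)·exp(−ΔΔG/RT), s⁻¹.

    A negative barrier is accepted and yields a rate above Γ·k_BT/h; callers
    classify such steps (see :func:`classify_stability`).
    """
    if gamma < 1.0:
        raise ValueError(f"gamma must be >= 1, got {gamma}")
    rt = constants.RT_kcal(temperature)
    return gamma * constants.kBT_over_h(temperature) * math.exp(-barrier_kcal / rt)


def reverse_barrier(ddG_forward: float, dG_reaction: float) -> float:
    """Reverse activation barrier ΔΔG_r = ΔΔG_f − ΔG (may be negative)."""
    return ddG_forward - dG_reaction


def equilibration_time(k_forward: float, k_reverse: float) -> float:
    """Time to reach 99.9 % of the equilibrium composition, ln(10³)/(k_f+k_r), s."""
    total = k_forward + k_reverse
    if total <= 0:
        raise ValueError("k_forward + k_reverse must be positive")
    return LN_1000 / total


def lifetime(k_reverse: float) -> float:
    """Product lifetime τ = 1/k_r, s."""
    if k_reverse <= 0:
        raise ValueError(f"k_reverse must be positive, got {k_reverse}")
    return 1.0 / k_reverse


def equilibrium_constant(
    dG_reaction: float,
    temperature: float = STANDARD_TEMPERATURE,
    constants: ConstantsConvention = CODATA2018,
) -> float:
    """K = exp(−ΔG/RT); equals k_f/k_r since Γ and the prefactor cancel."""
    return math.exp(-dG_reaction / constants.RT_kcal(temperature))


def scale_wavenumber(nu: float, factor: float = DEFAULT_FREQUENCY_SCALE) -> float:
    """Apply a harmonic-frequency scaling factor to a wavenumber."""
    if nu < 0:
        raise ValueError(f"nu must be nonnegative, got {nu}")
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    return nu * factor


def vibrational_period(
    nu: float, constants: ConstantsConvention = CODATA2018
) -> float:
    """Period of a vibration of wavenumber ν̃, 1/(c·ν̃), s."""
    if nu <= 0:
        raise ValueError(f"nu must be positive, got {nu}")
    return 1.0 / (constants.light_speed * nu)


def invert_rate_to_barrier(
    rate: float,
    gamma: float = 1.0,
    temperature: float = STANDARD_TEMPERATURE,
    constants: ConstantsConvention = CODATA2018,
) -> float:
    """Recover the Gibbs activation barrier from a rate: −RT·ln(k/(Γ·k_BT/h))."""
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    prefactor = gamma * constants.kBT_over_h(temperature)
    return -constants.RT_kcal(temperature) * math.log(rate / prefactor)


def classify_stability(
    ddG_reverse: float,
    tau_lifetime: float,
    lowest_mode: Optional[float] = None,
    constants: ConstantsConvention = CODATA2018,
) -> Stability:
    """Dynamic-stability class of the product tautomer.

    Precedence: a nonpositive reverse barrier wins (``barrierless_reverse``);
    otherwise, when the lowest torsional wavenumber is supplied and the
    lifetime is shorter than its vibrational period, the tautomer is
    ``dynamically_unstable``; otherwise ``stable``.  Without a supplied
    ``lowest_mode`` the dynamically-unstable verdict is never issued.
    """
    if ddG_reverse <= 0:
        return Stability.BARRIERLESS_REVERSE
    if lowest_mode is not None and tau_lifetime < vibrational_period(lowest_mode, constants):
        return Stability.DYNAMICALLY_UNSTABLE
    return Stability.STABLE


def compute_kinetics(
    reaction: TautomericReaction,
    constants: ConstantsConvention = CODATA2018,
    use_scaled_nu: bool = False,
    scale_factor: float = DEFAULT_FREQUENCY_SCALE,
    lowest_mode: Optional[float] = None,
) -> KineticsResult:
    """Full kinetic characterization of one reaction at its stated temperature.

    ``use_scaled_nu`` pre-scales the imaginary wavenumber by ``scale_factor``
    before the tunneling correction; it is off by default because supplied
    wavenumbers are commonly already scaled.
    """
    T = reaction.temperature
    nu = scale_wavenumber(reaction.nu_imag, scale_factor) if use_scaled_nu else reaction.nu_imag
    gamma = wigner_correction(nu, T, constants)
    ddG_r = reverse_barrier(reaction.ddG_forward, reaction.dG_reaction)
    k_f = eyring_rate(reaction.ddG_forward, T, gamma, constants)
    k_r = eyring_rate(ddG_r, T, gamma, constants)
    tau = lifetime(k_r)
    tau999 = equilibration_time(k_f, k_r)
    return KineticsResult(
        reaction_name=reaction.name,
        gamma=gamma,
        k_forward=k_f,
        k_reverse=k_r,
        K_eq=equilibrium_constant(reaction.dG_reaction, T, constants),
        tau_lifetime=tau,
        tau_999=tau999,
        ddG_forward=reaction.ddG_forward,
        ddG_reverse=ddG_r,
        stability=classify_stability(ddG_r, tau, lowest_mode, constants),
    )
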