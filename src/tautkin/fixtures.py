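"""Embedded reference dataset: the quercetin proton-transfer reaction network.

Two tables are transcribed from the published MP2/6-311++G(2df,pd)//
B3LYP/6-311++G(d,p) study of intramolecular single-proton-transfer
tautomerization of the isolated quercetin molecule:

* the *kinetics table* — 13 tautomeric transitions with imaginary TS
  wavenumbers, forward/reverse Gibbs and electronic barriers, reaction
  energies, and the published rate constants and time scales;
* the *contacts table* — per-structure (3,−1) BCP descriptors of every
  intramolecular H-bond and attractive vdW contact, with the published
  empirical energies.

Published rate constants, lifetimes and contact energies are stored as
``reference`` annotations, kept strictly out of compute paths; formulas are
always re-evaluated from the input descriptors.  One published OH⋯O energy
(6.78 kcal·mol⁻¹ at ρ = 0.026, O3H⋯O4 row of TS_5↔5*C8H2) does not follow
the OH⋯O formula that yields 3.12 there, as the analogous rows of other
conformers do; it is stored as printed but flagged ``inconsistent``.
"""

from __future__ import annotations

from .types import (
    ContactClass,
    ContactRecord,
    ContactReference,
    Formula,
    ReactionReference,
    ReactionSet,
    Role,
    StationaryPoint,
    TautomericReaction,
)

# --------------------------------------------------------------------------
# kinetics table: (name, reactant, ts, product,
#                  nu_i, dG, dE, ddG_f, ddE_f, ddG_r, ddE_r,
#                  k_f, k_r, tau_999, tau)
# energies kcal/mol, wavenumbers cm^-1, rates s^-1, times s
# --------------------------------------------------------------------------

_TABLE1 = [
    # (a) proton transfer C8H -> O1
    ("1↔1*_O1H", "1", "TS_1↔1*O1H", "1*_O1H",
     1150.3, 87.11, 90.07, 96.31, 100.00, 9.20, 9.93,
     3.09e-58, 2.43e6, 2.84e-6, 4.12e-7),
    ("4↔4*_O1H", "4", "TS_4↔4*O1H", "4*_O1H",
     1264.1, 91.76, 92.64, 92.66, 95.39, 0.90, 2.75,
     1.64e-55, 3.31e12, 2.09e-12, 3.02e-13),
    ("7↔7*_O1H", "7", "TS_7↔7*O1H", "7*_O1H",
     1157.2, 87.23, 90.20, 96.26, 99.75, 9.03, 9.55,
     3.58e-58, 3.26e6, 2.12e-6, 3.07e-7),
    ("10↔10*_O1H", "10", "TS_10↔10*O1H", "10*_O1H",
     1151.7, 87.13, 90.18, 96.27, 99.95, 9.14, 9.77,
     3.31e-58, 2.69e6, 2.57e-6, 3.72e-7),
    # (b) proton transfer O7H/O3'H -> C6/C2'
    ("1↔1*_C6H2", "1", "TS_1↔1*C6H2", "1*_C6H2",
     1970.0, 20.80, 22.30, 65.30, 68.98, 44.50, 46.68,
     3.53e-35, 6.37e-20, 1.08e20, 1.57e19),
    ("1↔1*_C2'H2", "1", "TS_1↔1*C2'H2", "1*_C2'H2",
     2116.5, 17.77, 17.98, 68.15, 71.67, 50.38, 53.69,
     3.21e-37, 3.47e-24, 1.99e24, 2.88e23),
    # (c) OH-group rotation then proton transfer to C8/C6/C2'/C5'
    ("5↔5*_C8H2", "5", "TS_5↔5*C8H2", "5*_C8H2",
     1983.6, 13.72, 14.99, 20.46, 21.98, 6.74, 6.99,
     2.77e-2, 3.21e8, 2.15e-8, 3.12e-9),
    ("25↔25*_C6H2", "25", "TS_25↔25*C6H2", "25*_C6H2",
     2008.3, 13.27, 14.49, 61.63, 64.96, 48.36, 50.47,
     1.79e-32, 9.69e-23, 7.13e22, 1.03e22),
    ("20↔1**_C2'H2", "20", "TS_20↔1**C2'H2", "1**_C2'H2",
     1370.9, 29.63, 31.10, 34.71, 36.93, 5.08, 5.83,
     5.79e-13, 3.14e9, 2.20e-9, 3.19e-10),
    ("10↔1*_C5'H2", "10", "TS_10↔1*C5'H2", "1*_C5'H2",
     2087.7, 22.85, 24.62, 70.59, 74.59, 47.74, 49.97,
     5.09e-39, 2.93e-22, 2.35e22, 3.41e21),
    # (d) proton transfer O3H -> O4
    ("1↔1*_O5H/O4H", "1", "TS_1↔1*O5H/O4H", "1*_O5H/O4H",
     892.1, 14.30, 14.70, 13.10, 15.20, -1.20, 0.50,
     2.62e3, 8.09e13, 8.54e-14, 1.24e-14),
    # (e) proton transfer O7H/O5H -> C6
    ("1_O5H/O4H/O3H↔1*_O5H/O4H/O3H",
     "1_O5H/O4H/O3H", "TS_1_O5H/O4H/O3H↔1*_O5H/O4H/O3H", "1*_O5H/O4H/O3H",
     1766.3, 30.82, 30.25, 49.01, 51.67, 18.19, 21.42,
     2.66e-23, 1.07, 6.43, 0.93),
    ("1_O4H/O3H↔1*_O5H/O4H/O3H",
     "1_O4H/O3H", "TS_1_O4H/O3H↔1*_O5H/O4H/O3H", "1*_O5H/O4H/O3H",
     1791.5, 57.65, 58.54, 75.24, 79.43, 17.59, 20.89,
     1.56e-42, 3.02, 2.29, 0.33),
]

# --------------------------------------------------------------------------
# contacts table: (structure label, dihedral C3-C2-C1'-C6' [deg], dipole [D],
#                  [(donor, acceptor, printed E, marker,
#                    rho, lap_rho, 100*eps, d_AB, d_HB, angle), ...])
# marker: None = OH...O formula, "*" = EML, "**" = strong-CH...O formula,
#         "!"  = OH...O formula but the printed value is inconsistent with it
# --------------------------------------------------------------------------

_TABLE2 = [
    # (a) C8H -> O1
    ("1", 180.0, 0.35, [
        ("O5H", "O4", 6.71, None, 0.041, 0.124, 1.52, 2.655, 1.770, 147.3),
        ("O3H", "O4", 3.36, None, 0.027, 0.103, 60.55, 2.625, 2.009, 119.0),
        ("C2'H", "O3", 4.01, "*", 0.018, 0.076, 0.92, 2.883, 2.137, 123.8),
    ]),
    ("TS_1↔1*O1H", -164.8, 3.38, [
        ("O5H", "O4", 2.89, None, 0.025, 0.082, 1.10, 2.830, 1.990, 142.9),
        ("O3H", "O4", 3.84, None, 0.029, 0.109, 38.00, 2.600, 1.963, 120.4),
        ("C2'H", "O3", 3.32, "*", 0.016, 0.063, 10.19, 2.924, 2.221, 120.6),
    ]),
    ("1*_O1H", -155.3, 1.83, [
        ("O5H", "O4", 9.10, None, 0.051, 0.148, 2.33, 2.565, 1.672, 147.8),
        ("O3H", "O4", 5.75, None, 0.037, 0.134, 17.66, 2.509, 1.853, 121.6),
        ("C9", "O1", 6.47, "*", 0.029, 0.090, 2.46, 2.895, None, None),
        ("C2'H", "O3", 3.38, "*", 0.016, 0.064, 26.96, 2.856, 2.253, 113.1),
    ]),
    ("4", 180.0, 5.33, [
        ("O5H", "O4", 6.47, None, 0.040, 0.124, 1.46, 2.659, 1.776, 147.3),
        ("O3H", "O4", 3.36, None, 0.027, 0.103, 60.63, 2.624, 2.009, 118.9),
        ("C6'H", "O3", 3.83, "*", 0.018, 0.073, 0.80, 2.895, 2.159, 123.3),
    ]),
    ("TS_4↔4*O1H", 162.2, 7.77, [
        ("O5H", "O4", 2.65, None, 0.024, 0.081, 1.20, 2.835, 1.995, 143.0),
        ("O3H", "O4", 3.84, None, 0.029, 0.109, 38.52, 2.601, 1.965, 120.2),
        ("C6'H", "O3", 3.07, "*", 0.015, 0.058, 12.45, 2.942, 2.261, 119.2),
    ]),
    ("4*_O1H", 154.4, 8.88, [
        ("O5H", "O4", 5.04, None, 0.034, 0.112, 1.32, 2.705, 1.842, 145.2),
        ("O3H", "O4", 4.32, None, 0.031, 0.113, 30.34, 2.579, 1.939, 120.5),
        ("C6'H", "O3", 2.57, "*", 0.012, 0.048, 22.18, 2.975, 2.358, 114.7),
    ]),
    ("7", 180.0, 5.05, [
        ("O5H", "O4", 6.71, None, 0.041, 0.125, 1.50, 2.652, 1.767, 147.3),
        ("O3H", "O4", 3.12, None, 0.026, 0.102, 68.01, 2.630, 2.020, 118.5),
        ("C2'H", "O3", 3.83, "*", 0.018, 0.073, 0.02, 2.886, 2.160, 122.4),
    ]),
    ("TS_7↔7*O1H", -162.0, 4.84, [
        ("O5H", "O4", 2.89, None, 0.025, 0.082, 1.09, 2.828, 1.988, 142.9),
        ("O3H", "O4", 3.60, None, 0.028, 0.107, 42.14, 2.606, 1.977, 119.8),
        ("C2'H", "O3", 3.03, "*", 0.014, 0.058, 13.43, 2.936, 2.267, 118.2),
    ]),
    ("7*_O1H", -151.5, 4.65, [
        ("O5H", "O4", 9.10, None, 0.051, 0.147, 2.27, 2.565, 1.673, 147.8),
        ("O3H", "O4", 5.28, None, 0.035, 0.131, 19.50, 2.516, 1.869, 121.0),
        ("C9", "O1", 6.54, "*", 0.029, 0.091, 2.45, 2.374, None, None),
        ("C2'H", "O3", 2.98, "*", 0.014, 0.056, 36.27, 2.876, 2.327, 109.7),
    ]),
    ("10", 180.0, 2.99, [
        ("O5H", "O4", 6.71, None, 0.041, 0.124, 1.51, 2.654, 1.770, 147.3),
        ("O3H", "O4", 3.12, None, 0.026, 0.103, 61.90, 2.626, 2.011, 118.9),
        ("C2'H", "O3", 3.98, "*", 0.018, 0.075, 1.02, 2.889, 2.141, 124.1),
    ]),
    ("TS_10↔10*O1H", -164.7, 2.34, [
        ("O5H", "O4", 2.89, None, 0.025, 0.082, 1.09, 2.830, 1.990, 142.9),
        ("O3H", "O4", 3.84, None, 0.029, 0.109, 38.76, 2.601, 1.966, 120.3),
        ("C2'H", "O3", 3.27, "*", 0.015, 0.062, 10.11, 2.932, 2.227, 120.8),
    ]),
    ("10*_O1H", -154.8, 2.24, [
        ("O5H", "O4", 9.10, None, 0.051, 0.148, 2.31, 2.565, 1.673, 147.8),
        ("O3H", "O4", 5.51, None, 0.036, 0.133, 18.06, 2.510, 1.857, 121.5),
        ("C9", "O1", 6.52, "*", 0.029, 0.091, 2.51, 2.375, None, None),
        ("C2'H", "O3", 3.30, "*", 0.015, 0.062, 27.26, 2.865, 2.263, 113.1),
    ]),
    # (b) O7H/O3'H -> C6/C2'
    ("TS_1↔1*C6H2", 179.3, 3.96, [
        ("HC6H", "O7", 28.46, "**", 0.116, 0.059, 20.81, 2.211, 1.388, 105.3),
        ("O5H", "O4", 8.62, None, 0.049, 0.136, 1.51, 2.595, 1.692, 148.4),
        ("O3H", "O4", 3.12, None, 0.026, 0.101, 69.93, 2.633, 2.025, 118.4),
        ("C2'H", "O3", 3.97, "*", 0.018, 0.075, 1.12, 2.886, 2.141, 123.8),
    ]),
    ("1*_C6H2", 180.0, 5.34, [
        ("O5H", "O4", 8.86, None, 0.050, 0.137, 1.47, 2.587, 1.687, 147.5),
        ("O3H", "O4", 2.65, None, 0.024, 0.099, 96.94, 2.646, 2.048, 117.7),
        ("C2'H", "O3", 4.14, "*", 0.019, 0.078, 1.09, 2.872, 2.126, 123.9),
    ]),
    ("TS_1↔1*C2'H2", -176.8, 3.94, [
        ("O5H", "O4", 6.47, None, 0.040, 0.124, 1.37, 2.657, 1.775, 147.0),
        ("O3H", "O4", 2.89, None, 0.025, 0.100, 76.39, 2.637, 2.032, 118.1),
        ("C2'H", "O3", 3.05, "*", 0.014, 0.058, 39.78, 2.833, 2.322, 106.5),
        ("HC2'H", "O3'", 26.97, "**", 0.110, 0.072, 28.82, 2.244, 1.409, 105.0),
    ]),
    ("1*_C2'H2", 180.0, 3.80, [
        ("O5H", "O4", 6.47, None, 0.040, 0.124, 1.43, 2.657, 1.775, 147.1),
        ("O3H", "O4", 3.12, None, 0.026, 0.102, 68.85, 2.631, 2.022, 118.4),
        ("O3", "C2'", 2.90, "*", 0.012, 0.056, 374.04, 2.807, None, None),
        ("O4'H", "O3'", 2.65, None, 0.024, 0.098, 139.26, 2.650, 2.071, 116.2),
    ]),
    # (c) OH rotation then proton transfer to C8/C6/C2'/C5'
    ("5", 180.0, 3.01, [
        ("O5H", "O4", 6.47, None, 0.040, 0.123, 1.47, 2.660, 1.777, 147.2),
        ("O3H", "O4", 3.36, None, 0.027, 0.104, 58.22, 2.623, 2.004, 119.1),
        ("C2'H", "O3", 4.01, "*", 0.018, 0.076, 0.91, 2.883, 2.138, 123.8),
    ]),
    ("TS_5↔5*C8H2", 177.3, 4.60, [
        ("O5H", "O4", 8.35, None, 0.048, 0.136, 1.28, 2.607, 1.700, 149.6),
        ("O3H", "O4", 6.78, "!", 0.026, 0.103, 61.23, 2.623, 2.010, 118.6),
        ("C2'H", "O3", 3.87, "*", 0.018, 0.073, 1.71, 2.894, 2.151, 123.6),
        ("HC8H", "O7", 30.20, "**", 0.123, 0.033, 17.10, 2.209, 1.363, 105.4),
    ]),
    ("5*_C8H2", 180.0, 6.69, [
        ("O5H", "O4", 7.19, None, 0.043, 0.130, 1.07, 2.642, 1.746, 149.1),
        ("O3H", "O4", 3.36, None, 0.027, 0.104, 62.47, 2.620, 2.008, 118.5),
        ("C2'H", "O3", 3.84, "*", 0.018, 0.073, 0.71, 2.897, 2.154, 123.7),
    ]),
    ("25", 180.0, 3.55, [
        ("O3H", "O4", 4.56, None, 0.032, 0.117, 31.44, 2.571, 1.921, 121.2),
        ("O5", "O4", 2.91, "*", 0.012, 0.049, 13.37, 2.765, None, None),
        ("C2'H", "O3", 3.93, "*", 0.018, 0.074, 0.62, 2.890, 2.145, 123.8),
    ]),
    ("TS_25↔25*C6H2", 179.7, 2.51, [
        ("HC6H", "O5", 31.44, "**", 0.128, 0.012, 15.09, 2.208, 1.347, 105.3),
        ("O3H", "O4", 4.16, None, 0.030, 0.112, 2.00, 2.590, 1.950, 120.5),
        ("C2'H", "O3", 3.87, "*", 0.018, 0.073, 0.56, 2.895, 2.151, 123.8),
    ]),
    ("25*_C6H2", 179.6, 4.46, [
        ("O5", "O4", 2.55, "*", 0.010, 0.041, 188.30, 2.903, None, None),
        ("O3H", "O4", 4.80, None, 0.033, 0.118, 28.83, 2.564, 1.909, 121.5),
        ("C2'H", "O3", 3.75, "*", 0.017, 0.071, 0.38, 2.906, 2.162, 123.8),
    ]),
    ("20", 135.5, 3.62, [
        ("O5H", "O4", 8.38, None, 0.048, 0.136, 1.36, 2.600, 1.700, 148.6),
        ("O3H", "C2'", 2.36, "*", 0.012, 0.045, 251.5, 3.033, 2.242, 138.5),
    ]),
    ("TS_20↔1**C2'H2", 148.4, 4.07, [
        ("O5H", "O4", 8.71, None, 0.049, 0.138, 1.11, 2.591, 1.692, 148.5),
        ("HC2'H", "O3", 27.22, "**", 0.111, 0.085, 3.56, 2.509, 1.398, 141.0),
    ]),
    ("1**_C2'H2", 180.0, 3.40, [
        ("O5H", "O4", 8.62, None, 0.049, 0.138, 0.89, 2.594, 1.697, 148.2),
        ("C2'", "O3", 4.47, "*", 0.018, 0.075, 458.16, 2.695, None, None),
    ]),
    ("TS_10↔1*C5'H2", -175.7, 3.21, [
        ("O5H", "O4", 6.47, None, 0.040, 0.124, 1.48, 2.657, 1.774, 147.1),
        ("O3H", "O4", 3.36, None, 0.027, 0.104, 57.17, 2.621, 2.003, 119.1),
        ("C2'H", "O3", 4.28, "*", 0.019, 0.080, 2.57, 2.885, 2.107, 126.5),
        ("HC5'H", "O4'", 27.47, "**", 0.112, 0.070, 25.78, 2.232, 1.407, 104.6),
    ]),
    ("1*_C5'H2", -173.4, 4.69, [
        ("O5H", "O4", 6.47, None, 0.040, 0.123, 1.37, 2.661, 1.780, 146.8),
        ("O3H", "O4", 3.36, None, 0.027, 0.106, 52.39, 2.614, 1.994, 119.2),
        ("C5'H", "O4'", 4.11, "*", 0.019, 0.077, 3.93, 2.894, 2.125, 125.8),
    ]),
    # (d) O3H -> O4
    ("TS_1↔1*O5H/O4H", 180.0, 3.79, [
        ("O5H", "O4", 2.65, None, 0.024, 0.090, 0.90, 2.802, 1.964, 143.0),
        ("O4H", "O3", 22.48, None, 0.107, 0.082, 1.04, 2.354, 1.408, 136.1),
        ("C2'H", "O3", 3.75, "*", 0.018, 0.066, 3.88, 2.958, 2.175, 127.2),
    ]),
    ("1*_O5H/O4H", 180.0, 4.06, [
        ("O5H", "O4", 2.89, None, 0.025, 0.100, 4.07, 2.754, 1.923, 142.1),
        ("O4H", "O3", 7.43, None, 0.044, 0.128, 12.54, 2.503, 1.783, 125.2),
        ("C2'H", "O3", 4.53, "*", 0.021, 0.077, 3.16, 2.903, 2.114, 127.3),
    ]),
    # (e) O7H/O5H -> C6
    ("1_O5H/O4H/O3H", 180.0, 8.58, [
        ("O4H", "O5", 5.04, None, 0.034, 0.128, 6.17, 2.634, 1.806, 140.7),
        ("O3H", "O4", 2.17, None, 0.022, 0.100, 66.71, 2.613, 2.047, 115.4),
        ("C2'H", "O3", 4.15, "*", 0.019, 0.078, 1.36, 2.868, 2.130, 123.2),
    ]),
    ("TS_1_O5H/O4H/O3H↔1*_O5H/O4H/O3H", 180.0, 7.99, [
        ("O4H", "O5", 5.75, None, 0.037, 0.135, 6.00, 2.613, 1.765, 142.5),
        ("O3H", "O4", 2.17, None, 0.022, 0.099, 79.70, 2.617, 2.055, 115.1),
        ("C2'H", "O3", 4.11, "*", 0.019, 0.077, 1.28, 2.871, 2.133, 123.2),
    ]),
    ("1*_O5H/O4H/O3H", 180.0, 6.68, [
        ("O4H", "O5", 6.47, None, 0.040, 0.138, 5.72, 2.599, 1.740, 143.4),
        ("O3H", "O4", 1.93, None, 0.021, 0.097, 126.99, 2.633, 2.076, 114.7),
        ("C2'H", "O3", 4.21, "*", 0.019, 0.079, 1.29, 2.863, 2.124, 123.3),
    ]),
    ("TS_1_O4H/O3H↔1*_O5H/O4H/O3H", 180.0, 6.05, [
        ("O4H", "O5", 4.47, None, 0.032, 0.100, 1.67, 2.735, 1.856, 145.7),
        ("C2'H", "O3", 4.32, "*", 0.019, 0.081, 1.39, 2.686, 2.143, 113.9),
    ]),
]


def _infer_class(donor: str, acceptor: str) -> ContactClass:
    if donor.startswith("H") and donor.endswith("H"):
        return ContactClass.CH2_O
    if donor.endswith("H"):
        if donor.startswith("O"):
            return ContactClass.OH_O if acceptor.startswith("O") else ContactClass.OH_C
        return ContactClass.CH_O
    if donor.startswith("O") and acceptor.startswith("O"):
        return ContactClass.VDW_OO
    return ContactClass.VDW_CO


_MARKER_FORMULA = {None: Formula.NBH, "!": Formula.NBH, "*": Formula.EML, "**": Formula.BYH}


def _contact(row: tuple) -> ContactRecord:
    donor, acceptor, energy, marker, rho, lap, eps100, d_ab, d_hb, angle = row
    return ContactRecord(
        donor_label=donor,
        acceptor_label=acceptor,
        contact_class=_infer_class(donor, acceptor),
        rho=rho,
        lap_rho=lap,
        ellipticity=eps100 / 100.0,
        d_AB=d_ab,
        d_HB=d_hb,
        angle_AHB=angle,
        reference=ContactReference(
            energy=energy,
            formula=_MARKER_FORMULA[marker],
            inconsistent=(marker == "!"),
        ),
    )


def _role(label: str) -> Role:
    return Role.TRANSITION_STATE if label.startswith("TS") else Role.MINIMUM


def table2_structures() -> list[StationaryPoint]:
    """All stationary points of the contacts table, each with its contacts."""
    return [
        StationaryPoint(
            label=label,
            role=_role(label),
            dipole=mu,
            dihedral_C3C2C1pC6p=dihedral,
            contacts=tuple(_contact(c) for c in rows),
        )
        for label, dihedral, mu, rows in _TABLE2
    ]


def table1_reaction_set() -> ReactionSet:
    """The 13-reaction kinetics table as a validated :class:`ReactionSet`.

    Stationary points are included as bare labelled records (the contacts
    table is a separate fixture); published rates and time scales ride along
    as reference annotations.
    """
    structures: dict[str, StationaryPoint] = {}
    reactions = []
    for (name, reac, ts, prod, nu, dg, de, ddg_f, dde_f, ddg_r, dde_r,
         k_f, k_r, tau999, tau) in _TABLE1:
        for label in (reac, prod):
            structures.setdefault(label, StationaryPoint(label=label, role=Role.MINIMUM))
        structures.setdefault(
            ts, StationaryPoint(label=ts, role=Role.TRANSITION_STATE)
        )
        reactions.append(
            TautomericReaction(
                name=name,
                reactant=reac,
                ts=ts,
                product=prod,
                nu_imag=nu,
                dG_reaction=dg,
                dE_reaction=de,
                ddG_forward=ddg_f,
                ddE_forward=dde_f,
                reference=ReactionReference(
                    k_forward=k_f,
                    k_reverse=k_r,
                    tau_999=tau999,
                    tau_lifetime=tau,
                    ddG_reverse=ddg_r,
                    ddE_reverse=dde_r,
                ),
            )
        )
    return ReactionSet(
        reference_label="1",
        structures=tuple(structures.values()),
        reactions=tuple(reactions),
        metadata={
            "level_of_theory": "MP2/6-311++G(2df,pd)//B3LYP/6-311++G(d,p)",
            "frequency_scale_factor": "0.9668",
            "temperature_K": "298.15",
        },
    )


def load_fixture(name: str):
    """Load an embedded fixture by name.

    ``"table1"`` → the kinetics :class:`ReactionSet` (13 reactions);
    ``"table2"`` → the list of contact-bearing :class:`StationaryPoint`.
    """
    if name == "table1":
        return table1_reaction_set()
    if name == "table2":
        return table2_structures()
    raise KeyError(f"unknown fixture {name!r}; available: 'table1', 'table2'")
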