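"""Unit system and physical constants.

The package works in a single internal unit system throughout:
length nm, time ps, mass u, force pN, energy pN*nm, stress/pressure bar.
Conversion factors below are the only place unit arithmetic happens;
everything else annotates units in docstrings and variable names.
"""

#: Boltzmann constant, J/K (CODATA exact).
KB_J_PER_K = 1.380649e-23

#: 1 J expressed in pN*nm  (1 pN*nm = 1e-12 N * 1e-9 m = 1e-21 J).
PN_NM_PER_J = 1e21

#: 1 pN/nm^2 expressed in bar  (1 pN/nm^2 = 1e6 Pa = 10 bar).
BAR_PER_PN_NM2 = 10.0

#: 1 kJ/mol/nm expressed in pN.
PN_PER_KJ_MOL_NM = 1.66054

#: 1 u*nm^2/ps^2 expressed in pN*nm (kinetic-energy conversion).
PN_NM_PER_U_NM2_PS2 = 1.66054

#: Body temperature used by default in the kinetics modules, K.
BODY_TEMPERATURE_K = 310.15

#: kT at 310.15 K, pN*nm. Fixed constant so kinetics are reproducible to the digit.
KT_BODY_PN_NM = 4.2821


def thermal_energy(temperature_k: float) -> float:
    """kT in pN*nm at the given temperature.

    Returns the fixed :data:`KT_BODY_PN_NM` when the temperature is exactly
    310.15 K so that every code path uses the same rounded constant.
    """
    if temperature_k == BODY_TEMPERATURE_K:
        return KT_BODY_PN_NM
    return KB_J_PER_K * temperature_k * PN_NM_PER_J
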