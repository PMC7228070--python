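"""Physical constants and shared defaults.

Energies are kcal/mol throughout; torsion angles are degrees at every
public interface and converted to radians only where a formula demands it.
"""

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 0.0019872

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Equilibrium twist per base-pair step of B-DNA, degrees.
DEFAULT_TAU0 = 34.5

#: Rise per base-pair step used for default contour lengths, nm.
RISE_PER_STEP_NM = 0.34

#: Number of torsionally active base-pair steps in the reference 50-mers
#: (the twist restraint acts between base pairs 4 and 47).
DEFAULT_ACTIVE_STEPS = 43


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
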