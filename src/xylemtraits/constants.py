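"""Physical constants used in the Hagen-Poiseuille conductivity calculation."""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Properties of liquid water at 20 degrees Celsius.

    Attributes
    ----------
    water_viscosity : float
        Dynamic viscosity eta, in Pa*s.
    water_density : float
        Density rho_w, in kg/m^3.
    """

    water_viscosity: float = 1.002e-3
    water_density: float = 998.2


DEFAULT_CONSTANTS = PhysicalConstants()
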