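"""Physical constants and unit conversions.

Internal computation is in SI; tabular I/O encodes units in column names
(``x_um``, ``t_s``, ``g_Gcm``) and molecular coordinates are in nm.
"""

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN_J_PER_K: float = 1.380649e-23

#: Proton gyromagnetic ratio in gradient-NMR units, s^-1 G^-1
#: (= 2.675e8 rad s^-1 T^-1 expressed per gauss).
PROTON_GAMMA_PER_S_G: float = 2.6752e4

#: Default sample temperature for room-temperature microrheology, K.
ROOM_TEMPERATURE_K: float = 295.15

#: Gradient amplitude conversion: gauss/cm -> gauss/m.
G_PER_CM_TO_G_PER_M: float = 100.0

#: Length conversions.
UM_TO_M: float = 1e-6
M_TO_UM: float = 1e6
NM_TO_M: float = 1e-9

#: Mean-squared displacement conversion, um^2 -> m^2.
UM2_TO_M2: float = 1e-12


def stokes_einstein_diffusivity(
    viscosity_pa_s: float, probe_radius_m: float, temperature_k: float
) -> float:
    """Stokes–Einstein diffusion coefficient D = kB T / (6 π η r), m²/s."""
    import math

    return BOLTZMANN_J_PER_K * temperature_k / (
        6.0 * math.pi * viscosity_pa_s * probe_radius_m
    )
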