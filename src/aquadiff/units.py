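"""Physical constants and unit conversions.

Internal convention: lengths in micrometres, times in milliseconds, so
diffusivities are um^2/ms and membrane permeabilities um/ms.  Public
interfaces accept the units conventional in the diffusion-MRI literature
(D in um^2/s, b in s/mm^2, tau in us) and convert at the boundary.
"""

AVOGADRO = 6.02214076e23  # mol^-1
GAMMA_1H = 2.675e8  # gyromagnetic ratio of 1H, rad s^-1 T^-1


def d_um2s_to_um2ms(d_um2_per_s: float) -> float:
    """Diffusivity: um^2/s -> um^2/ms."""
    return d_um2_per_s * 1e-3


def d_um2ms_to_um2s(d_um2_per_ms: float) -> float:
    """Diffusivity: um^2/ms -> um^2/s."""
    return d_um2_per_ms * 1e3


def tau_us_to_ms(tau_us: float) -> float:
    """Time step: us -> ms."""
    return tau_us * 1e-3


def b_smm2_to_msum2(b_s_per_mm2: float) -> float:
    """b-value: s/mm^2 -> ms/um^2.  1000 s/mm^2 == 1e-3 ms/um^2."""
    return b_s_per_mm2 * 1e-6 * 1e3  # s/mm^2 -> s/um^2 is 1e-6; s->ms is 1e3


def b_msum2_to_smm2(b_ms_per_um2: float) -> float:
    """b-value: ms/um^2 -> s/mm^2."""
    return b_ms_per_um2 * 1e3


def um3_to_litre(v_um3: float) -> float:
    """Volume: um^3 -> L.  1 um^3 = 1e-15 L."""
    return v_um3 * 1e-15
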