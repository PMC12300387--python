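"""Optical constants of the low-finesse Fabry-Perot cavity.

The sensor is a two-beam (low-finesse) Fabry-Perot interferometer: light
partially reflects off the cleaved fiber end (intensity ``I1``) and off a
thin elastic membrane (``I2``) that rides on the artery.  The reflected
intensity follows the cosine interference law

    I(t) = I1 + I2 + 2*sqrt(I1*I2) * cos(4*pi*n/lambda * (z + s*dz(t)) + pi)

so successive intensity extrema are separated by a cavity-length change of
``lambda / (4 n)`` — the *halfwave quantum*, the native displacement
resolution of fringe counting.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OpticalConfig:
    """Constants of the interference law.

    Parameters
    ----------
    wavelength_nm:
        Laser wavelength in vacuum [nm].  Default 1551.3 (telecom C-band).
    refractive_index:
        Refractive index of the medium inside the cavity (air), >= 1.
    static_cavity_length_nm:
        Resting cavity length z [nm]; only its phase modulo the fringe
        period matters, the default is an arbitrary realistic gap.
    intensity_fiber:
        I1, intensity reflected from the fiber end [a.u.].
    intensity_membrane:
        I2, intensity reflected from the membrane, treated as constant
        (the small-variation regime of the two-beam approximation) [a.u.].
    """

    wavelength_nm: float = 1551.3
    refractive_index: float = 1.003
    static_cavity_length_nm: float = 1.0e5
    intensity_fiber: float = 1.0
    intensity_membrane: float = 0.2

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")
        if self.refractive_index < 1:
            raise ValueError(
                f"refractive_index must be >= 1, got {self.refractive_index}"
            )
        if self.static_cavity_length_nm <= 0:
            raise ValueError("static_cavity_length_nm must be > 0")
        if self.intensity_fiber <= 0 or self.intensity_membrane <= 0:
            raise ValueError("reflected intensities I1, I2 must be > 0")

    @property
    def halfwave_quantum_nm(self) -> float:
        """Cavity-length change between successive intensity extrema, lambda/(4n)."""
        return self.wavelength_nm / (4.0 * self.refractive_index)

    @property
    def fringe_amplitude(self) -> float:
        """Peak amplitude of the interference (AC) term, 2*sqrt(I1*I2)."""
        return 2.0 * (self.intensity_fiber * self.intensity_membrane) ** 0.5
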