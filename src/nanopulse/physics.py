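"""Closed-form physical models for a solid-state nanopore sensor.

Open-pore current from a series cylinder + access resistance model,
steric-blockade pulse amplitude, a four-component background-noise power
spectral density, and the SNR-driven noise scaling used to calibrate
synthetic traces.

Units: lengths in nm, conductivity in S/m, mobility in m^2/(V s), areal
charge in C/m^2, current in nA, PSD in nA^2/Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "PoreSpec",
    "Electrolyte",
    "NoisePSDParams",
    "SnrSpec",
    "effective_conductivity",
    "open_pore_current",
    "blockade_amplitude",
    "noise_psd",
    "noise_rms",
    "snr_noise_scale",
]


@dataclass(frozen=True)
class PoreSpec:
    """Cylindrical nanopore geometry and surface charge."""

    diameter_nm: float = 20.0
    thickness_nm: float = 20.0
    surface_charge_C_per_m2: float = -0.02

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0 or self.thickness_nm <= 0:
            raise ValueError("pore diameter and thickness must be positive")


@dataclass(frozen=True)
class Electrolyte:
    """Electrolyte transport properties (defaults: 100 mM KCl at 25 C)."""

    kcl_mM: float = 100.0
    bulk_conductivity_S_per_m: float = 1.28
    cation_mobility_m2_per_Vs: float = 7.62e-8

    def __post_init__(self) -> None:
        if min(self.kcl_mM, self.bulk_conductivity_S_per_m,
               self.cation_mobility_m2_per_Vs) <= 0:
            raise ValueError("electrolyte parameters must be positive")


# Default coefficients chain the four components so the dominant term hands
# over flicker -> electrode -> white -> dielectric near 20 Hz, 200 Hz, 2 kHz.
_A_FLICKER = 1e-6
_A_ELECTRODE = _A_FLICKER / math.sqrt(20.0)
_A_WHITE = _A_ELECTRODE / math.sqrt(200.0)
_A_DIELECTRIC = _A_WHITE / 2000.0


@dataclass(frozen=True)
class NoisePSDParams:
    """One-sided background-noise PSD: a_f/f^beta + a_e/f^gamma + a_w + a_d*f."""

    a_flicker: float = _A_FLICKER
    beta: float = 1.0
    a_electrode: float = _A_ELECTRODE
    gamma: float = 0.5
    a_white: float = _A_WHITE
    a_dielectric: float = _A_DIELECTRIC
    f_min_Hz: float = 1.0
    f_max_Hz: float = 5000.0

    def __post_init__(self) -> None:
        for name in ("a_flicker", "a_electrode", "a_white", "a_dielectric"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.f_min_Hz < self.f_max_Hz):
            raise ValueError("need 0 < f_min_Hz < f_max_Hz")


@dataclass(frozen=True)
class SnrSpec:
    """Target SNR = amplitude / (p2p_factor * noise RMS)."""

    snr: float
    p2p_factor: float = 6.0

    def __post_init__(self) -> None:
        if self.snr <= 0 or self.p2p_factor <= 0:
            raise ValueError("snr and p2p_factor must be positive")


def effective_conductivity(pore: PoreSpec, elec: Electrolyte) -> float:
    """Bulk conductivity plus the surface-conduction term 4*mu*|sigma|/d (S/m)."""
    d_m = pore.diameter_nm * 1e-9
    kappa = elec.bulk_conductivity_S_per_m + (
        4.0 * elec.cation_mobility_m2_per_Vs
        * abs(pore.surface_charge_C_per_m2) / d_m
    )
    return kappa


def open_pore_current(pore: PoreSpec, elec: Electrolyte, bias_V: float) -> float:
    """Open-pore current in nA for a cylindrical pore with access resistance.

    R = (4 L / (pi d^2) + 1/d) / kappa_eff, I0 = V / R.
    """
    if not math.isfinite(bias_V):
        raise ValueError("bias_V must be finite")
    kappa = effective_conductivity(pore, elec)
    if kappa <= 0:
        raise ValueError("effective conductivity must be positive")
    d = pore.diameter_nm * 1e-9
    length = pore.thickness_nm * 1e-9
    resistance = (4.0 * length / (math.pi * d * d) + 1.0 / d) / kappa
    return bias_V / resistance * 1e9


def blockade_amplitude(pore: PoreSpec, d_np_nm: float, i0_nA: float) -> float:
    """Steric-blockade pulse amplitude (nA, positive magnitude).

    dI = I0 * d_np^3 / (d^2 * (L + 0.8 d)) with d the pore diameter and L its
    thickness; strictly increasing in the sphere diameter d_np.
    """
    if d_np_nm <= 0:
        raise ValueError("sphere diameter must be positive")
    if d_np_nm >= pore.diameter_nm:
        raise ValueError("sphere does not translocate: d_np >= pore diameter")
    d = pore.diameter_nm
    volume_term = d_np_nm**3 / (d * d * (pore.thickness_nm + 0.8 * d))
    return i0_nA * volume_term


def noise_psd(params: NoisePSDParams, f_Hz):
    """One-sided PSD S(f) in nA^2/Hz, vectorized over frequency."""
    f = np.asarray(f_Hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    s = (
        params.a_flicker / f**params.beta
        + params.a_electrode / f**params.gamma
        + params.a_white
        + params.a_dielectric * f
    )
    return s if s.ndim else float(s)


def noise_rms(params: NoisePSDParams) -> float:
    """RMS (nA): sqrt of the PSD integral over [f_min, f_max] by quadrature."""
    if params.beta >= 1.0 and params.f_min_Hz <= 0:
        raise ValueError("flicker integral diverges with f_min <= 0")
    if (params.a_flicker == params.a_electrode == params.a_white
            == params.a_dielectric == 0.0):
        return 0.0
    val, _ = integrate.quad(
        lambda f: noise_psd(params, f),
        params.f_min_Hz,
        params.f_max_Hz,
        limit=200,
        epsabs=0.0,
        epsrel=1e-12,
    )
    return math.sqrt(val)


def snr_noise_scale(target: SnrSpec, spike_amplitude_nA: float,
                    base_rms_nA: float) -> float:
    """Multiplier s on the unit noise so that A / (p2p_factor * s * rms) = snr."""
    if spike_amplitude_nA <= 0:
        raise ValueError("spike amplitude must be positive")
    if base_rms_nA <= 0:
        raise ValueError("base noise RMS must be positive")
    return spike_amplitude_nA / (target.p2p_factor * target.snr * base_rms_nA)
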