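"""Micrometeorology: from 10-m wind measurements to release-height wind.

Wind speed is routinely measured at 10 m over short vegetation. Diaspores,
however, are released at heights from 3 cm (ground-dwelling species) to 10 m
(epiphytes), above or below canopies of variable height. This module chains
the standard surface-layer relationships to translate a measured wind speed
into the mean horizontal wind at the release height and the vertical
turbulence there:

1. friction velocity over short vegetation from von Kármán's law,
   u*_s = K·Ū_s / ln(w / Z0_s), with Z0_s = 0.1·h_s;
2. friction velocity over a canopy of height h, assuming the mean velocity at
   the top of the atmospheric surface layer (~200 m) is unaffected by the
   ground texture:
   u* = u*_s · (ln 200 − ln(h_s/10)) / (ln 200 − ln(h/10));
3. turbulence σ_w = 1.25·u*;
4. mean wind at the release height H: the logarithmic profile
   Ū_H = u*·ln((H − d)/Z0)/K (Z0 = 0.1·h, d = 0.7·h) above the canopy, and
   the exponential in-canopy profile Ū_H = Ū_h·exp(α·(H/h − 1)) below it,
   with attenuation α = 0.24 + 0.096·Z0 + 0.016·(ln Z0)².

All logarithms are natural. Every quantity is linear in the measured wind
speed. Functions accept scalars or numpy arrays and broadcast elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindProfileConstants",
    "SiteWind",
    "friction_velocity_short",
    "friction_velocity_tall",
    "turbulence",
    "alpha_coefficient",
    "wind_at_canopy_top",
    "wind_at_release",
    "derive_site_wind",
]


@dataclass(frozen=True)
class WindProfileConstants:
    """Constants of the wind-profile chain.

    K: von Kármán constant (0.4). h_s: reference short-vegetation height (m)
    over which wind is measured. w: anemometer height (m). asl_top: height of
    the atmospheric-surface-layer top (m) at which canopy texture no longer
    affects the mean velocity.
    """

    K: float = 0.4
    h_s: float = 0.3
    w: float = 10.0
    asl_top: float = 200.0

    def __post_init__(self) -> None:
        for name in ("K", "h_s", "w", "asl_top"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def z0_s(self) -> float:
        """Roughness length of the reference short vegetation, 0.1·h_s."""
        return 0.1 * self.h_s


DEFAULT_CONSTANTS = WindProfileConstants()


@dataclass(frozen=True)
class SiteWind:
    """Derived wind state of one site (or elementwise over a grid)."""

    U_s: np.ndarray | float
    h: np.ndarray | float
    H: float
    u_star_s: np.ndarray | float
    u_star: np.ndarray | float
    sigma_w: np.ndarray | float
    U_H: np.ndarray | float
    U_h: np.ndarray | float


def friction_velocity_short(U_s, constants: WindProfileConstants = DEFAULT_CONSTANTS):
    """Friction velocity over the reference short vegetation (von Kármán)."""
    U_s = np.asarray(U_s, dtype=float)
    if np.any(U_s < 0):
        raise ValueError("wind speed must be non-negative")
    out = constants.K * U_s / np.log(constants.w / constants.z0_s)
    return float(out) if out.ndim == 0 else out


def friction_velocity_tall(u_star_s, h, constants: WindProfileConstants = DEFAULT_CONSTANTS):
    """Friction velocity over a canopy of height ``h``.

    Matches the surface-layer-top velocity between the short-vegetation and
    canopy log profiles. Identity when ``h == h_s``.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("canopy height must be positive")
    denom = np.log(constants.asl_top) - np.log(h / 10.0)
    if np.any(denom <= 0):
        raise ValueError(
            f"canopy height {float(np.max(h))} m reaches the surface-layer top "
            f"({constants.asl_top} m); profile matching undefined"
        )
    numer = np.log(constants.asl_top) - np.log(constants.h_s / 10.0)
    out = np.asarray(u_star_s, dtype=float) * numer / denom
    return float(out) if out.ndim == 0 else out


def turbulence(u_star):
    """Standard deviation of vertical wind velocity, σ_w = 1.25·u*."""
    u_star = np.asarray(u_star, dtype=float)
    if np.any(u_star < 0):
        raise ValueError("friction velocity must be non-negative")
    out = 1.25 * u_star
    return float(out) if out.ndim == 0 else out


def alpha_coefficient(Z0):
    """In-canopy attenuation coefficient α(Z0) = 0.24 + 0.096·Z0 + 0.016·ln²Z0."""
    Z0 = np.asarray(Z0, dtype=float)
    if np.any(Z0 <= 0):
        raise ValueError("roughness length must be positive")
    out = 0.24 + 0.096 * Z0 + 0.016 * np.log(Z0) ** 2
    return float(out) if out.ndim == 0 else out


def _floor_canopy(h, constants: WindProfileConstants):
    # Raster canopy heights below the reference vegetation would make the
    # profile matching amplify the wind; clamp to h_s.
    return np.maximum(np.asarray(h, dtype=float), constants.h_s)


def wind_at_canopy_top(U_s, h, constants: WindProfileConstants = DEFAULT_CONSTANTS):
    """Mean wind speed at the canopy top (log profile evaluated at H = h)."""
    h = _floor_canopy(h, constants)
    u_star = friction_velocity_tall(friction_velocity_short(U_s, constants), h, constants)
    # At H = h: (h − 0.7h)/0.1h = 3, independent of h.
    out = u_star * np.log(3.0) / constants.K
    return float(out) if np.ndim(out) == 0 else out


def wind_at_release(U_s, h, H, constants: WindProfileConstants = DEFAULT_CONSTANTS):
    """Mean horizontal wind speed at the release height ``H``.

    Above the canopy (H ≥ h) the logarithmic profile applies; below it the
    exponential in-canopy profile, anchored at the canopy-top wind. The two
    agree at H = h, so the profile is continuous in H.
    """
    if not np.all(np.asarray(H) > 0):
        raise ValueError("release height must be positive")
    h = _floor_canopy(h, constants)
    u_star_s = friction_velocity_short(U_s, constants)
    u_star = friction_velocity_tall(u_star_s, h, constants)
    Z0 = 0.1 * h
    d = 0.7 * h
    above = np.asarray(H >= h)
    height_arg = (H - d) / Z0
    if np.any(above & (height_arg <= 0)):
        raise ValueError(
            "release height is at/above the canopy but H - d <= Z0: the "
            "logarithmic profile is undefined inside the roughness sublayer"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        log_profile = u_star * np.log(height_arg) / constants.K
    U_h = u_star * np.log(3.0) / constants.K
    alpha = alpha_coefficient(Z0)
    exp_profile = U_h * np.exp(alpha * (H / h - 1.0))
    out = np.where(above, log_profile, exp_profile)
    return float(out) if out.ndim == 0 else out


def derive_site_wind(
    U_s, h, H: float, constants: WindProfileConstants = DEFAULT_CONSTANTS
) -> SiteWind:
    """Full chain: measured wind → friction velocities, turbulence, Ū_H."""
    h_eff = _floor_canopy(h, constants)
    u_star_s = friction_velocity_short(U_s, constants)
    u_star = friction_velocity_tall(u_star_s, h_eff, constants)
    return SiteWind(
        U_s=U_s,
        h=h_eff,
        H=H,
        u_star_s=u_star_s,
        u_star=u_star,
        sigma_w=turbulence(u_star),
        U_H=wind_at_release(U_s, h_eff, H, constants),
        U_h=wind_at_canopy_top(U_s, h_eff, constants),
    )
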