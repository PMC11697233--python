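"""ANSI-indexed Zernike polynomial machinery.

Modes are indexed with the ANSI single-index convention
``j = (n(n + 2) + m) / 2`` over radial order ``n`` and azimuthal frequency
``m``, and evaluated in the *orthonormal* (unit-RMS over the unit disk)
normalization.  With orthonormal modes the Euclidean norm of the
coefficients, piston and tilt excluded, equals the true RMS wavefront
distortion in radians — which is what makes fixed-RMS rescaling of an
aberration meaningful.

Coefficient vectors are plain sequences of radians; index ``m`` of the
vector is the ANSI index of the mode it multiplies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ZernikeMode",
    "BoundsProfile",
    "BoundsMode",
    "ansi_to_nm",
    "nm_to_ansi",
    "max_index_for_order",
    "evaluate_mode",
    "wavefront",
    "rms",
    "bound_rms",
    "sample_coefficients",
    "rescale_to_rms",
    "single_mode_coefficients",
    "experimental_bounds",
    "simulation_bounds",
    "defocus_only_bounds",
    "coefficients_to_json",
    "coefficients_from_json",
]

#: ANSI indices of the paired single-aberration modes (cos-like, sin-like).
_PAIRED_MODES = {"astigmatism": (3, 5), "coma": (7, 8), "trefoil": (6, 9)}
_SINGLE_MODES = {"defocus": 4, "spherical": 12}


def ansi_to_nm(ansi_index: int) -> tuple[int, int]:
    """Map an ANSI single index to (radial order n, azimuthal frequency m).

    The inverse of ``j = (n(n + 2) + m) / 2``; e.g. 4 -> (2, 0) (defocus)
    and 12 -> (4, 0) (primary spherical).
    """
    j = int(ansi_index)
    if j < 0:
        raise ValueError("ANSI index must be non-negative")
    n = int((-3.0 + math.sqrt(9.0 + 8.0 * j)) // 2) + 1
    # guard against floating point at triangular-number boundaries
    while n * (n + 1) // 2 > j:
        n -= 1
    while (n + 1) * (n + 2) // 2 <= j:
        n += 1
    m = 2 * j - n * (n + 2)
    return n, m


def nm_to_ansi(n: int, m: int) -> int:
    """ANSI single index of the mode with radial order n, frequency m."""
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise ValueError(f"invalid Zernike orders (n={n}, m={m})")
    return (n * (n + 2) + m) // 2


def max_index_for_order(radial_order: int) -> int:
    """Largest ANSI index contained in aberrations up to ``radial_order``.

    Equals ``(n + 1)(n + 2) / 2 - 1``; radial order 4 gives 14, so a
    coefficient vector spanning orders <= 4 has 15 entries (piston included
    in the indexing even though it is excluded from use).
    """
    n = int(radial_order)
    if n < 0:
        raise ValueError("radial order must be non-negative")
    return (n + 1) * (n + 2) // 2 - 1


def _radial_poly(n: int, m_abs: int, r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r, dtype=float)
    for k in range((n - m_abs) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)
            )
        )
        out += c * r ** (n - 2 * k)
    return out


@dataclass(frozen=True)
class ZernikeMode:
    """A single Zernike mode identified by its ANSI index."""

    ansi_index: int

    @property
    def nm(self) -> tuple[int, int]:
        return ansi_to_nm(self.ansi_index)

    @property
    def n(self) -> int:
        return self.nm[0]

    @property
    def m(self) -> int:
        return self.nm[1]


def evaluate_mode(mode: ZernikeMode | int, r, theta) -> np.ndarray:
    """Evaluate the orthonormal Zernike mode at polar pupil coordinates.

    ``r`` must lie in [0, 1]. Orthonormal normalization: sqrt(n+1) for
    m = 0, sqrt(2(n+1)) otherwise, so every mode has unit RMS over the
    unit disk (piston evaluates to the constant 1).
    """
    j = mode.ansi_index if isinstance(mode, ZernikeMode) else int(mode)
    n, m = ansi_to_nm(j)
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(r < 0) or np.any(r > 1 + 1e-12):
        raise ValueError("pupil radius must lie in [0, 1]")
    rad = _radial_poly(n, abs(m), np.clip(r, 0.0, 1.0))
    if m == 0:
        return math.sqrt(n + 1.0) * rad
    norm = math.sqrt(2.0 * (n + 1.0))
    ang = np.cos(m * theta) if m > 0 else np.sin(-m * theta)
    return norm * rad * ang


def wavefront(coeffs: Sequence[float], r, theta) -> np.ndarray:
    """Phase map (radians): sum of coefficients times orthonormal modes."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phase = np.zeros(np.broadcast(r, theta).shape, dtype=float)
    for j, c in enumerate(np.asarray(coeffs, dtype=float)):
        if c != 0.0:
            phase += c * evaluate_mode(j, r, theta)
    return phase


def rms(coeffs: Sequence[float]) -> float:
    """RMS wavefront distortion: Euclidean norm of coefficients m >= 3.

    Piston and tilt (ANSI 0, 1, 2) carry no image-degrading information and
    are excluded by definition.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.size < 4:
        raise ValueError("coefficient vector must cover ANSI indices 0..3")
    return float(np.sqrt(np.sum(c[3:] ** 2)))


class BoundsMode(str, Enum):
    upper_bounded = "upper_bounded"
    fixed_rms = "fixed_rms"


@dataclass(frozen=True)
class BoundsProfile:
    """Per-mode upper bounds T_m on |c_m| plus an optional amplitude.

    ``amplitude`` is the maximum RMS (Omega, upper_bounded mode) or the
    exact RMS (Upsilon, fixed_rms mode) the sampled aberration is rescaled
    to; ``None`` leaves the raw bounded draw unscaled.
    """

    bounds: tuple[float, ...]
    mode: BoundsMode = BoundsMode.upper_bounded
    amplitude: float | None = None

    def __post_init__(self):
        b = tuple(float(t) for t in self.bounds)
        if len(b) < 4:
            raise ValueError("bounds must cover ANSI indices 0..3 at least")
        if any(t < 0 for t in b):
            raise ValueError("bounds must be non-negative")
        if any(t != 0.0 for t in b[:3]):
            raise ValueError("piston/tilt bounds (indices 0..2) must be 0")
        if self.amplitude is not None and self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        object.__setattr__(self, "bounds", b)
        object.__setattr__(self, "mode", BoundsMode(self.mode))

    @property
    def max_index(self) -> int:
        return len(self.bounds) - 1


def bound_rms(profile: BoundsProfile) -> float:
    """RMS of the bound vector itself (indices >= 3): the RMS_T normalizer."""
    return float(np.sqrt(sum(t * t for t in profile.bounds[3:])))


def experimental_bounds(max_index: int = 14) -> BoundsProfile:
    """Bounds used for experimental datasets: 0.5 rad everywhere, raised to
    1.5 rad for defocus (4) and primary spherical (12); piston/tilt zero."""
    t = [0.5] * (max_index + 1)
    t[0] = t[1] = t[2] = 0.0
    for j in (4, 12):
        if j <= max_index:
            t[j] = 1.5
    return BoundsProfile(tuple(t))


def simulation_bounds(max_index: int = 14) -> BoundsProfile:
    """Bounds used for phantom simulations: low-order modes weighted more —
    1.5 rad for astigmatism (3, 5), defocus (4) and spherical (12),
    0.5 rad otherwise; piston/tilt zero."""
    t = [0.5] * (max_index + 1)
    t[0] = t[1] = t[2] = 0.0
    for j in (3, 4, 5, 12):
        if j <= max_index:
            t[j] = 1.5
    return BoundsProfile(tuple(t))


def defocus_only_bounds(max_index: int = 14, bound: float = 1.5) -> BoundsProfile:
    """Bounds for the pure-defocus aberration type: T_4 = 1.5, rest zero."""
    t = [0.0] * (max_index + 1)
    t[4] = bound
    return BoundsProfile(tuple(t))


def sample_coefficients(
    profile: BoundsProfile, rng: int | np.random.Generator
) -> np.ndarray:
    """Draw a coefficient vector with each c_m uniform on [-T_m, T_m].

    Piston and tilt are identically zero.  If the profile carries an
    amplitude, the draw is rescaled: upper_bounded mode divides by RMS_T
    (so the amplitude Omega is a *maximum* RMS), fixed_rms mode divides by
    the draw's own RMS (so the amplitude Upsilon is the *exact* RMS).
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t = np.asarray(profile.bounds, dtype=float)
    c = gen.uniform(-t, t)
    c[t == 0.0] = 0.0
    if profile.amplitude is not None:
        if profile.mode is BoundsMode.fixed_rms:
            c = rescale_to_rms(c, profile.amplitude, "by_coeff_rms")
        else:
            rms_t = bound_rms(profile)
            if rms_t <= 0:
                raise ValueError("all-zero bounds cannot be amplitude-rescaled")
            c = c * (profile.amplitude / rms_t)
    return c


def rescale_to_rms(
    coeffs: Sequence[float], target_rms: float, normalizer: str = "by_coeff_rms",
    profile: BoundsProfile | None = None,
) -> np.ndarray:
    """Rescale a coefficient vector to a target RMS amplitude.

    ``by_coeff_rms`` divides by the vector's own RMS so the result has RMS
    exactly ``target_rms``; ``by_bound_rms`` divides by the RMS of the bound
    vector of ``profile`` so ``target_rms`` is an upper bound on the result's
    RMS.
    """
    c = np.asarray(coeffs, dtype=float)
    if target_rms <= 0:
        raise ValueError("target RMS must be positive")
    if normalizer == "by_coeff_rms":
        r = rms(c)
        if r <= 0:
            raise ValueError("degenerate aberration: zero-RMS coefficients")
        return c * (target_rms / r)
    if normalizer == "by_bound_rms":
        if profile is None:
            raise ValueError("by_bound_rms needs the BoundsProfile")
        rms_t = bound_rms(profile)
        if rms_t <= 0:
            raise ValueError("degenerate bounds: zero RMS_T")
        return c * (target_rms / rms_t)
    raise ValueError(f"unknown normalizer {normalizer!r}")


def single_mode_coefficients(
    mode_name: str,
    amplitude: float,
    split_angle: float | None = None,
    max_index: int = 14,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Coefficients for a single named aberration mode at exact RMS amplitude.

    Defocus and spherical are single ANSI modes (4 and 12).  Astigmatism,
    coma and trefoil are mode pairs, split as
    (cos(split_angle), sin(split_angle)) * amplitude so the joint RMS is the
    amplitude regardless of the split; if no angle is given one is drawn
    uniformly on [0, 2*pi).
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    c = np.zeros(max_index + 1)
    if mode_name in _SINGLE_MODES:
        j = _SINGLE_MODES[mode_name]
        if j > max_index:
            raise ValueError(f"max_index {max_index} does not include mode {j}")
        c[j] = amplitude
        return c
    if mode_name in _PAIRED_MODES:
        a, b = _PAIRED_MODES[mode_name]
        if max(a, b) > max_index:
            raise ValueError(f"max_index {max_index} does not include modes {a},{b}")
        if split_angle is None:
            gen = np.random.default_rng(rng)
            split_angle = gen.uniform(0.0, 2.0 * np.pi)
        c[a] = amplitude * np.cos(split_angle)
        c[b] = amplitude * np.sin(split_angle)
        return c
    raise ValueError(
        f"unknown mode {mode_name!r}; expected one of "
        f"{sorted(_SINGLE_MODES) + sorted(_PAIRED_MODES)}"
    )


def coefficients_to_json(coeffs: Sequence[float]) -> str:
    return json.dumps(
        {"ansi_convention": True, "coeffs_rad": [float(c) for c in coeffs]}
    )


def coefficients_from_json(text: str) -> np.ndarray:
    obj = json.loads(text)
    if not obj.get("ansi_convention", False):
        raise ValueError("coefficient JSON must declare ansi_convention: true")
    return np.asarray(obj["coeffs_rad"], dtype=float)
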