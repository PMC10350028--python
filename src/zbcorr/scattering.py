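"""Gaussian-sum atomic scattering factors and peak densities.

An isolated atom's scattering factor is conventionally tabulated as a sum of
Gaussians in the scattering-vector magnitude ``s = sin(theta)/lambda``:

    f(s) = sum_i a_i * exp(-b_i * s^2) + c

(four Gaussians plus a constant for the X-ray Cromer-Mann tables; five
Gaussians, ``c = 0``, for the electron parameterization).  Thermal motion
multiplies the factor by ``exp(-B * s^2)``, i.e. adds ``B`` to every width.

Because each reciprocal-space Gaussian transforms to a real-space Gaussian,
the density at the atomic center follows in closed form:

    rho(0) = sum_i a_i * (4*pi / (b_i + B_iso))**1.5 + c * (4*pi / B_iso)**1.5

The constant ``c`` is the zero-width limit of a Gaussian, so it is broadened
by ``B_iso`` alone; this term diverges as ``B_iso -> 0``, hence the
``B_iso > 0`` requirement.  Matching the true ``rho(0)`` with a single
Gaussian of height ``Z * (4*pi/(B0 + B_iso))**1.5`` defines the effective
atomic-shape width ``B0`` used in the total ``B = B0 + B_iso`` split.

Units: X-ray amplitudes are in electrons and densities in e/A^3; electron
(Coulomb-potential) factors are in the parameterization's native units, so
only relative comparisons are meaningful for that radiation type.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GaussianSumFactor",
    "SpreadResult",
    "available_elements",
    "get_factor",
    "load_factor_table",
    "form_factor",
    "density_at_origin",
    "effective_b0",
    "rho0_spread",
]

_FOUR_PI = 4.0 * np.pi

RADIATION_TYPES = ("xray", "electron")


@dataclass(frozen=True)
class GaussianSumFactor:
    """Published Gaussian-sum scattering-factor coefficients for one element.

    Parameters
    ----------
    element : str
        Chemical symbol, e.g. ``"S"``.
    radiation : {"xray", "electron"}
        Which scattering experiment the coefficients describe.
    a, b : tuple of float
        Gaussian amplitudes and widths (A^2); equal length.
    c : float
        Constant term (0 for the electron sets).
    z : int
        Atomic number (electron count of the neutral atom).
    source : str
        Provenance string for the coefficient edition.
    """

    element: str
    radiation: str
    a: tuple[float, ...]
    b: tuple[float, ...]
    c: float
    z: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.radiation not in RADIATION_TYPES:
            raise ValueError(f"radiation must be one of {RADIATION_TYPES}, got {self.radiation!r}")
        if len(self.a) != len(self.b) or len(self.a) < 1:
            raise ValueError("a and b must be non-empty and of equal length")
        if any(bi < 0 for bi in self.b):
            raise ValueError("Gaussian widths b_i must be non-negative")
        if self.z <= 0:
            raise ValueError("atomic number must be positive")

    def form_factor(self, s, b_factor: float = 0.0):
        return form_factor(self, s, b_factor)

    def density_at_origin(self, b_iso: float) -> float:
        return density_at_origin(self, b_iso)

    def effective_b0(self, b_iso: float) -> float:
        return effective_b0(self, b_iso)


@lru_cache(maxsize=1)
def load_factor_table() -> pd.DataFrame:
    """Load the shipped coefficient table as a DataFrame (cached)."""
    with resources.files("zbcorr.data").joinpath("gaussian_sum_coefficients.csv").open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def get_factor(element: str, radiation: str = "xray") -> GaussianSumFactor:
    """Look up the embedded coefficient set for an element.

    Raises ``KeyError`` if the element/radiation pair is not shipped.
    """
    if radiation not in RADIATION_TYPES:
        raise ValueError(f"radiation must be one of {RADIATION_TYPES}, got {radiation!r}")
    df = load_factor_table()
    row = df[(df.element == element) & (df.radiation == radiation)]
    if row.empty:
        raise KeyError(f"no embedded {radiation} coefficients for element {element!r}")
    r = row.iloc[0]
    a = tuple(float(r[f"a{i}"]) for i in range(1, 6) if pd.notna(r[f"a{i}"]))
    b = tuple(float(r[f"b{i}"]) for i in range(1, 6) if pd.notna(r[f"b{i}"]))
    return GaussianSumFactor(
        element=element,
        radiation=radiation,
        a=a,
        b=b,
        c=float(r["c"]),
        z=int(r["Z"]),
        source=str(r["source"]),
    )


def available_elements(radiation: str = "xray") -> list[str]:
    df = load_factor_table()
    return sorted(df[df.radiation == radiation].element.tolist())


def form_factor(factor: GaussianSumFactor, s, b_factor: float = 0.0):
    """Scattering amplitude at ``s = sin(theta)/lambda`` (A^-1), smeared by B.

    Returns ``(sum_i a_i exp(-b_i s^2) + c) * exp(-B s^2)``; scalar in,
    scalar out, ndarray in, ndarray out.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("scattering vector magnitude s must be non-negative")
    if b_factor < 0:
        raise ValueError("temperature factor B must be non-negative")
    s2 = s_arr**2
    a = np.asarray(factor.a)
    b = np.asarray(factor.b)
    f = np.sum(a * np.exp(-np.multiply.outer(s2, b)), axis=-1) + factor.c
    f = f * np.exp(-b_factor * s2)
    return float(f) if np.isscalar(s) or s_arr.ndim == 0 else f


def density_at_origin(factor: GaussianSumFactor, b_iso: float) -> float:
    """Peak density rho(0) of the atom smeared by ``B_iso`` (A^2).

    Closed-form inverse Fourier transform of the B-smeared form factor at
    r = 0.  The constant term contributes ``c * (4 pi / B_iso)^{3/2}``, which
    is why ``B_iso`` must be strictly positive.
    """
    if b_iso <= 0:
        raise ValueError("B_iso must be > 0 (the constant term diverges otherwise)")
    a = np.asarray(factor.a)
    b = np.asarray(factor.b)
    rho = np.sum(a * (_FOUR_PI / (b + b_iso)) ** 1.5)
    rho += factor.c * (_FOUR_PI / b_iso) ** 1.5
    return float(rho)


def effective_b0(factor: GaussianSumFactor, b_iso: float) -> float:
    """Effective single-Gaussian shape width B0 (A^2) at a given ``B_iso``.

    Solves ``Z * (4 pi / (B0 + B_iso))^{3/2} = rho(0)`` for B0, i.e. finds
    the width of the single Gaussian of weight Z whose peak matches the
    multi-Gaussian peak density.  Closed form; no iteration.
    """
    rho0 = density_at_origin(factor, b_iso)
    if rho0 <= 0:
        raise ValueError(
            f"rho(0) = {rho0:.4g} <= 0 for {factor.element} at B_iso={b_iso}; no B0 solution"
        )
    return _FOUR_PI * (factor.z / rho0) ** (2.0 / 3.0) - b_iso


@dataclass(frozen=True)
class SpreadResult:
    """Peak-density contrast across a set of elements at a common B."""

    rho0: dict[str, float]
    spread: float  # (max - min) / mean
    pairwise: pd.DataFrame = field(repr=False)  # |rho_i - rho_j| / min(rho_i, rho_j)


def rho0_spread(factors: Sequence[GaussianSumFactor], b_factor: float) -> SpreadResult:
    """Relative spread of rho(0) across elements at temperature factor ``b_factor``.

    The headline number is ``(max - min) / mean``; the pairwise matrix holds
    ``|rho_i - rho_j| / min(rho_i, rho_j)`` for every element pair, since
    both denominator conventions are in common use for quoting contrast.
    """
    factors = list(factors)
    if len(factors) < 2:
        raise ValueError("need at least two factors to compute a spread")
    radiations = {f.radiation for f in factors}
    if len(radiations) > 1:
        raise ValueError(f"mixed radiation types {sorted(radiations)}; spread is per-radiation")
    rho = {f.element: density_at_origin(f, b_factor) for f in factors}
    values = np.array(list(rho.values()))
    spread = float((values.max() - values.min()) / values.mean())
    elements = list(rho)
    mat = pd.DataFrame(0.0, index=elements, columns=elements)
    for e1, e2 in itertools.combinations(elements, 2):
        d = abs(rho[e1] - rho[e2]) / min(rho[e1], rho[e2])
        mat.loc[e1, e2] = mat.loc[e2, e1] = d
    return SpreadResult(rho0=rho, spread=spread, pairwise=mat)
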