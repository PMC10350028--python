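"""Single-Gaussian scatterer and the two closed-form Z <-> B models.

A scatterer is represented by one Gaussian with effective electron count Z
and total width B (A^2), so the density is

    rho(r) = Z * (4 pi / B)^{3/2} * exp(-4 pi^2 r^2 / B),
    rho(0) = Z * (4 pi / B)^{3/2},

normalized so that the density integrates to Z.  The total width splits as
B = B0 + B_iso, with B0 the intrinsic atomic-shape contribution and B_iso
the isotropic displacement parameter that a refinement program reports.

If a site whose true scatterer is (Z1, B1) is instead refined with atomic
number Z2, the refined B2 shifts to compensate.  Two closed-form models of
that compensation:

* Model 1 (equal peak height): choose B2 so that rho2(0) = rho1(0), giving
  ``B2 = B1 * (Z2/Z1)^{2/3}``.
* Model 2 (least integrated squared density difference): choose B2 to
  minimize ``int (rho1 - rho2)^2 4 pi r^2 dr``, giving
  ``B2 = B1 * u^{2/5} / (2 - u^{2/5})`` with ``u = Z2/Z1``; the denominator
  vanishes at ``u = 2^{5/2}``, the edge of the model's domain.

Because both relations depend only on the ratio Z2/Z1, that ratio doubles as
the refined occupancy of the true Z1 scatterer at the site.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MODEL2_DOMAIN_LIMIT",
    "ModelKind",
    "GaussianAtom",
    "BComposition",
    "Model2DomainError",
    "NotInvertibleError",
    "NegativeBIsoWarning",
    "gaussian_density",
    "peak_density",
    "model1_b2",
    "model1_b2_iso",
    "model2_b2",
    "model2_b2_iso",
    "b2_iso",
    "b2_total",
    "occupancy_from_b",
    "sensitivity",
]

_FOUR_PI = 4.0 * np.pi

#: Singularity of the model-2 closed form: u = Z2/Z1 must stay below 2**(5/2).
MODEL2_DOMAIN_LIMIT: float = 2.0 ** 2.5


class Model2DomainError(ValueError):
    """Z2/Z1 at or beyond the model-2 singularity 2**(5/2)."""


class NotInvertibleError(ValueError):
    """B2_iso outside the range where the model can be inverted for occupancy."""


class NegativeBIsoWarning(UserWarning):
    """A model produced a negative B2_iso (physically inadmissible but analytic)."""


class ModelKind(enum.Enum):
    """Which Z <-> B compensation model to apply."""

    MODEL1_EQUAL_PEAK = "model1"
    MODEL2_MIN_DELTA_RHO_SQ = "model2"

    @classmethod
    def coerce(cls, value) -> "ModelKind":
        """Accept a ModelKind, 1/2, or strings like "1", "model2"."""
        if isinstance(value, cls):
            return value
        aliases = {
            1: cls.MODEL1_EQUAL_PEAK,
            2: cls.MODEL2_MIN_DELTA_RHO_SQ,
            "1": cls.MODEL1_EQUAL_PEAK,
            "2": cls.MODEL2_MIN_DELTA_RHO_SQ,
            "model1": cls.MODEL1_EQUAL_PEAK,
            "model2": cls.MODEL2_MIN_DELTA_RHO_SQ,
            "model1_equal_peak": cls.MODEL1_EQUAL_PEAK,
            "model2_min_delta_rho_sq": cls.MODEL2_MIN_DELTA_RHO_SQ,
        }
        key = value.lower() if isinstance(value, str) else value
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown model kind {value!r}") from None


@dataclass(frozen=True)
class GaussianAtom:
    """Single-Gaussian scatterer: electron count ``z`` and total width ``b`` (A^2)."""

    z: float
    b: float

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("Z must be > 0")
        if self.b <= 0:
            raise ValueError("B must be > 0")

    def density(self, r) :
        return gaussian_density(self, r)

    def peak_density(self) -> float:
        return peak_density(self)


@dataclass(frozen=True)
class BComposition:
    """The split B = B0 + B_iso of the total Gaussian width."""

    b0: float
    b_iso: float

    def __post_init__(self) -> None:
        if self.b0 < 0 or self.b_iso < 0:
            raise ValueError("B0 and B_iso must be >= 0")
        if self.total <= 0:
            raise ValueError("B0 + B_iso must be > 0")

    @property
    def total(self) -> float:
        return self.b0 + self.b_iso


def gaussian_density(atom: GaussianAtom, r):
    """Density rho(r) (e/A^3) of the single-Gaussian atom at radius r (A)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("radial distance r must be non-negative")
    rho = atom.z * (_FOUR_PI / atom.b) ** 1.5 * np.exp(-4.0 * np.pi**2 * r_arr**2 / atom.b)
    return float(rho) if np.isscalar(r) or r_arr.ndim == 0 else rho


def peak_density(atom: GaussianAtom) -> float:
    """rho(0) = Z (4 pi / B)^{3/2}."""
    return atom.z * (_FOUR_PI / atom.b) ** 1.5


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be > 0, got {value}")


def model1_b2(z1: float, b1: float, z2):
    """Total B2 preserving the peak density: ``B1 * (Z2/Z1)^{2/3}``."""
    _check_positive(z1=z1, b1=b1, z2=z2)
    z2_arr = np.asarray(z2, dtype=float)
    out = b1 * (z2_arr / z1) ** (2.0 / 3.0)
    return float(out) if z2_arr.ndim == 0 else out


def model1_b2_iso(b1_iso: float, b0: float, z1: float, z2):
    """Refined-B form of model 1: ``(B1_iso + B0)(Z2/Z1)^{2/3} - B0``.

    May be negative for small Z2/Z1; the analytic value is returned as-is
    with a :class:`NegativeBIsoWarning`.
    """
    comp = BComposition(b0=b0, b_iso=b1_iso)
    out = model1_b2(z1, comp.total, z2) - b0
    if np.any(np.asarray(out) < 0):
        warnings.warn(
            "model 1 yields negative B2_iso (analytic value returned)",
            NegativeBIsoWarning,
            stacklevel=2,
        )
    return out


def _model2_ratio_term(u):
    """``u^{2/5} / (2 - u^{2/5})`` with a domain check at u = 2**(5/2)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr >= MODEL2_DOMAIN_LIMIT):
        raise Model2DomainError(
            f"Z2/Z1 = {np.max(u_arr):.6g} is outside the model-2 domain "
            f"(singularity at 2**(5/2) = {MODEL2_DOMAIN_LIMIT:.6g})"
        )
    x = u_arr ** 0.4
    return x / (2.0 - x)


def model2_b2(z1: float, b1: float, z2):
    """Total B2 minimizing the integrated squared density difference."""
    _check_positive(z1=z1, b1=b1, z2=z2)
    out = b1 * _model2_ratio_term(np.asarray(z2, dtype=float) / z1)
    return float(out) if np.asarray(z2).ndim == 0 else out


def model2_b2_iso(b1_iso: float, b0: float, z1: float, z2):
    """Refined-B form of model 2 (B0 added before, subtracted after)."""
    comp = BComposition(b0=b0, b_iso=b1_iso)
    out = model2_b2(z1, comp.total, z2) - b0
    if np.any(np.asarray(out) < 0):
        warnings.warn(
            "model 2 yields negative B2_iso (analytic value returned)",
            NegativeBIsoWarning,
            stacklevel=2,
        )
    return out


def b2_total(model, z1: float, b1: float, z2):
    """Dispatch on :class:`ModelKind` for the total-B form."""
    model = ModelKind.coerce(model)
    if model is ModelKind.MODEL1_EQUAL_PEAK:
        return model1_b2(z1, b1, z2)
    return model2_b2(z1, b1, z2)


def b2_iso(model, b1_iso: float, b0: float, z1: float, z2):
    """Dispatch on :class:`ModelKind` for the refined-B (iso) form."""
    model = ModelKind.coerce(model)
    if model is ModelKind.MODEL1_EQUAL_PEAK:
        return model1_b2_iso(b1_iso, b0, z1, z2)
    return model2_b2_iso(b1_iso, b0, z1, z2)


def occupancy_from_b(b1_iso: float, b0: float, b2_iso: float, model) -> float:
    """Invert a model for the occupancy ratio u = Z2/Z1 given a refined B2_iso.

    Exact algebraic inverse of the corresponding forward relation; the raw
    ratio is returned (values > 1 mean a heavier effective scatterer).
    """
    model = ModelKind.coerce(model)
    b1_total = BComposition(b0=b0, b_iso=b1_iso).total
    b2_total_ = b2_iso + b0
    if b2_total_ <= 0:
        raise NotInvertibleError(
            f"B2_iso + B0 = {b2_total_:.6g} <= 0; no occupancy solution "
            f"(B2_iso={b2_iso}, B0={b0})"
        )
    if model is ModelKind.MODEL1_EQUAL_PEAK:
        return float((b2_total_ / b1_total) ** 1.5)
    # model 2: B2 = B1 x/(2-x) with x = u^{2/5}  =>  x = 2 B2 / (B1 + B2)
    x = 2.0 * b2_total_ / (b1_total + b2_total_)
    return float(x ** 2.5)


def sensitivity(model, u: float, b1_iso: float, b0: float = 0.0) -> float:
    """Local log-log slope d ln(B2_iso) / d ln(Z2) of a model at ratio ``u``.

    With ``T = B1_iso + B0`` the model-1 iso curve is ``g(u) = T u^{2/3} - B0``
    and the slope is ``(2/3) T u^{2/3} / g(u)``; model 2 differentiates the
    ``x/(2-x)`` form analytically.  For B0 = 0 the slopes at u = 1 are the
    exponents 2/3 and 4/5 themselves.
    """
    model = ModelKind.coerce(model)
    _check_positive(u=u)
    t = BComposition(b0=b0, b_iso=b1_iso).total
    if model is ModelKind.MODEL1_EQUAL_PEAK:
        g = t * u ** (2.0 / 3.0)
        dg_dlnu = (2.0 / 3.0) * g
    else:
        _model2_ratio_term(u)  # domain check
        x = u ** 0.4
        g = t * x / (2.0 - x)
        dg_dlnu = 0.8 * t * x / (2.0 - x) ** 2
    b2i = g - b0
    if b2i <= 0:
        raise ValueError(f"B2_iso = {b2i:.6g} <= 0 at u={u}; log-slope undefined")
    return float(dg_dlnu / b2i)
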