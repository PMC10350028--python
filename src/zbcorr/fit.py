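"""Fitting the Z <-> B model curves to tables of refined B-factors.

The data shape is a table of (element, Z, refined B_iso) rows, the result of
substituting different elements at one crystallographic site and re-refining
only the B-factors.  This module provides:

* :class:`ZBTable` — a validated pandas-backed container with CSV round-trip.
* :class:`ZBCurveModel` / :class:`ZBCurveFit` — a model/results pair in the
  statsmodels idiom: the model holds the data and the fixed physics
  parameters (which compensation model, Z1, B0), ``fit()`` estimates the
  free reference B1_iso by least squares, and the results object carries the
  estimate, its standard error, residuals, a ``summary()`` table and a
  ``plot()`` of data plus curve.  ``evaluate()`` scores a fully fixed curve
  (no free parameters), as when parameter values are quoted rather than fit.
* :func:`linear_fractional_ratio` — an OLS line through a restricted Z range
  and the dimensionless statistic (dB/B)/(dZ/Z) evaluated on that line at a
  reference Z, the number used to say "a 10% change in Z moves B by ~9%".
* :func:`generate_synthetic_table` — reproducible synthetic tables drawn
  from either model curve plus homoscedastic Gaussian noise, for
  parameter-recovery and misspecification experiments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import MODEL2_DOMAIN_LIMIT, ModelKind, b2_iso

__all__ = [
    "ZBTable",
    "LinearFit",
    "ZBCurveModel",
    "ZBCurveFit",
    "linear_fractional_ratio",
    "fit_model_curve",
    "generate_synthetic_table",
]


class ZBTable:
    """Rows of (element, Z, refined B_iso, label); thin validated DataFrame wrapper."""

    COLUMNS = ("element", "Z", "B_iso", "label")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ZBTable missing columns {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["Z"] = df["Z"].astype(float)
        df["B_iso"] = df["B_iso"].astype(float)
        if not np.all(df["Z"] > 0):
            raise ValueError("all Z must be > 0")
        if not np.all(np.isfinite(df["B_iso"])):
            raise ValueError("all B_iso must be finite")
        for label, group in df.groupby("label"):
            if group["Z"].duplicated().any():
                raise ValueError(f"duplicate Z values within label {label!r}")
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def z(self) -> np.ndarray:
        return self._df["Z"].to_numpy()

    @property
    def b_iso(self) -> np.ndarray:
        return self._df["B_iso"].to_numpy()

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        labels = sorted(self._df["label"].unique())
        return f"ZBTable({len(self)} rows, labels={labels})"

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "ZBTable":
        return cls(pd.DataFrame.from_records(list(records)))

    @classmethod
    def from_csv(cls, path) -> "ZBTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path=None):
        """Write ``element,Z,B_iso,label`` CSV; round-trips to full float precision."""
        if path is None:
            buf = io.StringIO()
            self._df.to_csv(buf, index=False, float_format="%.17g")
            return buf.getvalue()
        self._df.to_csv(path, index=False, float_format="%.17g")
        return None


@dataclass(frozen=True)
class LinearFit:
    """OLS line B_iso = slope*Z + intercept over a restricted Z window."""

    slope: float
    intercept: float
    stderr_slope: float
    z_range: tuple[float, float]
    z_ref: float
    fractional_ratio: float
    n: int


def linear_fractional_ratio(
    table: ZBTable, z_lo: float, z_hi: float, z_ref: float = 16.0
) -> LinearFit:
    """OLS line through rows with z_lo <= Z <= z_hi and its log-log slope at z_ref.

    ``fractional_ratio = slope * z_ref / (slope * z_ref + intercept)`` is
    (dB/B)/(dZ/Z) evaluated at ``z_ref`` on the fitted line.
    """
    mask = (table.z >= z_lo) & (table.z <= z_hi)
    z, b = table.z[mask], table.b_iso[mask]
    if len(z) < 3:
        raise ValueError(f"need >= 3 rows with {z_lo} <= Z <= {z_hi}, found {len(z)}")
    if np.ptp(z) == 0:
        raise ValueError("degenerate fit: all in-range Z identical")
    res = stats.linregress(z, b)
    b_at_ref = res.slope * z_ref + res.intercept
    if b_at_ref == 0:
        raise ValueError("fitted line passes through zero at z_ref; ratio undefined")
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr_slope=float(res.stderr),
        z_range=(float(z_lo), float(z_hi)),
        z_ref=float(z_ref),
        fractional_ratio=float(res.slope * z_ref / b_at_ref),
        n=int(len(z)),
    )


class ZBCurveModel:
    """A Z <-> B compensation curve to be fitted to a (Z, B_iso) table.

    Parameters
    ----------
    table : ZBTable or DataFrame
        The refined-B data.
    model : ModelKind or {1, 2}
        Which compensation model generates the curve.
    z1 : float
        Atomic number of the true scatterer (fixed).
    b0 : float
        Atomic-shape contribution to B (A^2, fixed).
    """

    def __init__(self, table, model, z1: float, b0: float):
        if isinstance(table, pd.DataFrame):
            table = ZBTable(table)
        if len(table) < 2:
            raise ValueError("need at least 2 rows to constrain the curve")
        self.table = table
        self.model = ModelKind.coerce(model)
        self.z1 = float(z1)
        self.b0 = float(b0)
        if self.model is ModelKind.MODEL2_MIN_DELTA_RHO_SQ:
            bad = table.z[table.z / self.z1 >= MODEL2_DOMAIN_LIMIT]
            if bad.size:
                raise ValueError(
                    f"Z values {sorted(bad)} lie outside the model-2 domain "
                    f"(Z/Z1 >= 2**(5/2) with Z1={self.z1})"
                )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model, z1: float, b0: float) -> "ZBCurveModel":
        return cls(df, model, z1, b0)

    @classmethod
    def from_csv(cls, path, model, z1: float, b0: float) -> "ZBCurveModel":
        return cls(ZBTable.from_csv(path), model, z1, b0)

    def predict(self, b1_iso: float, z=None):
        """Model curve B2_iso at the table's Z values (or a supplied array)."""
        z = self.table.z if z is None else np.asarray(z, dtype=float)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # negative-B warnings are data, not errors, here
            return b2_iso(self.model, b1_iso, self.b0, self.z1, z)

    def fit(self, start: float | None = None) -> "ZBCurveFit":
        """Least-squares estimate of the free reference B1_iso."""
        p0 = float(np.median(self.table.b_iso)) if start is None else float(start)

        def curve(z, b1_iso):
            return self.predict(b1_iso, z)

        try:
            popt, pcov = optimize.curve_fit(
                curve, self.table.z, self.table.b_iso, p0=[max(p0, 1e-3)]
            )
        except RuntimeError as exc:  # pragma: no cover - hard to trigger for 1 param
            raise RuntimeError(f"curve fit failed to converge: {exc}") from exc
        b1_iso = float(popt[0])
        bse = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
        return ZBCurveFit(self, b1_iso=b1_iso, bse=bse, fixed=False)

    def evaluate(self, b1_iso: float) -> "ZBCurveFit":
        """Score a fully fixed curve (quoted parameters, nothing estimated)."""
        return ZBCurveFit(self, b1_iso=float(b1_iso), bse=float("nan"), fixed=True)


class ZBCurveFit:
    """Results of fitting (or evaluating) a :class:`ZBCurveModel`.

    Attributes
    ----------
    params : dict
        ``{"b1_iso": estimate}`` plus the fixed ``z1`` and ``b0``.
    bse : float
        Standard error of the B1_iso estimate (NaN when fixed).
    resid, fittedvalues : ndarray
        Per-point residuals ``B_obs - B_model`` and model values.
    rss : float
        Residual sum of squares (A^4).
    """

    def __init__(self, model: ZBCurveModel, b1_iso: float, bse: float, fixed: bool):
        self.model = model
        self.b1_iso = b1_iso
        self.bse = bse
        self.fixed = fixed
        self.fittedvalues = model.predict(b1_iso)
        self.resid = model.table.b_iso - self.fittedvalues
        self.rss = float(np.sum(self.resid**2))
        self.nobs = len(model.table)
        self.df_resid = self.nobs - (0 if fixed else 1)

    @property
    def params(self) -> dict[str, float]:
        return {"b1_iso": self.b1_iso, "z1": self.model.z1, "b0": self.model.b0}

    def summary(self) -> str:
        kind = "1 (equal peak density)" if self.model.model is ModelKind.MODEL1_EQUAL_PEAK \
            else "2 (min integrated squared density difference)"
        mode = "fixed (evaluated)" if self.fixed else "estimated (least squares)"
        se = "fixed" if self.fixed else f"{self.bse:.4f}"
        lines = [
            "Z-B compensation curve fit",
            "=" * 46,
            f"Model:            {kind}",
            f"Observations:     {self.nobs}",
            f"Z1 (fixed):       {self.model.z1:g} e-",
            f"B0 (fixed):       {self.model.b0:g} A^2",
            f"B1_iso:           {self.b1_iso:.4f} A^2   ({mode})",
            f"  std err:        {se}",
            f"RSS:              {self.rss:.6g} A^4",
            f"RMS residual:     {np.sqrt(self.rss / self.nobs):.4f} A^2",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None, n_curve: int = 200):
        """Scatter of the table plus the fitted curve vs Z2/Z1."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        z1 = self.model.z1
        z = self.model.table.z
        ax.plot(z / z1, self.model.table.b_iso, "o", label="refined B_iso")
        z_grid = np.linspace(z.min(), z.max(), n_curve)
        ax.plot(z_grid / z1, self.model.predict(self.b1_iso, z_grid), "-",
                label=f"model curve (B1_iso={self.b1_iso:.2f})")
        ax.set_xlabel("Z2 / Z1")
        ax.set_ylabel(r"$B_{iso}$ ($\mathrm{\AA}^2$)")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        return (f"<ZBCurveFit model={self.model.model.value} b1_iso={self.b1_iso:.4f} "
                f"rss={self.rss:.4g} nobs={self.nobs}>")


def fit_model_curve(table, model, z1: float, b0: float, b1_iso: float | None = None) -> ZBCurveFit:
    """Fit (``b1_iso=None``) or evaluate (``b1_iso`` given) a model curve."""
    m = ZBCurveModel(table, model, z1, b0)
    return m.fit() if b1_iso is None else m.evaluate(b1_iso)


# default element symbols for synthetic rows, by nearest lighter Z
_SYMBOLS = {
    1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C", 7: "N", 8: "O", 9: "F",
    10: "Ne", 11: "Na", 12: "Mg", 13: "Al", 14: "Si", 15: "P", 16: "S", 17: "Cl",
    18: "Ar", 19: "K", 20: "Ca", 21: "Sc", 22: "Ti", 23: "V", 24: "Cr", 25: "Mn",
    26: "Fe", 27: "Co", 28: "Ni", 29: "Cu", 30: "Zn", 31: "Ga", 32: "Ge",
    33: "As", 34: "Se",
}


def generate_synthetic_table(
    model,
    z1: float,
    b0: float,
    b1_iso: float,
    z_values: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    label: str = "synthetic",
) -> ZBTable:
    """Synthetic (Z, B_iso) table from a model curve plus Gaussian noise.

    Emulates the data produced by substituting elements at a single site and
    re-refining B: the curve value at each Z plus independent homoscedastic
    Gaussian noise of standard deviation ``noise_sd`` (A^2).  Fully
    reproducible for a given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    z_arr = np.asarray(list(z_values), dtype=float)
    model = ModelKind.coerce(model)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        b_true = np.atleast_1d(b2_iso(model, b1_iso, b0, z1, z_arr))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=z_arr.shape) if noise_sd > 0 else 0.0
    records = [
        {
            "element": _SYMBOLS.get(int(round(z)), f"Z{int(round(z))}"),
            "Z": float(z),
            "B_iso": float(bt + (noise[i] if noise_sd > 0 else 0.0)),
            "label": label,
        }
        for i, (z, bt) in enumerate(zip(z_arr, b_true))
    ]
    return ZBTable.from_records(records)
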