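"""BMI z-scores via the LMS method, outlier trimming, and dichotomization.

The LMS method summarizes a growth reference by three age- and sex-specific
curves: L (Box-Cox power), M (median), S (coefficient of variation). An
observed BMI ``x`` maps to ``z = ((x/M)^L - 1) / (L S)`` (or
``ln(x/M)/S`` when L is zero), projecting the observation onto the
reference distribution. The real UK1990 reference table is licensed, so a
synthetic reference with plausible monotone median curves ships instead
(clearly a stand-in, not the published charts); any user-supplied table in
the same (sex, age, L, M, S) CSV layout is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LMSReference",
    "synthetic_reference",
    "lms_zscore",
    "invert_zscore",
    "trim_outliers",
    "dichotomize",
]

_L_EPS = 1e-8


@dataclass
class LMSReference:
    """L/M/S curves on an age grid, per sex ('male'/'female')."""

    table: pd.DataFrame  # columns: sex, age, L, M, S

    def __post_init__(self):
        req = {"sex", "age", "L", "M", "S"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"LMS table missing columns: {sorted(missing)}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ValueError("M and S must be positive")
        for sex, sub in self.table.groupby("sex"):
            ages = sub["age"].to_numpy()
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"age grid not strictly increasing for {sex!r}")

    @classmethod
    def from_csv(cls, path: str) -> "LMSReference":
        return cls(pd.read_csv(path))

    def curves(self, sex: str):
        sub = self.table[self.table["sex"] == sex]
        if sub.empty:
            raise KeyError(f"no reference rows for sex {sex!r}")
        return (sub["age"].to_numpy(), sub["L"].to_numpy(),
                sub["M"].to_numpy(), sub["S"].to_numpy())

    def interpolate(self, sex, age):
        """Linearly interpolate (L, M, S) in age; no extrapolation."""
        grid, L, M, S = self.curves(sex)
        age = np.asarray(age, dtype=float)
        if np.any(age < grid[0]) or np.any(age > grid[-1]):
            raise ValueError(
                f"age outside reference grid [{grid[0]}, {grid[-1]}]")
        return (np.interp(age, grid, L), np.interp(age, grid, M),
                np.interp(age, grid, S))


def synthetic_reference(age_min: float = 2.0, age_max: float = 18.0,
                        step: float = 0.5) -> LMSReference:
    """A synthetic LMS fixture spanning ages 2-18, both sexes.

    Median BMI dips in early childhood (adiposity rebound) then rises
    through adolescence; S grows modestly with age; L is mildly negative
    (right-skewed BMI). Shapes are plausible for UK children but are not
    the published 1990 reference values.
    """
    ages = np.arange(age_min, age_max + step / 2, step)
    rows = []
    for sex, m_shift, s_shift in (("male", 0.0, 0.0), ("female", -0.2, 0.005)):
        M = 16.5 - 0.35 * (ages - 2) + 0.045 * (ages - 2) ** 2 + m_shift
        S = 0.085 + 0.0035 * (ages - 2) + s_shift
        L = -1.2 - 0.03 * (ages - 2)
        rows.append(pd.DataFrame(
            {"sex": sex, "age": ages, "L": L, "M": M, "S": S}))
    return LMSReference(pd.concat(rows, ignore_index=True))


def lms_zscore(x, sex, age, ref: LMSReference):
    """Age/sex-standardized z-score for BMI ``x`` (kg/m^2)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("BMI must be positive")
    L, M, S = ref.interpolate(sex, age)
    L, M, S = np.broadcast_arrays(L, M, S)
    z = np.where(np.abs(L) > _L_EPS,
                 ((x / M) ** np.where(np.abs(L) > _L_EPS, L, 1.0) - 1.0)
                 / (np.where(np.abs(L) > _L_EPS, L, 1.0) * S),
                 np.log(x / M) / S)
    return z if z.shape else float(z)


def invert_zscore(z, sex, age, ref: LMSReference):
    """BMI whose z-score is ``z``: ``M (1 + L S z)^(1/L)`` (``M e^{Sz}`` at L=0)."""
    z = np.asarray(z, dtype=float)
    L, M, S = ref.interpolate(sex, age)
    L, M, S = np.broadcast_arrays(L, M, S)
    Lsafe = np.where(np.abs(L) > _L_EPS, L, 1.0)
    base = 1.0 + Lsafe * S * z
    if np.any(base[np.abs(L) > _L_EPS] <= 0):
        raise ValueError("z-score outside the representable Box-Cox range")
    x = np.where(np.abs(L) > _L_EPS,
                 M * np.sign(base) * np.abs(base) ** (1.0 / Lsafe),
                 M * np.exp(S * z))
    return x if x.shape else float(x)


def trim_outliers(values, k: float = 3.0) -> np.ndarray:
    """Mask retaining values within ``k`` SDs of the sample mean.

    Single pass: mean and SD are computed once on all non-missing input
    (not re-iterated after deletion). Missing (NaN) entries are never
    retained. Entries exactly at ``k`` SDs are removed (``>=`` rule).
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    mu = values[finite].mean()
    sd = values[finite].std()
    with np.errstate(invalid="ignore"):
        mask = finite & (np.abs(values - mu) < k * sd)
    if sd == 0.0:
        mask = finite.copy()     # nothing exceeds zero spread
    if np.isinf(k):
        mask = finite.copy()
    return mask


def dichotomize(values, cutpoint) -> np.ndarray:
    """Binary indicator: 1 iff the healthy-coded category is >= ``cutpoint``.

    Categories are integer-coded with higher values healthier; ``cutpoint``
    names the lowest category mapping to 1 and must sit on a category
    boundary (an integer). A cutpoint below the lowest observed level
    degenerates to all 1.
    """
    values = np.asarray(values)
    cp = float(cutpoint)
    if not cp.is_integer():
        raise ValueError("cutpoint must name a category boundary (integer)")
    return (values >= cp).astype(int)
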