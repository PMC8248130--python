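"""Fractional-dose selection surfaces over the (D0, n) plane.

For two schemes delivering the same total physical dose, the survival
ratio ``S(Da)**Na / S(Db)**Nb`` says which scheme kills more tumour
cells: values below 1 favour scheme A.  Two canonical comparisons are
built in,

* ``hypo_10v2``  — one 10-Gy fraction versus five 2-Gy fractions
  (hypofractionated SBRT/SRT), and
* ``hyper_1p2v2`` — 2/1.2 fractions of 1.2 Gy (twice daily, matched
  daily physical dose) versus one 2-Gy fraction (hyperfractionation),

evaluated on a grid of (D0, n) to map which cell lines benefit from
large or small fractions.  The ratio is identically 1 along the n = 1
line: a pure exponential response cannot distinguish fractionation
schemes of equal physical dose.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core_model import UMAParams, uma_log_survival

__all__ = ["RatioGrid", "scheme_survival_ratio", "ratio_grid", "RATIO_KINDS"]

#: (Da, Na, Db, Nb) per named ratio kind.
RATIO_KINDS = {
    "hypo_10v2": (10.0, 1.0, 2.0, 5.0),
    "hyper_1p2v2": (1.2, 2.0 / 1.2, 2.0, 1.0),
}


def scheme_survival_ratio(
    params: UMAParams,
    dose_a: float,
    fractions_a: float,
    dose_b: float,
    fractions_b: float,
) -> float:
    """Survival ratio S(Da)**Na / S(Db)**Nb (real-valued exponents).

    The two schemes should deliver the same total physical dose; a
    mismatch is tolerated with a warning since near-matched schedules
    (e.g. BID 1.2-Gy days) are legitimate comparisons.
    """
    if dose_a <= 0 or dose_b <= 0 or fractions_a <= 0 or fractions_b <= 0:
        raise ValueError("doses and fraction counts must be > 0")
    if not math.isclose(dose_a * fractions_a, dose_b * fractions_b, rel_tol=1e-9):
        warnings.warn(
            f"schemes deliver different physical doses "
            f"({dose_a * fractions_a:g} vs {dose_b * fractions_b:g} Gy)",
            stacklevel=2,
        )
    log_ratio = fractions_a * float(uma_log_survival(params, dose_a)) - \
        fractions_b * float(uma_log_survival(params, dose_b))
    return math.exp(log_ratio)


@dataclass(frozen=True)
class RatioGrid:
    """Scheme-survival-ratio values on a (D0, n) grid.

    ``values[i, j]`` is the ratio at ``n_axis[i]``, ``do_axis[j]``; all
    values are positive and the n = 1 row (if present) is exactly 1.
    """

    do_axis: np.ndarray
    n_axis: np.ndarray
    values: np.ndarray
    ratio_kind: str
    schemes: Tuple[float, float, float, float]  # (Da, Na, Db, Nb)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per (D0, n, ratio)."""
        nn, dd = np.meshgrid(self.n_axis, self.do_axis, indexing="ij")
        return pd.DataFrame(
            {"d0_gy": dd.ravel(), "n": nn.ravel(), "ratio": self.values.ravel()}
        )

    def to_csv(self, path_or_buffer=None):
        return self.to_dataframe().to_csv(path_or_buffer, index=False)

    # -- diagnostics -------------------------------------------------------
    def d0_monotonicity(self) -> np.ndarray:
        """Sign of d(ratio)/d(D0) per n row: +1, -1 or 0 (mixed)."""
        diffs = np.diff(self.values, axis=1)
        out = np.zeros(len(self.n_axis))
        out[np.all(diffs > 0, axis=1)] = 1
        out[np.all(diffs < 0, axis=1)] = -1
        return out

    def n_peak_locations(self) -> np.ndarray:
        """Per D0 column, the n at which the ratio is smallest — the
        stationary point across n where the compared scheme gains the
        most tumour control (d ratio / d n = 0 when interior)."""
        idx = np.argmin(self.values, axis=0)
        return self.n_axis[idx]


def ratio_grid(
    ratio_kind: str = "hypo_10v2",
    do_range: Tuple[float, float] = (0.5, 7.0),
    n_range: Tuple[float, float] = (0.2, 20.0),
    resolution: int = 61,
    custom_schemes: Optional[Tuple[float, float, float, float]] = None,
) -> RatioGrid:
    """Evaluate a scheme-survival-ratio surface over the (D0, n) plane.

    ``ratio_kind`` is ``"hypo_10v2"``, ``"hyper_1p2v2"`` or
    ``"custom"`` with ``custom_schemes=(Da, Na, Db, Nb)``.  Axes are
    geometric (both parameters act multiplicatively) and always include
    n = 1, where the ratio is exactly 1.
    """
    if ratio_kind == "custom":
        if custom_schemes is None:
            raise ValueError("custom ratio kind needs custom_schemes=(Da,Na,Db,Nb)")
        schemes = tuple(float(v) for v in custom_schemes)
    elif ratio_kind in RATIO_KINDS:
        schemes = RATIO_KINDS[ratio_kind]
    else:
        raise ValueError(f"unknown ratio kind {ratio_kind!r}")
    (d_lo, d_hi), (n_lo, n_hi) = do_range, n_range
    if not (0 < d_lo < d_hi and 0 < n_lo < n_hi):
        raise ValueError("ranges must be positive and increasing")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    do_axis = np.geomspace(d_lo, d_hi, resolution)
    n_axis = np.geomspace(n_lo, n_hi, resolution)
    if n_lo <= 1.0 <= n_hi:
        n_axis = np.unique(np.concatenate([n_axis, [1.0]]))

    da, na, db, nb = schemes
    values = np.empty((len(n_axis), len(do_axis)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # physical-dose mismatch already vetted
        for i, n in enumerate(n_axis):
            for j, d0 in enumerate(do_axis):
                values[i, j] = scheme_survival_ratio(UMAParams(d0, n), da, na, db, nb)
    return RatioGrid(
        do_axis=do_axis, n_axis=n_axis, values=values,
        ratio_kind=ratio_kind, schemes=schemes,
    )
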