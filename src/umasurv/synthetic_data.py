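"""Synthetic clonogenic-assay curves and the packaged cell-line table.

``generate_curve`` emulates a multi-replicate clonogenic assay: the
UMA (or mixture) model gives the mean survival at each dose, and each
replicate is the mean perturbed by multiplicative lognormal noise —
survival fractions derived from colony counts are positive with
roughly dose-proportional relative scatter, which a lognormal captures
and a Gaussian on the linear scale does not.  The zero-dose point is
always emitted as exactly (0 Gy, S = 1) with a single replicate and no
spread, matching the normalisation convention of published curves.

``table1_fixture`` returns the packaged table of fitted (D0, n) for
31 human tumour cell-line survival curves with the fractionation
scheme, the published dose-dependent alpha and alpha/beta, the UMA
EQD2 and the clinical-alpha/beta LQ EQD2 per row.  It is the reference
input for the reproduction tests and the batch CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .core_model import MixtureParams, UMAParams, uma_survival
from .fitting import SurvivalCurve

__all__ = [
    "GeneratorConfig",
    "generate_curve",
    "table1_fixture",
    "table1_row",
    "DEFAULT_DOSES_INVITRO",
    "DEFAULT_DOSES_INVIVO",
]

#: Default dose grids (Gy) mirroring typical in-vitro and in-vivo assays.
DEFAULT_DOSES_INVITRO: Tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
DEFAULT_DOSES_INVIVO: Tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic survival curve.

    ``noise_sigma`` is the SD of the Gaussian noise applied to log
    survival (multiplicative lognormal on the linear scale); 0.1 is a
    realistic replicate scatter for careful clonogenic work.  The same
    config always produces the identical curve.
    """

    params: Union[UMAParams, MixtureParams]
    doses: Tuple[float, ...] = DEFAULT_DOSES_INVITRO
    replicates: int = 3
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.doses) == 0:
            raise ValueError("dose list must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))


def generate_curve(config: GeneratorConfig) -> SurvivalCurve:
    """Draw one synthetic survival curve from the configured model.

    Replicates at dose D are ``S_model(D) * exp(eps)`` with
    ``eps ~ N(0, noise_sigma^2)``, clipped into (0, 1]; the zero-dose
    anchor is emitted noise-free as (0 Gy, 1.0).
    """
    rng = np.random.default_rng(config.seed)
    points = []
    for d in sorted(set(config.doses) | {0.0}):
        if d == 0.0:
            points.append((0.0, (1.0,)))
            continue
        mean = float(uma_survival(config.params, d))
        eps = rng.normal(0.0, config.noise_sigma, size=config.replicates)
        reps = np.clip(mean * np.exp(eps), None, 1.0)
        points.append((d, tuple(float(s) for s in reps)))
    return SurvivalCurve.from_points(points, add_zero_dose=False)


def table1_fixture() -> pd.DataFrame:
    """The packaged 31-row cell-line parameter table.

    Columns: ``cell_line``, ``tumor``, ``d0_gy``, ``n``,
    ``dose_per_fraction_gy``, ``fractions``, the published
    ``alpha_printed_gy_inv``, ``alpha_beta_printed_gy`` (NaN where the
    ratio is undefined, n = 1), ``eqd2_printed_gy``,
    ``lq_eqd2_printed_gy``, the clinical ``clinical_alpha_beta_gy``
    used in the LQ comparison column (3 Gy prostate, 8 Gy lung and
    colorectal, 10 Gy otherwise), a ``group`` label for the published
    scheme cohorts, and ``ref_d0_gy``/``ref_n`` for the one
    mixed-radiation row whose EQD2 is referenced to the same line's
    gamma-ray response.
    """
    with resources.files("umasurv.data").joinpath("table1_parameters.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def table1_row(cell_line: str) -> pd.Series:
    """Look up one fixture row by its (unique) cell-line label."""
    df = table1_fixture()
    hit = df[df["cell_line"] == cell_line]
    if len(hit) != 1:
        raise KeyError(f"cell line {cell_line!r} not found (or ambiguous) in fixture")
    return hit.iloc[0]
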