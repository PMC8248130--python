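"""Equivalent-dose calculations under the UMA model, with LQ comparators.

EQD2 is the total dose delivered in 2-Gy fractions that produces the
same end survival as a given scheme.  Because the UMA log-survival is
linear in the number of fractions, the equivalent number of 2-Gy
fractions for a course of N fractions of D Gy is

    N2 = N * [ln n - ln(exp(D/D0)+n-1)] / [ln n - ln(exp(2/D0)+n-1)]

and EQD2 = 2 Gy * N2.  Sessions with different fractional doses simply
add their per-session EQD2.  For mixed radiation qualities (e.g.
alpha-particle treatment referenced to the same cell line's gamma-ray
response) the treatment-radiation parameters enter the numerator and
the reference-radiation parameters the denominator.

Under the UMA model a single dose term carries all dose dependence, so
the biologically effective dose is the physical dose itself; the
classical LQ BED and LQ EQD2 are provided for comparison only.

For a tumour with mixed sub-populations the governing EQD2 is the
*minimum* over components: at the end of treatment the most
radioresistant compartment (the one hardest to trade up to 2-Gy
fractions) dominates regrowth.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .core_model import MixtureParams, UMAParams, uma_log_survival

__all__ = [
    "TreatmentScheme",
    "EquivalenceResult",
    "uma_eqd2",
    "lq_eqd2",
    "lq_bed",
    "mixture_eqd2",
    "equivalent_fraction_number",
]


@dataclass(frozen=True)
class TreatmentScheme:
    """Ordered sessions of (dose per fraction in Gy, fraction count).

    Fraction counts are positive; they may be non-integral to express
    schedules like twice-daily 1.2-Gy fractions matched to a 2-Gy daily
    physical dose (2/1.2 fractions per day).
    """

    sessions: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        sess = tuple((float(d), float(n)) for d, n in self.sessions)
        if not sess:
            raise ValueError("scheme must contain at least one session")
        for d, n in sess:
            if not (d > 0 and math.isfinite(d)):
                raise ValueError(f"dose per fraction must be > 0 Gy, got {d}")
            if not (n > 0 and math.isfinite(n)):
                raise ValueError(f"fraction count must be > 0, got {n}")
        object.__setattr__(self, "sessions", sess)

    @classmethod
    def single(cls, dose_per_fraction: float, fractions: float) -> "TreatmentScheme":
        return cls(((dose_per_fraction, fractions),))

    @classmethod
    def parse(cls, text: str) -> "TreatmentScheme":
        """Parse the scheme mini-language ``"DxN[+DxN...]"``.

        ``"20x1"`` is one 20-Gy fraction, ``"7x5+2x5"`` five 7-Gy
        fractions followed by five 2-Gy fractions.
        """
        sessions: List[Tuple[float, float]] = []
        for pos, part in enumerate(text.strip().split("+")):
            m = re.fullmatch(r"\s*([0-9]*\.?[0-9]+)\s*[xX]\s*([0-9]*\.?[0-9]+)\s*", part)
            if m is None:
                raise ValueError(
                    f"cannot parse session {pos + 1} ({part!r}); expected 'DOSExCOUNT'"
                )
            sessions.append((float(m.group(1)), float(m.group(2))))
        return cls(tuple(sessions))

    @property
    def total_dose(self) -> float:
        """Total physical dose in Gy."""
        return sum(d * n for d, n in self.sessions)

    def __str__(self) -> str:
        return "+".join(f"{d:g}x{n:g}" for d, n in self.sessions)


@dataclass(frozen=True)
class EquivalenceResult:
    """EQD2 of a scheme with its equivalent fraction number and end survival."""

    eqd2: float
    n2: float
    end_survival: float
    per_session: Tuple[float, ...]
    reference_dose: float = 2.0


def _per_fraction_log_survival(params: UMAParams, dose: float) -> float:
    return float(uma_log_survival(params, dose))


def uma_eqd2(
    params: UMAParams,
    scheme: TreatmentScheme,
    params_ref: Optional[UMAParams] = None,
    reference_dose: float = 2.0,
) -> EquivalenceResult:
    """Equivalent dose in ``reference_dose``-Gy fractions under the UMA model.

    Parameters
    ----------
    params
        Response of the cells to the treatment radiation.
    scheme
        The fractionation scheme delivered.
    params_ref
        Response of the same cells to the reference radiation (defaults
        to ``params``); used in the denominator so that, e.g., an
        alpha-particle course can be expressed in 2-Gy photon fractions.
    reference_dose
        Fraction size of the reference schedule, default 2 Gy (EQD2).

    The defining property is iso-survival:
    ``S_end = S(D)**N = S_ref(x)**Nx`` with ``EQDx = x * Nx``.
    """
    if not isinstance(params, UMAParams):
        raise TypeError("uma_eqd2 takes single-population parameters; "
                        "use mixture_eqd2 for mixtures")
    if params_ref is None:
        params_ref = params
    if not (reference_dose > 0):
        raise ValueError("reference_dose must be > 0 Gy")
    log_s_ref = _per_fraction_log_survival(params_ref, reference_dose)
    # log_s_ref < 0 always (survival strictly decreasing), so no pole.
    per_session = tuple(
        reference_dose * n * _per_fraction_log_survival(params, d) / log_s_ref
        for d, n in scheme.sessions
    )
    eqd = sum(per_session)
    log_end = sum(n * _per_fraction_log_survival(params, d) for d, n in scheme.sessions)
    return EquivalenceResult(
        eqd2=eqd,
        n2=eqd / reference_dose,
        end_survival=math.exp(log_end),
        per_session=per_session,
        reference_dose=reference_dose,
    )


def equivalent_fraction_number(
    params: UMAParams, dose_per_fraction: float, fractions: float,
    reference_dose: float = 2.0,
) -> float:
    """Real-valued number of reference-dose fractions iso-effective with
    ``fractions`` fractions of ``dose_per_fraction`` Gy."""
    res = uma_eqd2(
        params,
        TreatmentScheme.single(dose_per_fraction, fractions),
        reference_dose=reference_dose,
    )
    return res.n2


def mixture_eqd2(
    mix: MixtureParams,
    scheme: TreatmentScheme,
    reference_dose: float = 2.0,
) -> float:
    """EQD2 of a mixed-population tumour: the minimum over components.

    The most radioresistant surviving compartment governs regrowth at
    the end of treatment, and it is the compartment with the lowest
    per-component EQD2 that bounds the achievable equivalent dose.
    """
    if not isinstance(mix, MixtureParams):
        raise TypeError("mixture_eqd2 takes MixtureParams")
    return min(
        uma_eqd2(p, scheme, reference_dose=reference_dose).eqd2
        for _, p in mix.components
    )


def lq_eqd2(alpha_beta: float, scheme: TreatmentScheme, reference_dose: float = 2.0) -> float:
    """Classical LQ-model EQD2: sum of N*D*(1+D/(a/b))/(1+x/(a/b)).

    A negative alpha/beta (inverted-shoulder analogue) is accepted with
    a warning; the single pole is alpha_beta == -reference_dose.
    """
    if alpha_beta == 0:
        raise ValueError("alpha/beta must be nonzero")
    if alpha_beta == -reference_dose:
        raise ValueError(f"alpha/beta = {-reference_dose} Gy is a pole of the LQ EQD formula")
    if alpha_beta < 0:
        warnings.warn(
            f"negative alpha/beta ratio ({alpha_beta} Gy) supplied to lq_eqd2",
            stacklevel=2,
        )
    return sum(
        n * d * (alpha_beta + d) / (alpha_beta + reference_dose)
        for d, n in scheme.sessions
    )


def lq_bed(alpha_beta: float, scheme: TreatmentScheme) -> float:
    """Classical LQ biologically effective dose, sum of N*D*(1+D/(a/b)).

    Under the UMA model the physical dose plays this role instead
    (``scheme.total_dose``); this function exists for the LQ comparison
    path only.
    """
    if alpha_beta == 0:
        raise ValueError("alpha/beta must be nonzero")
    return sum(n * d * (1.0 + d / alpha_beta) for d, n in scheme.sessions)
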