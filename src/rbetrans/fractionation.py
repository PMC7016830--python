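"""Isoeffective dose conversion between fractionation schedules via BED.

Linear-quadratic biologically effective dose:
``BED = D * (1 + (D / nf) / (alpha/beta))`` for total dose D delivered in
nf equal fractions. Converting a schedule keeps BED fixed and solves the
resulting quadratic for the new total dose. The rectal default is
alpha/beta = 3.9 Gy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FractionationScheme", "bed", "equivalent_total_dose", "DEFAULT_ALPHA_BETA"]

DEFAULT_ALPHA_BETA = 3.9


@dataclass(frozen=True)
class FractionationScheme:
    total_dose: float
    n_fractions: int
    alpha_beta: float = DEFAULT_ALPHA_BETA

    def __post_init__(self) -> None:
        if self.total_dose < 0:
            raise ValueError("total dose must be non-negative")
        if not (isinstance(self.n_fractions, (int, np.integer)) and self.n_fractions >= 1):
            raise ValueError("n_fractions must be a positive integer")
        if not self.alpha_beta > 0:
            raise ValueError("alpha/beta must be positive")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


def bed(scheme: FractionationScheme) -> float:
    """Biologically effective dose of a schedule [Gy]."""
    return scheme.total_dose * (1.0 + scheme.dose_per_fraction / scheme.alpha_beta)


def equivalent_total_dose(
    source: FractionationScheme,
    target_n_fractions: int,
    alpha_beta: float | None = None,
) -> float:
    """Total dose in ``target_n_fractions`` with the same BED as ``source``.

    Positive root of ``D^2 / (nf * alpha/beta) + D - BED = 0``; the
    discriminant is non-negative whenever BED >= 0, so the conversion is
    always defined.
    """
    if target_n_fractions < 1:
        raise ValueError("target_n_fractions must be a positive integer")
    ab = source.alpha_beta if alpha_beta is None else alpha_beta
    if ab <= 0:
        raise ValueError("alpha/beta must be positive")
    target_bed = bed(FractionationScheme(source.total_dose, source.n_fractions, ab))
    k = target_n_fractions * ab
    # D = (-1 + sqrt(1 + 4 BED / k)) * k / 2
    return 0.5 * k * (np.sqrt(1.0 + 4.0 * target_bed / k) - 1.0)
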