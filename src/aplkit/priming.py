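"""Priming-magnitude summaries: heat bars, paired one-tailed t-tests, CFSE.

Peptide-priming experiments measure, per donor and candidate peptide, the
percentage of tetramer-positive CD8 T-cells induced after ~2 weeks of
culture. This module normalizes those percentages into per-donor heat bars,
tests paired two-arm comparisons (natural epitope vs super-agonist) with a
one-tailed paired t-test, and converts CFSE-low percentages into
background-subtracted proliferation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrimingRecord",
    "HeatBarMatrix",
    "heat_bar",
    "paired_one_tailed_t",
    "cfse_proliferation",
]


@dataclass(frozen=True)
class PrimingRecord:
    donor: str
    peptide: str
    timepoint: int
    tetramer_pos_percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tetramer_pos_percent <= 100.0:
            raise ValueError("tetramer_pos_percent outside [0, 100]")


@dataclass(frozen=True)
class HeatBarMatrix:
    """Per-donor min-max normalized priming magnitudes plus a combined row."""

    matrix: pd.DataFrame
    combined: pd.Series


def heat_bar(percents: pd.DataFrame) -> HeatBarMatrix:
    """Min-max normalize a donors x peptides matrix of tetramer+ percentages.

    Each donor row maps to [0, 1] via ``(v - min) / (max - min)`` so the
    donor's best-priming peptide gets 1; a constant row (no discrimination)
    maps to all zeros. The combined row is the per-peptide mean of the
    normalized donor rows, weighting donors equally regardless of the
    absolute magnitudes they reached.
    """
    if percents.size == 0:
        raise ValueError("empty priming matrix")
    values = percents.to_numpy(dtype=float)
    if np.any((values < 0) | (values > 100)):
        raise ValueError("priming percentages outside [0, 100]")
    lo = values.min(axis=1, keepdims=True)
    span = values.max(axis=1, keepdims=True) - lo
    safe = np.where(span == 0, 1.0, span)
    normalized = np.where(span == 0, 0.0, (values - lo) / safe)
    matrix = pd.DataFrame(normalized, index=percents.index, columns=percents.columns)
    combined = matrix.mean(axis=0)
    combined.name = "combined"
    return HeatBarMatrix(matrix=matrix, combined=combined)


def paired_one_tailed_t(
    pairs: Sequence[tuple[float, float]],
    direction: Literal["b_greater", "a_greater"],
) -> tuple[float, int, float]:
    """Paired one-tailed t-test on (a_i, b_i) pairs.

    ``direction`` states which arm is hypothesized larger; it must be chosen
    before seeing the data (inferring it post hoc invalidates the test).
    Returns ``(t, df, p)`` where p is the upper-tail probability of the
    direction-signed mean difference.
    """
    if direction not in ("b_greater", "a_greater"):
        raise ValueError("direction must be 'b_greater' or 'a_greater'")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a if direction == "b_greater" else a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences: p undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(stats.t.sf(t, df))
    return t, df, p


def cfse_proliferation(
    pct_cfse_low_peptide: float, pct_cfse_low_dmso: float
) -> float:
    """Peptide-driven proliferation: CFSE-low % minus the DMSO background.

    Clipped at zero; below-background values are flagged with a warning.
    """
    for v in (pct_cfse_low_peptide, pct_cfse_low_dmso):
        if not 0.0 <= v <= 100.0:
            raise ValueError("CFSE-low percentages must be in [0, 100]")
    delta = pct_cfse_low_peptide - pct_cfse_low_dmso
    if delta < 0:
        warnings.warn(
            f"peptide condition below DMSO background ({delta:.2f}%); reporting 0",
            stacklevel=2,
        )
        return 0.0
    return delta
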