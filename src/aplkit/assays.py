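"""Quantification of T-cell functional validation assays.

Covers the downstream measurements used to validate candidate super-agonist
peptides: 4-parameter-logistic dose-response fitting of peptide titrations
(MIP-1beta ELISA / IFNgamma ELISpot), flow-cytometry killing with a CFSE
reference population, chromium-release specific lysis, T2 HLA-stabilization
indices, and per-tetramer-positive-cell effector dosing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "TitrationSeries",
    "DoseResponseFit",
    "KillingInput",
    "ChromiumInput",
    "DegenerateFitError",
    "four_pl",
    "fit_dose_response",
    "compare_sensitivity",
    "flow_killing_percent",
    "chromium_specific_lysis",
    "effectors_for_dose",
    "stabilization_index",
]


class DegenerateFitError(ValueError):
    """Raised when a titration carries no usable dose-response signal."""


@dataclass(frozen=True)
class TitrationSeries:
    """A peptide titration: readout (e.g. MIP-1beta ng/mL) vs molar concentration."""

    peptide: str
    concentrations: tuple[float, ...]
    readouts: tuple[float, ...]
    background: float = 0.0

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        reads = tuple(float(r) for r in self.readouts)
        if len(conc) != len(reads):
            raise ValueError("concentrations and readouts length mismatch")
        if any(c <= 0 for c in conc):
            raise ValueError("concentrations must be strictly positive")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "readouts", reads)

    def background_subtracted(self) -> np.ndarray:
        return np.asarray(self.readouts) - self.background


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters; ``log10_ec50`` is in log10 molar units."""

    bottom: float
    top: float
    log10_ec50: float
    hill_slope: float
    residual_sum_squares: float
    converged: bool

    @property
    def ec50(self) -> float:
        return 10.0**self.log10_ec50


def four_pl(
    log10_conc: np.ndarray,
    bottom: float,
    top: float,
    log10_ec50: float,
    hill: float,
) -> np.ndarray:
    """Four-parameter logistic on the log10 concentration axis."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log10_ec50 - log10_conc)))


def fit_dose_response(
    series: TitrationSeries,
    *,
    min_dynamic_range: float = 0.0,
) -> DoseResponseFit:
    """Least-squares 4PL fit of a background-subtracted titration.

    Initialization: bottom = min(y), top = max(y), log10 EC50 at the midpoint
    of the log-concentration range, hill slope 1. Bottom/top are bounded to
    the data range +/- 20%, the EC50 to the tested concentration range
    +/- 2 decades, the hill slope to [0.05, 20]. Deterministic given inputs.

    Raises
    ------
    DegenerateFitError
        Fewer than 4 distinct concentrations, or dynamic range at or below
        ``min_dynamic_range`` (flat readouts carry no EC50 information).
    """
    logc = np.log10(np.asarray(series.concentrations))
    y = series.background_subtracted()
    if len(set(series.concentrations)) < 4:
        raise DegenerateFitError("need >= 4 distinct concentrations to fit a 4PL")
    span = float(y.max() - y.min())
    if span <= min_dynamic_range:
        raise DegenerateFitError(
            f"dynamic range {span:g} at or below floor {min_dynamic_range:g}"
        )
    pad = 0.2 * span
    lo, hi = float(y.min()) - pad, float(y.max()) + pad
    p0 = [float(y.min()), float(y.max()), float((logc.min() + logc.max()) / 2.0), 1.0]
    bounds = (
        [lo, lo, float(logc.min()) - 2.0, 0.05],
        [hi, hi, float(logc.max()) + 2.0, 20.0],
    )
    popt, _ = optimize.curve_fit(
        four_pl, logc, y, p0=p0, bounds=bounds, maxfev=20000
    )
    resid = y - four_pl(logc, *popt)
    rss = float(np.dot(resid, resid))
    at_bound = any(
        math.isclose(p, b, rel_tol=1e-6, abs_tol=1e-9)
        for p, (blo, bhi) in zip(popt, zip(*bounds))
        for b in (blo, bhi)
    )
    bottom, top, log10_ec50, hill = (float(v) for v in popt)
    if top < bottom:
        bottom, top = top, bottom
    return DoseResponseFit(
        bottom=bottom,
        top=top,
        log10_ec50=log10_ec50,
        hill_slope=hill,
        residual_sum_squares=rss,
        converged=not at_bound,
    )


def compare_sensitivity(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> float:
    """EC50 fold change ``10**(log10_ec50_a - log10_ec50_b)``.

    A value > 1 means ligand ``b`` is the more sensitive (lower-EC50) ligand.
    """
    if not (fit_a.converged and fit_b.converged):
        raise DegenerateFitError("cannot compare sensitivity of degenerate fits")
    return 10.0 ** (fit_a.log10_ec50 - fit_b.log10_ec50)


@dataclass(frozen=True)
class KillingInput:
    """Flow-based killing event counts with a CFSE-labelled reference population."""

    exp_target_events: int
    exp_ref_events: int
    con_target_events: int
    con_ref_events: int

    def __post_init__(self) -> None:
        for name in (
            "exp_target_events",
            "exp_ref_events",
            "con_target_events",
            "con_ref_events",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.exp_ref_events == 0 or self.con_ref_events == 0:
            raise ValueError("reference (CFSE) event counts must be positive")
        if self.con_target_events == 0:
            raise ValueError("control target events must be positive")


def flow_killing_percent(inp: KillingInput) -> float:
    """Percentage killing from reference-normalized flow event counts.

    ``% = 100 - ((exp_target/exp_ref) / (con_target/con_ref)) * 100``.
    Negative values (target outgrowth over the control) are reported with a
    warning, never clipped: losing the sign hides assay failure.
    """
    exp_ratio = inp.exp_target_events / inp.exp_ref_events
    con_ratio = inp.con_target_events / inp.con_ref_events
    percent = 100.0 - (exp_ratio / con_ratio) * 100.0
    if percent < 0:
        warnings.warn(
            f"negative killing ({percent:.1f}%): target outgrowth over control",
            stacklevel=2,
        )
    return percent


@dataclass(frozen=True)
class ChromiumInput:
    """Chromium-51 release counts: experimental, spontaneous and maximum wells."""

    experimental_release: float
    spontaneous_release: float
    maximum_release: float

    def __post_init__(self) -> None:
        for name in ("experimental_release", "spontaneous_release", "maximum_release"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.maximum_release <= self.spontaneous_release:
            raise ValueError("maximum release must exceed spontaneous release")


def chromium_specific_lysis(inp: ChromiumInput) -> float:
    """Percent specific lysis: ``100 * (E - S) / (M - S)``, capped at 100.

    Spontaneous release comes from targets incubated alone, maximum release
    from detergent-lysed targets. Values below zero are reported with a
    warning (experimental release below spontaneous).
    """
    percent = (
        100.0
        * (inp.experimental_release - inp.spontaneous_release)
        / (inp.maximum_release - inp.spontaneous_release)
    )
    if percent < 0:
        warnings.warn(
            f"specific lysis {percent:.1f}% below zero "
            "(experimental release below spontaneous)",
            stacklevel=2,
        )
    return min(percent, 100.0)


def effectors_for_dose(
    tetramer_fraction: float,
    n_targets: int,
    tet_cells_per_targets: float = 2.0 / 3.0,
) -> int:
    """Total effector cells needed for a fixed tetramer+ cell : target ratio.

    When lines of different purity are compared on a per-antigen-specific-cell
    basis (e.g. two tetramer+ cells per three tumour cells), the total cell
    dose is ``ceil(ratio * n_targets / tetramer_fraction)``; a line with half
    the tetramer+ fraction needs twice the total cells.
    """
    if not 0.0 < tetramer_fraction <= 1.0:
        raise ValueError("tetramer_fraction must be in (0, 1]")
    if n_targets < 1:
        raise ValueError("n_targets must be positive")
    raw = (tet_cells_per_targets * n_targets) / tetramer_fraction
    # 1e-9 slack: decimal fractions like 0.008 are not binary-exact and must
    # not push an integral dose up by one cell
    return math.ceil(raw - 1e-9)


def stabilization_index(mfi_peptide: float, mfi_no_peptide: float) -> float:
    """Surface-HLA stabilization: MFI with peptide over MFI without.

    A ratio > 1 indicates the exogenous peptide stabilized surface HLA on the
    TAP-deficient T2 line (i.e. the peptide binds the restriction element).
    """
    if mfi_no_peptide <= 0:
        raise ValueError("mfi_no_peptide must be positive")
    return mfi_peptide / mfi_no_peptide
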