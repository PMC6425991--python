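"""Positional-scanning combinatorial peptide library (PS-CPL) landscapes.

A PS-CPL screen probes a T-cell clone with sublibraries in which one peptide
position is fixed to a defined residue and all other positions are randomised.
The per-sublibrary readout (e.g. MIP-1beta in ng/mL) yields a
``positions x residues`` response landscape. This module represents that
landscape (:class:`CplMatrix`), reads/writes it as TSV, subtracts the
T-cells-alone background, and converts it into an additive log-probability
scoring model (:class:`ScoringModel`) under the PS-CPL position-independence
assumption.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd

__all__ = [
    "STANDARD_AA",
    "CplMatrix",
    "ScoringModel",
    "read_cpl",
    "write_cpl",
    "preprocess",
    "build_scoring_model",
    "score_peptide",
]

#: The 20 standard amino acids, alphabetical one-letter codes.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CplMatrix:
    """A PS-CPL response landscape: one readout per (position, residue) sublibrary.

    Parameters
    ----------
    length
        Number of peptide positions (10 for a decamer screen).
    alphabet
        Ordered one-letter residue codes of the sublibrary panel.
    response
        ``length x len(alphabet)`` array of readouts, shared units.
    units
        Free-text unit label for the readouts.
    background
        Readout of T-cells incubated alone (same units).
    index_peptide
        The natural epitope the screen was anchored on, if any
        (e.g. the Melan-A decamer EAAGIGILTV).
    """

    length: int
    alphabet: tuple[str, ...]
    response: np.ndarray
    units: str = "ng/mL"
    background: float = 0.0
    index_peptide: str | None = None

    def __post_init__(self) -> None:
        alphabet = tuple(self.alphabet)
        object.__setattr__(self, "alphabet", alphabet)
        if len(set(alphabet)) != len(alphabet):
            raise ValueError("duplicate residue codes in alphabet")
        for code in alphabet:
            if not (isinstance(code, str) and len(code) == 1 and code.isalpha()):
                raise ValueError(f"invalid residue code {code!r}")
        resp = np.asarray(self.response, dtype=float)
        if resp.shape != (self.length, len(alphabet)):
            raise ValueError(
                f"response shape {resp.shape} != ({self.length}, {len(alphabet)})"
            )
        if not np.all(np.isfinite(resp)):
            raise ValueError("non-finite response entries")
        object.__setattr__(self, "response", resp)
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.index_peptide is not None:
            if len(self.index_peptide) != self.length:
                raise ValueError("index_peptide length mismatch")
            bad = set(self.index_peptide) - set(STANDARD_AA)
            if bad:
                raise ValueError(f"index_peptide has non-standard residues {bad}")

    def residue_index(self, code: str) -> int:
        try:
            return self.alphabet.index(code)
        except ValueError:
            raise KeyError(f"residue {code!r} not in alphabet") from None


def _parse_table(source: str | Path | TextIO) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError("empty CPL table")
    header = lines[0].split("\t")
    ncol = len(header)
    rows = [ln.split("\t") for ln in lines[1:]]
    for i, row in enumerate(rows):
        if len(row) != ncol:
            raise ValueError(f"ragged row {i + 1}: {len(row)} fields, expected {ncol}")
    return pd.DataFrame(rows, columns=pd.Index(header))


def read_cpl(
    source: str | Path | TextIO,
    *,
    units: str = "ng/mL",
    background: float = 0.0,
    index_peptide: str | None = None,
) -> CplMatrix:
    """Read a CPL response matrix from TSV.

    The expected layout is a header row of one-letter residue codes (first
    column names the position), then one numeric row per peptide position
    in order.
    """
    df = _parse_table(source)
    codes = list(df.columns[1:])
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate alphabet code(s) in header: {dupes}")
    for c in codes:
        if not (len(c) == 1 and c.isalpha()):
            raise ValueError(f"non-amino-acid column code {c!r}")
    body = df.iloc[:, 1:]
    try:
        values = body.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in CPL table: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError("missing cells in CPL table")
    return CplMatrix(
        length=values.shape[0],
        alphabet=tuple(codes),
        response=values,
        units=units,
        background=background,
        index_peptide=index_peptide,
    )


def _fmt(v: float) -> str:
    return np.format_float_positional(v, trim="-")


def write_cpl(matrix: CplMatrix, target: str | Path | TextIO | None = None) -> str:
    """Write a CplMatrix as TSV; returns the text.

    Values are emitted with shortest repr-faithful decimal formatting so a
    canonically formatted decimal TSV round-trips bit-identically through
    :func:`read_cpl`.
    """
    out = io.StringIO()
    out.write("pos\t" + "\t".join(matrix.alphabet) + "\n")
    for i in range(matrix.length):
        cells = "\t".join(_fmt(v) for v in matrix.response[i])
        out.write(f"{i + 1}\t{cells}\n")
    text = out.getvalue()
    if target is not None:
        if isinstance(target, (str, Path)):
            Path(target).write_text(text)
        else:
            target.write(text)
    return text


def preprocess(raw: CplMatrix, background: float | None = None) -> CplMatrix:
    """Background-subtract a raw screen: ``max(response - background, 0)``.

    Readouts below the T-cells-alone background are ELISA noise and are
    clipped to zero rather than rejected. A position whose whole row becomes
    zero carries no signal and is an error.
    """
    bg = raw.background if background is None else float(background)
    if bg < 0:
        raise ValueError("background must be non-negative")
    adjusted = np.clip(raw.response - bg, 0.0, None)
    dead = np.where(~(adjusted > 0).any(axis=1))[0]
    if dead.size:
        pos = ", ".join(str(p + 1) for p in dead)
        raise ValueError(f"position(s) {pos} all-zero after background subtraction")
    return replace(raw, response=adjusted, background=0.0)


@dataclass(frozen=True)
class ScoringModel:
    """Additive per-position log-probability weights derived from a CPL screen.

    ``weights[i, a] = ln((r[i, a] + eps) / sum_b (r[i, b] + eps))`` so each
    position row exponentiates to a probability simplex; peptide scores are
    sums of per-position weights (log-likelihood under position independence).
    """

    length: int
    alphabet: tuple[str, ...]
    weights: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.length, len(self.alphabet)):
            raise ValueError("weights shape mismatch")
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite weights")
        norms = np.exp(w).sum(axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9, rtol=0.0):
            raise ValueError("per-position weights do not normalize to 1")
        object.__setattr__(self, "weights", w)
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def residue_index(self, code: str) -> int:
        try:
            return self.alphabet.index(code)
        except ValueError:
            raise KeyError(f"residue {code!r} not in alphabet") from None


def build_scoring_model(
    matrix: CplMatrix, pseudocount: float | None = None
) -> ScoringModel:
    """Turn a preprocessed CPL matrix into a :class:`ScoringModel`.

    The default pseudocount is ``1e-3 * max(response)``: zero-response
    residues stay finite but strongly penalized.
    """
    if pseudocount is None:
        pseudocount = 1e-3 * float(matrix.response.max())
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    padded = matrix.response + pseudocount
    weights = np.log(padded) - np.log(padded.sum(axis=1, keepdims=True))
    # renormalize exactly in log space to absorb float rounding
    weights = weights - np.log(np.exp(weights).sum(axis=1, keepdims=True))
    return ScoringModel(
        length=matrix.length,
        alphabet=matrix.alphabet,
        weights=weights,
        pseudocount=pseudocount,
    )


def score_peptide(model: ScoringModel, sequence: str) -> float:
    """Additive score of a peptide: sum over positions of ``w[i, seq[i]]``."""
    if len(sequence) != model.length:
        raise ValueError(
            f"sequence length {len(sequence)} != model length {model.length}"
        )
    total = 0.0
    for i, residue in enumerate(sequence):
        total += model.weights[i, model.residue_index(residue)]
    return total


def read_peptides(source: str | Path | TextIO) -> list[str]:
    """Read peptides from a plain list (one per line) or FASTA."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    stripped = text.lstrip()
    if stripped.startswith(">"):
        from Bio import SeqIO

        return [str(rec.seq) for rec in SeqIO.parse(io.StringIO(text), "fasta")]
    return [ln.strip() for ln in text.splitlines() if ln.strip()]
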