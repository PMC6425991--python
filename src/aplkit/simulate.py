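"""Synthetic forward models for every pipeline input, with planted ground truth.

The study's raw cellular data (screen readouts, titrations, killing wells,
sequenced repertoires, and the reference complex geometry) are emulated here
by generators that are pure functions of their parameters and a seed, so
each analysis stage can be tested against known ground truth without any
external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import KillingInput, TitrationSeries, four_pl
from .clonotypes import ClonotypeRecord, Repertoire
from .landscape import STANDARD_AA, CplMatrix
from .structure import StructureModel

__all__ = [
    "RecognitionGroundTruth",
    "FourPLParams",
    "random_ground_truth",
    "simulate_cpl",
    "simulate_titration",
    "simulate_killing_events",
    "simulate_repertoires",
    "make_toy_pmhc_pair",
]


@dataclass(frozen=True)
class RecognitionGroundTruth:
    """A planted per-position recognition landscape for a simulated clone.

    Peptide activation is ``activation_scale * logistic(sum_i energy[i, aa_i])``;
    the optimum sequence concatenates the per-position energy argmaxes.
    """

    length: int
    alphabet: tuple[str, ...]
    energy: np.ndarray
    activation_scale: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        e = np.asarray(self.energy, dtype=float)
        if e.shape != (self.length, len(self.alphabet)):
            raise ValueError("energy shape mismatch")
        if not np.all(np.isfinite(e)):
            raise ValueError("non-finite energies")
        object.__setattr__(self, "energy", e)
        if self.activation_scale <= 0:
            raise ValueError("activation_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def optimum_sequence(self) -> str:
        return "".join(self.alphabet[j] for j in self.energy.argmax(axis=1))


def random_ground_truth(
    seed: int,
    length: int = 10,
    alphabet: str | tuple[str, ...] = STANDARD_AA,
    boost_range: tuple[float, float] = (3.0, 4.0),
    off_sd: float = 0.3,
    activation_scale: float = 1.0,
    noise_sd: float | None = None,
) -> RecognitionGroundTruth:
    """Draw a recognition landscape for a highly specific clone.

    Each position has one strongly preferred residue (energy boost drawn
    uniformly from ``boost_range`` above the N(0, off_sd) background of the
    other residues), matching the sharply peaked per-position preferences a
    high-avidity clone shows in a PS-CPL screen. Rows are centred to zero
    mean so that random decamers land in the responsive mid-range of the
    logistic activation rather than at its saturated tails.
    """
    rng = np.random.default_rng(seed)
    alphabet = tuple(alphabet)
    energy = rng.normal(0.0, off_sd, size=(length, len(alphabet)))
    preferred = rng.integers(0, len(alphabet), size=length)
    energy[np.arange(length), preferred] += rng.uniform(*boost_range, size=length)
    energy -= energy.mean(axis=1, keepdims=True)
    if noise_sd is None:
        noise_sd = 0.05 * activation_scale
    return RecognitionGroundTruth(
        length=length,
        alphabet=alphabet,
        energy=energy,
        activation_scale=activation_scale,
        noise_sd=noise_sd,
        seed=seed,
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cpl(
    gt: RecognitionGroundTruth,
    n_peptides_per_sublibrary: int = 2000,
    seed: int = 0,
    units: str = "ng/mL",
) -> CplMatrix:
    """Forward-simulate a PS-CPL screen of the planted clone.

    For every (position, residue) sublibrary, ``n`` peptides are drawn
    uniformly over the alphabet with that position fixed; the well readout
    is the mean peptide activation plus additive Gaussian noise at the
    sublibrary-mean level (one ELISA readout per well), clipped at zero.
    """
    if n_peptides_per_sublibrary < 1:
        raise ValueError("need at least one peptide per sublibrary")
    rng = np.random.default_rng(seed)
    n_aa = len(gt.alphabet)
    response = np.empty((gt.length, n_aa))
    for i in range(gt.length):
        for a in range(n_aa):
            seqs = rng.integers(0, n_aa, size=(n_peptides_per_sublibrary, gt.length))
            seqs[:, i] = a
            energies = gt.energy[np.arange(gt.length), seqs].sum(axis=1)
            activation = gt.activation_scale * _logistic(energies)
            response[i, a] = activation.mean() + rng.normal(0.0, gt.noise_sd)
    response = np.clip(response, 0.0, None)
    return CplMatrix(
        length=gt.length,
        alphabet=gt.alphabet,
        response=response,
        units=units,
        background=0.0,
        index_peptide=None,
    )


@dataclass(frozen=True)
class FourPLParams:
    bottom: float
    top: float
    log10_ec50: float
    hill: float = 1.0


def simulate_titration(
    params: FourPLParams,
    concentrations: tuple[float, ...],
    cv: float = 0.0,
    seed: int = 0,
    peptide: str = "synthetic",
) -> TitrationSeries:
    """Simulate a titration: 4PL readouts with multiplicative Gaussian noise."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    clean = four_pl(
        np.log10(conc), params.bottom, params.top, params.log10_ec50, params.hill
    )
    noisy = clean * (1.0 + rng.normal(0.0, cv, size=clean.shape))
    return TitrationSeries(
        peptide=peptide,
        concentrations=tuple(conc),
        readouts=tuple(float(v) for v in noisy),
        background=0.0,
    )


def simulate_killing_events(
    true_kill_fraction: float,
    n_targets_seeded: int = 5000,
    n_ref: int = 100_000,
    seed: int = 0,
) -> KillingInput:
    """Simulate a flow killing well against an effector-free control well.

    Surviving experimental targets are Binomial(n, 1 - kill fraction); the
    control condition has kill fraction 0 and both wells receive the same
    fixed CFSE reference spike.
    """
    if not 0.0 <= true_kill_fraction <= 1.0:
        raise ValueError("true_kill_fraction must be in [0, 1]")
    if n_targets_seeded < 1 or n_ref < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    exp_target = int(rng.binomial(n_targets_seeded, 1.0 - true_kill_fraction))
    con_target = int(rng.binomial(n_targets_seeded, 1.0))
    return KillingInput(
        exp_target_events=exp_target,
        exp_ref_events=n_ref,
        con_target_events=con_target,
        con_ref_events=n_ref,
    )


def _random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 21))
    inner = "".join(
        STANDARD_AA[j] for j in rng.integers(0, len(STANDARD_AA), size=length - 2)
    )
    return "C" + inner + "F"  # canonical CDR3 framing


def simulate_repertoires(
    n_shared_alpha: int = 2,
    n_shared_beta: int = 1,
    n_private_a: int = 50,
    n_private_b: int = 50,
    alpha_fraction: float = 0.5,
    count_p: float = 0.3,
    seed: int = 0,
) -> tuple[Repertoire, Repertoire]:
    """Two repertoires with an exactly planted shared-clonotype structure.

    Private clonotypes are split alpha/beta by ``alpha_fraction``; CDR3s are
    rejection-sampled to be globally unique so the planted counts are the
    only sharing. Clone sizes follow a geometric distribution (parameter
    ``count_p``), mimicking skewed clonal expansions.
    """
    if min(n_shared_alpha, n_shared_beta, n_private_a, n_private_b) < 0:
        raise ValueError("clonotype counts must be non-negative")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()

    def fresh_cdr3() -> str:
        while True:
            s = _random_cdr3(rng)
            if s not in seen:
                seen.add(s)
                return s

    def draw_v(chain: str) -> str:
        # TRAV12-2 bias on alpha mirrors the germline skew of this specificity
        if chain == "alpha":
            if rng.random() < 0.6:
                return "TRAV12-2"
            return f"TRAV{int(rng.integers(1, 42))}"
        return f"TRBV{int(rng.integers(1, 31))}"

    def make_records(pairs: list[tuple[str, str]]) -> tuple[ClonotypeRecord, ...]:
        return tuple(
            ClonotypeRecord(
                chain=chain,
                cdr3_aa=cdr3,
                v_gene=draw_v(chain),
                count=int(rng.geometric(count_p)),
            )
            for chain, cdr3 in pairs
        )

    shared = [("alpha", fresh_cdr3()) for _ in range(n_shared_alpha)] + [
        ("beta", fresh_cdr3()) for _ in range(n_shared_beta)
    ]

    def private(n: int) -> list[tuple[str, str]]:
        return [
            ("alpha" if rng.random() < alpha_fraction else "beta", fresh_cdr3())
            for _ in range(n)
        ]

    rep_a = Repertoire(line_id="line_a", records=make_records(shared + private(n_private_a)))
    rep_b = Repertoire(line_id="line_b", records=make_records(shared + private(n_private_b)))
    return rep_a, rep_b


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _toy_complex(n_groove: int = 60, n_peptide: int = 10) -> StructureModel:
    """A synthetic two-chain pMHC-like scaffold (groove chain A, peptide C).

    Pseudo-residues carry N/CA/C/O backbone atoms only; the groove is two
    parallel helical walls flanking a straight peptide, enough geometry for
    superposition, contact and RMSD computations. Synthetic stand-in, not a
    real HLA fold.
    """
    offsets = {
        "N": np.array([-0.8, 0.6, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([0.9, 0.5, 0.2]),
        "O": np.array([1.0, 1.4, 0.6]),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    rows = []
    half = n_groove // 2
    for r in range(n_groove):
        wall = 0 if r < half else 1
        k = r if wall == 0 else r - half
        theta = 0.6 * k
        base = np.array(
            [
                1.5 * k,
                (7.0 if wall == 0 else -7.0) + 1.5 * math.cos(theta),
                1.5 * math.sin(theta),
            ]
        )
        for name, off in offsets.items():
            pos = base + off
            rows.append(("A", r + 1, "ALA", name, elements[name], *pos, "", 1.0))
    for r in range(n_peptide):
        base = np.array([4.0 + 3.5 * r, 0.0, 2.0 + 0.8 * math.sin(0.9 * r)])
        for name, off in offsets.items():
            pos = base + off
            rows.append(("C", r + 1, "ALA", name, elements[name], *pos, "", 1.0))
    atoms = pd.DataFrame(
        rows,
        columns=["chain", "resnum", "resname", "atom", "element",
                 "x", "y", "z", "altloc", "occupancy"],
    )
    return StructureModel(atoms=atoms, entry_id="TOY")


def make_toy_pmhc_pair(
    seed: int = 0,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    perturbation_sd: float = 0.0,
    n_groove: int = 60,
    n_peptide: int = 10,
) -> tuple[StructureModel, StructureModel]:
    """A toy complex and a rigidly moved copy with peptide-only perturbation.

    The second model is the first under a rigid transform (random from the
    seed unless given), with isotropic Gaussian noise of ``perturbation_sd``
    Angstrom added to peptide atoms only — the groove stays rigid, so
    groove-frame superposition recovers the transform exactly and the
    peptide backbone RMSD reflects the planted perturbation alone.
    """
    if perturbation_sd < 0:
        raise ValueError("perturbation_sd must be non-negative")
    rng = np.random.default_rng(seed)
    reference = _toy_complex(n_groove=n_groove, n_peptide=n_peptide)
    if rotation is None:
        axis = rng.normal(size=3)
        rotation = _rotation_matrix(axis, float(rng.uniform(0, 2 * math.pi)))
    if translation is None:
        translation = rng.uniform(-20, 20, size=3)
    atoms = reference.atoms.copy()
    xyz = atoms[["x", "y", "z"]].to_numpy(dtype=float)
    moved = xyz @ np.asarray(rotation).T + np.asarray(translation)
    pep_mask = (atoms["chain"] == "C").to_numpy()
    if perturbation_sd > 0:
        moved[pep_mask] += rng.normal(0.0, perturbation_sd, size=(pep_mask.sum(), 3))
    atoms[["x", "y", "z"]] = moved
    mobile = StructureModel(atoms=atoms, entry_id="TOY-MOVED")
    return reference, mobile
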