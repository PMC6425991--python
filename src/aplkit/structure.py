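"""Peptide-MHC structural mimicry: contacts, superposition RMSD, orientation.

Compares two peptide-HLA binary complexes in the frame of the HLA binding
groove: heavy-atom contact counts between peptide and groove, peptide
backbone RMSD after superposing the complexes on groove C-alpha atoms, and
exposed/buried classification of peptide side chains by Shrake-Rupley
solvent-accessible surface area. Structures are consumed from standard PDB
coordinate files (e.g. a deposited pMHC entry).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "ContactReport",
    "OrientationRecord",
    "MimicryReport",
    "read_structure",
    "write_structure",
    "transform_model",
    "count_contacts",
    "superpose",
    "peptide_backbone_rmsd",
    "shrake_rupley_sasa",
    "classify_orientation",
    "mimicry_report",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Van der Waals radii (A) for heavy elements common in protein structures.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_RADIUS = 1.70

#: Reference maximal side-chain accessible surface areas (A^2), Gly-X-Gly
#: tripeptide values (Miller et al. standard set). Glycine has no side chain.
MAX_SIDECHAIN_ASA = {
    "ALA": 67.0, "ARG": 196.0, "ASN": 113.0, "ASP": 106.0, "CYS": 104.0,
    "GLN": 144.0, "GLU": 138.0, "HIS": 151.0, "ILE": 140.0, "LEU": 137.0,
    "LYS": 167.0, "MET": 160.0, "PHE": 175.0, "PRO": 105.0, "SER": 80.0,
    "THR": 102.0, "TRP": 217.0, "TYR": 187.0, "VAL": 117.0,
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class StructureModel:
    """Atomic coordinates of one model of a (p)MHC complex.

    ``atoms`` columns: chain, resnum, resname, atom, element, x, y, z,
    altloc, occupancy. After alternate-location resolution there is at most
    one atom per (chain, resnum, atom).
    """

    atoms: pd.DataFrame
    entry_id: str = ""
    model_number: int = 1

    def __post_init__(self) -> None:
        required = {"chain", "resnum", "resname", "atom", "element",
                    "x", "y", "z", "altloc", "occupancy"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns {sorted(missing)}")
        coords = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        dupes = self.atoms.duplicated(subset=["chain", "resnum", "atom"])
        if dupes.any():
            raise ValueError("duplicate (chain, resnum, atom) after altloc resolution")

    def coords(self, mask: pd.Series | None = None) -> np.ndarray:
        sub = self.atoms if mask is None else self.atoms[mask]
        return sub[["x", "y", "z"]].to_numpy(dtype=float)

    def chain(self, chain_id: str) -> pd.DataFrame:
        sub = self.atoms[self.atoms["chain"] == chain_id]
        if sub.empty:
            raise ValueError(f"chain {chain_id!r} not present")
        return sub


def read_structure(
    source: str | Path,
    *,
    exclude_waters: bool = True,
    exclude_hydrogens: bool = True,
) -> StructureModel:
    """Read the first model of a PDB file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties go to altloc 'A'); waters and hydrogens are dropped by default.
    """
    st = gemmi.read_structure(str(source))
    if len(st) == 0:
        raise ValueError(f"no coordinate records in {source}")
    model = st[0]
    rows = []
    for chain in model:
        for residue in chain:
            if exclude_waters and residue.name in _WATER_NAMES:
                continue
            for atom in residue:
                element = atom.element.name.upper()
                if exclude_hydrogens and element in ("H", "D"):
                    continue
                rows.append(
                    (
                        chain.name,
                        residue.seqid.num,
                        residue.name,
                        atom.name,
                        element,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.altloc or "",
                        atom.occ,
                    )
                )
    if not rows:
        raise ValueError(f"no usable atoms in {source}")
    atoms = pd.DataFrame(
        rows,
        columns=["chain", "resnum", "resname", "atom", "element",
                 "x", "y", "z", "altloc", "occupancy"],
    )
    # resolve altlocs: highest occupancy wins, ties by altloc letter ('' ~ 'A')
    atoms["_alt_rank"] = atoms["altloc"].replace("", "A")
    atoms = (
        atoms.sort_values(["occupancy", "_alt_rank"], ascending=[False, True])
        .drop_duplicates(subset=["chain", "resnum", "atom"], keep="first")
        .drop(columns="_alt_rank")
        .sort_index()
        .reset_index(drop=True)
    )
    return StructureModel(atoms=atoms, entry_id=st.name or Path(str(source)).stem)


def write_structure(model: StructureModel, target: str | Path) -> None:
    """Write a StructureModel to a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.entry_id or "MODL"
    md = gemmi.Model("1")
    for chain_id, chain_df in model.atoms.groupby("chain", sort=False):
        chain = gemmi.Chain(str(chain_id))
        for (resnum, resname), res_df in chain_df.groupby(
            ["resnum", "resname"], sort=False
        ):
            residue = gemmi.Residue()
            residue.name = str(resname)
            residue.seqid = gemmi.SeqId(int(resnum), " ")
            for row in res_df.itertuples():
                atom = gemmi.Atom()
                atom.name = row.atom
                atom.element = gemmi.Element(row.element)
                atom.pos = gemmi.Position(row.x, row.y, row.z)
                atom.occ = float(row.occupancy)
                atom.altloc = row.altloc or "\0"
                residue.add_atom(atom)
            chain.add_residue(residue)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(target))


def transform_model(
    model: StructureModel, rotation: np.ndarray, translation: np.ndarray
) -> StructureModel:
    """Apply a rigid transform ``x -> R x + t`` to every atom."""
    atoms = model.atoms.copy()
    xyz = atoms[["x", "y", "z"]].to_numpy(dtype=float)
    atoms[["x", "y", "z"]] = xyz @ np.asarray(rotation).T + np.asarray(translation)
    return StructureModel(
        atoms=atoms, entry_id=model.entry_id, model_number=model.model_number
    )


@dataclass(frozen=True)
class ContactReport:
    """Heavy-atom peptide-groove contacts below a distance cutoff."""

    cutoff: float
    pairs: tuple[tuple[tuple[str, int, str], tuple[str, int, str], float], ...]

    @property
    def contact_count(self) -> int:
        return len(self.pairs)


def count_contacts(
    model: StructureModel,
    peptide_chain: str,
    hla_chain: str,
    groove_residue_range: tuple[int, int] = (1, 180),
    cutoff: float = 4.0,
) -> ContactReport:
    """Count heavy-atom pairs between peptide and HLA groove under ``cutoff``.

    The groove defaults to heavy-chain residues 1-180 (the alpha1/alpha2
    platform domains). The inequality is strict (< cutoff), matching the
    convention of reporting crystallographic contacts below a threshold.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pep = model.chain(peptide_chain)
    hla = model.chain(hla_chain)
    lo, hi = groove_residue_range
    groove = hla[(hla["resnum"] >= lo) & (hla["resnum"] <= hi)]
    if groove.empty:
        raise ValueError(
            f"no groove atoms in chain {hla_chain!r} residues {lo}-{hi}"
        )
    pep_xyz = pep[["x", "y", "z"]].to_numpy(dtype=float)
    groove_xyz = groove[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(groove_xyz)
    pairs = []
    for pi, neighbours in enumerate(tree.query_ball_point(pep_xyz, r=cutoff)):
        prow = pep.iloc[pi]
        for gi in sorted(neighbours):
            grow = groove.iloc[gi]
            dist = float(np.linalg.norm(pep_xyz[pi] - groove_xyz[gi]))
            if dist < cutoff:  # query_ball_point includes the boundary
                pairs.append(
                    (
                        (prow["chain"], int(prow["resnum"]), prow["atom"]),
                        (grow["chain"], int(grow["resnum"]), grow["atom"]),
                        dist,
                    )
                )
    return ContactReport(cutoff=cutoff, pairs=tuple(pairs))


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of paired point sets.

    Returns ``(R, t, rmsd)`` with the proper rotation (det +1) and
    translation minimizing RMSD of ``R @ mobile + t`` against ``reference``.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference configuration")
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    moved = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def _matched_coords(
    df_a: pd.DataFrame, df_b: pd.DataFrame, atom_names: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    a = df_a[df_a["atom"].isin(atom_names)]
    b = df_b[df_b["atom"].isin(atom_names)]
    merged = a.merge(
        b, on=["resnum", "atom"], suffixes=("_a", "_b"), how="inner"
    ).sort_values(["resnum", "atom"])
    if len(merged) < len(a) or len(merged) < len(b):
        raise ValueError("unmatched atoms between the two models")
    return (
        merged[["x_a", "y_a", "z_a"]].to_numpy(dtype=float),
        merged[["x_b", "y_b", "z_b"]].to_numpy(dtype=float),
    )


def peptide_backbone_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    peptide_chain: str = "C",
    hla_chain: str = "A",
    groove_residue_range: tuple[int, int] = (1, 180),
    backbone_atoms: tuple[str, ...] = BACKBONE_ATOMS,
) -> float:
    """Peptide backbone RMSD in the groove frame.

    The two complexes are superposed on groove C-alpha atoms; the RMSD is
    then computed over the peptide backbone atoms without further fitting,
    so it measures presentation geometry within the groove, not peptide
    self-similarity.
    """
    lo, hi = groove_residue_range
    hla_a, hla_b = model_a.chain(hla_chain), model_b.chain(hla_chain)
    groove_a = hla_a[(hla_a["resnum"] >= lo) & (hla_a["resnum"] <= hi)]
    groove_b = hla_b[(hla_b["resnum"] >= lo) & (hla_b["resnum"] <= hi)]
    ca_a, ca_b = _matched_coords(groove_a, groove_b, ("CA",))
    rotation, translation, _ = superpose(ca_b, ca_a)
    pep_a = model_a.chain(peptide_chain)
    pep_b = model_b.chain(peptide_chain)
    if set(pep_a["resnum"]) != set(pep_b["resnum"]):
        raise ValueError("peptides have unequal lengths or residue numbering")
    bb_a, bb_b = _matched_coords(pep_a, pep_b, tuple(backbone_atoms))
    expected = len(set(pep_a["resnum"])) * len(backbone_atoms)
    if len(bb_a) != expected:
        raise ValueError("missing peptide backbone atoms")
    moved = bb_b @ rotation.T + translation
    return float(np.sqrt(np.mean(np.sum((moved - bb_a) ** 2, axis=1))))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: list[str] | np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere sampling.

    Each atom's solvent sphere (vdW radius + probe) is sampled at
    ``n_points`` quasi-uniform points; the accessible fraction is the share
    of points outside every neighbouring atom's solvent sphere. An isolated
    atom therefore returns exactly ``4 * pi * (r + probe)^2``.
    """
    xyz = np.asarray(coords, dtype=float)
    radii = np.array(
        [VDW_RADII.get(str(e).upper(), DEFAULT_RADIUS) for e in elements]
    ) + probe_radius
    sphere = _sphere_points(n_points)
    tree = cKDTree(xyz)
    max_r = radii.max()
    areas = np.empty(len(xyz))
    for i in range(len(xyz)):
        pts = xyz[i] + radii[i] * sphere
        neighbours = [
            j for j in tree.query_ball_point(xyz[i], r=radii[i] + max_r) if j != i
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 >= radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


@dataclass(frozen=True)
class OrientationRecord:
    resnum: int
    resname: str
    sidechain_sasa: float | None
    relative_sasa: float | None
    classification: str  # "exposed" | "buried" | "not-classified"


def classify_orientation(
    model: StructureModel,
    peptide_chain: str,
    groove_chains: tuple[str, ...] = ("A",),
    probe_radius: float = 1.4,
    n_points: int = 960,
    rel_threshold: float = 0.25,
) -> list[OrientationRecord]:
    """Classify peptide side chains as solvent-exposed or groove-buried.

    Side-chain SASA is computed in the context of the full complex
    (peptide plus groove chains); a residue is exposed iff its side-chain
    SASA relative to the free-tripeptide reference is at least
    ``rel_threshold``. Glycine (no side chain) and residues with missing
    side-chain atoms are reported as not-classified rather than failing.
    """
    chains = (peptide_chain, *groove_chains)
    context = model.atoms[model.atoms["chain"].isin(chains)].reset_index(drop=True)
    pep = context[context["chain"] == peptide_chain]
    if pep.empty:
        raise ValueError(f"peptide chain {peptide_chain!r} not present")
    areas = shrake_rupley_sasa(
        context[["x", "y", "z"]].to_numpy(dtype=float),
        context["element"].tolist(),
        probe_radius=probe_radius,
        n_points=n_points,
    )
    records = []
    for resnum, res_df in pep.groupby("resnum", sort=True):
        resname = str(res_df["resname"].iloc[0])
        side = res_df[~res_df["atom"].isin(BACKBONE_ATOMS + ("OXT",))]
        if resname == "GLY" or resname not in MAX_SIDECHAIN_ASA or side.empty:
            records.append(
                OrientationRecord(int(resnum), resname, None, None, "not-classified")
            )
            continue
        sc_sasa = float(areas[side.index].sum())
        rel = sc_sasa / MAX_SIDECHAIN_ASA[resname]
        cls = "exposed" if rel >= rel_threshold else "buried"
        records.append(OrientationRecord(int(resnum), resname, sc_sasa, rel, cls))
    return records


@dataclass(frozen=True)
class MimicryReport:
    """Groove-frame comparison of two pMHC complexes."""

    groove_superposition_rmsd: float
    peptide_backbone_rmsd: float
    contacts_a: ContactReport
    contacts_b: ContactReport
    orientation_a: tuple[OrientationRecord, ...]
    orientation_b: tuple[OrientationRecord, ...]


def mimicry_report(
    model_a: StructureModel,
    model_b: StructureModel,
    peptide_chain: str = "C",
    hla_chain: str = "A",
    groove_residue_range: tuple[int, int] = (1, 180),
    cutoff: float = 4.0,
    n_points: int = 960,
    rel_threshold: float = 0.25,
) -> MimicryReport:
    """Full mimicry comparison: contacts, groove superposition, orientation."""
    lo, hi = groove_residue_range
    hla_a, hla_b = model_a.chain(hla_chain), model_b.chain(hla_chain)
    groove_a = hla_a[(hla_a["resnum"] >= lo) & (hla_a["resnum"] <= hi)]
    groove_b = hla_b[(hla_b["resnum"] >= lo) & (hla_b["resnum"] <= hi)]
    ca_a, ca_b = _matched_coords(groove_a, groove_b, ("CA",))
    _, _, groove_rmsd = superpose(ca_b, ca_a)
    bb_rmsd = peptide_backbone_rmsd(
        model_a, model_b, peptide_chain, hla_chain, groove_residue_range
    )
    return MimicryReport(
        groove_superposition_rmsd=groove_rmsd,
        peptide_backbone_rmsd=bb_rmsd,
        contacts_a=count_contacts(
            model_a, peptide_chain, hla_chain, groove_residue_range, cutoff
        ),
        contacts_b=count_contacts(
            model_b, peptide_chain, hla_chain, groove_residue_range, cutoff
        ),
        orientation_a=tuple(
            classify_orientation(
                model_a, peptide_chain, (hla_chain,), n_points=n_points,
                rel_threshold=rel_threshold,
            )
        ),
        orientation_b=tuple(
            classify_orientation(
                model_b, peptide_chain, (hla_chain,), n_points=n_points,
                rel_threshold=rel_threshold,
            )
        ),
    )
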