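"""3D molecular geometry: embedding, partial charges and surface areas.

Structures are embedded from SMILES with distance geometry (ETKDG) and
relaxed with the MMFF94 force field (UFF fallback), giving one deterministic
low-energy conformer per seed.  Partial charges come from the Gasteiger
electronegativity-equalisation scheme.  Solvent-accessible surface areas are
computed with a Shrake-Rupley sphere quadrature over van der Waals spheres
inflated by the probe radius (1.4 A water probe by default; probe 0 gives
the bare van der Waals surface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem


@dataclass
class MoleculeGeometry:
    """Embedded molecule with per-atom charges and surface areas.

    ``coords`` are in angstrom, ``masses`` in amu, ``vdw_radii`` in angstrom,
    ``charges`` in elementary charges, ``sasa`` in square angstrom.  ``mol``
    keeps the hydrogen-explicit RDKit molecule for graph queries.
    """

    mol: Chem.Mol
    symbols: list[str]
    masses: np.ndarray
    vdw_radii: np.ndarray
    coords: np.ndarray
    bonds: list[tuple[int, int]]
    charges: np.ndarray | None = None
    sasa: np.ndarray | None = None
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


def embed_molecule(smiles: str, seed: int = 2018) -> MoleculeGeometry:
    """Parse a SMILES, add hydrogens and build one minimised 3D conformer.

    Deterministic for a fixed seed.  Charges and SASA are populated by
    :func:`compute_charges` and :func:`compute_sasa`.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    # single atoms cannot be embedded by distance geometry; place at origin
    if mol.GetNumAtoms() == 1:
        conf = Chem.Conformer(1)
        conf.SetAtomPosition(0, (0.0, 0.0, 0.0))
        mol.AddConformer(conf)
    else:
        code = AllChem.EmbedMolecule(mol, params)
        if code != 0:
            raise ValueError(f"3D embedding failed for {smiles!r}")
        try:
            if AllChem.MMFFHasAllMoleculeParams(mol):
                AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
            else:
                AllChem.UFFOptimizeMolecule(mol, maxIters=500)
        except Exception:
            pass  # an unconverged minimisation still yields a usable conformer

    pt = Chem.GetPeriodicTable()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    masses = np.array([a.GetMass() for a in mol.GetAtoms()], dtype=float)
    radii = np.array([pt.GetRvdw(a.GetAtomicNum()) for a in mol.GetAtoms()], dtype=float)
    coords = mol.GetConformer().GetPositions().astype(float)
    if not np.all(np.isfinite(coords)):
        raise ValueError(f"non-finite coordinates for {smiles!r}")
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return MoleculeGeometry(
        mol=mol,
        symbols=symbols,
        masses=masses,
        vdw_radii=radii,
        coords=coords,
        bonds=bonds,
        smiles=smiles,
    )


def compute_charges(geom: MoleculeGeometry) -> MoleculeGeometry:
    """Assign Gasteiger partial charges (iterative charge equalisation).

    The charges sum to the net molecular charge and symmetry-equivalent
    atoms receive equal charges because the scheme works on the graph.
    """
    AllChem.ComputeGasteigerCharges(geom.mol, throwOnParamFailure=True)
    q = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in geom.mol.GetAtoms()], dtype=float
    )
    if not np.all(np.isfinite(q)):
        raise ValueError(f"charge assignment failed for {geom.smiles!r}")
    geom.charges = q
    return geom


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere quadrature points (golden-spiral lattice)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_sasa(
    geom: MoleculeGeometry, probe_radius: float = 1.4, n_sphere_points: int = 960
) -> MoleculeGeometry:
    """Per-atom solvent-accessible surface area by Shrake-Rupley quadrature.

    Each atom's accessible sphere (radius r_vdw + probe) is sampled with
    ``n_sphere_points`` test points; the accessible fraction times the sphere
    area gives the atomic SASA.  The total molecular surface area (TMSA) is
    the sum over atoms.
    """
    if n_sphere_points < 12:
        raise ValueError("n_sphere_points must be at least 12")
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    unit = sphere_points(n_sphere_points)
    radii = geom.vdw_radii + probe_radius
    coords = geom.coords
    n = geom.n_atoms
    sasa = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        sasa[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    geom.sasa = sasa
    return geom


def prepare_geometry(
    smiles: str,
    seed: int = 2018,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> MoleculeGeometry:
    """Embed, charge and surface a molecule in one call."""
    geom = embed_molecule(smiles, seed=seed)
    compute_charges(geom)
    compute_sasa(geom, probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    return geom
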