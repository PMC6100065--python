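"""Molecular descriptor engine.

Implements the four descriptor families used by the critical-property and
acentric-factor models: constitutional (composition counts), topological
(connectivity-graph invariants), geometrical (mass/volume/surface measures
from the 3D conformer) and electrostatic (charged-partial-surface-area,
CPSA, descriptors combining Gasteiger charges with atomic solvent-accessible
surface areas).

Descriptor catalogue (names are the column names emitted):

Constitutional — counts over the hydrogen-explicit molecule; "relative"
means divided by the total atom count (hydrogens included; heavy-atom
normalisation is available via ``relative_to_heavy``):

* ``Relative number of F atoms``, ``Number of Cl atoms``
* ``Number of aromatic bonds``, ``Relative number of rings`` (SSSR count)
* ``Relative number of double bonds`` (non-aromatic double bonds)
* ``Relative molecular weight`` (molecular weight / atom count, amu)

Topological:

* ``Randic index (order 1)`` — sum over heavy-atom bonds of
  (d_i d_j)^(-1/2), d = heavy-atom degree.
* ``Kier-Hall index (order 2)`` — sum over length-2 heavy-atom paths of
  (dv_i dv_j dv_k)^(-1/2) with the valence delta dv = Zv - h for second-row
  atoms and dv = (Zv - h)/(Z - Zv - 1) beyond the second row.
* ``Structural information content (order 0)`` — Shannon entropy of the
  element partition over all atoms (H included) divided by log2(atom count);
  defined as 0 for a single atom.

Geometrical:

* ``Moment of inertia A/B/C`` — principal moments about the centre of mass,
  sorted A <= B <= C, in amu*A^2.
* ``Gravitation index (all bonds)`` — sum over bonds of m_i*m_j/r_ij^2.
* ``Molecular surface area`` — TMSA (solvent-accessible, A^2).
* ``Molecular volume`` — grid-estimated van der Waals volume (A^3).

Electrostatic / CPSA — q are partial charges, SA atomic solvent-accessible
surface areas, TMSA their sum.  The 1-suffix denotes a charge-weighted sum,
the 2-suffix a plain surface sum (Stanton-Jurs style); H-bond donors are
hydrogens bonded to N, O or S, acceptors are N, O or F (both configurable).
The HASA/HDSA/HDCA variants are reconstructions: the CPSA family has several
published variants and the exact convention is documented here rather than
assumed to match any one code:

* ``PNSA3`` = sum(q_i*SA_i, q_i < 0); ``PPSA3`` = sum(q_i*SA_i, q_i > 0);
  ``FPSA3`` = PPSA3/TMSA
* ``HASA1`` = sum(q_a*SA_a) over acceptors; ``HASA2`` = sum(SA_a);
  emitted also as ``HASA2/TMSA^0.5``
* ``HDSA1`` = sum(q_h*SA_h) over donor hydrogens, emitted as ``HDSA1/TMSA``;
  ``HDCA2`` = sum(SA_h), emitted also as ``HDCA2/TMSA``
* ``Relative negative charged SA`` (RNCS) = SA of the most negative atom
  divided by its relative charge q_min/sum(q_i<0); ``Relative positive
  charged SA`` (RPCS) symmetrically
* ``Polarity parameter (Qmax-Qmin)``; ``Count of H-donor sites``
* ``Topographic electronic index (all pairs)`` = sum over atom pairs of
  |q_i - q_j|/r_ij^2; ``... (all bonds)`` restricts the sum to bonded pairs
* ``TMSA``
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from qspr.datamodel import ENGINE_COMPUTED, Dataset, DescriptorMatrix
from qspr.geometry import MoleculeGeometry, prepare_geometry

DONOR_NEIGHBOURS = ("N", "O", "S")
ACCEPTOR_ELEMENTS = ("N", "O", "F")


@dataclass
class DescriptorConfig:
    """Engine settings: probe radius (A), quadrature density, embed seed,
    and whether "relative" counts divide by all atoms or heavy atoms only."""

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    seed: int = 2018
    relative_to_heavy: bool = False
    donor_neighbours: tuple[str, ...] = DONOR_NEIGHBOURS
    acceptor_elements: tuple[str, ...] = ACCEPTOR_ELEMENTS


def _atom_count(geom: MoleculeGeometry, cfg: DescriptorConfig) -> int:
    if cfg.relative_to_heavy:
        return sum(1 for s in geom.symbols if s != "H")
    return geom.n_atoms


def constitutional_descriptors(
    geom: MoleculeGeometry, cfg: DescriptorConfig | None = None
) -> dict[str, float]:
    """Composition counts; no geometry or charges needed."""
    cfg = cfg or DescriptorConfig()
    mol = geom.mol
    n = _atom_count(geom, cfg)
    n_f = sum(1 for s in geom.symbols if s == "F")
    n_cl = sum(1 for s in geom.symbols if s == "Cl")
    n_aromatic = sum(1 for b in mol.GetBonds() if b.GetIsAromatic())
    n_double = sum(
        1
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.DOUBLE and not b.GetIsAromatic()
    )
    n_rings = len(Chem.GetSSSR(mol))
    mw = Descriptors.MolWt(mol)
    return {
        "Relative number of F atoms": n_f / n,
        "Number of Cl atoms": float(n_cl),
        "Number of aromatic bonds": float(n_aromatic),
        "Relative number of rings": n_rings / n,
        "Relative number of double bonds": n_double / n,
        "Relative molecular weight": mw / n,
    }


def _heavy_graph(geom: MoleculeGeometry):
    """Heavy-atom indices, their degrees and heavy-heavy bonds."""
    mol = geom.mol
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    heavy_set = set(heavy)
    degree = {
        i: sum(1 for nb in mol.GetAtomWithIdx(i).GetNeighbors() if nb.GetIdx() in heavy_set)
        for i in heavy
    }
    bonds = [
        (i, j)
        for i, j in geom.bonds
        if i in heavy_set and j in heavy_set
    ]
    return heavy, degree, bonds


def _valence_delta(atom: Chem.Atom) -> float:
    """Kier-Hall valence delta: (Zv - h) for second-row atoms, with the
    (Z - Zv - 1) denominator correction for higher rows."""
    z = atom.GetAtomicNum()
    zv = Chem.GetPeriodicTable().GetNOuterElecs(z)
    h = atom.GetTotalNumHs(includeNeighbors=True)
    if z <= 10:
        return float(zv - h)
    return (zv - h) / (z - zv - 1)


def topological_descriptors(
    geom: MoleculeGeometry, cfg: DescriptorConfig | None = None
) -> dict[str, float]:
    """Connectivity indices and zero-order structural information content."""
    mol = geom.mol
    heavy, degree, bonds = _heavy_graph(geom)

    randic = 0.0
    for i, j in bonds:
        if degree[i] > 0 and degree[j] > 0:
            randic += 1.0 / math.sqrt(degree[i] * degree[j])

    # length-2 heavy-atom paths, each counted once, keyed by the middle atom
    heavy_set = set(heavy)
    chi2v = 0.0
    dv = {i: _valence_delta(mol.GetAtomWithIdx(i)) for i in heavy}
    for mid in heavy:
        nbrs = [nb.GetIdx() for nb in mol.GetAtomWithIdx(mid).GetNeighbors() if nb.GetIdx() in heavy_set]
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                prod = dv[i] * dv[mid] * dv[k]
                if prod > 0:
                    chi2v += 1.0 / math.sqrt(prod)

    n = geom.n_atoms
    if n <= 1:
        sic0 = 0.0
    else:
        counts = pd.Series(geom.symbols).value_counts().to_numpy(dtype=float)
        p = counts / n
        ic0 = float(-(p * np.log2(p)).sum())
        sic0 = ic0 / math.log2(n)

    return {
        "Randic index (order 1)": randic,
        "Kier-Hall index (order 2)": chi2v,
        "Structural information content (order 0)": sic0,
    }


def principal_moments(masses: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Principal moments of inertia about the centre of mass, sorted
    I_A <= I_B <= I_C, in amu*A^2 (rigid-rotor convention)."""
    masses = np.asarray(masses, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(masses) < 2:
        raise ValueError("moments of inertia require at least 2 atoms")
    x = coords - np.average(coords, axis=0, weights=masses)
    r2 = np.sum(x**2, axis=1)
    tensor = np.einsum("a,ab,ac->bc", masses, x, x)
    inertia = np.eye(3) * np.sum(masses * r2) - tensor
    return np.sort(np.linalg.eigvalsh(inertia))


def gravitation_index(
    masses: np.ndarray, coords: np.ndarray, bonds: list[tuple[int, int]]
) -> float:
    """Sum over bonds of m_i*m_j/r_ij^2 (amu^2/A^2) — bulk cohesiveness
    due to dispersion interactions."""
    if len(masses) < 2:
        raise ValueError("gravitation index requires at least 2 atoms")
    grav = 0.0
    for i, j in bonds:
        rij2 = float(np.sum((coords[i] - coords[j]) ** 2))
        grav += masses[i] * masses[j] / rij2
    return grav


def geometrical_descriptors(
    geom: MoleculeGeometry, cfg: DescriptorConfig | None = None
) -> dict[str, float]:
    """Principal moments of inertia, gravitation index, surface and volume."""
    if geom.n_atoms < 2:
        raise ValueError("geometrical descriptors require at least 2 atoms")
    if geom.sasa is None:
        raise ValueError("SASA not computed; call compute_sasa first")
    moments = principal_moments(geom.masses, geom.coords)
    grav = gravitation_index(geom.masses, geom.coords, geom.bonds)
    volume = AllChem.ComputeMolVolume(geom.mol)
    return {
        "Moment of inertia A": float(moments[0]),
        "Moment of inertia B": float(moments[1]),
        "Moment of inertia C": float(moments[2]),
        "Gravitation index (all bonds)": grav,
        "Molecular surface area": float(np.sum(geom.sasa)),
        "Molecular volume": float(volume),
    }


def _donor_hydrogens(geom: MoleculeGeometry, cfg: DescriptorConfig) -> list[int]:
    out = []
    for atom in geom.mol.GetAtoms():
        if atom.GetSymbol() != "H":
            continue
        if any(nb.GetSymbol() in cfg.donor_neighbours for nb in atom.GetNeighbors()):
            out.append(atom.GetIdx())
    return out


def electrostatic_descriptors(
    geom: MoleculeGeometry, cfg: DescriptorConfig | None = None
) -> dict[str, float]:
    """CPSA family, polarity parameter and topographic electronic indices."""
    cfg = cfg or DescriptorConfig()
    if geom.charges is None or geom.sasa is None:
        raise ValueError("charges and SASA must be computed first")
    q = geom.charges
    sa = geom.sasa
    tmsa = float(sa.sum())
    if tmsa <= 0:
        raise ValueError("TMSA is zero; surface areas unavailable")

    neg = q < 0
    pos = q > 0
    pnsa3 = float(np.sum(q[neg] * sa[neg])) if neg.any() else 0.0
    ppsa3 = float(np.sum(q[pos] * sa[pos])) if pos.any() else 0.0

    acceptors = [
        a.GetIdx() for a in geom.mol.GetAtoms() if a.GetSymbol() in cfg.acceptor_elements
    ]
    donors_h = _donor_hydrogens(geom, cfg)
    hasa1 = float(sum(q[i] * sa[i] for i in acceptors))
    hasa2 = float(sum(sa[i] for i in acceptors))
    hdsa1 = float(sum(q[i] * sa[i] for i in donors_h))
    hdca2 = float(sum(sa[i] for i in donors_h))

    if neg.any():
        i_min = int(np.argmin(q))
        q_neg_total = float(q[neg].sum())
        rncs = float(sa[i_min] / (q[i_min] / q_neg_total))
    else:
        rncs = 0.0
    if pos.any():
        i_max = int(np.argmax(q))
        q_pos_total = float(q[pos].sum())
        rpcs = float(sa[i_max] / (q[i_max] / q_pos_total))
    else:
        rpcs = 0.0

    coords = geom.coords
    diff = q[:, None] - q[None, :]
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(len(q), k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_pairs = float(np.sum(np.abs(diff[iu]) / d2[iu]))
    t_bonds = 0.0
    for i, j in geom.bonds:
        t_bonds += abs(q[i] - q[j]) / d2[i, j]

    return {
        "TMSA": tmsa,
        "PNSA3": pnsa3,
        "PPSA3": ppsa3,
        "FPSA3": ppsa3 / tmsa,
        "HASA1": hasa1,
        "HASA2/TMSA^0.5": hasa2 / math.sqrt(tmsa),
        "HDSA1/TMSA": hdsa1 / tmsa,
        "HDCA2": hdca2,
        "HDCA2/TMSA": hdca2 / tmsa,
        "Relative negative charged SA": rncs,
        "Relative positive charged SA": rpcs,
        "Polarity parameter (Qmax-Qmin)": float(q.max() - q.min()),
        "Count of H-donor sites": float(len(donors_h)),
        "Topographic electronic index (all pairs)": t_pairs,
        "Topographic electronic index (all bonds)": float(t_bonds),
    }


def compute_descriptors(smiles: str, cfg: DescriptorConfig | None = None) -> dict[str, float]:
    """All catalogue descriptors for one molecule."""
    cfg = cfg or DescriptorConfig()
    geom = prepare_geometry(
        smiles,
        seed=cfg.seed,
        probe_radius=cfg.probe_radius,
        n_sphere_points=cfg.n_sphere_points,
    )
    out: dict[str, float] = {}
    out.update(constitutional_descriptors(geom, cfg))
    out.update(topological_descriptors(geom, cfg))
    out.update(geometrical_descriptors(geom, cfg))
    out.update(electrostatic_descriptors(geom, cfg))
    return out


def catalogue_names() -> list[str]:
    """Names of every descriptor the engine emits (methane as probe)."""
    return list(compute_descriptors("C").keys())


def build_descriptor_matrix(
    ds: Dataset, cfg: DescriptorConfig | None = None
) -> DescriptorMatrix:
    """Descriptor matrix aligned to dataset order.

    Per-molecule failures never abort the build: a molecule whose embedding
    or charge assignment fails gets missing cells for the affected
    descriptors and the build continues.
    """
    cfg = cfg or DescriptorConfig()
    names = catalogue_names()
    rows = []
    for rec in ds.records:
        try:
            vals = compute_descriptors(rec.smiles, cfg)
        except Exception:
            # fall back per family so partial information survives
            vals = {}
            try:
                from qspr.geometry import embed_molecule, compute_charges, compute_sasa

                geom = embed_molecule(rec.smiles, seed=cfg.seed)
                vals.update(constitutional_descriptors(geom, cfg))
                vals.update(topological_descriptors(geom, cfg))
                try:
                    compute_charges(geom)
                    compute_sasa(
                        geom,
                        probe_radius=cfg.probe_radius,
                        n_sphere_points=cfg.n_sphere_points,
                    )
                    vals.update(geometrical_descriptors(geom, cfg))
                    vals.update(electrostatic_descriptors(geom, cfg))
                except Exception:
                    pass
            except Exception:
                pass
        rows.append([vals.get(n, np.nan) for n in names])
    frame = pd.DataFrame(rows, index=ds.ids, columns=names, dtype=float)
    return DescriptorMatrix(frame=frame, provenance={n: ENGINE_COMPUTED for n in names})


def prefilter_descriptors(
    m: DescriptorMatrix, tolerance: float = 1e-12
) -> tuple[DescriptorMatrix, dict[str, str]]:
    """Drop descriptors not available for every structure or constant.

    Returns the reduced matrix and a {name: reason} map for the dropped
    columns ('missing' or 'constant').
    """
    if m.frame.empty:
        raise ValueError("empty descriptor matrix")
    dropped: dict[str, str] = {}
    keep: list[str] = []
    for name in m.descriptor_names:
        col = m.frame[name]
        if col.isna().any():
            dropped[name] = "missing"
        elif float(col.max() - col.min()) < tolerance:
            dropped[name] = "constant"
        else:
            keep.append(name)
    if not keep:
        raise ValueError("all descriptors dropped by pre-filter")
    return m.select(keep), dropped
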