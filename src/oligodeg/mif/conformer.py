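"""Seeded 3D embedding with partial charges and H-bond typing.

A single low-energy conformer is generated per molecule by distance
geometry (ETKDG) followed by MMFF94 relaxation, with Gasteiger-Marsili
partial charges (an iterative electronegativity-equalisation scheme).
The embedding is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem


class EmbeddingError(RuntimeError):
    """Raised when no 3D conformer could be generated."""


# van der Waals radii (Angstrom) and Lennard-Jones well depths
# (kcal/mol) per element; generic force-field magnitudes.
ATOM_LJ: dict[str, tuple[float, float]] = {
    "H": (1.10, 0.030),
    "C": (1.70, 0.086),
    "N": (1.55, 0.170),
    "O": (1.52, 0.210),
    "F": (1.47, 0.061),
    "P": (1.80, 0.200),
    "S": (1.80, 0.250),
    "Cl": (1.75, 0.300),
    "Br": (1.85, 0.320),
    "I": (1.98, 0.400),
}
DEFAULT_LJ = (1.70, 0.150)


@dataclass
class Conformer3D:
    """A single 3D conformer with per-atom field parameters."""

    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    charges: np.ndarray  # partial charges, e
    radii: np.ndarray  # vdW radii, Angstrom
    epsilons: np.ndarray  # LJ well depths, kcal/mol
    masses: np.ndarray  # atomic masses, amu
    hb_donor: np.ndarray  # heavy atom carrying an acidic H (bool)
    hb_acceptor: np.ndarray  # lone-pair N/O acceptor (bool)
    seed: int = 0
    smiles: str = ""
    mol: Chem.Mol | None = field(default=None, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()

    def translated(self, shift: np.ndarray) -> "Conformer3D":
        return self._with_coords(self.coords + np.asarray(shift, float))

    def rotated(self, rotation: np.ndarray) -> "Conformer3D":
        """Rigidly rotate about the centre of mass."""
        com = self.center_of_mass()
        return self._with_coords((self.coords - com) @ np.asarray(rotation, float).T + com)

    def to_principal_frame(self) -> "Conformer3D":
        """Canonical orientation: centre of mass at the origin, axes along
        the mass-weighted principal axes (largest spread first).

        Axis signs are fixed by the sign of the mass-weighted third
        moment along each of the first two axes (falling back to the
        largest-magnitude coordinate when the distribution is
        symmetric); the third axis completes a right-handed frame, so
        chirality is preserved.  Grid and surface descriptors computed
        in this frame are invariant under rigid motion of the input
        coordinates, up to eigenvector degeneracy in highly symmetric
        molecules.
        """
        com = self.center_of_mass()
        x = self.coords - com
        w = self.masses
        cov = (x * w[:, None]).T @ x / w.sum()
        vals, vecs = np.linalg.eigh(cov)
        vecs = vecs[:, np.argsort(vals)[::-1]]
        for k in range(2):
            proj = x @ vecs[:, k]
            skew = float((w * proj**3).sum())
            if abs(skew) < 1e-9:
                skew = proj[int(np.argmax(np.abs(proj)))]
            if skew < 0:
                vecs[:, k] *= -1.0
        vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])
        return self._with_coords(x @ vecs)

    def _with_coords(self, coords: np.ndarray) -> "Conformer3D":
        return Conformer3D(
            elements=self.elements,
            coords=coords,
            charges=self.charges,
            radii=self.radii,
            epsilons=self.epsilons,
            masses=self.masses,
            hb_donor=self.hb_donor,
            hb_acceptor=self.hb_acceptor,
            seed=self.seed,
            smiles=self.smiles,
            mol=self.mol,
        )


def _assign_hbond_roles(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    n = mol.GetNumAtoms()
    donor = np.zeros(n, bool)
    acceptor = np.zeros(n, bool)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in ("N", "O"):
            acceptor[atom.GetIdx()] = True
            if atom.GetTotalNumHs(includeNeighbors=True) > 0:
                donor[atom.GetIdx()] = True
    return donor, acceptor


def embed_3d(
    smiles: str,
    seed: int = 0,
    *,
    optimize: bool = True,
    max_attempts: int = 5,
) -> Conformer3D:
    """Embed a molecule in 3D, deterministically for a fixed seed.

    Raises :class:`EmbeddingError` after ``max_attempts`` distance-geometry
    failures (each retry perturbs the seed, so failures are reported with
    the seeds tried).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)

    params = AllChem.ETKDGv3()
    params.useRandomCoords = False
    conf_id = -1
    tried = []
    for attempt in range(max_attempts):
        attempt_seed = int(seed) + 7919 * attempt + 1
        params.randomSeed = attempt_seed
        tried.append(attempt_seed)
        conf_id = AllChem.EmbedMolecule(mol, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise EmbeddingError(f"embedding failed for {smiles!r} (seeds tried: {tried})")

    if optimize:
        try:
            if AllChem.MMFFHasAllMoleculeParams(mol):
                AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
            else:
                AllChem.UFFOptimizeMolecule(mol, maxIters=2000)
        except Exception:
            pass  # keep the raw DG geometry rather than fail

    AllChem.ComputeGasteigerCharges(mol)
    charges = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()], float
    )
    charges = np.nan_to_num(charges, nan=0.0, posinf=0.0, neginf=0.0)

    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    lj = np.array([ATOM_LJ.get(el, DEFAULT_LJ) for el in elements], float)
    masses = np.array([a.GetMass() for a in mol.GetAtoms()], float)
    coords = mol.GetConformer().GetPositions().astype(float)
    donor, acceptor = _assign_hbond_roles(mol)

    return Conformer3D(
        elements=elements,
        coords=coords,
        charges=charges,
        radii=lj[:, 0],
        epsilons=lj[:, 1],
        masses=masses,
        hb_donor=donor,
        hb_acceptor=acceptor,
        seed=int(seed),
        smiles=smiles,
        mol=mol,
    )
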