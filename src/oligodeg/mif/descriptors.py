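"""Condensation of probe fields into the 18 selected molecular descriptors.

The selected set comprises 12 water-probe (OH2) quantities -- four
integy moments IW1-IW4 (distance between the centre of mass and the
energy-weighted barycentre of the hydrophilic regions at increasingly
attractive energy levels) and eight capacity factors CW1-CW8
(hydrophilic volume over total molecular surface) -- plus logP
(Crippen atomic-additive octanol/water partition), the polar and
hydrophobic surface areas PSA and HSA, the most acidic pKa estimate
MpKaA, and the polar/apolar attraction descriptors EMDIF (energy
difference between the strongest polar and apolar interactions, signed
polar minus apolar) and EMDIS (distance between the atoms hosting
them).

Hydrophilic volumes are counted at the eight energy cutoffs
-0.2, -0.5, -1, -2, -3, -4, -5, -6 kcal/mol, the conventional ladder
for water-probe volume descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen
from sklearn.base import BaseEstimator, TransformerMixin

from oligodeg.mif.conformer import Conformer3D, embed_3d
from oligodeg.mif.fields import GridSpec, ProbeField, compute_all_fields
from oligodeg.mif.surface import surface_descriptors

ENERGY_CUTOFFS = (-0.2, -0.5, -1.0, -2.0, -3.0, -4.0, -5.0, -6.0)
EM_THRESHOLD = -0.2  # kcal/mol; weaker minima do not define EMDIF/EMDIS

DESCRIPTOR_NAMES = (
    "IW1", "IW2", "IW3", "IW4",
    "CW1", "CW2", "CW3", "CW4", "CW5", "CW6", "CW7", "CW8",
    "logP", "PSA", "HSA", "MpKaA", "EMDIF", "EMDIS",
)

# rule table for the most acidic pKa; the sentinel 20.0 marks
# "no ionisable proton in the table"
_PKA_RULES = (
    ("[CX3](=O)[OX2H1]", 4.4),  # carboxylic acid
    ("[OX2H][c]", 10.0),  # phenol
    ("[OX2H][CX4]", 15.5),  # aliphatic alcohol
    ("[NX3;H1,H2][CX3](=O)", 16.5),  # amide N-H
)
PKA_SENTINEL = 20.0


def most_acidic_pka(smiles_or_mol: str | Chem.Mol) -> float:
    """Most acidic pKa from a functional-group rule table."""
    mol = (
        Chem.MolFromSmiles(smiles_or_mol)
        if isinstance(smiles_or_mol, str)
        else smiles_or_mol
    )
    if mol is None:
        raise ValueError("unparseable structure")
    values = [
        pka
        for smarts, pka in _PKA_RULES
        if mol.HasSubstructMatch(Chem.MolFromSmarts(smarts))
    ]
    return min(values, default=PKA_SENTINEL)


def grid_volume_descriptors(
    field_oh2: ProbeField, conf: Conformer3D
) -> tuple[np.ndarray, np.ndarray]:
    """Hydrophilic volumes W1..W8 (A^3) and integy moments IW1..IW4 (A).

    Wk is the volume of grid nodes with energy at or below cutoff k;
    IWk is the distance from the centre of mass to the |E|-weighted
    barycentre of those nodes (0 when the level set is empty).
    """
    e = field_oh2.energies
    nodes = field_oh2.grid.node_coords()
    voxel = field_oh2.grid.spacing**3
    com = conf.center_of_mass()

    w = np.zeros(8)
    iw = np.zeros(4)
    for k, cutoff in enumerate(ENERGY_CUTOFFS):
        mask = e <= cutoff
        w[k] = mask.sum() * voxel
        if k < 4 and mask.any():
            weights = -e[mask]
            bary = weights @ nodes[mask] / weights.sum()
            iw[k] = float(np.linalg.norm(com - bary))
    return w, iw


def em_descriptors(
    fields: dict[str, ProbeField], conf: Conformer3D
) -> tuple[float, float]:
    """Attraction energy difference (EMDIF) and distance (EMDIS).

    The polar minimum is the deepest node over the OH2, O and N1 fields,
    the apolar minimum the deepest DRY node.  EMDIF = E_polar - E_apolar
    (signed); EMDIS is the distance between the atom nearest the polar
    minimum node and the atom nearest the apolar one.  Both are 0 when
    either minimum is weaker than -0.2 kcal/mol.
    """
    grids = {(f.grid.spacing,) + f.grid.origin + f.grid.shape for f in fields.values()}
    if len(grids) > 1:
        raise ValueError("all probe fields must share one grid")
    polar_fields = [fields[p] for p in ("OH2", "O", "N1") if p in fields]
    if not polar_fields or "DRY" not in fields:
        raise ValueError("need DRY and at least one polar probe field")

    e_pol, node_pol = min(
        ((f.min_energy(), f.argmin_node()) for f in polar_fields),
        key=lambda t: t[0],
    )
    dry = fields["DRY"]
    e_apol, node_apol = dry.min_energy(), dry.argmin_node()
    if e_pol > EM_THRESHOLD or e_apol > EM_THRESHOLD:
        return 0.0, 0.0

    atom_pol = int(np.argmin(np.linalg.norm(conf.coords - node_pol, axis=1)))
    atom_apol = int(np.argmin(np.linalg.norm(conf.coords - node_apol, axis=1)))
    emdis = float(np.linalg.norm(conf.coords[atom_pol] - conf.coords[atom_apol]))
    return float(e_pol - e_apol), emdis


@dataclass
class DescriptorVector:
    """All computed quantities for one molecule.

    ``selected`` holds the 18 modelling descriptors in canonical order;
    the supporting volumes and total surface are kept alongside.
    """

    smiles: str
    W: np.ndarray  # hydrophilic volumes at the 8 cutoffs, A^3
    IW: np.ndarray  # integy moments at the first 4 cutoffs, A
    S: float  # total molecular surface, A^2
    PSA: float
    HSA: float
    logP: float
    MpKaA: float
    EMDIF: float
    EMDIS: float
    selected: pd.Series = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        cw = self.W / self.S
        values = [*self.IW, *cw, self.logP, self.PSA, self.HSA,
                  self.MpKaA, self.EMDIF, self.EMDIS]
        self.selected = pd.Series(values, index=list(DESCRIPTOR_NAMES), dtype=float)

    @property
    def CW(self) -> np.ndarray:
        return self.W / self.S


def descriptor_vector(
    smiles: str,
    *,
    spacing: float = 0.5,
    margin: float = 5.0,
    seed: int = 0,
    conf: Conformer3D | None = None,
) -> DescriptorVector:
    """Compute the full descriptor vector for one molecule.

    Deterministic for a fixed seed (single seeded conformer; see the
    methods note for the single-conformer choice).
    """
    if conf is None:
        conf = embed_3d(smiles, seed=seed)
    conf = conf.to_principal_frame()  # rigid-motion invariant descriptors
    fields = compute_all_fields(conf, spacing=spacing, margin=margin)
    w, iw = grid_volume_descriptors(fields["OH2"], conf)
    s, psa, hsa = surface_descriptors(conf)
    emdif, emdis = em_descriptors(fields, conf)
    logp = Crippen.MolLogP(Chem.MolFromSmiles(smiles))
    pka = most_acidic_pka(smiles)
    return DescriptorVector(
        smiles=smiles, W=w, IW=iw, S=s, PSA=psa, HSA=hsa,
        logP=logp, MpKaA=pka, EMDIF=emdif, EMDIS=emdis,
    )


def descriptor_matrix(
    smiles_list,
    ids=None,
    *,
    spacing: float = 0.5,
    margin: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Molecules x 18 descriptor matrix (rows named by ``ids``)."""
    rows = [
        descriptor_vector(s, spacing=spacing, margin=margin, seed=seed).selected
        for s in smiles_list
    ]
    index = list(ids) if ids is not None else list(range(len(rows)))
    return pd.DataFrame(rows, index=index)


class MIFDescriptorCalculator(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: SMILES list -> 18-column descriptor matrix.

    Stateless (``fit`` records nothing beyond feature names); transform
    is deterministic for the configured seed.
    """

    def __init__(self, spacing: float = 0.5, margin: float = 5.0, seed: int = 0):
        self.spacing = spacing
        self.margin = margin
        self.seed = seed

    def fit(self, X, y=None):
        self.feature_names_out_ = list(DESCRIPTOR_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        return descriptor_matrix(
            X, spacing=self.spacing, margin=self.margin, seed=self.seed
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(DESCRIPTOR_NAMES, dtype=object)
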