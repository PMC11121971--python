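"""Monomer registry and construction of linear oligoester/oligoamide tetramers.

Model structures are built by formal polycondensation: monomer units
alternate between acyl (diacid) and hydroxy/amino (diol, polyol, diamine)
classes, one water molecule is eliminated per ester or amide bond, and
chain ends keep a free carboxylic acid / hydroxyl (or methyl ester, on
request).  Regiochemistry follows lipase selectivity for primary
hydroxyls: glycerol links through its 1,3 (primary) positions and
erythritol through its two terminal CH2OH groups, leaving secondary
hydroxyls free.  Stereocentres are left unspecified.

SMILES equality is always structural (canonical-form comparison), never
string comparison, because the same oligomer can be written from either
chain end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

__all__ = [
    "Monomer",
    "MONOMERS",
    "OligomerSequence",
    "BuiltStructure",
    "molecular_formula_mass",
    "structures_equal",
    "build_oligomer",
    "enumerate_tetramers",
    "read_smiles_file",
    "write_smiles_file",
]

WATER_AVG = 18.015
WATER_MONO = 18.0106
METHYL_END_AVG = 14.027  # CH2 increment of a methyl ester over a free acid
METHYL_END_MONO = 14.0157

ACYL_CLASSES = frozenset({"diacid"})
HYDROXY_CLASSES = frozenset({"diol", "polyol", "diamine"})


class ChemlibError(ValueError):
    """Raised for invalid monomer sequences or unparseable structures."""


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemlibError(f"unparseable SMILES: {smiles!r}")
    return mol


def molecular_formula_mass(smiles: str) -> tuple[str, float, float]:
    """Elemental formula, average and monoisotopic mass of a SMILES.

    >>> molecular_formula_mass("O")[0]
    'H2O'
    """
    mol = _mol_from_smiles(smiles)
    formula = rdMolDescriptors.CalcMolFormula(mol)
    return formula, Descriptors.MolWt(mol), Descriptors.ExactMolWt(mol)


def structures_equal(s1: str, s2: str, *, use_stereo: bool = False) -> bool:
    """True iff two SMILES denote the same molecule (canonical comparison).

    Stereo-insensitive by default: the tetramer fixtures carry no
    stereo-descriptors, and lipase-built oligomers are compared as flat
    graphs.
    """
    mols = []
    for s in (s1, s2):
        mol = _mol_from_smiles(s)
        if not use_stereo:
            Chem.RemoveStereochemistry(mol)
        mols.append(mol)
    return Chem.MolToSmiles(mols[0]) == Chem.MolToSmiles(mols[1])


@dataclass(frozen=True)
class Monomer:
    """One polycondensation building block.

    ``fragment`` is the in-chain SMILES piece used by the builder: acyl
    units expose two carbonyl carbons, hydroxy/amino units expose their
    two reactive primary O/N atoms at the fragment ends.
    """

    id: str
    smiles: str
    mclass: str  # diacid | diol | polyol | diamine
    fragment: str
    formula: str = field(default="", compare=False)
    avg_mass: float = field(default=0.0, compare=False)
    mono_mass: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        formula, avg, mono = molecular_formula_mass(self.smiles)
        object.__setattr__(self, "formula", formula)
        object.__setattr__(self, "avg_mass", avg)
        object.__setattr__(self, "mono_mass", mono)
        self._check_functionality()

    @property
    def is_acyl(self) -> bool:
        return self.mclass in ACYL_CLASSES

    def _check_functionality(self) -> None:
        mol = _mol_from_smiles(self.smiles)
        n_cooh = len(mol.GetSubstructMatches(Chem.MolFromSmarts("[CX3](=O)[OX2H1]")))
        n_oh = len(mol.GetSubstructMatches(Chem.MolFromSmarts("[OX2H1][CX4]")))
        n_ch2nh2 = len(mol.GetSubstructMatches(Chem.MolFromSmarts("[CH2][NX3H2]")))
        ok = {
            "diacid": n_cooh >= 2,
            "diol": n_oh >= 2,
            "polyol": n_oh > 2,
            "diamine": n_ch2nh2 >= 2,
        }.get(self.mclass)
        if ok is None:
            raise ChemlibError(f"unknown monomer class {self.mclass!r}")
        if not ok:
            raise ChemlibError(
                f"monomer {self.id}: functional groups inconsistent with class {self.mclass!r}"
            )


#: The monomer pool: three diacids (adipic, 2,5-furandicarboxylic and
#: terephthalic acid), three diols/polyols (1,4-butanediol, glycerol,
#: erythritol) and one diamine (2,5-bis(aminomethyl)furan).
MONOMERS: dict[str, Monomer] = {
    m.id: m
    for m in [
        Monomer("AA", "OC(=O)CCCCC(=O)O", "diacid", "C(=O)CCCCC(=O)"),
        Monomer("FDCA", "OC(=O)c1ccc(o1)C(=O)O", "diacid", "C(=O)c1ccc(o1)C(=O)"),
        Monomer("TA", "OC(=O)c1ccc(cc1)C(=O)O", "diacid", "C(=O)c1ccc(cc1)C(=O)"),
        Monomer("BDO", "OCCCCO", "diol", "OCCCCO"),
        Monomer("GLY", "OCC(O)CO", "polyol", "OCC(O)CO"),
        Monomer("ERY", "OCC(O)C(O)CO", "polyol", "OCC(O)C(O)CO"),
        Monomer("DAF", "NCc1ccc(o1)CN", "diamine", "NCc1ccc(o1)CN"),
    ]
}


@dataclass(frozen=True)
class OligomerSequence:
    """Ordered monomer sequence with linkage chemistry."""

    units: tuple[str, ...]
    linkage: str = "ester"  # ester | amide
    end_policy: str = "free_acid_ol"  # free_acid_ol | methyl_ester_end | dimethyl_ester

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        self.validate()

    def validate(self) -> None:
        if len(self.units) < 2:
            raise ChemlibError("sequence must contain at least two units")
        if self.linkage not in ("ester", "amide"):
            raise ChemlibError(f"unknown linkage {self.linkage!r}")
        if self.end_policy not in ("free_acid_ol", "methyl_ester_end", "dimethyl_ester"):
            raise ChemlibError(f"unknown end policy {self.end_policy!r}")
        monomers = [self._monomer(u) for u in self.units]
        for a, b in itertools.pairwise(monomers):
            if a.is_acyl == b.is_acyl:
                raise ChemlibError(
                    f"sequence must strictly alternate acyl and hydroxy/amino units: "
                    f"{a.id} followed by {b.id}"
                )
        non_acyl = [m for m in monomers if not m.is_acyl]
        if self.linkage == "amide":
            if any(m.mclass != "diamine" for m in non_acyl):
                raise ChemlibError("amide linkage requires diamine units in all non-acyl slots")
        else:
            if any(m.mclass == "diamine" for m in non_acyl):
                raise ChemlibError("diamine units require amide linkage")

    @staticmethod
    def _monomer(uid: str) -> Monomer:
        try:
            return MONOMERS[uid]
        except KeyError:
            raise ChemlibError(f"unknown monomer id {uid!r}") from None

    @property
    def monomers(self) -> list[Monomer]:
        return [self._monomer(u) for u in self.units]

    @property
    def label(self) -> str:
        return "-".join(self.units)


@dataclass(frozen=True)
class BuiltStructure:
    """Condensation product of an :class:`OligomerSequence`."""

    smiles: str
    formula: str
    avg_mass: float
    mono_mass: float
    source_sequence: OligomerSequence

    @property
    def n_bonds(self) -> int:
        return len(self.source_sequence.units) - 1


def build_oligomer(seq: OligomerSequence | Sequence[str], **kwargs) -> BuiltStructure:
    """Assemble the linear condensation product of a monomer sequence.

    One water is eliminated per ester/amide bond.  Terminal acyl units
    keep a free carboxylic acid (or are methylated per ``end_policy``);
    terminal diols keep a free primary hydroxyl; glycerol reacts through
    its 1,3-hydroxyls and erythritol through its terminal CH2OH groups.
    """
    if not isinstance(seq, OligomerSequence):
        seq = OligomerSequence(tuple(seq), **kwargs)
    units = seq.monomers
    n = len(units)
    methyl_ends = {
        "free_acid_ol": 0,
        "methyl_ester_end": 1,
        "dimethyl_ester": 2,
    }[seq.end_policy]

    parts: list[str] = []
    methyls_placed = 0
    for i, m in enumerate(units):
        frag = m.fragment
        if m.is_acyl:
            if i == 0:
                cap = "CO" if methyls_placed < methyl_ends else "O"
                methyls_placed += cap == "CO"
                frag = cap + frag
            if i == n - 1:
                cap = "OC" if methyls_placed < methyl_ends else "O"
                methyls_placed += cap == "OC"
                frag = frag + cap
        parts.append(frag)
    if methyls_placed < methyl_ends:
        raise ChemlibError(
            f"end policy {seq.end_policy!r} needs {methyl_ends} terminal acyl end(s), "
            f"sequence {seq.label} has {methyls_placed}"
        )
    smiles = "".join(parts)
    mol = _mol_from_smiles(smiles)
    canonical = Chem.MolToSmiles(mol)
    formula = rdMolDescriptors.CalcMolFormula(mol)
    return BuiltStructure(
        smiles=canonical,
        formula=formula,
        avg_mass=Descriptors.MolWt(mol),
        mono_mass=Descriptors.ExactMolWt(mol),
        source_sequence=seq,
    )


_PATTERNS = frozenset({"ABAB", "A1BA2B", "AB1AB2"})


def enumerate_tetramers(
    pool: Iterable[Monomer | str],
    patterns: Iterable[str] = ("ABAB", "A1BA2B", "AB1AB2"),
) -> list[OligomerSequence]:
    """Enumerate distinct tetramer sequences over a monomer pool.

    Composition patterns: ``ABAB`` repeats one acyl and one hydroxy
    monomer; ``A1BA2B`` combines two different acyl monomers with one
    hydroxy monomer; ``AB1AB2`` one acyl with two different hydroxy
    monomers.  Sequences producing canonically identical structures
    (e.g. a chain and its reverse reading) are deduplicated.
    """
    patterns = set(patterns)
    unknown = patterns - _PATTERNS
    if unknown:
        raise ChemlibError(f"unknown patterns: {sorted(unknown)}")
    members = [m if isinstance(m, Monomer) else MONOMERS[m] for m in pool]
    acyl = [m for m in members if m.is_acyl]
    hydroxy = [m for m in members if not m.is_acyl]
    if not acyl or not hydroxy:
        raise ChemlibError("pool must contain at least one acyl and one hydroxy/amino monomer")

    def linkage_for(h: Monomer) -> str:
        return "amide" if h.mclass == "diamine" else "ester"

    candidates: list[OligomerSequence] = []
    if "ABAB" in patterns:
        for a, b in itertools.product(acyl, hydroxy):
            candidates.append(
                OligomerSequence((a.id, b.id, a.id, b.id), linkage=linkage_for(b))
            )
    if "A1BA2B" in patterns:
        for (a1, a2), b in itertools.product(itertools.permutations(acyl, 2), hydroxy):
            candidates.append(
                OligomerSequence((a1.id, b.id, a2.id, b.id), linkage=linkage_for(b))
            )
    if "AB1AB2" in patterns:
        for a, (b1, b2) in itertools.product(acyl, itertools.permutations(hydroxy, 2)):
            if linkage_for(b1) != linkage_for(b2):
                continue  # mixed ester/amide chains are out of scope
            candidates.append(
                OligomerSequence((a.id, b1.id, a.id, b2.id), linkage=linkage_for(b1))
            )

    seen: set[str] = set()
    unique: list[OligomerSequence] = []
    for seq in candidates:
        key = build_oligomer(seq).smiles
        if key not in seen:
            seen.add(key)
            unique.append(seq)
    return unique


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a ``.smi`` file (``SMILES<TAB>id`` per line) into (smiles, id) pairs."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0]
        name = parts[1] if len(parts) > 1 else ""
        _mol_from_smiles(smiles)
        records.append((smiles, name))
    return records


def write_smiles_file(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    lines = [f"{smiles}\t{name}" for smiles, name in records]
    Path(path).write_text("\n".join(lines) + "\n")
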