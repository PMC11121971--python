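"""Probe-molecule interaction fields on a regular grid.

The interaction energy of a probe at a grid node is a sum over atoms of
a Lennard-Jones 12-6 term, a Coulomb term with distance-dependent
dielectric (eps = 4r) for charged probes, and a 12-10 hydrogen-bond
enhancement between complementary donor/acceptor partners.  The DRY
probe uses the hydrophobic formulation: dispersion only, no
electrostatics and no hydrogen bonding.  Energies are clamped into
[-30, +5] kcal/mol so that steric-clash nodes stay finite.

Probe parameters are GRID-like literature magnitudes and are shipped as
an editable table (:data:`PROBES`).  No numerical equality with any
commercial MIF engine is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from oligodeg.mif.conformer import Conformer3D

COULOMB_CONSTANT = 332.0636  # kcal mol^-1 Angstrom e^-2
ENERGY_CLAMP_HIGH = 5.0  # kcal/mol
ENERGY_CLAMP_LOW = -30.0  # kcal/mol
MAX_SPACING = 1.0  # Angstrom; coarser grids are refused
MIN_DISTANCE = 0.5  # Angstrom floor to keep 1/r terms finite


@dataclass(frozen=True)
class Probe:
    name: str
    epsilon: float  # kcal/mol LJ well depth
    rvdw: float  # Angstrom
    charge: float  # e
    hb_donor: bool
    hb_acceptor: bool
    hb_strength: float  # kcal/mol, depth of the 12-10 term
    hb_r0: float  # Angstrom, optimum H-bond heavy-atom distance


#: Editable probe-parameter table.  DRY is the hydrophobic probe, OH2 the
#: water probe (donor and acceptor), O the carbonyl-oxygen acceptor probe
#: and N1 the neutral amide-nitrogen donor probe.
PROBES: dict[str, Probe] = {
    "DRY": Probe("DRY", 0.20, 1.70, 0.0, False, False, 0.0, 3.0),
    "OH2": Probe("OH2", 0.15, 1.60, 0.0, True, True, 3.5, 2.8),
    "O": Probe("O", 0.20, 1.52, -0.15, False, True, 2.8, 2.8),
    "N1": Probe("N1", 0.16, 1.55, 0.10, True, False, 2.0, 3.0),
}


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned regular grid: origin plus shape*spacing."""

    spacing: float
    margin: float
    origin: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.spacing > MAX_SPACING:
            raise ValueError(
                f"grid spacing {self.spacing} A too coarse (max {MAX_SPACING} A)"
            )

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def node_coords(self) -> np.ndarray:
        """All node coordinates, shape (n_nodes, 3), C-order over (x, y, z)."""
        axes = [
            self.origin[i] + self.spacing * np.arange(self.shape[i])
            for i in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def corner_coords(self) -> np.ndarray:
        lo = np.asarray(self.origin, float)
        hi = lo + self.spacing * (np.asarray(self.shape) - 1)
        corners = [
            [x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])
        ]
        return np.asarray(corners)


def grid_for_conformer(
    conf: Conformer3D, spacing: float = 0.5, margin: float = 5.0
) -> GridSpec:
    """Grid covering the conformer's bounding box plus ``margin`` on all sides.

    The origin is snapped to the spacing lattice relative to the centre of
    mass so that a translated copy of the same conformer sees the same
    relative node positions.
    """
    com = conf.center_of_mass()
    lo = conf.coords.min(axis=0) - margin
    hi = conf.coords.max(axis=0) + margin
    lo_rel = np.floor((lo - com) / spacing) * spacing
    shape = tuple(int(np.ceil((h - (com[i] + lo_rel[i])) / spacing)) + 1
                  for i, h in enumerate(hi))
    origin = tuple(float(com[i] + lo_rel[i]) for i in range(3))
    return GridSpec(spacing=spacing, margin=margin, origin=origin, shape=shape)


@dataclass
class ProbeField:
    """Interaction energies (kcal/mol) of one probe on one grid."""

    probe: str
    energies: np.ndarray  # (n_nodes,)
    grid: GridSpec

    def min_energy(self) -> float:
        return float(self.energies.min())

    def argmin_node(self) -> np.ndarray:
        return self.grid.node_coords()[int(np.argmin(self.energies))]


def compute_field(
    conf: Conformer3D,
    probe: str | Probe,
    grid: GridSpec | None = None,
    *,
    spacing: float = 0.5,
    margin: float = 5.0,
    coulomb: bool = True,
) -> ProbeField:
    """Evaluate one probe's interaction field over the grid.

    ``coulomb=False`` disables electrostatics (used by closed-form LJ
    tests); the DRY probe never uses electrostatics or hydrogen bonding.
    """
    if isinstance(probe, str):
        try:
            probe = PROBES[probe]
        except KeyError:
            raise ValueError(f"unknown probe {probe!r}") from None
    if grid is None:
        grid = grid_for_conformer(conf, spacing=spacing, margin=margin)

    nodes = grid.node_coords()
    # pairwise distances in manageable node chunks to bound memory
    energies = np.zeros(len(nodes))
    eps_pair = np.sqrt(probe.epsilon * conf.epsilons)  # (n_atoms,)
    rmin_pair = probe.rvdw + conf.radii  # (n_atoms,)
    is_dry = probe.name == "DRY"
    hb_mask = np.zeros(conf.n_atoms, bool)
    if not is_dry:
        if probe.hb_donor:
            hb_mask |= conf.hb_acceptor
        if probe.hb_acceptor:
            hb_mask |= conf.hb_donor

    chunk = max(1, 2_000_000 // max(conf.n_atoms, 1))
    for start in range(0, len(nodes), chunk):
        block = nodes[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - conf.coords[None, :, :], axis=2)
        np.maximum(d, MIN_DISTANCE, out=d)
        inv6 = (rmin_pair / d) ** 6
        e = eps_pair * (inv6 * inv6 - 2.0 * inv6)  # LJ 12-6, min -eps at rmin
        if not is_dry:
            if coulomb and probe.charge != 0.0:
                e += COULOMB_CONSTANT * probe.charge * conf.charges / (4.0 * d * d)
            if probe.hb_strength > 0.0 and hb_mask.any():
                r = probe.hb_r0 / d[:, hb_mask]
                r10 = r**10
                e[:, hb_mask] += probe.hb_strength * (5.0 * r10 * r * r - 6.0 * r10)
        energies[start : start + chunk] = e.sum(axis=1)

    np.clip(energies, ENERGY_CLAMP_LOW, ENERGY_CLAMP_HIGH, out=energies)
    return ProbeField(probe=probe.name, energies=energies, grid=grid)


def compute_all_fields(
    conf: Conformer3D,
    *,
    spacing: float = 0.5,
    margin: float = 5.0,
    probes: tuple[str, ...] = ("DRY", "OH2", "O", "N1"),
) -> dict[str, ProbeField]:
    """All probe fields on one shared grid."""
    grid = grid_for_conformer(conf, spacing=spacing, margin=margin)
    return {p: compute_field(conf, p, grid) for p in probes}


def write_dx(field: ProbeField, path: str) -> None:
    """Dump a field in OpenDX grid format for visualisation."""
    g = field.grid
    nx, ny, nz = g.shape
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {g.origin[0]:.4f} {g.origin[1]:.4f} {g.origin[2]:.4f}",
        f"delta {g.spacing:.4f} 0 0",
        f"delta 0 {g.spacing:.4f} 0",
        f"delta 0 0 {g.spacing:.4f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {g.n_nodes} data follows",
    ]
    vals = field.energies
    for i in range(0, len(vals), 3):
        lines.append(" ".join(f"{v:.5e}" for v in vals[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
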