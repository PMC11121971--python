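"""Solvent-accessible surface area by the numerical dot-density method.

Each atom is covered with a quasi-uniform spherical mesh (golden-spiral
points) at radius r_vdw + r_probe; dots buried inside any neighbouring
atom's accessible sphere are discarded and the surviving fraction gives
the atom's accessible area.  The polar surface area (PSA) is the summed
contribution of N, O and their attached hydrogens; the hydrophobic
surface HSA is the remainder, so PSA + HSA = S holds exactly.
"""

from __future__ import annotations

import numpy as np

from oligodeg.mif.conformer import Conformer3D

PROBE_RADIUS = 1.4  # Angstrom, water probe
DOT_DENSITY = 960  # dots per atom sphere


def _sphere_dots(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral construction)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _polar_atom_mask(conf: Conformer3D) -> np.ndarray:
    """N, O and hydrogens bonded to N or O."""
    polar = np.array([el in ("N", "O") for el in conf.elements])
    if conf.mol is not None:
        for atom in conf.mol.GetAtoms():
            if atom.GetSymbol() == "H":
                nbrs = atom.GetNeighbors()
                if nbrs and nbrs[0].GetSymbol() in ("N", "O"):
                    polar[atom.GetIdx()] = True
    else:  # fall back on distance to nearest heavy atom
        heavy_polar = np.where(polar)[0]
        for i, el in enumerate(conf.elements):
            if el == "H" and len(heavy_polar):
                d = np.linalg.norm(conf.coords[heavy_polar] - conf.coords[i], axis=1)
                if d.min() < 1.2:
                    polar[i] = True
    return polar


def atom_surface_areas(
    conf: Conformer3D,
    *,
    probe_radius: float = PROBE_RADIUS,
    n_dots: int = DOT_DENSITY,
) -> np.ndarray:
    """Per-atom solvent-accessible areas (Angstrom^2), Shrake-Rupley style."""
    dots = _sphere_dots(n_dots)
    radii = conf.radii + probe_radius
    coords = conf.coords
    n = conf.n_atoms
    areas = np.zeros(n)

    # neighbour lists from pairwise distances
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    for i in range(n):
        ri = radii[i]
        cutoff2 = (ri + radii.max()) ** 2
        nbrs = np.where((d2[i] < cutoff2) & (np.arange(n) != i))[0]
        pts = coords[i] + ri * dots
        exposed = np.ones(len(pts), bool)
        for j in nbrs:
            if not exposed.any():
                break
            dj2 = ((pts[exposed] - coords[j]) ** 2).sum(axis=1)
            keep = dj2 >= radii[j] ** 2
            idx = np.where(exposed)[0]
            exposed[idx[~keep]] = False
        areas[i] = 4.0 * np.pi * ri * ri * exposed.sum() / n_dots
    return areas


def surface_descriptors(
    conf: Conformer3D,
    *,
    probe_radius: float = PROBE_RADIUS,
    n_dots: int = DOT_DENSITY,
) -> tuple[float, float, float]:
    """Total surface S, polar surface PSA and hydrophobic surface HSA.

    PSA + HSA = S by construction.
    """
    areas = atom_surface_areas(conf, probe_radius=probe_radius, n_dots=n_dots)
    polar = _polar_atom_mask(conf)
    s = float(areas.sum())
    psa = float(areas[polar].sum())
    return s, psa, s - psa
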