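"""Volume, surface and attraction descriptors: oracles and invariants."""

import numpy as np
import pytest

from oligodeg.mif import (
    DESCRIPTOR_NAMES,
    ENERGY_CUTOFFS,
    GridSpec,
    ProbeField,
    descriptor_vector,
    em_descriptors,
    embed_3d,
    grid_volume_descriptors,
    surface_descriptors,
)
from oligodeg.mif.descriptors import most_acidic_pka
from oligodeg.synthetic_data import gen_random_smiles
from tests.test_mif_fields import single_atom_conformer


def make_field(energies, spacing=1.0, origin=(0, 0, 0), probe="OH2"):
    energies = np.asarray(energies, float)
    shape = energies.shape
    grid = GridSpec(spacing=spacing, margin=0.0, origin=origin, shape=shape)
    return ProbeField(probe=probe, energies=energies.ravel(), grid=grid)


class TestVolumeDescriptors:
    def test_all_positive_field_gives_zeros(self):
        conf = single_atom_conformer("C")
        field = make_field(np.full((3, 3, 3), 1.0))
        w, iw = grid_volume_descriptors(field, conf)
        assert np.array_equal(w, np.zeros(8))
        assert np.array_equal(iw, np.zeros(4))

    def test_handbuilt_field_against_exhaustive_count(self):
        """Wk from a hand-built 3x3x3 field equals a brute-force voxel count."""
        rng = np.random.default_rng(5)
        energies = rng.uniform(-7, 2, size=(3, 3, 3))
        spacing = 0.5
        field = make_field(energies, spacing=spacing)
        conf = single_atom_conformer("C")
        w, _ = grid_volume_descriptors(field, conf)
        for k, cutoff in enumerate(ENERGY_CUTOFFS):
            count = 0
            for i in range(3):
                for j in range(3):
                    for l in range(3):
                        if energies[i, j, l] <= cutoff:
                            count += 1
            assert w[k] == pytest.approx(count * spacing**3)

    def test_nesting_property(self):
        rng = np.random.default_rng(6)
        field = make_field(rng.uniform(-8, 5, size=(6, 6, 6)))
        conf = single_atom_conformer("C")
        w, _ = grid_volume_descriptors(field, conf)
        assert all(w[k] >= w[k + 1] for k in range(7))

    def test_integy_moment_single_attractive_node(self):
        """One attractive node: IW equals its distance to the centre of mass."""
        energies = np.zeros((3, 3, 3))
        energies[2, 2, 2] = -3.0
        field = make_field(energies, spacing=1.0, origin=(0, 0, 0))
        conf = single_atom_conformer("C")  # centre of mass at origin
        w, iw = grid_volume_descriptors(field, conf)
        expected = np.linalg.norm([2.0, 2.0, 2.0])
        assert iw[0] == pytest.approx(expected)
        assert iw[1] == pytest.approx(expected)  # -3 passes the -0.5 cutoff too


class TestSurfaceDescriptors:
    def test_methane_has_no_polar_surface(self):
        s, psa, hsa = surface_descriptors(embed_3d("C", seed=1))
        assert psa == 0.0
        assert hsa == pytest.approx(s)

    def test_isolated_atom_sphere_closed_form(self):
        conf = single_atom_conformer("C")
        s, _, _ = surface_descriptors(conf)
        r = conf.radii[0] + 1.4
        assert s == pytest.approx(4 * np.pi * r * r, rel=0.01)

    def test_psa_plus_hsa_exact(self):
        for smi in ("OCC(O)CO", "CCOC(=O)C", "NCc1ccc(o1)CN"):
            s, psa, hsa = surface_descriptors(embed_3d(smi, seed=2))
            assert psa + hsa == pytest.approx(s, abs=1e-9)
            assert psa > 0


class TestEMDescriptors:
    @staticmethod
    def two_atom_conformer(distance):
        conf = single_atom_conformer("C")
        import dataclasses

        return dataclasses.replace(
            conf,
            elements=["C", "O"],
            coords=np.array([[0.0, 0, 0], [distance, 0, 0]]),
            charges=np.zeros(2),
            radii=np.array([1.7, 1.52]),
            epsilons=np.array([0.086, 0.21]),
            masses=np.array([12.0, 16.0]),
            hb_donor=np.zeros(2, bool),
            hb_acceptor=np.array([False, True]),
        )

    def test_toy_fields_give_interatomic_distance(self):
        conf = self.two_atom_conformer(4.0)
        grid = GridSpec(spacing=1.0, margin=0.0, origin=(-1, 0, 0), shape=(8, 1, 1))
        polar = np.full(8, 0.0)
        polar[5] = -4.0  # node at x=4, nearest atom = O
        apolar = np.full(8, 0.0)
        apolar[1] = -1.0  # node at x=0, nearest atom = C
        fields = {
            "OH2": ProbeField("OH2", polar, grid),
            "O": ProbeField("O", np.zeros(8), grid),
            "N1": ProbeField("N1", np.zeros(8), grid),
            "DRY": ProbeField("DRY", apolar, grid),
        }
        emdif, emdis = em_descriptors(fields, conf)
        assert emdis == pytest.approx(4.0)
        assert emdif == pytest.approx(-4.0 - (-1.0))

    def test_no_attractive_dry_region_gives_zeros(self):
        conf = self.two_atom_conformer(4.0)
        grid = GridSpec(spacing=1.0, margin=0.0, origin=(-1, 0, 0), shape=(8, 1, 1))
        polar = np.full(8, -3.0)
        weak_dry = np.full(8, -0.1)  # above the -0.2 threshold
        fields = {
            "OH2": ProbeField("OH2", polar, grid),
            "O": ProbeField("O", np.zeros(8), grid),
            "N1": ProbeField("N1", np.zeros(8), grid),
            "DRY": ProbeField("DRY", weak_dry, grid),
        }
        assert em_descriptors(fields, conf) == (0.0, 0.0)

    def test_grid_mismatch_rejected(self):
        conf = self.two_atom_conformer(4.0)
        g1 = GridSpec(spacing=1.0, margin=0.0, origin=(0, 0, 0), shape=(4, 1, 1))
        g2 = GridSpec(spacing=1.0, margin=0.0, origin=(1, 0, 0), shape=(4, 1, 1))
        fields = {
            "OH2": ProbeField("OH2", np.zeros(4), g1),
            "O": ProbeField("O", np.zeros(4), g1),
            "N1": ProbeField("N1", np.zeros(4), g1),
            "DRY": ProbeField("DRY", np.zeros(4), g2),
        }
        with pytest.raises(ValueError):
            em_descriptors(fields, conf)


class TestAcidityRules:
    @pytest.mark.parametrize(
        "smiles, pka",
        [
            ("OC(=O)c1ccc(o1)C(=O)O", 4.4),  # carboxylic acid
            ("Oc1ccccc1", 10.0),  # phenol
            ("OCC(O)CO", 15.5),  # aliphatic alcohol
            ("CC(=O)NC", 16.5),  # amide N-H
            ("CCCCCC", 20.0),  # sentinel: nothing ionisable
        ],
    )
    def test_rule_table(self, smiles, pka):
        assert most_acidic_pka(smiles) == pka

    def test_most_acidic_wins(self):
        # acid + alcohol on one molecule: the acid rule dominates
        assert most_acidic_pka("OCC(O)COC(=O)CCCC(=O)O") == 4.4


class TestDescriptorVector:
    def test_names_and_order_fixed(self):
        dv = descriptor_vector("CCO", spacing=1.0, seed=1)
        assert list(dv.selected.index) == list(DESCRIPTOR_NAMES)
        assert dv.selected.notna().all()

    def test_capacity_factor_ordering_polyol_vs_alkane(self):
        """Glycerol's hydrophilic volume per surface exceeds hexane's."""
        gly = descriptor_vector("OCC(O)CO", spacing=0.5, seed=1)
        hexane = descriptor_vector("CCCCCC", spacing=0.5, seed=1)
        assert gly.selected["CW1"] > hexane.selected["CW1"]

    def test_cw_equals_w_over_s(self):
        dv = descriptor_vector("OCC(O)CO", spacing=1.0, seed=2)
        assert np.allclose(dv.CW, dv.W / dv.S)
        assert dv.selected["CW3"] == pytest.approx(dv.W[2] / dv.S)

    def test_determinism(self):
        a = descriptor_vector("CCOC(=O)CC", spacing=1.0, seed=9)
        b = descriptor_vector("CCOC(=O)CC", spacing=1.0, seed=9)
        assert (a.selected == b.selected).all()


@pytest.fixture(scope="module")
def batch():
    smis = gen_random_smiles(60, seed=123)
    return [(s, descriptor_vector(s, spacing=1.0, seed=5)) for s in smis]


class TestDescriptorInvariants:
    """Property checks over a seeded batch of random small molecules."""

    def test_w_nesting_and_non_negative(self, batch):
        for _, dv in batch:
            assert (np.diff(dv.W) <= 1e-12).all()
            assert (dv.W >= 0).all()

    def test_surface_closure(self, batch):
        for _, dv in batch:
            assert dv.PSA + dv.HSA == pytest.approx(dv.S, abs=0.1)

    def test_emdis_non_negative(self, batch):
        for _, dv in batch:
            assert dv.EMDIS >= 0

    def test_rigid_motion_invariance(self, batch):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(77)
        for smi, dv in batch[:20]:
            conf = embed_3d(smi, seed=5)
            rot = Rotation.random(random_state=rng).as_matrix()
            moved = conf.rotated(rot).translated(rng.uniform(-15, 15, 3))
            dv2 = descriptor_vector(smi, conf=moved, spacing=1.0)
            for name in DESCRIPTOR_NAMES:
                a, b = dv.selected[name], dv2.selected[name]
                assert abs(a - b) <= 0.02 * max(abs(a), abs(b), 1e-9) + 1e-9

    def test_grid_refinement_stability(self):
        """Halving the spacing moves the populated volumes by < 10%."""
        smi = "OCC(O)COC(=O)CCCCC(=O)O"
        coarse = descriptor_vector(smi, spacing=0.8, seed=6)
        fine = descriptor_vector(smi, spacing=0.4, seed=6)
        for k in range(8):
            if coarse.W[k] > 5.0:  # volumes with more than a few voxels
                assert fine.W[k] == pytest.approx(coarse.W[k], rel=0.10)
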