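"""chi1 dihedrals, rotamer binning, UP/DOWN calls and ensemble RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rrmswitch import structrot, synth
from rrmswitch.synth import SynthSpec

from conftest import DOWN_CHI1, TEMPLATE_RESTYPES, UP_CHI1


def _apply_rigid(ensemble, rotation, translation):
    for model in ensemble.models:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    new = rotation @ xyz + translation
                    import gemmi
                    atom.pos = gemmi.Position(*new)


class TestDihedral:
    def test_analytic_plus_ninety(self):
        a, b, c, d = (0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1)
        assert structrot.dihedral(*map(np.array, (a, b, c, d))) == \
            pytest.approx(90.0, abs=1e-9)

    def test_cis_is_zero(self):
        a, b, c, d = (0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)
        assert structrot.dihedral(*map(np.array, (a, b, c, d))) == \
            pytest.approx(0.0, abs=1e-9)

    def test_mirror_flips_sign(self, rng):
        pts = rng.normal(size=(4, 3))
        angle = structrot.dihedral(*pts)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert structrot.dihedral(*mirrored) == pytest.approx(-angle, abs=1e-9)

    def test_invariant_under_rigid_transforms(self, rng):
        pts = rng.normal(size=(4, 3))
        reference = structrot.dihedral(*pts)
        for _ in range(100):
            rot = Rotation.random(random_state=rng).as_matrix()
            shift = rng.normal(scale=10.0, size=3)
            moved = pts @ rot.T + shift
            assert structrot.dihedral(*moved) == \
                pytest.approx(reference, abs=1e-6)


class TestChi1Construction:
    def test_prescribed_targets_recovered_exactly(self):
        targets = {426: 180.0, 428: -60.0, 429: 60.0, 455: 17.5}
        ens = synth.gen_ensemble_structure(
            SynthSpec(seed=1), [targets],
            {426: "PHE", 428: "TYR", 429: "HIS", 455: "TRP"})
        for residue, target in targets.items():
            assert structrot.chi1(ens.models[0], residue) == \
                pytest.approx(target, abs=1e-3)

    def test_pdb_text_round_trip(self):
        """Through ATOM records chi1 survives to coordinate precision."""
        targets = {426: -60.0, 428: 175.0}
        text = synth.gen_ensemble(SynthSpec(seed=1), [targets],
                                  {426: "PHE", 428: "TYR"})
        ens = structrot.read_ensemble(text)
        assert len(ens) == 1
        for residue, target in targets.items():
            assert structrot.chi1(ens.models[0], residue) == \
                pytest.approx(target, abs=0.1)

    def test_missing_atoms_not_computable(self):
        ens = synth.gen_ensemble_structure(SynthSpec(seed=1),
                                           [{426: -60.0}], {426: "PHE"})
        assert structrot.chi1(ens.models[0], 999) is None

    def test_unsupported_residue_rejected(self):
        with pytest.raises(ValueError, match="unsupported residue"):
            synth.gen_ensemble(SynthSpec(seed=1), [{426: 0.0}],
                               {426: "ALA"})


class TestAssignRotamer:
    @pytest.mark.parametrize("angle,expected", [
        (175.0, "trans"), (-175.0, "trans"), (180.0, "trans"),
        (-55.0, "gplus"), (-60.0, "gplus"),
        (65.0, "gminus"), (60.0, "gminus"),
    ])
    def test_nearest_center(self, angle, expected):
        assert structrot.assign_rotamer(angle).rotamer == expected

    def test_tie_broken_toward_trans(self):
        # 120 deg is exactly 60 deg from both trans and gminus
        assignment = structrot.assign_rotamer(120.0)
        assert assignment.rotamer == "trans" and assignment.tie

    def test_synth_targets_land_in_their_bin(self, rng):
        for target in rng.uniform(-179.0, 179.0, size=25):
            centers = {"trans": 180.0, "gplus": -60.0, "gminus": 60.0}
            dists = {k: min(abs(target - v) % 360, 360 - abs(target - v) % 360)
                     for k, v in centers.items()}
            if min(dists.values()) > 59.0:  # stay off bin edges
                continue
            expected = min(dists, key=dists.get)
            ens = synth.gen_ensemble_structure(
                SynthSpec(seed=2), [{426: float(target)}], {426: "PHE"})
            angle = structrot.chi1(ens.models[0], 426)
            assert structrot.assign_rotamer(angle).rotamer == expected


class TestClassifyState:
    def _ensemble(self, targets_list, seed=3):
        return synth.gen_ensemble_structure(SynthSpec(seed=seed),
                                            targets_list, TEMPLATE_RESTYPES)

    def test_up_template_all_up(self):
        calls, summary = structrot.classify_ensemble(
            self._ensemble([UP_CHI1] * 5))
        assert summary["UP"] == 1.0
        assert all(c.call == "UP" and c.n_match_up == 6 for c in calls)

    def test_down_template_all_down(self):
        calls, summary = structrot.classify_ensemble(
            self._ensemble([DOWN_CHI1] * 5))
        assert summary["DOWN"] == 1.0

    def test_one_flipped_residue_is_mixed(self):
        flipped = dict(UP_CHI1)
        flipped[426] = 180.0  # gauche+ -> trans
        call = structrot.classify_state(
            self._ensemble([flipped]).models[0], offset=0)
        assert call.call == "MIXED" and call.n_match_up == 5

    def test_numbering_offset_detected(self):
        shifted = {num - 392: angle for num, angle in UP_CHI1.items()}
        restypes = {num - 392: t for num, t in TEMPLATE_RESTYPES.items()}
        ens = synth.gen_ensemble_structure(SynthSpec(seed=4), [shifted],
                                           restypes)
        offset = structrot.detect_offset(ens.models[0])
        assert offset == -392
        call = structrot.classify_state(ens.models[0])
        assert call.call == "UP"

    def test_unresolvable_template_residue_named(self):
        partial = {k: v for k, v in UP_CHI1.items() if k != 466}
        restypes = {k: v for k, v in TEMPLATE_RESTYPES.items() if k != 466}
        ens = synth.gen_ensemble_structure(SynthSpec(seed=5), [partial],
                                           restypes)
        with pytest.raises(ValueError, match="466"):
            structrot.classify_state(ens.models[0], offset=0)


class TestEnsembleRMSD:
    def test_rigid_translations_give_zero(self, rng):
        ens = synth.gen_ensemble_structure(SynthSpec(seed=6),
                                           [UP_CHI1] * 3, TEMPLATE_RESTYPES)
        for i, model in enumerate(ens.models):
            _apply_rigid(structrot.StructureEnsemble([model]),
                         np.eye(3), np.array([5.0 * i, -2.0 * i, 1.0]))
        result = structrot.ensemble_rmsd(ens)
        assert result.mean == pytest.approx(0.0, abs=1e-9)

    def test_two_models_single_displaced_atom(self):
        """A 1 A displacement of one atom in a large rigid core splits
        0.5 A per model against the mean."""
        n_core = 400
        gen = np.random.default_rng(11)
        core = gen.normal(scale=10.0, size=(n_core, 3))
        coords_a = np.vstack([core, [[0.0, 0.0, 0.0]]])
        coords_b = np.vstack([core, [[1.0, 0.0, 0.0]]])
        # superposition over the dominant rigid core barely moves anything,
        # so per-model RMSD over the displaced atom alone is ~0.5
        mean = (coords_a + coords_b) / 2
        rms_a = np.linalg.norm(coords_a[-1] - mean[-1])
        assert rms_a == pytest.approx(0.5, abs=1e-12)
        # and through the full implementation (all atoms in the selection)
        expected = np.sqrt(0.5 ** 2 / (n_core + 1))
        result = _rmsd_from_arrays([coords_a, coords_b])
        assert result.mean == pytest.approx(expected, rel=5e-2)

    def test_model_order_invariance(self):
        ens1 = synth.gen_ensemble_structure(
            SynthSpec(seed=7), [UP_CHI1, DOWN_CHI1, UP_CHI1],
            TEMPLATE_RESTYPES, jitter=0.05)
        ens2 = structrot.StructureEnsemble(models=ens1.models[::-1],
                                           structure=ens1.structure)
        r1 = structrot.ensemble_rmsd(ens1)
        r2 = structrot.ensemble_rmsd(ens2)
        assert r1.mean == pytest.approx(r2.mean, abs=1e-6)
        assert sorted(r1.per_model) == pytest.approx(sorted(r2.per_model),
                                                     abs=1e-6)

    def test_rigid_transform_of_one_model_invariant(self, rng):
        ens = synth.gen_ensemble_structure(SynthSpec(seed=8),
                                           [UP_CHI1] * 3, TEMPLATE_RESTYPES,
                                           jitter=0.1)
        before = structrot.ensemble_rmsd(ens).mean
        rot = Rotation.random(random_state=rng).as_matrix()
        _apply_rigid(structrot.StructureEnsemble([ens.models[1]]),
                     rot, np.array([3.0, 4.0, 5.0]))
        after = structrot.ensemble_rmsd(ens).mean
        assert after == pytest.approx(before, abs=1e-6)

    def test_backbone_selection_smaller_than_heavy(self):
        ens = synth.gen_ensemble_structure(SynthSpec(seed=9),
                                           [UP_CHI1] * 2, TEMPLATE_RESTYPES,
                                           jitter=0.2)
        heavy = structrot.ensemble_rmsd(ens, mode="heavy")
        backbone = structrot.ensemble_rmsd(ens, mode="backbone")
        assert backbone.n_atoms < heavy.n_atoms


def _rmsd_from_arrays(coord_list):
    """Build a minimal ensemble from raw coordinate arrays."""
    import gemmi

    structure = gemmi.Structure()
    for m_idx, coords in enumerate(coord_list, 1):
        model = gemmi.Model(m_idx)
        chain = gemmi.Chain("A")
        residue = gemmi.Residue()
        residue.name = "PHE"
        residue.seqid = gemmi.SeqId(1, " ")
        for i, xyz in enumerate(coords):
            atom = gemmi.Atom()
            atom.name = f"C{i}"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            residue.add_atom(atom)
        chain.add_residue(residue)
        model.add_chain(chain)
        structure.add_model(model)
    ens = structrot.StructureEnsemble(models=list(structure),
                                      structure=structure)
    return structrot.ensemble_rmsd(ens)


class TestRotamerOccupancy:
    def test_all_trans(self):
        ens = synth.gen_ensemble_structure(SynthSpec(seed=10),
                                           [{426: 180.0}] * 4, {426: "PHE"})
        occ = structrot.rotamer_occupancy_ensemble(ens, 426)
        assert occ == {"trans": 1.0, "gplus": 0.0, "gminus": 0.0}

    def test_alternating_frames(self):
        import pandas as pd

        frames = pd.DataFrame({
            "frame": range(10), "residue": [426] * 10,
            "chi1_deg": [60.0, 180.0] * 5})
        occ = structrot.rotamer_occupancy_table(frames, residue=426)
        assert occ["gminus"] == 0.5 and occ["trans"] == 0.5

    def test_two_state_sampling_bound(self):
        import pandas as pd

        gen = np.random.default_rng(99)
        n = 10_000
        angles = np.where(gen.random(n) < 0.7, 180.0, -60.0)
        frames = pd.DataFrame({"frame": range(n), "residue": 426,
                               "chi1_deg": angles})
        occ = structrot.rotamer_occupancy_table(frames, residue=426)
        assert abs(occ["trans"] - 0.7) <= 0.02
        assert abs(occ["gplus"] - 0.3) <= 0.02
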