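"""Superposition, atom mapping, symmetry-aware RMSD, clash detection,
per-prediction records and conservation statistics."""


import networkx as nx
import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
import pytest

from cofoldprobe import (
    LigandGraph,
    MockPredictorConfig,
    ToyComplexParams,
    conservation_stats,
    detect_clashes,
    evaluate_prediction,
    ligand_rmsd,
    make_toy_complex,
    map_common_heavy_atoms,
    methylate,
    mock_predict,
    superpose_calpha,
)
from cofoldprobe.core_structures import Atom, ProteinLigandComplex, Residue
from cofoldprobe.pose_evaluation import (
    DEFAULT_VDW,
    VDW_RADII,
    AtomMapping,
    EvaluationRecord,
)
from cofoldprobe.site_challenges import build_suite


def nx_automorphisms(graph: LigandGraph) -> list[dict[int, int]]:
    """Exhaustive automorphism oracle via VF2, preserving element and
    formal charge (resonance-distinct atoms stay distinct)."""
    g = nx.Graph()
    for idx, atom in enumerate(graph.atoms):
        g.add_node(idx, element=atom.element, charge=atom.formal_charge)
    for i, j, _ in graph.bonds:
        g.add_edge(i, j)
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: (a["element"], a["charge"]) == (b["element"], b["charge"]),
    )
    return list(gm.isomorphisms_iter())


def brute_force_min_rmsd(pred: LigandGraph, ref: LigandGraph, pairs) -> float:
    """Minimum RMSD over ALL graph automorphisms of the reference."""
    ref_xyz, pred_xyz = ref.coords, pred.coords
    best = np.inf
    mapped = {r for r, _ in pairs}
    for auto in nx_automorphisms(ref):
        if not {auto[r] for r in mapped} <= mapped:
            continue
        d = np.array([ref_xyz[auto[r]] - pred_xyz[p] for r, p in pairs])
        best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    return best


class TestSuperposeCalpha:
    def test_identity(self, toy_complex):
        _, rmsd = superpose_calpha(toy_complex, toy_complex)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_invariance(self, toy_complex):
        moved = toy_complex.copy()
        R = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        shift = np.array([10.0, -4.0, 2.0])
        for res in moved.iter_residues():
            for a in res.atoms:
                a.coords = R @ a.coords + shift
        _, rmsd = superpose_calpha(moved, toy_complex)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_noisy_copy_matches_independent_oracle(self, toy_complex):
        import biotite.structure as struc

        rng = np.random.default_rng(5)
        noisy = toy_complex.copy()
        for res in noisy.iter_residues():
            for a in res.atoms:
                a.coords = a.coords + rng.normal(0, 0.3, 3)
        _, rmsd = superpose_calpha(noisy, toy_complex)

        ref_xyz = np.array([r.atom("CA").coords for r in toy_complex.iter_residues()])
        mob_xyz = np.array([r.atom("CA").coords for r in noisy.iter_residues()])
        fitted, _ = struc.superimpose(ref_xyz, mob_xyz)
        oracle = float(np.sqrt(np.mean(np.sum((fitted - ref_xyz) ** 2, axis=1))))
        # biotite works in single precision; agree to ~1e-5 Å
        assert rmsd == pytest.approx(oracle, abs=1e-5)

    def test_too_few_shared_residues(self, toy_complex, glucose):
        lone = ProteinLigandComplex(
            chains={"Q": [Residue("Q", 1, "", "GLY",
                                  [Atom("CA", "C", [0.0, 0.0, 0.0])])]},
            ligand=glucose, ligand_code="LIG", source_id="X",
        )
        with pytest.raises(ValueError, match="shared"):
            superpose_calpha(lone, toy_complex)


class TestAtomMapping:
    def test_identical_is_full_bijection(self, atp_3d):
        mapping = map_common_heavy_atoms(atp_3d, atp_3d, mode="identical")
        assert sorted(mapping.pairs) == [(i, i) for i in range(len(atp_3d.atoms))]
        assert mapping.coverage == 1.0

    def test_methylated_maps_all_base_atoms(self, glucose_3d):
        m3 = methylate(glucose_3d, 3)
        mapping = map_common_heavy_atoms(glucose_3d, m3, mode="modified")
        assert len(mapping.pairs) == glucose_3d.heavy_atom_count == 12
        mapped_pred = {p for _, p in mapping.pairs}
        unmapped = set(range(len(m3.atoms))) - mapped_pred
        assert len(unmapped) == 3  # the added methyl carbons
        assert all(m3.atoms[i].element == "C" for i in unmapped)

    def test_benzene_automorphism_count(self, benzene_ring):
        assert len(nx_automorphisms(benzene_ring)) == 12

    def test_injective_both_ways_enforced(self):
        with pytest.raises(ValueError, match="injective"):
            AtomMapping(pairs=[(0, 0), (1, 0)], coverage=1.0)

    def test_incomparable_raises(self, glucose, atp):
        with pytest.raises(ValueError, match="not comparable"):
            map_common_heavy_atoms(glucose, atp, mode="identical")


class TestLigandRmsd:
    def test_identical_pose_zero(self, benzene_ring):
        mapping = map_common_heavy_atoms(benzene_ring, benzene_ring)
        assert ligand_rmsd(benzene_ring, benzene_ring, mapping) == 0.0

    def test_uniform_translation(self, benzene_ring):
        moved = benzene_ring.with_coords(benzene_ring.coords + [3.0, 0, 0])
        mapping = map_common_heavy_atoms(benzene_ring, moved)
        assert ligand_rmsd(moved, benzene_ring, mapping, symmetry=False) == pytest.approx(3.0)

    def test_ring_rotation_symmetry(self, benzene_ring):
        rotated = benzene_ring.with_coords(np.roll(benzene_ring.coords, 1, axis=0))
        mapping = AtomMapping(pairs=[(i, i) for i in range(6)], coverage=1.0)
        on = ligand_rmsd(rotated, benzene_ring, mapping, symmetry=True)
        off = ligand_rmsd(rotated, benzene_ring, mapping, symmetry=False)
        assert on == pytest.approx(0.0, abs=1e-12)
        assert off > 0
        assert on == pytest.approx(
            brute_force_min_rmsd(rotated, benzene_ring, mapping.pairs), abs=1e-12
        )

    @pytest.mark.parametrize("smiles", ["c1ccccc1", "C1CCCCC1", "c1ccc2ccccc2c1", "CC(C)(C)C"])
    def test_symmetry_min_equals_exhaustive_oracle(self, smiles):
        graph = LigandGraph.from_smiles(smiles)
        n = len(graph.atoms)
        rng = np.random.default_rng(n)
        ref = graph.with_coords(rng.normal(0, 2, (n, 3)))
        pred = graph.with_coords(ref.coords[rng.permutation(n)])
        mapping = AtomMapping(pairs=[(i, i) for i in range(n)], coverage=1.0)
        ours = ligand_rmsd(pred, ref, mapping, symmetry=True)
        oracle = brute_force_min_rmsd(pred, ref, mapping.pairs)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_symmetry_never_increases(self, benzene_ring):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pred = benzene_ring.with_coords(
                benzene_ring.coords + rng.normal(0, 2, (6, 3))
            )
            mapping = AtomMapping(pairs=[(i, i) for i in range(6)], coverage=1.0)
            on = ligand_rmsd(pred, benzene_ring, mapping, symmetry=True)
            off = ligand_rmsd(pred, benzene_ring, mapping, symmetry=False)
            assert on <= off + 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**16))
    def test_invariant_under_global_rigid_motion(self, seed):
        # applying one rigid transform to both structures leaves RMSD fixed
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        graph = LigandGraph.from_smiles("c1ccccc1")
        ref = graph.with_coords(rng.normal(0, 2, (6, 3)))
        pred = graph.with_coords(ref.coords + rng.normal(0, 1, (6, 3)))
        mapping = AtomMapping(pairs=[(i, i) for i in range(6)], coverage=1.0)
        base = ligand_rmsd(pred, ref, mapping, symmetry=False)
        R = Rotation.random(random_state=int(seed)).as_matrix()
        t = rng.normal(0, 10, 3)
        moved_ref = ref.with_coords(ref.coords @ R.T + t)
        moved_pred = pred.with_coords(pred.coords @ R.T + t)
        assert ligand_rmsd(moved_pred, moved_ref, mapping, symmetry=False) == \
            pytest.approx(base, abs=1e-9)

    def test_empty_mapping_raises(self, benzene_ring):
        with pytest.raises(ValueError, match="empty"):
            ligand_rmsd(benzene_ring, benzene_ring,
                        AtomMapping(pairs=[], coverage=0.0))


def brute_force_clash_count(cplx, tolerance=0.4) -> int:
    """O(N*M) double-loop oracle over all protein/ligand heavy-atom pairs."""
    count = 0
    lig = cplx.ligand
    for res in cplx.iter_residues():
        for atom in res.atoms:
            for latom in lig.atoms:
                limit = (
                    VDW_RADII.get(atom.element.upper(), DEFAULT_VDW)
                    + VDW_RADII.get(latom.element.upper(), DEFAULT_VDW)
                    - tolerance
                )
                if np.linalg.norm(atom.coords - latom.coords) < limit:
                    count += 1
    return count


def sparse_planted_complex(k: int, seed: int) -> ProteinLigandComplex:
    """Ligand atoms 10 Å apart on a line; k protein atoms planted to clash
    with exactly one ligand atom each, the rest far away."""
    rng = np.random.default_rng(seed)
    n_lig = max(k, 3) + 2
    lig_xyz = np.stack([np.arange(n_lig) * 10.0, np.zeros(n_lig), np.zeros(n_lig)], axis=1)
    ligand = LigandGraph(
        atoms=[Atom(f"C{i+1}", "C", lig_xyz[i]) for i in range(n_lig)],
        bonds=[(i, i + 1, 1.0) for i in range(n_lig - 1)],
    )
    residues = []
    targets = rng.choice(n_lig, size=k, replace=False)
    for idx, j in enumerate(targets):
        pos = lig_xyz[j] + np.array([0.0, 0.0, 1.0])  # deep vdW overlap
        residues.append(
            Residue("A", idx + 1, "", "ALA",
                    [Atom("CA", "C", pos + [0, 3.2, 0]), Atom("CB", "C", pos)])
        )
    for extra in range(5):
        pos = np.array([extra * 10.0, 50.0, 0.0])
        residues.append(
            Residue("A", 100 + extra, "", "ALA",
                    [Atom("CA", "C", pos), Atom("CB", "C", pos + [0, 1.5, 0])])
        )
    return ProteinLigandComplex(
        chains={"A": residues}, ligand=ligand, ligand_code="LIG", source_id="PLANT"
    )


class TestDetectClashes:
    def test_deep_overlap(self):
        cplx = sparse_planted_complex(1, seed=1)
        assert detect_clashes(cplx).count == 1

    def test_exact_vdw_contact_is_not_clash(self):
        ligand = LigandGraph(atoms=[Atom("C1", "C", [0.0, 0.0, 0.0])], bonds=[])
        res = Residue("A", 1, "", "ALA",
                      [Atom("CB", "C", [2 * VDW_RADII["C"] - 0.4, 0.0, 0.0])])
        cplx = ProteinLigandComplex(chains={"A": [res]}, ligand=ligand,
                                    ligand_code="LIG", source_id="EDGE")
        assert detect_clashes(cplx).count == 0

    @pytest.mark.parametrize("k", [0, 1, 3, 7])
    def test_planted_counts(self, k):
        cplx = sparse_planted_complex(k, seed=k + 10)
        report = detect_clashes(cplx)
        assert report.count == k
        assert report.count == brute_force_clash_count(cplx)

    def test_many_random_complexes_match_oracle(self):
        for seed in range(100):
            k = seed % 6
            cplx = sparse_planted_complex(k, seed=seed)
            assert detect_clashes(cplx).count == brute_force_clash_count(cplx) == k


@pytest.fixture(scope="module")
def setup():
    cplx = make_toy_complex(ToyComplexParams(seed=23))
    suite = build_suite(cplx, 3.5)
    return cplx, suite


class TestEvaluatePrediction:
    def test_memorizer_conserves_everything(self, setup):
        cplx, suite = setup
        config = MockPredictorConfig(mode="memorizer", coordinate_noise=0.0, seed=1)
        for spec in suite:
            rec = evaluate_prediction(mock_predict(cplx, spec, config), cplx, spec)
            assert rec.conserved
            assert rec.ligand_rmsd == pytest.approx(0.0, abs=1e-8)

    def test_physics_breaks_packing(self, setup):
        cplx, suite = setup
        config = MockPredictorConfig(mode="physics", displacement=8.0, seed=1)
        packing = next(s for s in suite if s.kind == "packing")
        rec = evaluate_prediction(mock_predict(cplx, packing, config), cplx, packing)
        assert not rec.conserved
        assert rec.ligand_rmsd >= 8.0 - 0.1

    def test_threshold_is_strict(self):
        rec = EvaluationRecord(
            spec_id="x", kind="wild_type", ligand_rmsd=2.0,
            conserved=2.0 < 2.0, n_clashes=0,
        )
        assert rec.conserved is False

    def test_confidence_is_mean_of_mapped_atoms(self, setup):
        cplx, suite = setup
        config = MockPredictorConfig(mode="memorizer", seed=7)
        pred = mock_predict(cplx, suite[0], config)
        rec = evaluate_prediction(pred, cplx, suite[0])
        assert rec.ligand_confidence == pytest.approx(
            float(np.mean(pred.per_atom_confidence))
        )


class TestConservationStats:
    @staticmethod
    def _rec(kind, conserved, conf=None):
        return EvaluationRecord(
            spec_id=f"{kind}-{conserved}", kind=kind, ligand_rmsd=0.5 if conserved else 5.0,
            conserved=conserved, n_clashes=0, ligand_confidence=conf,
        )

    def test_all_conserved(self):
        summary = conservation_stats([self._rec("wild_type", True)] * 10)
        assert summary.fractions == {"wild_type": 1.0}

    def test_half(self):
        recs = [self._rec("packing", i < 4) for i in range(8)]
        assert conservation_stats(recs).fractions == {"packing": 0.5}

    def test_planted_pattern_counting_oracle(self):
        rng = np.random.default_rng(3)
        planted = {"wild_type": 0.9, "removal": 0.6, "packing": 0.1}
        recs = []
        for kind, frac in planted.items():
            flags = [rng.random() < frac for _ in range(200)]
            recs.extend(self._rec(kind, f) for f in flags)
        summary = conservation_stats(recs)
        for kind, frac in planted.items():
            conserved = sum(1 for r in recs if r.kind == kind and r.conserved)
            assert summary.fractions[kind] == conserved / 200
            assert summary.counts[kind] == (conserved, 200)

    def test_order_invariant(self):
        rng = np.random.default_rng(9)
        recs = [self._rec("inversion", rng.random() < 0.3) for _ in range(50)]
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert conservation_stats(recs).fractions == conservation_stats(shuffled).fractions

    def test_confidence_stratification_partitions(self):
        recs = [self._rec("wild_type", True, conf=90.0)] * 3 + [
            self._rec("wild_type", False, conf=50.0)
        ] * 5 + [self._rec("wild_type", True, conf=None)] * 2
        summary = conservation_stats(recs, confidence_cutoff=80.0)
        assert summary.fractions["wild_type"] == 0.5
        assert summary.stratified_fractions["wild_type"] == 1.0
        assert summary.stratified_counts["wild_type"][1] <= summary.counts["wild_type"][1]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            conservation_stats([])
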