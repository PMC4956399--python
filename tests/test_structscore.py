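"""PDB I/O, superposition, ensemble PCA, contacts and LJ rescoring."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata, pearsonr

from designscreen.structscore import (
    Atom,
    LJParams,
    PDBParseError,
    StructureModel,
    backbone_pca,
    interface_contacts,
    kabsch_rmsd,
    lj_interface_score,
    rank_correlation,
    read_pdb,
    write_pdb,
)
from designscreen.synthetic import simulate_structures


def toy_model(coords, chain="A", names=None, elements=None, model_id="toy"):
    atoms = []
    for i, xyz in enumerate(coords):
        atoms.append(
            Atom(
                chain=chain,
                resnum=i + 1,
                resname="GLY",
                name=(names[i] if names else "CA"),
                x=float(xyz[0]),
                y=float(xyz[1]),
                z=float(xyz[2]),
                element=(elements[i] if elements else "C"),
            )
        )
    return StructureModel(atoms, model_id)


class TestPdbIO:
    def test_round_trip_preserves_coordinates(self, rng):
        coords = np.round(rng.normal(scale=10, size=(10, 3)), 3)
        model = toy_model(coords)
        back = read_pdb(write_pdb(model))
        assert np.allclose(back.coords(), coords, atol=5e-4)
        assert [a.name for a in back.atoms] == ["CA"] * 10
        assert [a.chain for a in back.atoms] == ["A"] * 10

    def test_missing_chain_id_raises_with_line(self):
        text = write_pdb(toy_model(np.zeros((1, 3))))
        broken = text.replace("GLY A", "GLY  ")
        with pytest.raises(PDBParseError, match="line 1.*chain"):
            read_pdb(broken)

    def test_malformed_coordinate_field(self):
        text = write_pdb(toy_model(np.ones((2, 3))))
        lines = text.splitlines()
        lines[1] = lines[1][:30] + "  xx.xxx" + lines[1][38:]
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb("\n".join(lines))

    def test_synthetic_ensemble_round_trip(self):
        for model in simulate_structures(3, displacement_sd=0.4, seed=9):
            back = read_pdb(write_pdb(model))
            assert np.allclose(back.coords(), model.coords(), atol=5e-4)


class TestKabsch:
    def test_identical_models_zero(self, rng):
        m = toy_model(rng.normal(size=(8, 3)))
        assert kabsch_rmsd(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero(self, rng):
        coords = rng.normal(size=(8, 3))
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        moved = rot.apply(coords) + np.array([5.0, -2.0, 9.0])
        assert kabsch_rmsd(toy_model(coords), toy_model(moved)) < 1e-9

    def test_symmetry_and_prerotation_invariance(self, rng):
        a = toy_model(rng.normal(size=(6, 3)))
        b = toy_model(rng.normal(size=(6, 3)))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-9)
        spun = toy_model(Rotation.from_rotvec([1.0, 0.2, -0.5]).apply(a.coords()))
        assert kabsch_rmsd(spun, b) == pytest.approx(kabsch_rmsd(a, b), abs=1e-9)

    def test_matches_rotation_grid_oracle(self, rng):
        a = toy_model(rng.normal(size=(4, 3)))
        b = toy_model(rng.normal(size=(4, 3)))
        fast = kabsch_rmsd(a, b)
        pa = a.coords() - a.coords().mean(axis=0)
        pb = b.coords() - b.coords().mean(axis=0)
        best = np.inf
        grid = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        half = np.linspace(0, np.pi, 30)
        for ai, bi, ci in itertools.product(grid, half, grid):
            rot = Rotation.from_euler("zyz", [ai, bi, ci])
            rmsd = np.sqrt(((pa - rot.apply(pb)) ** 2).sum() / 4)
            best = min(best, rmsd)
        assert fast <= best + 1e-9
        assert best - fast < 1e-2  # grid resolution limits the oracle

    def test_selection_mismatch_lists_atoms(self, rng):
        a = toy_model(rng.normal(size=(4, 3)))
        b = toy_model(rng.normal(size=(3, 3)))
        with pytest.raises(ValueError, match="unpaired"):
            kabsch_rmsd(a, b)


class TestEnsembleSummary:
    def test_identical_ensemble_zeros(self, rng):
        m = toy_model(rng.normal(size=(5, 3)))
        rmsds, median = __import__("designscreen.structscore", fromlist=["x"]).ensemble_rmsd_summary([m, m], m)
        assert rmsds == [pytest.approx(0.0, abs=1e-12)] * 2 and median == pytest.approx(0.0, abs=1e-12)

    def test_single_model_median(self, rng):
        ref = toy_model(rng.normal(size=(5, 3)))
        other = toy_model(rng.normal(size=(5, 3)))
        from designscreen.structscore import ensemble_rmsd_summary

        rmsds, median = ensemble_rmsd_summary([other], ref)
        assert median == pytest.approx(rmsds[0])


class TestBackbonePCA:
    def test_query_member_matches_fit_score(self, rng):
        models = [toy_model(rng.normal(size=(6, 3))) for _ in range(8)]
        res = backbone_pca(models, [models[3]], n_components=2)
        assert np.allclose(res.query_projections[0], res.reference_projections[3], atol=1e-9)

    def test_variance_fractions_shape(self, rng):
        models = [toy_model(rng.normal(size=(6, 3))) for _ in range(8)]
        res = backbone_pca(models, [], n_components=4)
        assert (np.diff(res.variance_fractions) <= 1e-12).all()
        assert res.variance_fractions.sum() <= 1.0 + 1e-12

    def test_matches_dense_eigendecomposition(self, rng):
        from designscreen.structscore import _paired_coords, superpose

        models = [toy_model(rng.normal(size=(5, 3))) for _ in range(10)]
        res = backbone_pca(models, [], n_components=3)
        rows = []
        for m in models:
            sup = superpose(m, models[0], ("CA",))
            pm, _ = _paired_coords(sup, models[0], ("CA",))
            rows.append(pm.ravel())
        x = np.array(rows)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc / (len(models) - 1))
        order = np.argsort(evals)[::-1]
        oracle = xc @ evecs[:, order[:3]]
        for k in range(3):
            assert np.allclose(
                np.abs(res.reference_projections[:, k]), np.abs(oracle[:, k]), atol=1e-8
            )

    def test_too_few_references(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            backbone_pca([toy_model(rng.normal(size=(4, 3)))], [])


def two_chain_pair(distance):
    atoms = [
        Atom("A", 1, "GLY", "CA", 0.0, 0.0, 0.0, "C"),
        Atom("B", 1, "GLY", "CA", distance, 0.0, 0.0, "C"),
    ]
    return StructureModel(atoms, "pair")


class TestInterfaceContacts:
    def test_distance_boundary(self):
        model = StructureModel(
            [
                Atom("A", 1, "GLY", "CA", 0.0, 0.0, 0.0, "C"),
                Atom("A", 2, "GLY", "CA", 4.9, 0.0, 0.0, "C"),
                Atom("A", 3, "GLY", "CA", 10.2, 0.0, 0.0, "C"),
                Atom("B", 1, "GLY", "CA", 0.0, 30.0, 0.0, "C"),
            ],
            "toy",
        )
        hits = interface_contacts(model, [1], partner_chain="B", cutoff=5.0)
        assert hits == [2]  # 4.9 A in, 10.2 A out

    def test_zero_cutoff_empty(self):
        model = two_chain_pair(1.0)
        assert interface_contacts(model, [1], partner_chain="B", cutoff=0.0, variant_chain="A") == []

    def test_matches_all_pairs_oracle(self, rng):
        coords_a = rng.normal(scale=6, size=(30, 3))
        coords_b = rng.normal(scale=6, size=(20, 3)) + np.array([4.0, 0, 0])
        atoms = [
            Atom("A", i + 1, "GLY", "CA", *map(float, c), "C") for i, c in enumerate(coords_a)
        ] + [
            Atom("B", i + 1, "GLY", "CA", *map(float, c), "C") for i, c in enumerate(coords_b)
        ]
        model = StructureModel(atoms, "toy50")
        designed = [1, 2, 3, 4, 5]
        cutoff = 5.0
        hits = interface_contacts(model, designed, partner_chain="B", cutoff=cutoff)
        d_set = coords_a[:5]
        oracle = []
        for i, c in enumerate(coords_a):
            others = d_set[[j for j in range(5) if j != i]] if i < 5 else d_set
            if others.size and np.sqrt(((others - c) ** 2).sum(axis=1)).min() <= cutoff:
                oracle.append(i + 1)
        assert hits == oracle

    def test_side_chain_orientation_filter(self):
        # side chain of A1 points toward chain B; A2's points away
        atoms = [
            Atom("A", 1, "ALA", "N", -1.0, 0.0, 0.0, "N"),
            Atom("A", 1, "ALA", "CA", 0.0, 0.0, 0.0, "C"),
            Atom("A", 1, "ALA", "CB", 0.0, 2.0, 0.0, "C"),
            Atom("A", 2, "ALA", "N", 2.0, 0.0, 0.0, "N"),
            Atom("A", 2, "ALA", "CA", 3.0, 0.0, 0.0, "C"),
            Atom("A", 2, "ALA", "CB", 3.0, -2.0, 0.0, "C"),
            Atom("B", 1, "GLY", "CA", 1.5, 8.0, 0.0, "C"),
        ]
        model = StructureModel(atoms, "orient")
        any_atom = interface_contacts(model, [1, 2], partner_chain="B", cutoff=5.0)
        oriented = interface_contacts(
            model, [1, 2], partner_chain="B", cutoff=5.0, mode="side-chain-oriented"
        )
        assert set(any_atom) == {1, 2}
        assert oriented == [1]


class TestLJScore:
    def test_single_pair_minimum(self):
        sigma, eps = 3.4, 0.09
        r = 2 ** (1 / 6) * sigma
        model = two_chain_pair(r)
        score = lj_interface_score(model, [1], partner_chain="B")
        assert score.total == pytest.approx(-eps, abs=1e-12)

    def test_beyond_cutoff_zero(self):
        model = two_chain_pair(9.5)
        score = lj_interface_score(model, [1], partner_chain="B", params=LJParams(cutoff=8.0))
        assert score.total == 0.0 and score.attractive == 0.0 and score.repulsive == 0.0

    def test_matches_double_loop_oracle(self, rng):
        elements = ["C", "N", "O", "S", "C"]
        ca = rng.normal(scale=3, size=(5, 3))
        cb = rng.normal(scale=3, size=(5, 3)) + np.array([2.0, 0, 0])
        atoms = [
            Atom("A", i + 1, "GLY", "CA", *map(float, c), elements[i]) for i, c in enumerate(ca)
        ] + [
            Atom("B", i + 1, "GLY", "CA", *map(float, c), elements[i]) for i, c in enumerate(cb)
        ]
        model = StructureModel(atoms, "toy10")
        params = LJParams(cutoff=12.0)
        score = lj_interface_score(model, [1, 2, 3, 4, 5], partner_chain="B", params=params)
        total = 0.0
        for a in model.select(chains=("A",)):
            for b in model.select(chains=("B",)):
                r = np.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)
                if r >= params.cutoff:
                    continue
                s = 0.5 * (params.element_params[a.element][0] + params.element_params[b.element][0])
                e = np.sqrt(params.element_params[a.element][1] * params.element_params[b.element][1])
                total += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
        assert score.total == pytest.approx(total, abs=1e-10)
        assert score.total == pytest.approx(score.attractive + score.repulsive, abs=1e-10)

    def test_pair_additivity_over_disjoint_selections(self, rng):
        ca = rng.normal(scale=4, size=(6, 3))
        cb = rng.normal(scale=4, size=(4, 3)) + np.array([3.0, 0, 0])
        atoms = [
            Atom("A", i + 1, "GLY", "CA", *map(float, c), "C") for i, c in enumerate(ca)
        ] + [
            Atom("B", i + 1, "GLY", "CA", *map(float, c), "C") for i, c in enumerate(cb)
        ]
        model = StructureModel(atoms, "add")
        full = lj_interface_score(model, [1, 2, 3, 4, 5, 6], partner_chain="B").total
        parts = (
            lj_interface_score(model, [1, 2, 3], partner_chain="B").total
            + lj_interface_score(model, [4, 5, 6], partner_chain="B").total
        )
        assert full == pytest.approx(parts, abs=1e-10)

    def test_truncate_shift_continuous_at_cutoff(self):
        params = LJParams(cutoff=6.0, switch="truncate-shift")
        just_in = lj_interface_score(two_chain_pair(5.9999), [1], "B", params=params).total
        assert abs(just_in) < 1e-3

    def test_zero_distance_error(self):
        atoms = [
            Atom("A", 1, "GLY", "CA", 0.0, 0.0, 0.0, "C"),
            Atom("B", 1, "GLY", "CA", 0.0, 0.0, 0.0, "C"),
        ]
        with pytest.raises(ValueError, match="zero"):
            lj_interface_score(StructureModel(atoms, "z"), [1], partner_chain="B")

    def test_empty_selection_error(self):
        with pytest.raises(ValueError, match="empty"):
            lj_interface_score(two_chain_pair(3.0), [], partner_chain="B")


class TestRankCorrelation:
    def test_perfect_antimonotone(self):
        rho, _ = rank_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_constant_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = rank_correlation([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(rho)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho, _ = rank_correlation(x, y)
        oracle, _ = pearsonr(rankdata(x), rankdata(y))
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_lj_score_anticorrelates_with_counts_closed_loop(self, rng):
        """Tighter (lower) LJ interface energy -> more reads, on complexes
        whose ground-truth binding is the LJ score itself."""
        models = simulate_structures(100, displacement_sd=0.3, seed=17)
        totals = []
        for m in models:
            contacts = interface_contacts(m, list(range(1, 19)), partner_chain="B", cutoff=5.0)
            totals.append(lj_interface_score(m, contacts, partner_chain="B").total)
        totals = np.asarray(totals)
        scaled = (totals - totals.mean()) / totals.std()
        mu = 1e4 * 10 ** (-0.5 * scaled)
        counts = rng.poisson(mu)
        rho, p = rank_correlation(totals, counts)
        assert rho < 0 and p < 0.01
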