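import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from qsarkit.chem_io import Molecule
from qsarkit.comsia import (
    FIELD_NAMES,
    AlignmentSpec,
    FieldGrid,
    ProbeParams,
    align_to_template,
    build_grid,
    column_filter,
    contour_masks,
    field_block,
    field_contributions,
    fit_comsia,
    loo_q2,
    pls_fit,
    predict_comsia,
    select_onc,
    similarity_fields,
)
from qsarkit.synthetic import ToyMoleculeSpec, gen_toy_molecules


def _mol(coords, radii=None, charges=None, elements=None, mid="m"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return Molecule(
        id=mid,
        elements=elements or ["C"] * n,
        coords=coords,
        radii=np.asarray(radii) if radii is not None else np.full(n, 1.7),
        charges=np.asarray(charges, dtype=float) if charges is not None else np.zeros(n),
    )


class TestAlign:
    @staticmethod
    def _pair(rng, rotator):
        coords = rng.standard_normal((6, 3)) * 2
        tpl = _mol(coords, mid="tpl")
        R = rotator(rng)
        moved = _mol(coords @ R.T + rng.uniform(-4, 4, 3), mid="mv")
        return tpl, moved

    def test_self_alignment(self, rng):
        coords = rng.standard_normal((5, 3))
        tpl = _mol(coords, mid="tpl")
        spec = AlignmentSpec("tpl", {})
        aligned, rmsd = align_to_template([tpl], spec)
        assert rmsd["tpl"] == 0.0
        np.testing.assert_allclose(aligned[0].coords, coords, atol=1e-12)

    def test_rotate_recover(self, rng, rotator):
        tpl, moved = self._pair(rng, rotator)
        spec = AlignmentSpec("tpl", {"mv": [(i, i) for i in range(6)]})
        aligned, rmsd = align_to_template([tpl, moved], spec)
        assert rmsd["mv"] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(aligned[1].coords, tpl.coords, atol=1e-8)

    def test_two_atom_map_rejected(self, rng, rotator):
        tpl, moved = self._pair(rng, rotator)
        spec = AlignmentSpec("tpl", {"mv": [(0, 0), (1, 1)]})
        with pytest.raises(ValueError, match="3"):
            align_to_template([tpl, moved], spec)

    def test_collinear_map_rejected(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
        tpl = _mol(coords, mid="tpl")
        mv = _mol(coords + 1.0, mid="mv")
        spec = AlignmentSpec("tpl", {"mv": [(0, 0), (1, 1), (2, 2)]})
        with pytest.raises(ValueError, match="collinear"):
            align_to_template([tpl, mv], spec)


class TestBuildGrid:
    def test_single_atom_counts(self):
        mol = _mol([[0.0, 0.0, 0.0]])
        grid = build_grid([mol], spacing=2.0, margin=4.0)
        assert grid.shape == (5, 5, 5)
        np.testing.assert_allclose(grid.origin, [-4, -4, -4])

    def test_zero_margin_spans_bbox(self):
        mol = _mol([[0, 0, 0], [3, 1, 2]])
        grid = build_grid([mol], spacing=1.0, margin=0.0)
        np.testing.assert_allclose(grid.origin, [0, 0, 0])
        assert np.all(grid.upper_corner() >= [3, 1, 2])

    def test_union_of_molecules(self):
        a = _mol([[0, 0, 0]], mid="a")
        b = _mol([[10, 0, 0]], mid="b")
        grid = build_grid([a, b], spacing=2.0, margin=2.0)
        assert grid.origin[0] == -2
        assert grid.upper_corner()[0] >= 12

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            build_grid([_mol([[0, 0, 0]])], spacing=0.0)


class TestSimilarityFields:
    def test_atom_at_grid_point(self):
        mol = _mol([[0.0, 0.0, 0.0]], radii=[1.0], charges=[1.0])
        grid = FieldGrid(origin=np.zeros(3), spacing=1.0, shape=(1, 1, 1))
        f = similarity_fields(mol, grid, ProbeParams())
        assert f["S"][0] == -1.0  # w_probe = w_i = 1 exactly at r = 0
        assert f["E"][0] == -1.0

    def test_hand_exponential(self):
        mol = _mol([[2.0, 0.0, 0.0]], radii=[1.0], charges=[1.0])
        grid = FieldGrid(origin=np.zeros(3), spacing=1.0, shape=(1, 1, 1))
        f = similarity_fields(mol, grid, ProbeParams(alpha=0.3))
        assert f["S"][0] == pytest.approx(-np.exp(-1.2), abs=1e-12)

    def test_direct_summation_oracle(self, rng):
        from qsarkit.elements import ACCEPTOR_W, DONOR_W, HYDROPHOBIC_W

        elements = ["C", "N", "O", "H", "S"]
        mol = _mol(
            rng.standard_normal((5, 3)) * 2,
            radii=rng.uniform(1.2, 2.0, 5),
            charges=rng.uniform(-0.5, 0.5, 5),
            elements=elements,
        )
        grid = build_grid([mol], spacing=2.0, margin=3.0)
        probe = ProbeParams(alpha=0.3)
        f = similarity_fields(mol, grid, probe)
        pts = grid.points()
        tables = {"H": HYDROPHOBIC_W, "D": DONOR_W, "A": ACCEPTOR_W}
        for qi in range(grid.n_points):
            acc = {k: 0.0 for k in FIELD_NAMES}
            for ai in range(5):
                r2 = float(np.sum((pts[qi] - mol.coords[ai]) ** 2))
                g = np.exp(-probe.alpha * r2)
                acc["S"] += -probe.weights["S"] * mol.radii[ai] ** 3 * g
                acc["E"] += -probe.weights["E"] * mol.charges[ai] * g
                for k, tab in tables.items():
                    acc[k] += -probe.weights[k] * tab[elements[ai]] * g
            for k in FIELD_NAMES:
                assert f[k][qi] == pytest.approx(acc[k], abs=1e-12)

    def test_rotation_invariance(self, rng, rotator):
        mol = _mol(rng.standard_normal((4, 3)), charges=rng.uniform(-1, 1, 4))
        grid = build_grid([mol], spacing=2.0, margin=3.0)
        pts = grid.points()
        R = rotator(rng)
        mol_rot = mol.with_coords(mol.coords @ R.T)
        # rotate the grid points along with the molecule
        f0 = similarity_fields(mol, grid)
        d2 = np.sum(((pts @ R.T)[:, None, :] - mol_rot.coords[None, :, :]) ** 2, axis=2)
        g = np.exp(-0.3 * d2)
        s_rot = -(1.0) * (g @ (mol.radii**3))
        np.testing.assert_allclose(f0["S"], s_rot, atol=1e-10)

    def test_missing_charges_rejected(self):
        mol = Molecule(id="m", elements=["C"], coords=[[0, 0, 0]], radii=[1.7])
        grid = FieldGrid(origin=np.zeros(3), spacing=1.0, shape=(1, 1, 1))
        with pytest.raises(ValueError, match="charges"):
            similarity_fields(mol, grid)


class TestPls:
    def test_full_rank_equals_ols(self, rng):
        n, p = 20, 5
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        m = pls_fit(X, y, ncomp=p)
        A = np.column_stack([np.ones(n), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(m.predict(X), A @ beta, atol=1e-8)

    def test_univariate_equals_simple_regression(self, rng):
        x = rng.standard_normal(15)
        y = 2.0 * x + 1.0 + 0.1 * rng.standard_normal(15)
        m = pls_fit(x[:, None], y, 1)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        np.testing.assert_allclose(m.predict(x[:, None]), slope * x + intercept, atol=1e-10)

    def test_zero_x_predicts_mean(self, rng):
        X = np.zeros((10, 4))
        y = rng.standard_normal(10)
        m = pls_fit(X, y, 1)
        np.testing.assert_allclose(m.predict(X), y.mean(), atol=1e-12)

    def test_against_independent_pls(self, rng):
        # second, independent PLS formulation (library NIPALS)
        for _ in range(10):
            n, p = 16, 7
            X = rng.standard_normal((n, p))
            y = X @ rng.standard_normal(p) + 0.2 * rng.standard_normal(n)
            for nc in (1, 2, 4):
                ours = pls_fit(X, y, nc)
                ref = PLSRegression(n_components=nc, scale=False).fit(X, y)
                np.testing.assert_allclose(
                    ours.predict(X), ref.predict(X).ravel(), atol=1e-10
                )

    def test_ncomp_too_large(self, rng):
        with pytest.raises(ValueError):
            pls_fit(rng.standard_normal((5, 3)), rng.standard_normal(5), 10)


class TestLooQ2:
    def test_perfect_relation(self, rng):
        X = rng.standard_normal((15, 2))
        y = X @ [1.0, -1.0] + 2.0
        assert loo_q2(X, y, 2) == pytest.approx(1.0, abs=1e-8)

    def test_mean_only_is_zero(self, rng):
        X = np.zeros((12, 3))
        y = rng.standard_normal(12)
        assert loo_q2(X, y, 1) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle(self, rng):
        for _ in range(5):
            n, p = 12, 4
            X = rng.standard_normal((n, p))
            y = X @ rng.standard_normal(p) + rng.standard_normal(n)
            nc = 2
            press = denom = 0.0
            for i in range(n):
                mask = np.arange(n) != i
                ref = PLSRegression(n_components=nc, scale=False).fit(X[mask], y[mask])
                pred = float(ref.predict(X[i : i + 1]).ravel()[0])
                press += (y[i] - pred) ** 2
                denom += (y[i] - y[mask].mean()) ** 2
            assert loo_q2(X, y, nc) == pytest.approx(1 - press / denom, abs=1e-10)

    def test_q2_not_above_r2(self, rng):
        for _ in range(30):
            n, p = 14, 6
            X = rng.standard_normal((n, p))
            y = X @ rng.standard_normal(p) + rng.standard_normal(n)
            m = pls_fit(X, y, 2)
            assert loo_q2(X, y, 2) <= m.r2 + 1e-12


class TestSelectOnc:
    def test_matches_q2_trace(self, rng):
        X = rng.standard_normal((14, 6))
        y = X @ rng.standard_normal(6) + 0.5 * rng.standard_normal(14)
        onc, q2s = select_onc(X, y, 4)
        assert onc == int(np.argmax(q2s)) + 1
        for a, q in enumerate(q2s, start=1):
            assert q == pytest.approx(loo_q2(X, y, a), abs=1e-12)

    def test_two_latent_factor_recovery(self, rng):
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n, p = 30, 30
            T = r.standard_normal((n, 2))
            P = r.standard_normal((2, p))
            X = T @ P + 0.05 * r.standard_normal((n, p))
            y = T @ np.array([1.5, -1.0]) + 0.25 * r.standard_normal(n)
            onc, _ = select_onc(X, y, 5)
            hits += onc == 2
        assert hits >= 0.9 * n_seeds


class TestContributionsAndMasks:
    @staticmethod
    def _block(rng, n=10, pts=4):
        cols = [f"{k}:{i}" for k in FIELD_NAMES for i in range(pts)]
        return pd.DataFrame(rng.standard_normal((n, len(cols))), columns=cols)

    def test_single_field_dominates(self, rng):
        X = self._block(rng)
        m = pls_fit(X.to_numpy(), rng.standard_normal(10), 1, column_names=list(X.columns))
        m.coef = np.zeros_like(m.coef)
        m.coef[:4] = 1.0  # only steric columns
        contrib = field_contributions(m, X)
        assert contrib["S"] == pytest.approx(100.0)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-9)

    def test_direct_formula_oracle(self, rng):
        X = self._block(rng)
        y = rng.standard_normal(10)
        m = pls_fit(X.to_numpy(), y, 2, column_names=list(X.columns))
        contrib = field_contributions(m, X)
        sds = X.to_numpy().std(axis=0, ddof=1)
        scores = np.abs(m.coef) * sds
        for fi, k in enumerate(FIELD_NAMES):
            expected = 100 * scores[fi * 4 : (fi + 1) * 4].sum() / scores.sum()
            assert contrib[k] == pytest.approx(expected, abs=1e-9)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_coef_error(self, rng):
        X = self._block(rng)
        m = pls_fit(X.to_numpy(), rng.standard_normal(10), 1, column_names=list(X.columns))
        m.coef = np.zeros_like(m.coef)
        with pytest.raises(ValueError):
            field_contributions(m, X)

    def test_column_filter(self, rng):
        X = pd.DataFrame(
            {"a": np.ones(10), "b": rng.standard_normal(10), "c": rng.standard_normal(10) * 5}
        )
        mask = column_filter(X, 0.5)
        assert not mask[0] and mask[2]
        assert column_filter(X, 0.0).all()
        with pytest.raises(ValueError):
            column_filter(X, 1e9)

    def test_contour_masks(self, rng):
        X = self._block(rng, n=12, pts=10)
        y = rng.standard_normal(12)
        m = pls_fit(X.to_numpy(), y, 2, column_names=list(X.columns))
        masks = contour_masks(m, X, 80, 20)
        sds = X.to_numpy().std(axis=0, ddof=1)
        v = m.coef * sds
        for fi, k in enumerate(FIELD_NAMES):
            vk = v[fi * 10 : (fi + 1) * 10]
            assert masks[k]["favored"].sum() == np.sum(vk > np.percentile(vk, 80))
            assert masks[k]["disfavored"].sum() == np.sum(vk < np.percentile(vk, 20))

    def test_uniform_field_empty_masks(self, rng):
        X = self._block(rng, n=12, pts=6)
        m = pls_fit(X.to_numpy(), rng.standard_normal(12), 1, column_names=list(X.columns))
        m.coef = np.ones_like(m.coef)
        Xu = X.copy()
        Xu.loc[:, :] = rng.standard_normal(12)[:, None]  # all columns identical
        masks = contour_masks(m, Xu)
        for k in FIELD_NAMES:
            assert masks[k]["favored"].sum() == 0
            assert masks[k]["disfavored"].sum() == 0


class TestEndToEnd:
    def test_generative_recovery(self):
        mols, y, truth = gen_toy_molecules(ToyMoleculeSpec(n=20, seed=5))
        model = fit_comsia(mols, y, max_comp=4)
        assert model.pls.r2 >= 0.99
        top2 = sorted(model.pls.contributions, key=model.pls.contributions.get)[-2:]
        assert set(top2) == {"S", "E"}

    def test_training_molecule_prediction(self):
        mols, y, _ = gen_toy_molecules(ToyMoleculeSpec(n=12, seed=2))
        model = fit_comsia(mols, y, max_comp=3)
        fitted = model.pls.predict(
            field_block(mols, model.grid, model.probe).to_numpy()[:, model.column_mask]
        )
        for i, mol in enumerate(mols):
            assert predict_comsia(model, mol) == pytest.approx(fitted[i], abs=1e-10)

    def test_duplicate_molecule_same_prediction(self):
        mols, y, _ = gen_toy_molecules(ToyMoleculeSpec(n=8, seed=3))
        model = fit_comsia(mols, y, max_comp=2)
        dup = mols[0].with_coords(mols[0].coords)
        dup.id = "dup"
        assert predict_comsia(model, dup) == predict_comsia(model, mols[0])

    def test_extrapolation_warning(self):
        mols, y, _ = gen_toy_molecules(ToyMoleculeSpec(n=8, seed=4))
        model = fit_comsia(mols, y, max_comp=2)
        far = mols[0].with_coords(mols[0].coords + 100.0)
        with pytest.warns(UserWarning, match="outside"):
            predict_comsia(model, far)

    def test_heldout_prediction_quality(self):
        mols, y, _ = gen_toy_molecules(ToyMoleculeSpec(n=30, seed=6))
        train, test = mols[:20], mols[20:]
        model = fit_comsia(train, y[:20], max_comp=4)
        preds = np.array([predict_comsia(model, m) for m in test])
        press = np.sum((y[20:] - preds) ** 2)
        tss = np.sum((y[20:] - y[:20].mean()) ** 2)
        assert 1 - press / tss >= 0.5
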