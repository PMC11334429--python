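import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from manglift import PathModel, effects_decomposition, fit_plspm


def two_latent_data(seed=0, n=200, r=0.6):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = r * x + np.sqrt(1 - r**2) * rng.normal(size=n)
    return pd.DataFrame({"x": x, "y": y})


def two_latent_model(**kw):
    return PathModel(
        latent_names=["X", "Y"], paths=[("X", "Y")],
        blocks={"X": ["x"], "Y": ["y"]}, bootstrap_n=0, **kw,
    )


class TestClosedForms:
    def test_single_indicator_path_equals_pearson_r(self):
        data = two_latent_data(seed=1)
        res = fit_plspm(data, two_latent_model())
        r = stats.pearsonr(data["x"], data["y"])[0]
        assert res.path_coefficients.loc["Y", "X"] == pytest.approx(r, abs=1e-10)
        np.testing.assert_allclose(res.loadings.values, 1.0, atol=1e-10)

    def test_chain_total_effect_is_product(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = -0.4 * m + rng.normal(size=n)
        data = pd.DataFrame({"x": x, "m": m, "y": y})
        model = PathModel(
            latent_names=["X", "M", "Y"], paths=[("X", "M"), ("M", "Y")],
            blocks={"X": ["x"], "M": ["m"], "Y": ["y"]}, bootstrap_n=0,
        )
        res = fit_plspm(data, model)
        b_xm = res.path_coefficients.loc["M", "X"]
        b_my = res.path_coefficients.loc["Y", "M"]
        eff = res.effects.set_index(["from", "to"])
        assert eff.loc[("X", "Y"), "total"] == pytest.approx(b_xm * b_my, abs=1e-12)
        assert eff.loc[("X", "Y"), "direct"] == 0

    def test_single_indicator_model_equals_standardized_ols(self):
        rng = np.random.default_rng(3)
        n = 150
        a = rng.normal(size=n)
        b = 0.3 * a + rng.normal(size=n)
        y = 0.5 * a - 0.6 * b + rng.normal(size=n)
        data = pd.DataFrame({"a": a, "b": b, "y": y})
        model = PathModel(
            latent_names=["A", "B", "Y"], paths=[("A", "B"), ("A", "Y"), ("B", "Y")],
            blocks={"A": ["a"], "B": ["b"], "Y": ["y"]}, bootstrap_n=0,
        )
        res = fit_plspm(data, model)
        z = (data - data.mean()) / data.std(ddof=0)
        x = z[["a", "b"]].values
        beta = np.linalg.solve(x.T @ x, x.T @ z["y"].values)
        assert res.path_coefficients.loc["Y", "A"] == pytest.approx(beta[0], abs=1e-8)
        assert res.path_coefficients.loc["Y", "B"] == pytest.approx(beta[1], abs=1e-8)

    def test_gof_formula_and_perfect_chain(self):
        # noise-free single-indicator chain: loadings 1, R² = 1, GoF = 1
        n = 50
        x = np.linspace(-2, 2, n)
        data = pd.DataFrame({"x": x, "m": 2 * x, "y": -x})
        model = PathModel(
            latent_names=["X", "M", "Y"], paths=[("X", "M"), ("M", "Y")],
            blocks={"X": ["x"], "M": ["m"], "Y": ["y"]}, bootstrap_n=0,
        )
        res = fit_plspm(data, model)
        assert res.gof == pytest.approx(1.0, abs=1e-9)
        data2 = two_latent_data(seed=4, r=0.5)
        res2 = fit_plspm(data2, two_latent_model())
        expect = np.sqrt(res2.communalities.mean() * res2.r_squared.mean())
        assert res2.gof == pytest.approx(expect, abs=1e-12)


class TestInvariants:
    def test_latent_scores_unit_variance(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(size=(120, 6)), columns=list("abcdef"))
        model = PathModel(
            latent_names=["L1", "L2"], paths=[("L1", "L2")],
            blocks={"L1": ["a", "b", "c"], "L2": ["d", "e", "f"]}, bootstrap_n=0,
        )
        res = fit_plspm(data, model)
        np.testing.assert_allclose(res.scores.std(ddof=0).values, 1.0, atol=1e-9)

    def test_sign_flip_negates_incident_paths(self):
        rng = np.random.default_rng(6)
        n = 200
        lx = rng.normal(size=n)
        ly = 0.6 * lx + 0.8 * rng.normal(size=n)
        data = pd.DataFrame(
            {
                "x1": 0.8 * lx + 0.6 * rng.normal(size=n),
                "x2": 0.7 * lx + 0.7 * rng.normal(size=n),
                "y1": 0.8 * ly + 0.6 * rng.normal(size=n),
                "y2": 0.7 * ly + 0.7 * rng.normal(size=n),
            }
        )
        model = PathModel(
            latent_names=["X", "Y"], paths=[("X", "Y")],
            blocks={"X": ["x1", "x2"], "Y": ["y1", "y2"]}, bootstrap_n=0,
        )
        res = fit_plspm(data, model)
        flipped = data.copy()
        flipped[["x1", "x2"]] *= -1
        res2 = fit_plspm(flipped, model)
        assert res2.path_coefficients.loc["Y", "X"] == pytest.approx(
            -res.path_coefficients.loc["Y", "X"], abs=1e-8
        )

    def test_cyclic_or_unknown_paths_rejected(self):
        with pytest.raises(ValueError):
            PathModel(["A", "B"], [("B", "A")], {"A": ["a"], "B": ["b"]})
        with pytest.raises(ValueError):
            PathModel(["A", "B"], [("A", "C")], {"A": ["a"], "B": ["b"]})
        with pytest.raises(ValueError):
            PathModel(["A", "B"], [("A", "B")], {"A": ["a", "x"], "B": ["x"]})


class TestEffects:
    def test_random_dag_matches_path_enumeration(self):
        rng = np.random.default_rng(7)
        n_lat = 5
        names = [f"L{i}" for i in range(n_lat)]
        b = np.zeros((n_lat, n_lat))
        edges = []
        for j, i in itertools.combinations(range(n_lat), 2):
            if rng.random() < 0.6:
                b[i, j] = rng.normal()
                edges.append((j, i))
        eff = effects_decomposition(b, names)

        # brute-force: enumerate every directed path
        def all_paths_total(src, dst):
            total = 0.0
            stack = [(src, 1.0)]
            while stack:
                node, weight = stack.pop()
                for (a, c) in edges:
                    if a == node:
                        w = weight * b[c, a]
                        if c == dst:
                            total += w
                        else:
                            stack.append((c, w))
            return total

        table = eff.set_index(["from", "to"]) if len(eff) else None
        for j in range(n_lat):
            for i in range(n_lat):
                if i == j:
                    continue
                expect = all_paths_total(j, i)
                if table is not None and (names[j], names[i]) in table.index:
                    assert table.loc[(names[j], names[i]), "total"] == pytest.approx(
                        expect, abs=1e-10
                    )
                else:
                    assert expect == pytest.approx(0.0, abs=1e-12)

    def test_disconnected_pair_zero(self):
        b = np.zeros((3, 3))
        b[1, 0] = 0.5  # L0 -> L1 only
        eff = effects_decomposition(b, ["L0", "L1", "L2"]).set_index(["from", "to"])
        assert ("L0", "L2") not in eff.index


class TestRecovery:
    # six indicators per block: composite reliability 6·0.64/(6·0.64+0.36)
    # ≈ 0.91 at loading 0.8, keeping composite attenuation of the path
    # estimates well inside the ±0.1 recovery band
    K = 6

    @classmethod
    def simulate_known_model(cls, rng, n=500, loading=0.8, paths=(0.5, -0.3)):
        lx = rng.normal(size=n)
        lm = paths[0] * lx + np.sqrt(1 - paths[0] ** 2) * rng.normal(size=n)
        ly = paths[1] * lm + np.sqrt(1 - paths[1] ** 2) * rng.normal(size=n)
        noise = np.sqrt(1 - loading**2)
        cols = {}
        for name, lv in (("x", lx), ("m", lm), ("y", ly)):
            for k in range(cls.K):
                cols[f"{name}{k}"] = loading * lv + noise * rng.normal(size=n)
        return pd.DataFrame(cols)

    @classmethod
    def chain_model(cls, bootstrap_n=0, seed=0):
        return PathModel(
            latent_names=["X", "M", "Y"], paths=[("X", "M"), ("M", "Y")],
            blocks={
                "X": [f"x{k}" for k in range(cls.K)],
                "M": [f"m{k}" for k in range(cls.K)],
                "Y": [f"y{k}" for k in range(cls.K)],
            },
            bootstrap_n=bootstrap_n, seed=seed,
        )

    def test_known_paths_recovered(self):
        rng = np.random.default_rng(10)
        res = fit_plspm(self.simulate_known_model(rng), self.chain_model())
        assert abs(res.path_coefficients.loc["M", "X"] - 0.5) < 0.1
        assert abs(res.path_coefficients.loc["Y", "M"] - (-0.3)) < 0.1

    def test_bootstrap_flags_true_path(self):
        rng = np.random.default_rng(11)
        data = self.simulate_known_model(rng)
        res = fit_plspm(data, self.chain_model(bootstrap_n=100, seed=1))
        assert res.boot_p.loc["M", "X"] < 0.01
        assert res.boot_se.loc["M", "X"] > 0
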