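"""PLS path engine: analytic reductions, recovery, effects, bootstrap, SRMR."""

import numpy as np
import pandas as pd
import pytest

from ecostoich.path_model import (
    PathModelError,
    PathModelSpec,
    bootstrap_paths,
    fit_pls,
    srmr,
    study_path_spec,
    total_effects,
)


def two_block_spec():
    return PathModelSpec(blocks={"A": ["a1"], "B": ["b1"]},
                         paths=[("A", "B")])


def simulate_reflective(spec, inner_coefs, loadings, n, rng):
    """Independent generator: latents from the structural equations,
    indicators as loading * latent + noise, all standardized."""
    order = spec.topological_order()
    latents = {}
    for b in order:
        preds = spec.predecessors(b)
        s = np.zeros(n)
        for p in preds:
            s = s + inner_coefs[(p, b)] * latents[p]
        explained = np.var(s)
        noise_sd = np.sqrt(max(1 - explained, 0.05))
        s = s + rng.normal(0, noise_sd, n)
        latents[b] = (s - s.mean()) / s.std()
    data = {}
    for b, inds in spec.blocks.items():
        for i in inds:
            lam = loadings[i]
            x = lam * latents[b] + np.sqrt(1 - lam**2) * rng.normal(size=n)
            data[i] = x
    return pd.DataFrame(data), latents


class TestFitPls:
    def test_single_indicator_path_equals_pearson_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=300)
        b = 0.6 * a + rng.normal(size=300)
        df = pd.DataFrame({"a1": a, "b1": b})
        res = fit_pls(df, two_block_spec())
        r = np.corrcoef(a, b)[0, 1]
        assert res.path_coefficients.loc["A", "B"] == pytest.approx(r, abs=1e-10)
        assert res.r2["B"] == pytest.approx(r**2, abs=1e-10)

    def test_chain_recovers_known_coefficients(self):
        rng = np.random.default_rng(7)
        n = 5000
        a = rng.normal(size=n)
        b = 0.6 * a + rng.normal(size=n)
        c = 0.5 * b + rng.normal(size=n)
        df = pd.DataFrame({"a1": a, "b1": b, "c1": c})
        spec = PathModelSpec(
            blocks={"A": ["a1"], "B": ["b1"], "C": ["c1"]},
            paths=[("A", "B"), ("B", "C")],
        )
        res = fit_pls(df, spec)
        # standardized truths: 0.6/sqrt(1.36), 0.5*sd(B)/sd(C)
        t_ab = 0.6 / np.sqrt(1.36)
        t_bc = 0.5 * np.sqrt(1.36) / np.sqrt(0.25 * 1.36 + 1)
        assert res.path_coefficients.loc["A", "B"] == pytest.approx(t_ab, abs=0.05)
        assert res.path_coefficients.loc["B", "C"] == pytest.approx(t_bc, abs=0.05)

    def test_latent_scores_standardized(self):
        rng = np.random.default_rng(1)
        spec = study_path_spec("C")
        loadings = {i: 0.9 for b in spec.blocks.values() for i in b}
        coefs = {e: 0.4 for e in spec.paths}
        df, _ = simulate_reflective(spec, coefs, loadings, 400, rng)
        res = fit_pls(df, spec)
        for b in spec.blocks:
            s = res.scores[b]
            assert s.mean() == pytest.approx(0.0, abs=1e-10)
            assert s.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
            # sign convention: latent tracks its first indicator
            first = spec.blocks[b][0]
            assert np.corrcoef(s, df[first])[0, 1] > 0

    def test_scale_invariance_of_standardized_outputs(self):
        rng = np.random.default_rng(2)
        spec = study_path_spec("P")
        loadings = {i: 0.85 for b in spec.blocks.values() for i in b}
        coefs = {e: 0.3 for e in spec.paths}
        df, _ = simulate_reflective(spec, coefs, loadings, 300, rng)
        res = fit_pls(df, spec)
        df2 = df.copy()
        df2["BG"] = df2["BG"] * 1000.0
        res2 = fit_pls(df2, spec)
        pd.testing.assert_frame_equal(res.path_coefficients,
                                      res2.path_coefficients)

    def test_collinear_indicators_rejected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=100)
        df = pd.DataFrame({"a1": a, "a2": 2 * a, "b1": rng.normal(size=100)})
        spec = PathModelSpec(blocks={"A": ["a1", "a2"], "B": ["b1"]},
                             paths=[("A", "B")])
        with pytest.raises(PathModelError, match="collinear"):
            fit_pls(df, spec)

    def test_constant_indicator_rejected(self):
        df = pd.DataFrame({"a1": np.ones(50),
                           "b1": np.random.default_rng(4).normal(size=50)})
        with pytest.raises(PathModelError, match="constant indicator"):
            fit_pls(df, two_block_spec())


class TestTotalEffects:
    def make(self, edges, blocks):
        P = pd.DataFrame(0.0, index=blocks, columns=blocks)
        for (s, t), c in edges.items():
            P.loc[s, t] = c
        return P

    def test_indirect_product_rule(self):
        P = self.make({("a", "b"): 0.5, ("b", "c"): 0.4}, list("abc"))
        T = total_effects(P)
        assert T.loc["a", "c"] == pytest.approx(0.20, abs=1e-12)

    def test_direct_plus_indirect_sum_rule(self):
        P = self.make({("a", "b"): 0.5, ("b", "c"): 0.4, ("a", "c"): 0.3},
                      list("abc"))
        assert total_effects(P).loc["a", "c"] == pytest.approx(0.50, abs=1e-12)

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        blocks = list("abcde")
        edges = {}
        for i in range(5):
            for j in range(i + 1, 5):  # upper-triangular => acyclic
                if rng.random() < 0.7:
                    edges[(blocks[i], blocks[j])] = rng.normal()
        T = total_effects(self.make(edges, blocks))

        def enumerate_paths(s, t):
            total = 0.0
            stack = [(s, 1.0)]
            while stack:
                node, prod = stack.pop()
                for (u, v), c in edges.items():
                    if u == node:
                        if v == t:
                            total += prod * c
                        else:
                            stack.append((v, prod * c))
            return total

        for s in blocks:
            for t in blocks:
                if s != t:
                    assert T.loc[s, t] == pytest.approx(
                        enumerate_paths(s, t), abs=1e-12)

    def test_cycle_detected(self):
        P = self.make({("a", "b"): 0.5, ("b", "a"): 0.5}, list("ab"))
        with pytest.raises(PathModelError, match="cycle"):
            total_effects(P)
        with pytest.raises(PathModelError, match="cycle"):
            PathModelSpec(blocks={"a": ["x"], "b": ["y"]},
                          paths=[("a", "b"), ("b", "a")]).topological_order()


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"a1": rng.normal(size=120),
                           "b1": rng.normal(size=120)})
        a = bootstrap_paths(df, two_block_spec(), n_boot=100, seed=9)
        b = bootstrap_paths(df, two_block_spec(), n_boot=100, seed=9)
        pd.testing.assert_frame_equal(a["paths"], b["paths"])
        pd.testing.assert_frame_equal(a["total_effects"], b["total_effects"])

    def test_strong_effect_is_significant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=200)
        b = 0.8 * a + 0.6 * rng.normal(size=200)
        df = pd.DataFrame({"a1": a, "b1": b})
        res = bootstrap_paths(df, two_block_spec(), n_boot=200, seed=10)
        assert res["paths"]["p"].iloc[0] < 0.001

    def test_minimum_resamples_enforced(self):
        df = pd.DataFrame({"a1": np.arange(50.0), "b1": np.arange(50.0) ** 2})
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_paths(df, two_block_spec(), n_boot=50)


class TestSrmr:
    def test_rank_one_block_reproduces_its_correlations(self):
        # indicators that are noisy copies of one factor with equal loadings
        rng = np.random.default_rng(11)
        n = 20000
        f = rng.normal(size=n)
        g = 0.5 * f + rng.normal(size=n)
        lam = 0.8
        df = pd.DataFrame({
            "a1": lam * f + np.sqrt(1 - lam**2) * rng.normal(size=n),
            "a2": lam * f + np.sqrt(1 - lam**2) * rng.normal(size=n),
            "b1": g,
        })
        spec = PathModelSpec(blocks={"A": ["a1", "a2"], "B": ["b1"]},
                             paths=[("A", "B")])
        res = fit_pls(df, spec)
        assert srmr(res, df) < 0.05

    def test_true_factor_structure_fits_well(self):
        # data generated from the study topology with strong reflective
        # loadings should leave little correlation unexplained
        rng = np.random.default_rng(12)
        spec = study_path_spec("C")
        loadings = {i: 0.9 for b in spec.blocks.values() for i in b}
        coefs = {e: 0.35 for e in spec.paths}
        df, _ = simulate_reflective(spec, coefs, loadings, 4000, rng)
        res = fit_pls(df, spec)
        assert srmr(res, df) < 0.05

    def test_structure_violation_inflates_srmr(self):
        # a block whose indicators are not one-factor (two near-duplicates
        # plus an unrelated one) cannot be reproduced
        rng = np.random.default_rng(13)
        n = 2000
        f = rng.normal(size=n)
        a1 = f + 0.2 * rng.normal(size=n)
        a2 = f + 0.2 * rng.normal(size=n)
        a3 = 0.2 * f + rng.normal(size=n)
        b1 = 0.5 * f + rng.normal(size=n)
        df = pd.DataFrame({"a1": a1, "a2": a2, "a3": a3, "b1": b1})
        spec = PathModelSpec(blocks={"A": ["a1", "a2", "a3"], "B": ["b1"]},
                             paths=[("A", "B")])
        good = fit_pls(df, spec)
        value = srmr(good, df)
        assert value >= 0
        rng2 = np.random.default_rng(14)
        clean, _ = simulate_reflective(spec, {("A", "B"): 0.5},
                                       {"a1": 0.9, "a2": 0.9, "a3": 0.9,
                                        "b1": 1.0}, 2000, rng2)
        assert value > srmr(fit_pls(clean, spec), clean)

    def test_unfitted_model_rejected(self, study_frame):
        with pytest.raises(PathModelError, match="not fitted"):
            srmr(None, study_frame)


class TestSpecValidation:
    def test_unknown_block_in_path(self):
        with pytest.raises(PathModelError, match="unknown block"):
            PathModelSpec(blocks={"A": ["a1"]}, paths=[("A", "Z")]).validate()

    def test_orphan_block(self):
        with pytest.raises(PathModelError, match="not on any path"):
            PathModelSpec(blocks={"A": ["a1"], "B": ["b1"], "C": ["c1"]},
                          paths=[("A", "B")]).validate()

    def test_missing_indicator_columns(self, study_frame):
        spec = PathModelSpec(blocks={"A": ["nope"], "B": ["BG"]},
                             paths=[("A", "B")])
        with pytest.raises(PathModelError, match="missing"):
            fit_pls(study_frame, spec)

    def test_study_specs_fit_the_synthetic_study(self, study_frame):
        for target, endpoint in (("C", "C_limitation"), ("P", "P_limitation")):
            res = fit_pls(study_frame, study_path_spec(target))
            assert endpoint in res.r2
            assert 0 <= res.r2[endpoint] <= 1
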