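"""Planar filtered networks, permutation-FDR edges, module detection, and
module/hub/eigengene significance machinery."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from songcircuit.network import (
    GeneNetwork,
    ModuleSet,
    correlation_fdr,
    detect_modules,
    hub_genes,
    module_coefficient_test,
    module_eigengene,
    module_preservation,
    planar_filtered_network,
    select_variable_genes,
)


def complete_edges(n, rng):
    nodes = [f"g{i:02d}" for i in range(n)]
    rows = [
        {"gene_a": a, "gene_b": b, "r": rng.uniform(-1, 1)}
        for a, b in itertools.combinations(nodes, 2)
    ]
    return pd.DataFrame(rows)


class TestSelectVariableGenes:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(0, 1, (50, 20)),
                            index=[f"g{i}" for i in range(50)])
        expr.loc["g0"] = 3.14
        sel = select_variable_genes(expr, n=49)
        assert "g0" not in sel

    def test_n_equal_total_returns_all_varying(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 1, (30, 10)),
                            index=[f"g{i}" for i in range(30)])
        assert len(select_variable_genes(expr, n=30)) == 30

    def test_planted_overdispersion_recovered(self):
        # count-like data with a mean-variance trend; planted genes have
        # 10x the baseline NB dispersion
        rng = np.random.default_rng(2)
        n_genes, n_planted, n_samples = 300, 30, 40
        means = rng.lognormal(3, 1, n_genes)
        disp = np.full(n_genes, 0.05)
        disp[:n_planted] = 0.5
        lam = rng.gamma(1 / disp[:, None], (means * disp)[:, None],
                        (n_genes, n_samples))
        counts = rng.poisson(lam)
        expr = pd.DataFrame(np.log1p(counts),
                            index=[f"g{i:03d}" for i in range(n_genes)])
        sel = select_variable_genes(expr, n=n_planted)
        planted = {f"g{i:03d}" for i in range(n_planted)}
        assert len(planted & set(sel)) >= 0.9 * n_planted


class TestCorrelationFDR:
    def test_duplicated_gene_always_retained(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(0, 1, (10, 12)),
                            index=[f"g{i}" for i in range(10)])
        expr.loc["g1"] = expr.loc["g0"]  # r = 1 pair
        edges = correlation_fdr(expr, n_perm=30, seed=1)
        pairs = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
        assert ("g0", "g1") in pairs or ("g1", "g0") in pairs

    def test_null_matrix_retains_few_edges(self):
        rng = np.random.default_rng(1)
        retained_frac = []
        for rep in range(5):
            expr = pd.DataFrame(rng.normal(0, 1, (30, 20)),
                                index=[f"g{i}" for i in range(30)])
            edges = correlation_fdr(expr, n_perm=30, seed=rep)
            retained_frac.append(len(edges) / (30 * 29 / 2))
        # under independence, retention stays near/below the FDR target
        assert np.mean(retained_frac) < 0.1

    def test_matches_exhaustive_enumeration_small(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(0, 1, (5, 6)),
                            index=[f"g{i}" for i in range(5)])
        expr.loc["g1"] = expr.loc["g0"] + rng.normal(0, 0.01, 6)
        got = correlation_fdr(expr, fdr=0.05, exhaustive=True)

        # independent enumeration of the same estimand
        X = expr.to_numpy()
        Z = X - X.mean(axis=1, keepdims=True)
        Z = Z / np.sqrt((Z**2).sum(axis=1, keepdims=True))
        obs = np.abs(np.corrcoef(X)[np.triu_indices(5, 1)])
        thresholds = np.linspace(0.0, 1.0, 101)[1:]
        perm_counts = np.zeros(len(thresholds))
        perms = list(itertools.permutations(range(6)))
        for pi in perms:
            M = Z @ Z[:, list(pi)].T
            pc = np.abs(M[np.triu_indices(5, 1)])
            perm_counts += [(pc >= t).sum() for t in thresholds]
        perm_counts /= len(perms)
        obs_counts = np.array([(obs >= t).sum() for t in thresholds])
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr_curve = np.where(obs_counts > 0, perm_counts / obs_counts, 0)
        ok = np.where((fdr_curve < 0.05) & (obs_counts > 0))[0]
        expected_n = 0 if len(ok) == 0 else int((obs >= thresholds[ok[0]]).sum())
        assert len(got) == expected_n

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            correlation_fdr(expr)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(0, 1, (20, 10)),
                            index=[f"g{i}" for i in range(20)])
        expr.iloc[:5] = expr.iloc[0].to_numpy() + rng.normal(0, 0.2, (5, 10))
        loose = correlation_fdr(expr, n_perm=30, fdr=0.2, seed=0)
        tight = correlation_fdr(expr, n_perm=30, fdr=0.02, seed=0)
        assert len(tight) <= len(loose)


class TestPlanarFilteredNetwork:
    def test_k4_fully_kept(self):
        rng = np.random.default_rng(0)
        net = planar_filtered_network(complete_edges(4, rng))
        assert net.graph.number_of_edges() == 6

    def test_k5_planar_bound(self):
        rng = np.random.default_rng(1)
        net = planar_filtered_network(complete_edges(5, rng))
        assert net.graph.number_of_edges() == 9  # 3(n-2)

    @pytest.mark.parametrize("n", [5, 10, 50])
    def test_complete_graph_reaches_bound(self, n):
        rng = np.random.default_rng(n)
        net = planar_filtered_network(complete_edges(n, rng))
        assert net.graph.number_of_edges() == 3 * (n - 2)
        assert nx.check_planarity(net.graph)[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_greedy_oracle(self, seed):
        """Same greedy estimand, independently coded insertion loop."""
        rng = np.random.default_rng(seed)
        edges = complete_edges(10, rng)
        net = planar_filtered_network(edges)

        df = edges.copy()
        df["w"] = df["r"].abs()
        df = df.sort_values(["w", "gene_a", "gene_b"],
                            ascending=[False, True, True], kind="stable")
        G = nx.Graph()
        for _, row in df.iterrows():
            H = G.copy()
            H.add_edge(row["gene_a"], row["gene_b"])
            if nx.is_planar(H):
                G = H
        assert set(map(frozenset, net.graph.edges())) == set(
            map(frozenset, G.edges())
        )


def two_clique_network(rng, n_per=12, between=0):
    """Two dense cliques, optionally a few weak bridges."""
    nodes_a = [f"a{i}" for i in range(n_per)]
    nodes_b = [f"b{i}" for i in range(n_per)]
    rows = []
    for grp in (nodes_a, nodes_b):
        for x, y in itertools.combinations(grp, 2):
            rows.append({"gene_a": x, "gene_b": y, "r": rng.uniform(0.7, 0.9)})
    for i in range(between):
        rows.append({"gene_a": nodes_a[i], "gene_b": nodes_b[i],
                     "r": rng.uniform(0.05, 0.1)})
    return planar_filtered_network(pd.DataFrame(rows))


class TestDetectModules:
    def test_two_disconnected_cliques_recovered(self):
        rng = np.random.default_rng(0)
        net = two_clique_network(rng)
        mods = detect_modules(net, scales=(1.0,), min_size=5, seed=0)
        parts = sorted(
            [tuple(sorted(m.genes)) for m in mods], key=lambda t: t[0]
        )
        assert len(parts) == 2
        assert all(g.startswith("a") for g in parts[0])
        assert all(g.startswith("b") for g in parts[1])

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        net = two_clique_network(rng, between=3)
        a = detect_modules(net, seed=5)
        b = detect_modules(net, seed=5)
        assert {m.module_id: m.genes for m in a} == {
            m.module_id: m.genes for m in b
        }

    def test_planted_partition_high_ari(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(2)
        groups = {f"g{i:03d}": i // 25 for i in range(100)}
        rows = []
        for x, y in itertools.combinations(groups, 2):
            r = rng.uniform(0.7, 0.9) if groups[x] == groups[y] else (
                rng.uniform(0.05, 0.15))
            rows.append({"gene_a": x, "gene_b": y, "r": r})
        net = planar_filtered_network(pd.DataFrame(rows))
        mods = detect_modules(net, scales=(1.0,), min_size=5, seed=0)
        label_map = {}
        for i, m in enumerate(mods):
            for g in m.genes:
                label_map[g] = i
        shared = [g for g in groups if g in label_map]
        ari = adjusted_rand_score(
            [groups[g] for g in shared], [label_map[g] for g in shared]
        )
        assert ari > 0.9

    def test_hierarchy_parents_recorded(self):
        rng = np.random.default_rng(3)
        net = two_clique_network(rng, between=3)
        mods = detect_modules(net, scales=(0.5, 2.0), min_size=3, seed=0)
        fine = [m for m in mods if m.scale == 2.0]
        assert fine
        for m in fine:
            assert m.parent is None or m.parent in mods.modules


class TestModuleCoefficientTest:
    def _modules(self, gene_sets):
        from songcircuit.network import Module

        return ModuleSet(
            modules={
                f"M{i}": Module(f"M{i}", set(gs), None, 1.0)
                for i, gs in enumerate(gene_sets)
            }
        )

    def test_all_zero_coefficients_never_flagged(self):
        genes = [f"g{i}" for i in range(100)]
        coefs = pd.Series(0.0, index=genes)
        mods = self._modules([genes[:20]])
        out = module_coefficient_test(mods, coefs, seed=0)
        assert not out["significant"].any()
        assert out["mean_coefficient"].iloc[0] == 0.0

    def test_top_coefficient_module_flagged_high(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(500)]
        coefs = pd.Series(rng.normal(0, 1, 500), index=genes)
        top50 = list(coefs.nlargest(50).index)
        out = module_coefficient_test(self._modules([top50]), coefs, seed=1)
        assert out["significant"].iloc[0]
        assert out["direction"].iloc[0] == "high"

    def test_tiny_module_skipped_with_warning(self):
        coefs = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="skipped"):
            out = module_coefficient_test(
                self._modules([["g0", "g1"]]), coefs, seed=0
            )
        assert out.empty

    def test_random_module_false_flag_rate_near_two_percent(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:04d}" for i in range(1000)]
        coefs = pd.Series(rng.normal(0, 1, 1000), index=genes)
        sets = [list(rng.choice(genes, 30, replace=False)) for _ in range(400)]
        out = module_coefficient_test(self._modules(sets), coefs,
                                      n_draws=100, seed=3)
        rate = out["significant"].mean()
        assert 0.0 < rate < 0.06


def star_plus_background():
    """A 6-node star module (unit weights) inside a low-weight background."""
    rows = [{"gene_a": "hub", "gene_b": f"leaf{i}", "r": 1.0} for i in range(5)]
    for i in range(20):
        rows.append(
            {"gene_a": f"x{i}", "gene_b": f"x{(i + 1) % 20}", "r": 0.1}
        )
    return planar_filtered_network(pd.DataFrame(rows))


class TestHubGenes:
    def test_star_center_is_unique_hub(self):
        from songcircuit.network import Module

        net = star_plus_background()
        mods = ModuleSet(
            modules={"M1": Module("M1", {"hub"} | {f"leaf{i}" for i in range(5)},
                                  None, 1.0)}
        )
        out = hub_genes(net, mods, n_perm=200, seed=0)
        hubs = set(out.loc[out["hub"], "gene"])
        assert hubs == {"hub"}

    def test_exchangeable_weights_give_no_hub(self):
        from songcircuit.network import Module

        rows = [
            {"gene_a": a, "gene_b": b, "r": 0.5}
            for a, b in itertools.combinations([f"g{i}" for i in range(5)], 2)
        ]
        net = planar_filtered_network(pd.DataFrame(rows))
        genes = set(net.graph.nodes)
        mods = ModuleSet(modules={"M1": __import__(
            "songcircuit.network", fromlist=["Module"]
        ).Module("M1", genes, None, 1.0)})
        out = hub_genes(net, mods, n_perm=100, seed=0)
        assert not out["hub"].any()

    def test_matches_exhaustive_weight_permutations(self):
        """Tiny path graph: MC p-values agree with full enumeration."""
        from songcircuit.network import Module

        rows = [
            {"gene_a": "a", "gene_b": "b", "r": 0.9},
            {"gene_a": "b", "gene_b": "c", "r": 0.5},
            {"gene_a": "c", "gene_b": "d", "r": 0.2},
            {"gene_a": "d", "gene_b": "e", "r": 0.1},
        ]
        net = planar_filtered_network(pd.DataFrame(rows))
        module_genes = {"a", "b", "c", "d", "e"}
        mods = ModuleSet(modules={"M1": Module("M1", module_genes, None, 1.0)})
        out = hub_genes(net, mods, n_perm=400, seed=0).set_index("gene")

        weights = [0.9, 0.5, 0.2, 0.1]
        edge_list = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        obs = {g: 0.0 for g in module_genes}
        for (a, b), w in zip(edge_list, weights):
            obs[a] += w
            obs[b] += w
        exact = {}
        perms = list(itertools.permutations(weights))
        for g in module_genes:
            count = 0
            for pw in perms:
                conn = 0.0
                for (a, b), w in zip(edge_list, pw):
                    if g in (a, b):
                        conn += w
                if conn >= obs[g] - 1e-12:
                    count += 1
            exact[g] = (count / len(perms))
        for g in module_genes:
            # MC estimate with pseudocount stays close to the exact tail
            assert out.loc[g, "p"] == pytest.approx(exact[g], abs=0.12)


class TestModuleEigengene:
    def test_perfectly_correlated_module_membership_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 30)
        expr = pd.DataFrame(
            {f"s{i}": base[i] * np.ones(5) for i in range(30)},
            index=[f"g{i}" for i in range(5)],
        )
        expr = expr * np.arange(1, 6)[:, None]  # scaled copies, r = 1
        eig, member = module_eigengene(expr, [f"g{i}" for i in range(5)])
        assert np.allclose(member[[f"g{i}" for i in range(5)]], 1.0)

    def test_outside_independent_gene_low_membership(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 50)
        rows = {f"g{i}": base + rng.normal(0, 0.2, 50) for i in range(8)}
        rows["outsider"] = rng.normal(0, 1, 50)
        expr = pd.DataFrame(rows).T
        expr.columns = [f"s{i}" for i in range(50)]
        eig, member = module_eigengene(expr, [f"g{i}" for i in range(8)])
        assert abs(member["outsider"]) < 0.3

    def test_sign_convention_mean_membership_positive(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 40)
        expr = pd.DataFrame(
            {f"g{i}": -base + rng.normal(0, 0.3, 40) for i in range(6)}
        ).T
        eig, member = module_eigengene(expr, list(expr.index))
        assert member[list(expr.index)].mean() > 0

    def test_eigengene_variance_explained_exceeds_mean_r(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 60)
        expr = pd.DataFrame(
            {f"g{i}": base + rng.normal(0, 0.5, 60) for i in range(10)}
        ).T
        genes = list(expr.index)
        eig, member = module_eigengene(expr, genes)
        var_explained = np.mean(member[genes] ** 2)
        C = np.corrcoef(expr.loc[genes])
        mean_r = C[np.triu_indices(len(genes), 1)].mean()
        assert var_explained >= mean_r

    def test_constant_module_rejected(self):
        expr = pd.DataFrame(np.ones((4, 10)), index=list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            module_eigengene(expr, list("abcd"))


class TestModulePreservation:
    def _planted(self, rng, n_samples=40, coupled=True):
        base = rng.normal(0, 1, n_samples)
        rows = {}
        for i in range(12):
            rows[f"m{i}"] = base + rng.normal(0, 0.4, n_samples) if coupled else (
                rng.normal(0, 1, n_samples))
        for i in range(40):
            rows[f"n{i}"] = rng.normal(0, 1, n_samples)
        return pd.DataFrame(rows).T

    def test_self_preservation_is_maximal(self):
        from songcircuit.network import Module

        rng = np.random.default_rng(0)
        expr = self._planted(rng)
        mods = ModuleSet(
            modules={"M1": Module("M1", {f"m{i}" for i in range(12)}, None, 1.0)}
        )
        out = module_preservation(mods, expr, expr, n_perm=50, seed=1)
        assert out["z_composite"].iloc[0] > 2
        assert out["p"].iloc[0] < 0.05

    def test_shared_module_across_datasets_preserved(self):
        from songcircuit.network import Module

        rng = np.random.default_rng(1)
        ref = self._planted(rng)
        test = self._planted(rng)
        mods = ModuleSet(
            modules={"M1": Module("M1", {f"m{i}" for i in range(12)}, None, 1.0)}
        )
        out = module_preservation(mods, ref, test, n_perm=100, seed=2)
        assert out["p_bonferroni"].iloc[0] < 0.05

    def test_destroyed_structure_not_preserved(self):
        from songcircuit.network import Module

        rng = np.random.default_rng(2)
        ref = self._planted(rng)
        test = self._planted(rng, coupled=False)
        mods = ModuleSet(
            modules={"M1": Module("M1", {f"m{i}" for i in range(12)}, None, 1.0)}
        )
        out = module_preservation(mods, ref, test, n_perm=100, seed=3)
        assert out["p"].iloc[0] > 0.01
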