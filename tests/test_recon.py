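import math

import numpy as np
import pytest
from scipy.stats import poisson

from mlrecon import (
    GeometricModel,
    PoissonModel,
    count_losses,
    enumerate_reconciliations,
    lca_reconciliation,
    log_likelihood,
    parse_newick,
    setting_of,
)
from mlrecon.recon import (
    Reconciliation,
    check_reconciliation,
    setting_log_likelihood,
)

from conftest import random_instance


class TestModels:
    @pytest.mark.parametrize("cls", [PoissonModel, GeometricModel])
    @pytest.mark.parametrize("rate,tau", [(0.1, 1.0), (0.005, 20.0),
                                          (2.0, 3.5)])
    def test_pmf_normalizes(self, cls, rate, tau):
        model = cls(rate)
        total = sum(math.exp(model.log_pmf(tau, d)) for d in range(201))
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("cls", [PoissonModel, GeometricModel])
    def test_invalid_rate(self, cls):
        with pytest.raises(ValueError, match="invalid rate"):
            cls(0.0)

    def test_poisson_matches_scipy(self):
        model = PoissonModel(0.3)
        for tau, d in [(1.0, 0), (5.0, 3), (17.2, 11)]:
            assert model.log_pmf(tau, d) == pytest.approx(
                poisson.logpmf(d, 0.3 * tau), rel=1e-12)

    def test_zero_branch(self):
        model = PoissonModel(0.5)
        assert model.log_pmf(0.0, 0) == 0.0
        assert model.log_pmf(0.0, 3) == -np.inf


class TestLcaReconciliation:
    def test_example_a_setting(self, example_a, species_ab):
        R = lca_reconciliation(example_a, species_ab)
        st = setting_of(R)
        root = species_ab.root
        leaf_a = next(v for v in species_ab.leaves()
                      if species_ab.label(v) == "a")
        leaf_b = next(v for v in species_ab.leaves()
                      if species_ab.label(v) == "b")
        assert (st.dup[root], st.spec[root]) == (1, 2)
        assert (st.dup[leaf_a], st.spec[leaf_a]) == (2, 0)
        assert (st.dup[leaf_b], st.spec[leaf_b]) == (0, 0)

    def test_congruent_pair(self, species_ab):
        G = parse_newick("(a,b);", kind="gene")
        R = lca_reconciliation(G, species_ab)
        assert R.sigma == {G.root}
        assert sum(setting_of(R).dup) == 0

    def test_setting_conserves_events(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            G, S = random_instance(rng)
            st = setting_of(lca_reconciliation(G, S))
            assert st.total() == len(G.leaves()) - 1


class TestLikelihood:
    def test_example_a_value(self, example_a, species_ab):
        """Three Poisson factors: 2, 0 and 1 duplications on unit branches."""
        R = lca_reconciliation(example_a, species_ab)
        got = log_likelihood(species_ab, example_a, R, PoissonModel(0.1),
                             root_length=1.0)
        mu = 0.1
        expected = (poisson.logpmf(2, mu) + poisson.logpmf(0, mu)
                    + poisson.logpmf(1, mu))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(math.log(5e-4) - 0.3, rel=1e-9)

    def test_zero_duplications_closed_form(self):
        S = parse_newick("((a:2,b:3):4,c:5);", kind="species")
        G = parse_newick("((a,b),c);", kind="gene")
        R = lca_reconciliation(G, S)
        rate = 0.07
        got = log_likelihood(S, G, R, PoissonModel(rate), root_length=1.5)
        assert got == pytest.approx(-rate * (2 + 3 + 4 + 5 + 1.5), rel=1e-12)

    def test_edgeless_root_duplications_are_free(self, example_a, species_ab):
        """Without a root edge only the leaf branches contribute."""
        R = lca_reconciliation(example_a, species_ab)
        model = PoissonModel(0.1)
        got = log_likelihood(species_ab, example_a, R, model)
        assert got == pytest.approx(model.log_pmf(1.0, 2)
                                    + model.log_pmf(1.0, 0), rel=1e-12)

    def test_depends_only_on_dup_counts(self, example_a, species_ab):
        """Settings with equal duplication distributions score equally."""
        model = PoissonModel(0.2)
        seen = {}
        for R in enumerate_reconciliations(example_a, species_ab):
            st = setting_of(R)
            ll = log_likelihood(species_ab, example_a, R, model,
                                root_length=1.0)
            ll2 = setting_log_likelihood(species_ab, st, model,
                                         root_length=1.0)
            assert ll == pytest.approx(ll2, rel=1e-12)
            if st.dup in seen:
                assert ll == pytest.approx(seen[st.dup], rel=1e-12)
            seen[st.dup] = ll

    def test_rate_mle_closed_form(self, example_a, species_ab):
        """For a fixed reconciliation the likelihood is unimodal in the rate
        with maximum at (total duplications) / (total branch length)."""
        R = lca_reconciliation(example_a, species_ab)
        lam_hat = 3 / 3.0  # 3 duplications, three unit branches
        grid = np.linspace(0.05, 3.0, 241)
        vals = [log_likelihood(species_ab, example_a, R, PoissonModel(r),
                               root_length=1.0) for r in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(lam_hat, abs=0.02)
        d = np.diff(vals)
        switch = np.sum((d[:-1] > 0) & (d[1:] <= 0))
        assert switch == 1  # unimodal


class TestLosses:
    def test_congruent_no_losses(self, species_ab):
        G = parse_newick("(a,b);", kind="gene")
        assert count_losses(lca_reconciliation(G, species_ab)) == 0

    def test_single_loss_from_root_duplication(self, species_ab):
        """A root duplication with one lineage reaching only species a
        passes the root speciation once without a surviving b copy."""
        G = parse_newick("(a,(a,b));", kind="gene")
        R = lca_reconciliation(G, species_ab)
        assert count_losses(R) == 1

    def test_matches_embedding_walk(self):
        """The arithmetic loss count equals an explicit embedding walk that
        descends every gene edge through the species tree and counts
        speciations passed without an event."""
        rng = np.random.default_rng(5)

        def walk_losses(R):
            G, S = R.G, R.S
            losses = 0

            def descend(u, x):
                # lineage for node u currently entering species node x
                nonlocal losses
                while x != R.m[u]:
                    # speciation at x: continue into the child covering m(u)
                    nxt = next(c for c in S.children(x)
                               if S.is_ancestor_or_self(R.m[u], c))
                    losses += 1  # the sibling copy dies out
                    x = nxt
                if G.is_leaf(u):
                    return
                c1, c2 = G.children(u)
                if u in R.sigma:
                    s1, s2 = S.children(x)
                    a = s1 if S.is_ancestor_or_self(R.m[c1], s1) else s2
                    b = s2 if a == s1 else s1
                    descend(c1, a)
                    descend(c2, b)
                else:
                    descend(c1, x)
                    descend(c2, x)

            descend(G.root, R.m[G.root])
            return losses

        for _ in range(20):
            G, S = random_instance(rng, max_species=5, max_gene=7)
            for i, R in enumerate(enumerate_reconciliations(G, S)):
                assert count_losses(R) == walk_losses(R)
                if i > 40:
                    break


class TestOracleEnumeration:
    def test_contains_lca_and_all_valid(self, example_a, species_ab):
        R_star = lca_reconciliation(example_a, species_ab)
        found = False
        count = 0
        seen = set()
        for R in enumerate_reconciliations(example_a, species_ab):
            check_reconciliation(R)
            count += 1
            seen.add((R.m, R.sigma))
            if R.m == R_star.m and R.sigma == R_star.sigma:
                found = True
        assert found
        assert len(seen) == count  # enumeration is deduplicated

    def test_impossible_root_setting(self, example_a, species_ab):
        """No reconciliation puts 2 duplications and 2 speciations at the
        species root for the worked example."""
        root = species_ab.root
        combos = {(setting_of(R).dup[root], setting_of(R).spec[root])
                  for R in enumerate_reconciliations(example_a, species_ab)}
        assert (2, 2) not in combos
        assert (1, 2) in combos  # the lca-reconciliation's combination

    def test_size_cap(self, species_ab):
        G = parse_newick("(((((a,a),(a,a)),((a,a),(a,a))),b),(a,b));",
                         kind="gene")
        with pytest.raises(Exception, match="too large"):
            list(enumerate_reconciliations(G, species_ab, cap=9))
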