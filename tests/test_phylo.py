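"""ML inference and parsimony statistics, checked against closed forms and
exhaustive oracles on small instances."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from lcnpipe.census import topology_key
from lcnpipe.mlcore import (TreeLikelihood, compress_patterns,
                            enumerate_topologies, n_topologies,
                            neighbor_joining, jc_distance_matrix,
                            rooted_structure)
from lcnpipe.models import (ModelMatrices, SubstitutionModel,
                            discrete_gamma_rates)
from lcnpipe.phylo import (Alignment, bootstrap_support, ci_ri, count_pi_sites,
                           exhaustive_ml_search, fitch_steps, gc_content,
                           log_likelihood, select_model)
from lcnpipe.simulate import (SimulationConfig, simulate_alignment,
                              simulate_gene_tree)


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# column statistics

def test_pi_site_definition():
    # columns: (A,A,G,G,C,C) informative; (A,A,A,A,G,G) informative;
    # (G,G,A,C,-,R) not informative (gap and R do not support any state)
    aln = Alignment(list("uvwxyz"), [
        "AAG", "AAG", "GAA", "GAC", "CG-", "CGR",
    ])
    assert count_pi_sites(aln) == 2
    aln2 = Alignment(list("uvwxyz"), ["A", "A", "A", "A", "A", "G"])
    assert count_pi_sites(aln2) == 0  # singleton


def test_pi_sites_ignore_ambiguity_support():
    # two A, one G plus one R: R must not lift G to count 2
    aln = Alignment(list("abcd"), ["A", "A", "G", "R"])
    assert count_pi_sites(aln) == 0


@pytest.mark.parametrize("seqs,expected", [
    (["GG", "CC"], 100.0),
    (["AT", "AT"], 0.0),
    (["A-", "GN"], 50.0),   # only A and G counted
    (["SS", "WW"], 50.0),   # S counts GC, W counts AT
])
def test_gc_content(seqs, expected):
    aln = Alignment([f"t{i}" for i in range(len(seqs))], seqs)
    assert gc_content(aln) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# model machinery

def test_discrete_gamma_rates_average_to_one():
    for alpha in (0.1, 0.5, 1.0, 5.0, 50.0):
        r = discrete_gamma_rates(alpha, 4)
        assert r.shape == (4,)
        assert np.all(np.diff(r) > 0)
        assert abs(r.mean() - 1.0) < 1e-9


def test_transition_matrix_rows_are_distributions():
    m = SubstitutionModel(family="GTR", freqs=(0.3, 0.25, 0.2, 0.25),
                          exchangeabilities=(1.2, 3.0, 0.8, 1.1, 2.5, 1.0))
    mm = ModelMatrices(m)
    for t in (0.0, 0.01, 0.3, 2.0):
        P = mm.transition(t)[0]
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= 0)
    assert np.allclose(mm.transition(0.0)[0], np.eye(4), atol=1e-12)
    # detailed balance: pi_i P_ij = pi_j P_ji (reversibility)
    P = mm.transition(0.2)[0]
    pi = np.asarray(m.freqs)
    assert np.allclose(pi[:, None] * P, (pi[:, None] * P).T, atol=1e-12)


# ---------------------------------------------------------------------------
# likelihood: closed forms and exhaustive oracle

def test_two_taxon_jc_branch_length_matches_closed_form():
    for p in (0.05, 0.1, 0.25):
        n = 20_000
        k = round(p * n)
        data = compress_patterns(["a", "b"], ["A" * n, "G" * k + "A" * (n - k)])
        tl = TreeLikelihood(((0, 1),), data, SubstitutionModel("JC69"))
        tl.optimize_branches(tol=1e-10, max_sweeps=30, xtol=1e-9)
        t_hat = sum(tl.bl.values())
        t_closed = -0.75 * math.log(1.0 - 4.0 * (k / n) / 3.0)
        assert abs(t_hat - t_closed) < 1e-6


def _brute_force_loglik(tree, model, aln):
    """Sum over all internal-state assignments, one site at a time."""
    from lcnpipe.phylo import tree_to_edges
    edges, bl = tree_to_edges(tree, aln.taxa)
    n = len(aln.taxa)
    root, parent, children, post = rooted_structure(edges, n)
    mm = ModelMatrices(model)
    P = {v: mm.transition(bl[v])[0] for v in post}
    pi = np.asarray(model.freqs)
    idx = {c: i for i, c in enumerate("ACGT")}
    internals = [v for v in post + [root] if v >= n]
    total = 0.0
    for site in range(aln.length):
        obs = {i: idx[aln.seqs[i][site]] for i in range(n)}
        site_l = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            st = dict(zip(internals, assign))
            st.update(obs)
            p = pi[st[root]]
            for v in post:
                p *= P[v][st[parent[v]], st[v]]
            site_l += p
        total += math.log(site_l)
    return total


def test_pruning_equals_exhaustive_state_summation():
    rng = np.random.default_rng(2)
    taxa = list("abcd")
    aln = Alignment(taxa, ["".join(rng.choice(list("ACGT"), 10))
                           for _ in taxa])
    tree = _tree("((a:0.12,b:0.3):0.08,(c:0.25,d:0.05):0.11);")
    model = SubstitutionModel(family="HKY85", freqs=(0.3, 0.2, 0.2, 0.3),
                              kappa=3.0)
    assert log_likelihood(tree, model, aln) == pytest.approx(
        _brute_force_loglik(tree, model, aln), abs=1e-9)


def test_likelihood_invariant_under_taxon_reordering_and_rerooting():
    rng = np.random.default_rng(4)
    taxa = list("abcd")
    seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in taxa]
    aln = Alignment(taxa, seqs)
    model = SubstitutionModel(family="HKY85", freqs=(0.28, 0.22, 0.22, 0.28),
                              kappa=2.5)
    t1 = _tree("((a:0.1,b:0.2):0.12,(c:0.3,d:0.1):0.02);")
    t2 = _tree("(a:0.1,b:0.2,(c:0.3,d:0.1):0.14);")       # rerooted
    t3 = _tree("((d:0.1,c:0.3):0.07,(b:0.2,a:0.1):0.07);")  # rotated
    l1 = log_likelihood(t1, model, aln)
    assert log_likelihood(t2, model, aln) == pytest.approx(l1, abs=1e-8)
    assert log_likelihood(t3, model, aln) == pytest.approx(l1, abs=1e-8)
    shuffled = Alignment(taxa[::-1], seqs[::-1])
    assert log_likelihood(t1, model, shuffled) == pytest.approx(l1, abs=1e-8)


def test_pattern_compression_preserves_likelihood():
    """Summing single-column likelihoods equals the compressed-matrix
    likelihood."""
    rng = np.random.default_rng(6)
    taxa = list("abcd")
    seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in taxa]
    aln = Alignment(taxa, seqs)
    tree = _tree("((a:0.1,b:0.2):0.05,(c:0.15,d:0.12):0.05);")
    model = SubstitutionModel("JC69")
    full = log_likelihood(tree, model, aln)
    per_column = sum(
        log_likelihood(tree, model,
                       Alignment(taxa, [s[i] for s in seqs]))
        for i in range(60))
    assert full == pytest.approx(per_column, abs=1e-8)


def test_ambiguity_codes_act_as_partial_observations():
    """An R tip sums likelihood over A and G."""
    model = SubstitutionModel("JC69")
    tree = _tree("(a:0.1,b:0.1);")
    l_r = log_likelihood(tree, model, Alignment(["a", "b"], ["R", "A"]))
    l_a = log_likelihood(tree, model, Alignment(["a", "b"], ["A", "A"]))
    l_g = log_likelihood(tree, model, Alignment(["a", "b"], ["G", "A"]))
    assert math.exp(l_r) == pytest.approx(math.exp(l_a) + math.exp(l_g),
                                          rel=1e-10)
    # a gap contributes no information: lnL equals the single-taxon prior
    l_gap = log_likelihood(tree, model, Alignment(["a", "b"], ["-", "A"]))
    assert l_gap == pytest.approx(math.log(0.25), abs=1e-10)


# ---------------------------------------------------------------------------
# topology enumeration and search

def test_topology_counts_follow_double_factorial():
    for n, expected in [(4, 3), (5, 15), (6, 105), (7, 945)]:
        assert n_topologies(n) == expected
        topos = enumerate_topologies(n)
        assert len(topos) == expected
        taxa = [f"t{i}" for i in range(n)]
        keys = {topology_key_from_edges(e, taxa) for e in topos}
        assert len(keys) == expected  # all distinct as unrooted topologies


def topology_key_from_edges(edges, taxa):
    from lcnpipe.mlcore import canonical_key
    return canonical_key(edges, taxa)


def test_three_taxa_has_single_topology():
    star = _tree("(a:0.05,b:0.08,c:0.1);")
    aln = simulate_alignment(star, SubstitutionModel("JC69"), 500, seed=3)
    res = exhaustive_ml_search(aln, SubstitutionModel("JC69"))
    assert res.n_topologies == 1
    # equals direct optimization on that topology
    data = compress_patterns(aln.taxa, aln.seqs)
    tl = TreeLikelihood(enumerate_topologies(3)[0], data,
                        SubstitutionModel("JC69"))
    assert res.log_likelihood == pytest.approx(
        tl.optimize_branches(tol=1e-8), abs=1e-3)


def test_true_topology_recovered_from_clean_data(six_taxa_config, hky_model):
    cfg = six_taxa_config
    hits = 0
    for seed in range(10):
        tree = simulate_gene_tree(1 + seed % 3, 4.0e-9, cfg.root_age_years,
                                  taxa=cfg.taxa, seed=seed)
        aln = simulate_alignment(tree, cfg.model, 2500, seed=seed + 50)
        res = exhaustive_ml_search(aln, hky_model)
        hits += topology_key(res.tree) == topology_key(tree)
    assert hits >= 9


# ---------------------------------------------------------------------------
# model selection

def test_jc_data_selects_equal_rate_model(six_taxa_config):
    """On data simulated under JC69, the winner carries no rate structure
    (no kappa, no GTR exchangeabilities, no gamma); base-frequency drift of
    the finite root sequence legitimately lets F81 win occasionally, so
    JC69 itself must win in most seeds."""
    cfg = six_taxa_config
    jc_wins = 0
    for seed in range(5):
        tree = simulate_gene_tree(1, 4.0e-9, cfg.root_age_years,
                                  taxa=cfg.taxa, seed=seed)
        aln = simulate_alignment(tree, SubstitutionModel("JC69"), 1500,
                                 seed=seed + 9)
        res = select_model(aln)
        assert res.best.family in ("JC69", "F81")
        assert res.best.gamma_categories == 0
        jc_wins += res.table.iloc[0]["model"] == "JC69"
    assert jc_wins >= 3


def test_nested_models_never_lose_likelihood(six_taxa_config):
    cfg = six_taxa_config
    tree = simulate_gene_tree(1, 4.5e-9, cfg.root_age_years, taxa=cfg.taxa,
                              seed=3)
    aln = simulate_alignment(tree, cfg.model, 1200, seed=21)
    lnl = select_model(aln).table.set_index("model")["lnL"]
    tol = 1e-3  # optimizer tolerance; nesting is exact at the optimum
    assert lnl["K80"] >= lnl["JC69"] - tol
    assert lnl["HKY85"] >= lnl["K80"] - tol
    assert lnl["HKY85"] >= lnl["F81"] - tol
    assert lnl["GTR"] >= lnl["HKY85"] - tol
    for family in ("JC69", "K80", "F81", "HKY85", "GTR"):
        assert lnl[family + "+G4"] >= lnl[family] - tol


# ---------------------------------------------------------------------------
# bootstrap

def test_bootstrap_is_seed_deterministic_and_confident_on_clean_data(
        six_taxa_config, hky_model):
    cfg = six_taxa_config
    tree = simulate_gene_tree(1, 4.5e-9, cfg.root_age_years, taxa=cfg.taxa,
                              seed=11)
    aln = simulate_alignment(tree, cfg.model, 900, seed=12)
    b1 = bootstrap_support(aln, hky_model, replicates=30, seed=5)
    b2 = bootstrap_support(aln, hky_model, replicates=30, seed=5)
    assert b1.supports == b2.supports
    assert len(b1.supports) == 3  # three internal branches on 6 taxa
    assert all(s >= 95.0 for s in b1.supports.values())


# ---------------------------------------------------------------------------
# parsimony

def _brute_fitch_column(edges, n, state_sets):
    """Minimum mutations over all internal (and ambiguous-tip) assignments."""
    root, parent, children, post = rooted_structure(edges, n)
    internals = [v for v in post + [root] if v >= n]
    tips = list(range(n))
    choices = []
    for v in tips:
        s = state_sets[v]
        choices.append(sorted(s) if s is not None else list("ACGT"))
    best = math.inf
    for tip_assign in itertools.product(*choices):
        fixed = dict(zip(tips, tip_assign))
        for internal_assign in itertools.product("ACGT", repeat=len(internals)):
            st = dict(zip(internals, internal_assign))
            st.update(fixed)
            steps = sum(1 for v in post if st[v] != st[parent[v]])
            best = min(best, steps)
    return best


def test_fitch_equals_brute_force_on_five_taxon_columns():
    from lcnpipe.phylo import _fitch_site, _site_state_sets
    rng = np.random.default_rng(9)
    taxa = list("abcde")
    edges = enumerate_topologies(5)[7]
    root, parent, children, post = rooted_structure(edges, 5)
    for _ in range(12):
        column = "".join(rng.choice(list("ACGTR-"), 5))
        aln = Alignment(taxa, list(column))
        sets = _site_state_sets(aln, 0)
        got = _fitch_site(children, post, root, 5, sets)
        want = _brute_fitch_column(edges, 5, sets)
        assert got == want, column


def test_max_steps_formula_matches_worst_tree():
    """g_i (tips with non-modal states) equals the maximum over all
    5-taxon topologies of the Fitch length."""
    from lcnpipe.phylo import _fitch_site, _site_state_sets
    rng = np.random.default_rng(14)
    taxa = list("abcde")
    for _ in range(8):
        column = "".join(rng.choice(list("ACGT"), 5))
        aln = Alignment(taxa, list(column))
        sets = _site_state_sets(aln, 0)
        counts = {b: column.count(b) for b in set(column)}
        g_formula = sum(counts.values()) - max(counts.values())
        g_brute = max(
            _fitch_site(*_rooted_parts(e), sets)
            for e in enumerate_topologies(5))
        assert g_formula == g_brute, column


def _rooted_parts(edges):
    root, parent, children, post = rooted_structure(edges, 5)
    return children, post, root, 5


def test_homoplasy_free_data_has_ci_ri_one(six_taxa_config):
    cfg = six_taxa_config
    tree = simulate_gene_tree(1, 2.0e-9, cfg.root_age_years, taxa=cfg.taxa,
                              seed=2)
    # very short branches: essentially every variable site is single-hit
    aln = simulate_alignment(tree, SubstitutionModel("JC69"), 300, seed=3)
    from lcnpipe.phylo import tree_to_edges
    edges, _ = tree_to_edges(tree, aln.taxa)
    ci, ri = ci_ri(edges, aln)
    assert ci == pytest.approx(1.0, abs=0.08)
    assert ri == pytest.approx(1.0, abs=0.15)


def test_perfect_cherry_character_scores_ci_ri_one():
    taxa = list("abcdef")
    tree = _tree("(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):1);")
    aln = Alignment(taxa, ["AAG", "AAG", "GCG", "GCG", "GCA", "GCA"])
    ci, ri = ci_ri(tree, aln)
    assert (ci, ri) == (1.0, 1.0)
    assert fitch_steps(tree, aln) == 3  # one step per column


def test_ci_on_ml_tree_beats_random_tree(six_taxa_config, hky_model):
    cfg = six_taxa_config
    rng = np.random.default_rng(0)
    wins = 0
    for seed in range(5):
        tree = simulate_gene_tree(1, 4.5e-9, cfg.root_age_years,
                                  taxa=cfg.taxa, seed=seed)
        aln = simulate_alignment(tree, cfg.model, 1500, seed=seed + 33)
        res = exhaustive_ml_search(aln, hky_model)
        ci_ml, _ = ci_ri(res.edges, aln)
        random_edges = enumerate_topologies(6)[int(rng.integers(105))]
        ci_rand, _ = ci_ri(random_edges, aln)
        wins += ci_ml >= ci_rand
    assert wins >= 4


# ---------------------------------------------------------------------------
# distance starting trees

def test_neighbor_joining_recovers_clean_topology(six_taxa_config):
    cfg = six_taxa_config
    tree = simulate_gene_tree(1, 5.0e-9, cfg.root_age_years, taxa=cfg.taxa,
                              seed=8)
    aln = simulate_alignment(tree, SubstitutionModel("JC69"), 4000, seed=9)
    data = compress_patterns(aln.taxa, aln.seqs)
    edges = neighbor_joining(jc_distance_matrix(data))
    from lcnpipe.mlcore import canonical_key
    from lcnpipe.phylo import tree_to_edges
    true_edges, _ = tree_to_edges(tree, aln.taxa)
    assert canonical_key(edges, aln.taxa) == canonical_key(true_edges, aln.taxa)
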