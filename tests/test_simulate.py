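"""The synthetic-data generator: rates, trees, sequences, contigs,
annotations — each checked against analytic expectations."""

import math

import dendropy
import numpy as np
import pytest

from lcnpipe.contigs import OrientedContig, merge_contigs
from lcnpipe.models import SubstitutionModel
from lcnpipe.rates import cross_root_mean, patristic_matrix
from lcnpipe.simulate import (ContigScheme, PlantedGene, RateDistribution,
                              SimulationConfig, fragment_to_contigs,
                              make_exon_mask, simulate_alignment,
                              simulate_annotation, simulate_gene_tree,
                              simulate_loci, simulate_rates)


# ---------------------------------------------------------------------------
# rates

def test_gamma_rate_sample_mean_matches_parameters():
    shape, scale = 14.076, 3.098e-10
    rates = simulate_rates(50, RateDistribution("gamma", shape=shape, scale=scale),
                           seed=11)
    mean, sd = shape * scale, math.sqrt(shape) * scale
    assert abs(rates.mean() - mean) < 3 * sd / math.sqrt(50)
    assert np.all(rates > 0)


def test_degenerate_normal_gives_identical_rates():
    rates = simulate_rates(5, RateDistribution("normal", mean=3.6e-9, sd=0.0),
                           seed=0)
    assert np.allclose(rates, 3.6e-9)


def test_gamma_moment_recovery_at_large_n():
    """Method-of-moments shape on a large sample recovers the parameter."""
    rates = simulate_rates(10_000, RateDistribution("gamma", shape=14.076,
                                                    scale=3.098e-10), seed=3)
    k_hat = rates.mean() ** 2 / rates.var()
    assert abs(k_hat - 14.076) / 14.076 < 0.05


def test_normal_rates_always_positive():
    dist = RateDistribution("normal", mean=1e-10, sd=5e-10)
    rates = simulate_rates(200, dist, seed=5)
    assert np.all(rates > 0)


def test_invalid_rate_parameters_rejected():
    with pytest.raises(ValueError):
        RateDistribution("gamma", shape=-1.0)
    with pytest.raises(ValueError):
        simulate_rates(0, RateDistribution(), seed=0)


# ---------------------------------------------------------------------------
# gene trees

def test_tree_is_ultrametric_with_exact_root_to_tip_length():
    """rate 1.9e-9 over 15.9 Ma: every root-to-tip path is 0.030 subs/site
    and every cross-root tip pair distance is 0.060."""
    cfg = SimulationConfig()
    tree = simulate_gene_tree(1, 1.9e-9, 1.59e7, taxa=cfg.taxa)
    expected = 1.9e-9 * 1.59e7
    for leaf in tree.leaf_node_iter():
        assert abs(leaf.distance_from_root() - expected) < 1e-12
    D = patristic_matrix(tree)
    for a in cfg.ingroup:
        for b in cfg.outgroup:
            assert abs(D.loc[a, b] - 2 * expected) < 1e-12


def test_cross_root_mean_equals_two_t_r_exactly():
    cfg = SimulationConfig()
    for topo in (1, 2, 3):
        tree = simulate_gene_tree(topo, 4.2e-9, 1.59e7, taxa=cfg.taxa)
        d = cross_root_mean(tree, cfg.ingroup, cfg.outgroup)
        assert abs(d - 2 * 4.2e-9 * 1.59e7) < 1e-12


def test_zero_rate_rejected():
    with pytest.raises(ValueError):
        simulate_gene_tree(1, 0.0, 1.59e7)


def test_unknown_topology_rejected():
    with pytest.raises(ValueError):
        simulate_gene_tree(9, 1e-9, 1.59e7)


def test_same_seed_gives_identical_newick():
    a = simulate_gene_tree(1, 3e-9, 1.59e7, seed=4, jitter_sd=0.3)
    b = simulate_gene_tree(1, 3e-9, 1.59e7, seed=4, jitter_sd=0.3)
    assert a.as_string(schema="newick") == b.as_string(schema="newick")


# ---------------------------------------------------------------------------
# alignments

def _two_taxon_tree(t: float) -> dendropy.Tree:
    return dendropy.Tree.get(data=f"(a:{t / 2},b:{t / 2});", schema="newick",
                             preserve_underscores=True)


def test_jc_divergence_matches_closed_form():
    """Observed mismatch fraction agrees with p = (3/4)(1 - e^(-4t/3))."""
    t, L = 0.12, 100_000
    aln = simulate_alignment(_two_taxon_tree(t), SubstitutionModel("JC69"),
                             L, seed=9)
    p_exp = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
    p_obs = sum(a != b for a, b in zip(*aln.seqs)) / L
    assert abs(p_obs - p_exp) < 3 * math.sqrt(p_exp * (1 - p_exp) / L)


def test_zero_length_branches_give_identical_sequences():
    tree = dendropy.Tree.get(data="((a:0,b:0):0,(c:0,d:0):0);",
                             schema="newick", preserve_underscores=True)
    aln = simulate_alignment(tree, SubstitutionModel("JC69"), 500, seed=2)
    assert len(set(aln.seqs)) == 1


def test_neutral_multiplier_leaves_partitions_indistinguishable():
    """With multiplier 1, exon and intron columns follow one process: a
    two-proportion z-test on per-partition mismatch counts should reject
    at alpha=0.01 only at the nominal rate across seeds."""
    from scipy.stats import norm
    t, L = 0.1, 4000
    mask = make_exon_mask(L)
    rejections = 0
    for seed in range(20):
        aln = simulate_alignment(_two_taxon_tree(t), SubstitutionModel("JC69"),
                                 L, exon_mask=mask, exon_rate_multiplier=1.0,
                                 seed=seed)
        diff = np.array([a != b for a, b in zip(*aln.seqs)])
        p1, n1 = diff[mask].mean(), mask.sum()
        p2, n2 = diff[~mask].mean(), (~mask).sum()
        pool = diff.mean()
        z = (p1 - p2) / math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        if abs(z) > norm.ppf(0.995):
            rejections += 1
    assert rejections <= 3


def test_exon_multiplier_slows_exon_sites():
    t, L = 0.2, 20_000
    mask = make_exon_mask(L)
    aln = simulate_alignment(_two_taxon_tree(t), SubstitutionModel("JC69"), L,
                             exon_mask=mask, exon_rate_multiplier=0.3, seed=1)
    diff = np.array([a != b for a, b in zip(*aln.seqs)])
    assert diff[mask].mean() < 0.7 * diff[~mask].mean()


def test_mask_length_mismatch_rejected():
    with pytest.raises(ValueError):
        simulate_alignment(_two_taxon_tree(0.1), SubstitutionModel("JC69"),
                           100, exon_mask=np.zeros(99, dtype=bool))


# ---------------------------------------------------------------------------
# contig fragmentation

def test_tiling_arithmetic_matches_example():
    seq = "A" * 1000
    contigs, truth = fragment_to_contigs(seq, ContigScheme(400, 100, 0))
    assert [(c.start, c.end) for c in contigs] == [(0, 400), (300, 700),
                                                  (600, 1000)]


def test_zero_heterozygosity_round_trip_is_lossless():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), size=1200))
    contigs, _ = fragment_to_contigs(seq, ContigScheme(400, 100, 0))
    oriented = [OrientedContig(c.contig_id, "locus", c.start, c.end,
                               c.sequence) for c in contigs]
    merged = merge_contigs(oriented, individual_id="x")
    assert merged.sequence == seq


def test_heterozygous_site_becomes_iupac_code_downstream():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=1500))
    contigs, truth = fragment_to_contigs(seq, ContigScheme(400, 150, 0),
                                         heterozygosity=0.05, seed=13)
    assert truth.het_sites, "expected at least one injected het site"
    oriented = [OrientedContig(c.contig_id, "locus", c.start, c.end,
                               c.sequence) for c in contigs]
    merged = merge_contigs(oriented, individual_id="x")
    from lcnpipe.iupac import code_for
    for pos, (ref, alt) in truth.het_sites.items():
        assert merged.sequence[pos] == code_for({ref, alt})
    # everywhere else the source base survives
    for i, c in enumerate(seq):
        if i not in truth.het_sites:
            assert merged.sequence[i] == c


def test_gap_scheme_leaves_uncovered_stretches():
    seq = "C" * 1000
    contigs, _ = fragment_to_contigs(seq, ContigScheme(300, 0, 50))
    spans = [(c.start, c.end) for c in contigs]
    assert spans == [(0, 300), (350, 650), (700, 1000)]


def test_invalid_scheme_rejected():
    with pytest.raises(ValueError):
        ContigScheme(length=50, overlap=100)


# ---------------------------------------------------------------------------
# annotated genomes

def test_planted_qualifying_group_of_three(tmp_path):
    planted = [PlantedGene(f"g{i}", length=2500, intron_lengths=(450, 450),
                           spacing_after=10_000) for i in range(3)]
    sim = simulate_annotation(planted, seed=1)
    assert sim.truth["passes"].all()
    assert set(sim.truth["group_id"]) == {"group1"}


def test_boundary_intron_rules():
    ok = PlantedGene("ok", length=2500, intron_lengths=(500,))
    bad = PlantedGene("bad", length=2500, intron_lengths=(501,))
    sim = simulate_annotation([ok, bad], seed=2)
    t = sim.truth.set_index("gene_id")
    assert t.loc["ok", "passes_intron"]
    assert not t.loc["bad", "passes_intron"]


def test_duplicated_gene_excluded_as_multi_copy():
    planted = [PlantedGene("dup", length=2500, intron_lengths=(450,),
                           n_copies=2, copy_evalue=1e-50)]
    sim = simulate_annotation(planted, seed=3)
    row = sim.truth.iloc[0]
    assert row["copies"] == 2 and not row["passes_copies"]
    # a below-threshold copy does not count
    weak = [PlantedGene("weak", length=2500, intron_lengths=(450,),
                        n_copies=2, copy_evalue=1e-10)]
    sim2 = simulate_annotation(weak, seed=3)
    assert sim2.truth.iloc[0]["passes_copies"]


def test_overlapping_planted_genes_rejected():
    with pytest.raises(ValueError):
        simulate_annotation([PlantedGene("a", spacing_after=-5),
                             PlantedGene("b")], seed=0)


# ---------------------------------------------------------------------------
# whole datasets

def test_simulated_dataset_is_seed_deterministic():
    cfg = SimulationConfig(seed=7, n_loci=2, locus_length_range=(900, 1000))
    a = simulate_loci(cfg)
    b = simulate_loci(cfg)
    for la, lb in zip(a, b):
        assert la.alignment.seqs == lb.alignment.seqs
        assert la.true_rate == lb.true_rate
        assert (la.gene_tree.as_string(schema="newick")
                == lb.gene_tree.as_string(schema="newick"))
        for taxon in cfg.taxa:
            assert [c.sequence for c in la.contig_sets[taxon]] == \
                   [c.sequence for c in lb.contig_sets[taxon]]


def test_simulated_locus_invariants():
    cfg = SimulationConfig(seed=5, n_loci=3, locus_length_range=(800, 1200))
    for locus in simulate_loci(cfg):
        assert locus.alignment.length in range(800, 1201)
        d = cross_root_mean(locus.gene_tree, cfg.ingroup, cfg.outgroup)
        assert abs(d - 2 * cfg.root_age_years * locus.true_rate) < 1e-12
        assert locus.true_topology_id in (1, 2, 3)
        assert all(set(s) <= set("ACGT") for s in locus.alignment.seqs)
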