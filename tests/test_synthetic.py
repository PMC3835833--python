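"""Generator correctness: determinism, planted structure, count law."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from twolib import (
    ConfigError,
    SimulationConfig,
    assign_truth,
    generate_counts,
    generate_reads,
    generate_reference,
    generate_spot_table,
    simulate_all,
    write_fastq,
)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(n_genes=0)
    with pytest.raises(ConfigError):
        SimulationConfig(gene_length_range=(500, 100))
    with pytest.raises(ConfigError):
        SimulationConfig(de_fraction=1.5)
    with pytest.raises(ConfigError):
        SimulationConfig(fold_changes=(2.0, 1.0))
    with pytest.raises(ConfigError):
        SimulationConfig(library_sizes=(0, 100))
    with pytest.raises(ConfigError):
        # read longer than the shortest possible gene
        SimulationConfig(gene_length_range=(30, 100), emit_reads=True, read_length=49)


def test_reference_deterministic_and_bounded():
    cfg = SimulationConfig(n_genes=100, n_terms=5, genes_per_term=10, seed=7)
    ref1 = generate_reference(cfg)
    ref2 = generate_reference(cfg)
    pd.testing.assert_frame_equal(ref1.genes, ref2.genes)
    pd.testing.assert_frame_equal(ref1.annotations, ref2.annotations)
    assert ref1.sequences == ref2.sequences
    lo, hi = cfg.gene_length_range
    assert ref1.genes["length_bp"].between(lo, hi).all()
    # each term annotates at most genes_per_term distinct genes
    sizes = ref1.annotations.groupby(["term_type", "term_id"]).size()
    assert (sizes <= 10).all()
    assert (ref1.annotations.groupby("term_type").size() <= 50).all()


def test_fastq_bytes_identical_under_seed(tmp_path):
    cfg = SimulationConfig(seed=3, emit_reads=True, n_reads=50, n_genes=20,
                           library_sizes=(1000, 1000))
    paths = []
    for name in ("a.fastq", "b.fastq"):
        reads, _, _ = generate_reads(cfg, generate_reference(cfg))
        p = tmp_path / name
        write_fastq(reads, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_null_config_draws_identical_means():
    cfg = SimulationConfig(n_genes=50, de_fraction=0.0, seed=2,
                           library_sizes=(10_000, 10_000))
    ref = generate_reference(cfg)
    truth = assign_truth(cfg, ref)
    assert truth.de_gene_ids == set()
    assert all(fc == 1.0 for fc in truth.true_fold_change.values())


def test_zero_expression_gene_yields_zero_counts():
    cfg = SimulationConfig(n_genes=10, de_fraction=0.0, seed=4,
                           library_sizes=(10_000, 10_000))
    ref = generate_reference(cfg)
    truth = assign_truth(cfg, ref)
    g0 = ref.genes["gene_id"].iloc[0]
    truth.true_mean_rpkm[g0] = 0.0
    control, infected = generate_counts(cfg, truth, ref)
    assert control.counts[g0] == 0
    assert infected.counts[g0] == 0


def test_poisson_mean_matches_rpkm_inversion():
    """Monte-Carlo check: one gene at RPKM 1000, L=1000, N=1e6 has Poisson
    mean 1e9*C/(N*L) inverted, i.e. 1000; 1e4 draws land within 3 SE."""
    rng = np.random.default_rng(0)
    mu = 1000.0 * 1e6 * 1000.0 / 1e9  # = 1000 expected reads
    draws = rng.poisson(mu, size=10_000)
    se = math.sqrt(mu / draws.size)
    assert abs(draws.mean() - mu) < 3 * se


def test_count_generation_follows_configured_means():
    cfg = SimulationConfig(n_genes=200, de_fraction=0.1, seed=9,
                           library_sizes=(500_000, 500_000))
    ref = generate_reference(cfg)
    truth = assign_truth(cfg, ref)
    control, infected = generate_counts(cfg, truth, ref)
    lengths = ref.lengths
    mu_c = np.array([truth.true_mean_rpkm[g] * cfg.library_sizes[0] * lengths[g] / 1e9
                     for g in control.counts.index])
    # totals concentrate around the library size (generator normalisation)
    assert abs(control.counts.sum() - cfg.library_sizes[0]) < 5 * math.sqrt(cfg.library_sizes[0])
    # per-gene counts within 6 sigma of their configured Poisson means
    resid = (control.counts.to_numpy() - mu_c) / np.sqrt(np.maximum(mu_c, 1.0))
    assert np.all(np.abs(resid) < 6.0)
    # fold change applied only in the infected library
    for g in truth.de_gene_ids:
        assert truth.true_fold_change[g] != 1.0


def test_error_free_reads_are_exact_substrings(small_config):
    cfg = dataclasses.replace(small_config, adaptor_fraction=0.0,
                              highn_fraction=0.0, lowq_fraction=0.0,
                              base_error_rate=0.0)
    ref = generate_reference(cfg)
    reads, origins, cats = generate_reads(cfg, ref)
    assert set(cats.values()) == {"clean"}
    for r in reads:
        assert r.sequence in ref.sequences[origins[r.read_id]]


def test_contamination_fractions_binomial(small_config):
    cfg = dataclasses.replace(small_config, n_reads=1000, adaptor_fraction=0.1,
                              highn_fraction=0.0, lowq_fraction=0.0)
    ref = generate_reference(cfg)
    _, _, cats = generate_reads(cfg, ref)
    n_adaptor = sum(1 for c in cats.values() if c == "adaptor")
    sigma = math.sqrt(1000 * 0.1 * 0.9)
    assert abs(n_adaptor - 100) < 3 * sigma


def test_spot_table_closed_forms(default_study):
    cfg, truth, ref = default_study.config, default_study.truth, default_study.reference
    sim = generate_spot_table(cfg, truth, ref)
    # CT values invert the 2^-ddCT model exactly
    for _, row in sim.qpcr.iterrows():
        ddct = ((row.ct_target_infected - row.ct_ref_infected)
                - (row.ct_target_control - row.ct_ref_control))
        assert 2.0 ** (-ddct) == pytest.approx(sim.qpcr_truth[row.gene_id], rel=1e-12)
    # presence/absence spots are all-zero in exactly one condition
    for spot_id, cat in sim.spot_truth.items():
        grp = sim.spots[sim.spots.spot_id == spot_id]
        c = grp.loc[grp.condition == "control", "vol_percent"]
        i = grp.loc[grp.condition == "infected", "vol_percent"]
        if cat == "infected_only":
            assert (c == 0).all() and (i > 0).all()
        elif cat == "control_only":
            assert (i == 0).all() and (c > 0).all()
        else:
            assert (c > 0).all() and (i > 0).all()


def test_spot_zero_noise_ratio_exactly_one():
    cfg = SimulationConfig(seed=1, spot_cv=0.0, spot_de_fraction=0.0,
                           absent_spot_fraction=0.0, n_genes=50,
                           library_sizes=(10_000, 10_000))
    study = simulate_all(cfg)
    wide = study.spot_sim.spots.pivot_table(
        index="spot_id", columns="condition", values="vol_percent", aggfunc="mean")
    assert np.allclose(wide["infected"] / wide["control"], 1.0)


def test_simulate_all_is_reproducible(small_config):
    s1 = simulate_all(small_config)
    s2 = simulate_all(small_config)
    pd.testing.assert_series_equal(s1.control.counts, s2.control.counts)
    pd.testing.assert_series_equal(s1.infected.counts, s2.infected.counts)
    pd.testing.assert_frame_equal(s1.spot_sim.spots, s2.spot_sim.spots)
    assert s1.truth.de_gene_ids == s2.truth.de_gene_ids
    assert [r.sequence for r in s1.reads] == [r.sequence for r in s2.reads]
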