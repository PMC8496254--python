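"""Simulator: meiosis model, selection, read-count emission, determinism."""

import numpy as np
import pytest

from capmap import (SelectionSpec, SimConfig, TABLE2_LENGTHS_CM,
                    simulate_dataset, simulate_gamete, simulate_parent,
                    simulate_read_counts, simulate_s1_population)
from capmap.core import validate_allele_counts
from capmap.errors import ConfigError, SimulationError
from capmap.simulate import _rng
from capmap.twopoint import haldane_inv
from scipy import stats


def test_default_lengths_match_published_total():
    assert len(TABLE2_LENGTHS_CM) == 12
    assert sum(TABLE2_LENGTHS_CM) == pytest.approx(942.17, abs=0.015)


def test_parent_markers_heterozygous_with_recorded_phase():
    cfg = SimConfig(chrom_lengths_cM=(50.0,), markers_per_chromosome=3,
                    n_individuals=5, seed=1)
    truth = simulate_parent(cfg)
    # every marker carries both parental alleles (heterozygous parent) and a phase
    assert len(truth.metadata) == 3
    assert set(truth.phase) <= {0, 1}
    assert (truth.metadata["allele_a"] != truth.metadata["allele_b"]).all()


def test_parent_phase_deterministic_for_seed():
    cfg = SimConfig(chrom_lengths_cM=(50.0, 70.0), markers_per_chromosome=40, seed=11)
    assert np.array_equal(simulate_parent(cfg).phase, simulate_parent(cfg).phase)


def test_nonincreasing_marker_positions_rejected():
    with pytest.raises(ConfigError):
        SimConfig(chrom_lengths_cM=(50.0,),
                  markers_per_chromosome=[np.array([1.0, 1.0, 2.0])]).marker_positions()


def test_gamete_poisson_crossover_mean():
    cfg = SimConfig(chrom_lengths_cM=(100.0,), markers_per_chromosome=2, seed=2)
    truth = simulate_parent(cfg)
    rng = np.random.default_rng(42)
    n = 10_000
    counts = [len(simulate_gamete(truth, 0, rng)[1]) for _ in range(n)]
    # Poisson mean L/100 = 1.0; 3 standard errors of the mean
    assert np.mean(counts) == pytest.approx(1.0, abs=3.0 * np.sqrt(1.0 / n))


def test_gamete_recombination_matches_inverse_haldane():
    d = 30.0
    cfg = SimConfig(chrom_lengths_cM=(d,), markers_per_chromosome=[np.array([0.0, d])], seed=2)
    truth = simulate_parent(cfg)
    rng = np.random.default_rng(5)
    n = 20_000
    rec = 0
    for _ in range(n):
        hap, _ = simulate_gamete(truth, 0, rng)
        rec += int(hap[0] != hap[1])
    p = haldane_inv(d)
    se = np.sqrt(p * (1 - p) / n)
    assert rec / n == pytest.approx(p, abs=3 * se)


def test_s1_genotypes_fit_1_2_1():
    # one marker per chromosome so the pooled calls are independent draws
    cfg = SimConfig(chrom_lengths_cM=(50.0,) * 25, markers_per_chromosome=1,
                    n_individuals=400, seed=4)
    truth = simulate_parent(cfg)
    simulate_s1_population(truth, cfg)
    g = truth.genotypes().calls
    counts = np.bincount(g.ravel(), minlength=3)
    total = counts.sum()
    assert total == 10_000
    _, p = stats.chisquare(counts, f_exp=np.array([0.25, 0.5, 0.25]) * total)
    assert p > 0.001


def test_zygotic_selection_eliminates_disfavored_genotype():
    spec = SelectionSpec(chromosome=0, position_cM=25.0, mode="zygotic",
                         disfavored="AA", strength=0.0)
    cfg = SimConfig(chrom_lengths_cM=(50.0,), markers_per_chromosome=11,
                    n_individuals=300, seed=5, selection_loci=(spec,))
    truth = simulate_parent(cfg)
    simulate_s1_population(truth, cfg)
    col = truth.genotypes().calls[:, truth.selection_markers[0]]
    assert (col == 0).sum() == 0


def test_one_sex_gametic_selection_gives_half_half():
    spec = SelectionSpec(chromosome=0, position_cM=25.0, mode="gametic_one_sex",
                         disfavored="A", strength=0.0)
    cfg = SimConfig(chrom_lengths_cM=(50.0,), markers_per_chromosome=11,
                    n_individuals=2000, seed=6, selection_loci=(spec,))
    truth = simulate_parent(cfg)
    simulate_s1_population(truth, cfg)
    col = truth.genotypes().calls[:, truth.selection_markers[0]]
    freqs = np.bincount(col, minlength=3) / len(col)
    assert freqs[0] == 0.0
    se = 3 * np.sqrt(0.25 / len(col))
    assert freqs[1] == pytest.approx(0.5, abs=se)
    assert freqs[2] == pytest.approx(0.5, abs=se)


def test_impossible_selection_hits_rejection_cap():
    loci = (SelectionSpec(0, 25.0, "gametic_both", "A", 0.0),
            SelectionSpec(0, 25.0, "gametic_both", "B", 0.0))
    cfg = SimConfig(chrom_lengths_cM=(50.0,), markers_per_chromosome=11,
                    n_individuals=2, seed=7, selection_loci=loci)
    truth = simulate_parent(cfg)
    with pytest.raises(SimulationError):
        simulate_s1_population(truth, cfg)


def test_mirror_phase_invariance():
    """Flipping the parental phase of a marker subset complements exactly
    those markers' calls."""
    cfg = SimConfig(chrom_lengths_cM=(60.0,), markers_per_chromosome=20,
                    n_individuals=40, seed=8)
    truth = simulate_parent(cfg)
    simulate_s1_population(truth, cfg)
    base = truth.genotypes().calls
    flipped_phase = truth.phase.copy()
    subset = np.array([0, 3, 7, 19])
    flipped_phase[subset] = 1 - flipped_phase[subset]
    flipped = truth.genotypes(phase=flipped_phase).calls
    for j in range(base.shape[1]):
        if j in subset:
            assert np.array_equal(flipped[:, j], 2 - base[:, j])
        else:
            assert np.array_equal(flipped[:, j], base[:, j])


def test_individual_streams_stable_under_population_growth():
    cfg_small = SimConfig(chrom_lengths_cM=(50.0,), markers_per_chromosome=10,
                          n_individuals=20, seed=9)
    cfg_big = SimConfig(chrom_lengths_cM=(50.0,), markers_per_chromosome=10,
                        n_individuals=35, seed=9)
    t_small = simulate_s1_population(simulate_parent(cfg_small), cfg_small)
    t_big = simulate_s1_population(simulate_parent(cfg_big), cfg_big)
    assert np.array_equal(t_small.gamete_haps, t_big.gamete_haps[:, :20, :])


def test_read_counts_model_and_invariants():
    cfg = SimConfig(chrom_lengths_cM=(60.0,), markers_per_chromosome=50,
                    n_individuals=100, seed=10, coverage_mean=96.0,
                    seq_error_rate=0.0, missing_rate=0.0)
    truth = simulate_parent(cfg)
    simulate_s1_population(truth, cfg)
    g = truth.genotypes()
    table = simulate_read_counts(g, cfg)
    validate_allele_counts(table)
    # mean depth within 2% of the target at >= 1e4 cells (law of large numbers)
    assert table["depth"].mean() == pytest.approx(96.0, rel=0.02)
    # e=0: homozygotes emit no reads for the other allele, no "other" reads
    by_truth = g.calls.ravel()  # table rows are individual-major
    assert (table["count_other"] == 0).all()
    assert (table.loc[by_truth == 0, "count_b"] == 0).all()
    assert (table.loc[by_truth == 2, "count_a"] == 0).all()
    het = table.loc[by_truth == 1]
    assert (het["count_a"] / het["depth"]).mean() == pytest.approx(0.5, abs=0.01)


def test_missing_rate_zeroes_cells():
    cfg = SimConfig(chrom_lengths_cM=(60.0,), markers_per_chromosome=40,
                    n_individuals=100, seed=12, missing_rate=0.05)
    truth, counts = simulate_dataset(cfg)
    frac0 = (counts["depth"] == 0).mean()
    assert frac0 == pytest.approx(0.05, abs=0.01)


def test_dataset_fully_deterministic_for_seed():
    cfg = SimConfig(chrom_lengths_cM=(50.0, 70.0), markers_per_chromosome=15,
                    n_individuals=30, seed=13)
    t1, c1 = simulate_dataset(cfg)
    t2, c2 = simulate_dataset(cfg)
    assert c1.equals(c2)
    assert np.array_equal(t1.genotypes().calls, t2.genotypes().calls)


def test_obligate_crossovers_approach_twice_map_length():
    """Mean observed crossovers per individual -> 2 L / 100 on dense markers."""
    from capmap import count_obligate_xo

    cfg = SimConfig(chrom_lengths_cM=(100.0,), markers_per_chromosome=201,
                    n_individuals=400, seed=14, missing_rate=0.0, seq_error_rate=0.0)
    truth = simulate_parent(cfg)
    simulate_s1_population(truth, cfg)
    g = truth.genotypes(phase=np.zeros(201, dtype=np.int8))
    per, _ = count_obligate_xo(list(g.marker_ids), g)
    assert per.mean() == pytest.approx(2.0, rel=0.10)
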