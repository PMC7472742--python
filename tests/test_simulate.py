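import dataclasses

import numpy as np
import pytest

import sdrmap as sm
from sdrmap.errors import InvalidConfigError
from sdrmap.io import MISSING

from conftest import split_panel


def _explainable(off, sire, dam):
    off = tuple(sorted(off))
    return any(tuple(sorted((p, m))) == off
               for p in set(sire) for m in set(dam))


def test_family_offspring_are_mendelian_consistent(family_sim):
    """Exhaustive scan: every offspring call is one paternal plus one
    maternal allele."""
    table, _, _ = family_sim
    for family in table.families():
        fam = table.subset_family(family)
        sire = next(i for i, ind in enumerate(fam.individuals) if ind.role == "sire")
        dam = next(i for i, ind in enumerate(fam.individuals) if ind.role == "dam")
        for i, ind in enumerate(fam.individuals):
            if ind.role != "offspring":
                continue
            for j in range(len(fam.markers)):
                call = tuple(fam.calls[i, j])
                if MISSING in call:
                    continue
                assert _explainable(call, tuple(fam.calls[sire, j]),
                                    tuple(fam.calls[dam, j]))


def test_simulation_is_deterministic(config):
    a = sm.simulate_family(config, seed=11)
    b = sm.simulate_family(config, seed=11)
    np.testing.assert_array_equal(a[0].calls, b[0].calls)
    assert a[2].true_sex == b[2].true_sex
    assert a[2].planted_crossovers == b[2].planted_crossovers
    pa = sm.simulate_parentage_panel(config, seed=11)
    pb = sm.simulate_parentage_panel(config, seed=11)
    np.testing.assert_array_equal(pa[0].calls, pb[0].calls)
    np.testing.assert_array_equal(pa[1].calls, pb[1].calls)


def test_no_crossover_family_has_two_paternal_haplotypes(config):
    cfg = dataclasses.replace(config, crossover_rate=0.0,
                              offspring_per_family=10)
    table, phases, truth = sm.simulate_family(cfg, seed=5)
    assert truth.planted_crossovers == []
    for phase in phases:
        fam = table.subset_family(phase.family)
        sire_i = next(i for i, ind in enumerate(fam.individuals)
                      if ind.role == "sire")
        inf = phase.pat_informative
        pat_seqs = set()
        for i, ind in enumerate(fam.individuals):
            if ind.role != "offspring":
                continue
            k = phase.offspring_ids.index(ind.id)
            hap = phase.pat_transmission[k]
            assert len(set(hap)) == 1  # no within-meiosis switching
            pat_seqs.add(tuple(phase.sire_haps[hap[0] - 1, inf]))
        assert len(pat_seqs) <= 2
        mat_seqs = {tuple(phase.dam_haps[phase.mat_transmission[k][0] - 1,
                                         phase.mat_informative])
                    for k in range(len(phase.offspring_ids))}
        assert len(mat_seqs) <= 2


def test_true_sex_follows_sdr_haplotype(config, family_sim):
    table, phases, truth = family_sim
    causal = 0.5 * (config.sdr_interval[0] + config.sdr_interval[1])
    for phase in phases:
        j = int(np.argmin(np.abs(phase.positions - causal)))
        # marker nearest the causal locus lies inside the interval
        assert config.sdr_interval[0] <= phase.positions[j] <= config.sdr_interval[1]
        crossed_near = {ind for ind, (l, r), parent in truth.planted_crossovers
                        if parent == "paternal"}
        for k, ind in enumerate(phase.offspring_ids):
            if ind in crossed_near:
                continue  # haplotype constant anyway only for non-recombinants
            hap = phase.pat_transmission[k, j]
            assert truth.true_sex[ind] == ("male" if hap == 2 else "female")


def test_forced_crossover_shows_opposite_pattern_on_one_side(config):
    """A planted paternal crossover between markers 4 and 5 makes that
    offspring match the other paternal haplotype group (the opposite
    putative sex's genotypes) for all markers on one side."""
    cfg = dataclasses.replace(config, crossover_rate=0.0)
    table, phases, truth = sm.simulate_family(cfg, seed=9,
                                              forced_crossovers=[(0, 0, 3)])
    phase = phases[0]
    oid = phase.offspring_ids[0]
    assert any(ind == oid and lr == ("M04", "M05")
               for ind, lr, parent in truth.planted_crossovers)
    hap = phase.pat_transmission[0]
    assert len(set(hap[:4])) == 1 and len(set(hap[4:])) == 1
    assert hap[0] != hap[-1]


def test_config_rejections(config):
    with pytest.raises(InvalidConfigError, match="SDR interval"):
        dataclasses.replace(config, sdr_interval=(5.0, 6.0)).validate()
    with pytest.raises(InvalidConfigError):
        dataclasses.replace(config, genes_per_lg=(10,) * 23).validate()
    with pytest.raises(InvalidConfigError):
        dataclasses.replace(config, crossover_rate=1.5).validate()
    with pytest.raises(InvalidConfigError):
        dataclasses.replace(config, marker_positions=(1.0, 1.0, 2.0),
                            n_markers_sdr=3).validate()


def test_panel_truth_and_empty_offspring(config, panel_sim):
    offspring, candidates, truth = panel_sim
    assert offspring.n_individuals == config.n_larvae
    assert len({truth.true_parent[o] for o in offspring.individual_ids}) == 1
    # every offspring shares an allele with each true parent at every marker
    males, dam = split_panel(candidates)
    sire = males.subset_individuals([truth.true_parent["L01"]])
    for i in range(offspring.n_individuals):
        for j in range(len(offspring.markers)):
            o = set(offspring.calls[i, j])
            assert o & set(sire.calls[0, j])
            assert o & set(dam.calls[0, j])

    empty, cand2, _ = sm.simulate_parentage_panel(
        dataclasses.replace(config, n_larvae=0), seed=2)
    assert empty.n_individuals == 0
    assert cand2.n_individuals == config.n_candidate_sires + 1


def test_single_weak_marker_flags_low_power(config):
    cfg = dataclasses.replace(config, n_parentage_markers=1,
                              alleles_per_marker=2)
    _, _, truth = sm.simulate_parentage_panel(cfg, seed=3)
    assert truth.low_power_panel
    assert truth.expected_nonexclusion > 0.05


def test_counts_truth_placement(config, assignment16, ortho, counts_sim):
    counts, truth = counts_sim
    assert len(truth.true_de_genes) == config.n_de_genes
    on_sd = [g for g, info in truth.true_de_genes.items()
             if info["linkage_group"] == config.sd_lg]
    assert len(on_sd) == round(config.frac_de_on_sdlg * config.n_de_genes)
    assert set(truth.true_sex_specific_genes) <= set(truth.true_de_genes)

    all_sd = sm.simulate_counts(assignment16, ortho,
                                dataclasses.replace(config, frac_de_on_sdlg=1.0),
                                seed=8)[1]
    assert all(info["linkage_group"] == config.sd_lg
               for info in all_sd.true_de_genes.values())


def test_null_counts_have_no_group_difference(config, assignment16, ortho):
    cfg = dataclasses.replace(config, effect_log2fc=0.0)
    counts, truth = sm.simulate_counts(assignment16, ortho, cfg, seed=6)
    assert len(truth.true_de_genes) == cfg.n_de_genes  # labels still planted
    a_cols = [i for i, s in enumerate(counts.sample_ids)
              if assignment16.groups[s] == "A"]
    b_cols = [i for i, s in enumerate(counts.sample_ids)
              if assignment16.groups[s] == "B"]
    de_idx = [counts.gene_ids.index(g) for g in truth.true_de_genes]
    la = counts.counts[:, a_cols].sum()
    lb = counts.counts[:, b_cols].sum()
    ratios = np.log2((counts.counts[np.ix_(de_idx, a_cols)].sum(axis=1) + 0.5) / la) \
        - np.log2((counts.counts[np.ix_(de_idx, b_cols)].sum(axis=1) + 0.5) / lb)
    # no systematic shift among the labelled genes under the null
    assert abs(np.mean(ratios)) < 0.2
    assert (counts.counts[de_idx].min(axis=1) > 0).mean() > 0.5  # no zeroed group


def test_sex_specific_requires_de_subset(config, assignment16, ortho):
    with pytest.raises(InvalidConfigError):
        sm.simulate_counts(assignment16, ortho,
                           dataclasses.replace(config, n_sex_specific=200),
                           seed=1)
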