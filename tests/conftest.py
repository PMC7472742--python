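import dataclasses

import numpy as np
import pytest

import sdrmap as sm


@pytest.fixture(scope="session")
def config():
    return sm.SimConfig()


@pytest.fixture(scope="session")
def family_sim(config):
    """Two simulated full-sib families on the 15-marker SDR panel."""
    return sm.simulate_family(config, seed=1)


@pytest.fixture(scope="session")
def panel_sim(config):
    """A spawning-group parentage panel that happens to be fully
    informative at this seed (ground-truth power metadata verified in
    the tests that rely on it)."""
    return sm.simulate_parentage_panel(config, seed=2)


@pytest.fixture(scope="session")
def ortho(config):
    return sm.simulate_orthology(config, seed=3)


@pytest.fixture(scope="session")
def assignment16(config, family_sim):
    """Paternal-scenario assignment of 16 larvae (8 per group) from the
    first simulated family — the RNA-sequenced subset."""
    _, phases, _ = family_sim
    a = sm.assign_sex_groups(phases[0], "paternal",
                             sdr_interval=config.sdr_interval)
    keep = sorted(a.groups)[:config.n_expression_samples]
    return sm.SexGroupAssignment(
        "paternal", {s: a.groups[s] for s in keep},
        {s: a.haplotypes[s] for s in keep})


@pytest.fixture(scope="session")
def counts_sim(config, assignment16, ortho):
    return sm.simulate_counts(assignment16, ortho, config, seed=4)


def split_panel(candidates):
    """Split the generated candidate table into (candidate males, dam)."""
    males = candidates.subset_individuals(
        [i.id for i in candidates.individuals if i.role == "candidate"])
    dam = candidates.subset_individuals(
        [i.id for i in candidates.individuals if i.role == "dam"])
    return males, dam


def fig2_style_tables():
    """Hand-built two-family genotype matrix with the canonical structure:
    one male discordant (female pattern) over the last 4 markers, one
    female discordant (male pattern) over the first 3 markers of the
    other family. Male pattern is 12, female pattern 11 throughout."""
    cfg = sm.SimConfig()
    mmap = sm.sdr_marker_map(cfg)
    m = len(mmap.marker_ids)
    male_call, female_call = (1, 2), (1, 1)
    individuals, rows, sexes = [], [], {}

    def add(ind_id, family, sex, calls):
        individuals.append(sm.Individual(ind_id, family, "unknown", "offspring"))
        rows.append(calls)
        sexes[ind_id] = sex

    for family, n_m, n_f in (("A1", 4, 4), ("B", 4, 4)):
        for k in range(n_m):
            calls = [male_call] * m
            if family == "A1" and k == 3:  # male #4: female pattern, last 4
                calls[m - 4:] = [female_call] * 4
            add(f"{family}_m{k + 1}", family, "male", calls)
        for k in range(n_f):
            calls = [female_call] * m
            if family == "B" and k == 3:  # female: male pattern, first 3
                calls[:3] = [male_call] * 3
            add(f"{family}_f{k + 1}", family, "female", calls)
    table = sm.GenotypeTable(tuple(individuals), tuple(mmap.marker_ids),
                             np.array(rows, dtype=np.int32), mmap)
    return table, mmap, sexes


def brute_force_events(table, consensus, min_run):
    """Independent oracle: scan every (individual, contiguous window over
    informative markers) pair for maximal all-discordant windows."""
    from sdrmap.io import MISSING
    events = []
    fam_of = {ind.id: ind.family for ind in table.individuals}
    for ind_id, sex in sorted(consensus.sexes.items()):
        family = fam_of[ind_id]
        i = table.index_of(ind_id)
        opp = 1 if sex == "male" else 0
        seq = []  # (marker, discordant?) over informative, non-missing markers
        for j, marker in enumerate(table.markers):
            if not consensus.informative(family, marker):
                continue
            call = (int(table.calls[i, j, 0]), int(table.calls[i, j, 1]))
            if MISSING in call:
                continue
            seq.append((marker, call == consensus.modes[family][marker][opp]))
        n = len(seq)
        for a in range(n):
            for b in range(a + min_run - 1, n):
                window = seq[a:b + 1]
                if not all(d for _, d in window):
                    continue
                left_ok = a == 0 or not seq[a - 1][1]
                right_ok = b == n - 1 or not seq[b + 1][1]
                if left_ok and right_ok:  # maximal
                    events.append((ind_id, tuple(mk for mk, _ in window)))
    return sorted(events)
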