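import dataclasses

import numpy as np
import pytest

import sdrmap as sm
from sdrmap.errors import (ConsensusUndefinedError, InconsistentEventsError,
                           InvalidConfigError)

from conftest import brute_force_events, fig2_style_tables


def _consensus_table(calls_by_id, sexes, markers, positions=None, family="F1"):
    individuals = tuple(sm.Individual(i, family, "unknown", "offspring")
                        for i in calls_by_id)
    calls = np.array(list(calls_by_id.values()), dtype=np.int32)
    mmap = None
    if positions is not None:
        mmap = sm.MarkerMap.from_records(
            [(m, "lg1", p) for m, p in zip(markers, positions)])
    table = sm.GenotypeTable(individuals, tuple(markers), calls, mmap)
    return table, sm.build_consensus(table, sexes)


def test_consensus_informative_and_tie_rules():
    table, cons = _consensus_table(
        {"m1": [(1, 2), (1, 2), (1, 2)],
         "m2": [(1, 2), (1, 2), (1, 1)],
         "f1": [(1, 1), (1, 2), (1, 2)],
         "f2": [(1, 1), (1, 2), (2, 2)]},
        {"m1": "male", "m2": "male", "f1": "female", "f2": "female"},
        ["a", "b", "c"])
    assert cons.informative("F1", "a")        # 12 vs 11
    assert not cons.informative("F1", "b")    # identical across sexes
    assert not cons.informative("F1", "c")    # female tie 12/22 -> undefined
    assert cons.modes["F1"]["a"] == ((1, 2), (1, 1))


def test_consensus_requires_both_sexes():
    with pytest.raises(ConsensusUndefinedError):
        _consensus_table({"m1": [(1, 2)], "m2": [(1, 2)]},
                         {"m1": "male", "m2": "male"}, ["a"])


def test_fig2_style_fixture_yields_two_opposite_end_events():
    """Two families, one individual with a 4-marker opposite-sex run at
    one end and one with a 3-marker run at the other end: exactly two
    events, trimming opposite ends."""
    table, mmap, sexes = fig2_style_tables()
    cons = sm.build_consensus(table, sexes)
    events = sm.detect_recombinants(table, cons, min_run=3)
    assert len(events) == 2
    by_ind = {e.individual: e for e in events}
    right = by_ind["A1_m4"]
    left = by_ind["B_f4"]
    assert right.run_markers == ("M12", "M13", "M14", "M15")
    assert right.flank_left == "M11" and right.flank_right is None
    assert left.run_markers == ("M01", "M02", "M03")
    assert left.flank_left is None and left.flank_right == "M04"

    interval = sm.refine_interval(events, mmap)
    # hand-computed margins: run edges M03 (0.57 Mbp) and M12 (2.685 Mbp)
    assert interval.start_mbp == pytest.approx(0.57)
    assert interval.end_mbp == pytest.approx(2.685)
    positions = [mmap.position(m) for m in mmap.marker_ids]
    assert min(positions) < interval.start_mbp < interval.end_mbp < max(positions)
    assert interval.n_markers == 10


def test_min_run_threshold_suppresses_short_runs():
    table, mmap, sexes = fig2_style_tables()
    cons = sm.build_consensus(table, sexes)
    assert len(sm.detect_recombinants(table, cons, min_run=4)) == 1
    assert len(sm.detect_recombinants(table, cons, min_run=5)) == 0
    with pytest.raises(InvalidConfigError):
        sm.detect_recombinants(table, cons, min_run=0)


def test_missing_and_uninformative_markers_do_not_break_runs():
    markers = [f"x{j}" for j in range(6)]
    positions = [float(j) for j in range(6)]
    male, female = (1, 2), (1, 1)
    # individual discordant at 0,1,3 with a missing call at 2: one run of 3
    calls = {
        "m1": [male] * 6, "m2": [male] * 6,
        "f1": [female] * 6, "f2": [female] * 6,
        "m3": [female, female, (0, 0), female, male, male],
    }
    table, cons = _consensus_table(
        calls, {i: ("male" if i.startswith("m") else "female") for i in calls},
        markers, positions)
    events = sm.detect_recombinants(table, cons, min_run=3)
    mine = [e for e in events if e.individual == "m3"]
    assert len(mine) == 1
    assert mine[0].run_markers == ("x0", "x1", "x3")
    assert mine[0].flank_right == "x4"


def test_all_concordant_yields_no_events():
    table, mmap, sexes = fig2_style_tables()
    concordant_ids = [i for i in table.individual_ids
                      if i not in ("A1_m4", "B_f4")]
    sub = table.subset_individuals(concordant_ids)
    cons = sm.build_consensus(sub, {i: sexes[i] for i in concordant_ids})
    assert sm.detect_recombinants(sub, cons, min_run=3) == []
    interval = sm.refine_interval([], mmap)
    assert interval.start_mbp == pytest.approx(min(
        mmap.position(m) for m in mmap.marker_ids))
    assert interval.end_mbp == pytest.approx(max(
        mmap.position(m) for m in mmap.marker_ids))


def test_single_event_refines_one_side_only():
    table, mmap, sexes = fig2_style_tables()
    cons = sm.build_consensus(table, sexes)
    events = sm.detect_recombinants(table, cons, min_run=3)
    left_only = [e for e in events if e.individual == "B_f4"]
    interval = sm.refine_interval(left_only, mmap)
    assert interval.start_mbp == pytest.approx(0.57)    # run margin
    assert interval.end_mbp == pytest.approx(3.39)      # outermost marker


def test_refinement_is_monotone():
    table, mmap, sexes = fig2_style_tables()
    cons = sm.build_consensus(table, sexes)
    events = sm.detect_recombinants(table, cons, min_run=3)
    one = sm.refine_interval(events[:1], mmap)
    both = sm.refine_interval(events, mmap)
    assert both.width_mbp <= one.width_mbp
    assert one.start_mbp <= both.start_mbp and both.end_mbp <= one.end_mbp


def test_contradictory_events_raise():
    markers = [f"x{j}" for j in range(6)]
    positions = [float(j) for j in range(6)]
    male, female = (1, 2), (1, 1)
    calls = {
        "m1": [male] * 6, "m2": [male] * 6, "m3": [male] * 6,
        "m4": [male] * 6, "f1": [female] * 6, "f2": [female] * 6,
        "m5": [female] * 4 + [male] * 2,   # discordant over the left 4
        "m6": [male] * 2 + [female] * 4,   # discordant over the right 4
    }
    table, cons = _consensus_table(
        calls, {i: ("male" if i.startswith("m") else "female") for i in calls},
        markers, positions)
    events = sm.detect_recombinants(table, cons, min_run=3)
    assert len(events) == 2
    # m5 allows only [3,5]; m6 allows only [0,2]: empty intersection
    with pytest.raises(InconsistentEventsError):
        sm.refine_interval(events, table.marker_map)


def test_gene_count_inside_interval(ortho):
    table, mmap, sexes = fig2_style_tables()
    cons = sm.build_consensus(table, sexes)
    events = sm.detect_recombinants(table, cons, min_run=3)
    interval = sm.refine_interval(events, mmap, ortho)
    expected = len(ortho.genes_in("tLG8", interval.start_mbp,
                                  interval.end_mbp))
    assert interval.n_genes == expected


def test_detection_matches_brute_force_oracle():
    """Greedy run detection agrees with an exhaustive window scan on
    small noisy families (<=12 individuals x 15 markers)."""
    rng = np.random.default_rng(17)
    for trial in range(25):
        markers = [f"x{j}" for j in range(15)]
        positions = [float(j) for j in range(15)]
        male, female = (1, 2), (1, 1)
        calls, sexes = {}, {}
        n_m, n_f = rng.integers(2, 7), rng.integers(2, 7)
        for k in range(n_m + n_f):
            sex = "male" if k < n_m else "female"
            own, opp = (male, female) if sex == "male" else (female, male)
            row = []
            for j in range(15):
                u = rng.random()
                if u < 0.12:
                    row.append(opp)
                elif u < 0.2:
                    row.append((0, 0))
                else:
                    row.append(own)
            calls[f"i{k}"] = row
            sexes[f"i{k}"] = sex
        table, cons = _consensus_table(calls, sexes, markers, positions)
        got = sorted((e.individual, e.run_markers)
                     for e in sm.detect_recombinants(table, cons, min_run=2))
        assert got == brute_force_events(table, cons, min_run=2)


def test_planted_crossovers_are_recovered(config):
    """Detected breakpoint gaps contain the planted inter-marker interval
    for every paternal event with a sufficient discordant run."""
    cfg = dataclasses.replace(config, crossover_rate=0.35, n_families=2)
    table, _, truth = sm.simulate_family(cfg, seed=31)
    sexes = {i: s for i, s in truth.true_sex.items()}
    # concordance filter drops markers that are not sex-associated
    cons = sm.build_consensus(table, sexes, min_concordance=0.8)
    events = sm.detect_recombinants(table, cons, min_run=3)
    planted = {(ind, lr) for ind, lr, parent in truth.planted_crossovers
               if parent == "paternal"}
    assert events, "expected at least one detected event at this rate"
    mmap = table.marker_map
    for e in events:
        matches = [lr for ind, lr in planted if ind == e.individual]
        assert matches, f"event for {e.individual} has no planted crossover"
        lo, hi = (mmap.position(matches[0][0]), mmap.position(matches[0][1]))
        covered = any(g0 <= lo and hi <= g1 for g0, g1 in e.breakpoints) \
            or e.flank_left is None and hi <= mmap.position(e.run_markers[-1]) \
            or e.flank_right is None and lo >= mmap.position(e.run_markers[0])
        assert covered


def test_refined_interval_covers_causal_locus(config):
    """Over 100 simulated families with planted crossovers and sex-linked
    markers selected by the concordance filter, the refined interval
    contains the causal SDR position in >= 95% of replicates."""
    cfg = dataclasses.replace(config, n_families=1, crossover_rate=0.4)
    causal = 0.5 * (cfg.sdr_interval[0] + cfg.sdr_interval[1])
    covered = total = 0
    for rep in range(100):
        table, _, truth = sm.simulate_family(cfg, seed=500 + rep)
        cons = sm.build_consensus(table, truth.true_sex, min_concordance=0.8)
        events = sm.detect_recombinants(table, cons, min_run=3)
        interval = sm.refine_interval(events, table.marker_map)
        total += 1
        covered += interval.start_mbp <= causal <= interval.end_mbp
    assert covered / total >= 0.95
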