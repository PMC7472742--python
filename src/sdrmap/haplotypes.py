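"""Parental-haplotype phasing and phenotype-free sex-group assignment.

In a full-sib family segregating an XY-type sex-determining region (SDR),
the sire's two haplotypes over the SDR markers split the offspring into
two putative sex-groups even though larvae show no sexual phenotype. The
same machinery applied to the dam's haplotypes gives the alternative
ZW-type grouping, and a size-preserving random permutation of labels
gives a negative-control grouping.

Phasing is greedy: it is seeded at the most informative marker (sire
heterozygous, dam homozygous, most offspring resolvable) and extended
marker by marker, choosing at each new marker the orientation of the two
parental alleles that keeps most offspring on the haplotype they carried
at the previous informative marker. An offspring whose transmitted
haplotype switches along the marker order is flagged as a candidate
recombinant when at least ``min_run`` consecutive informative markers
support the alternative haplotype.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidConfigError, UnphaseableFamilyError
from .io import MISSING, GenotypeTable, MarkerMap

logger = logging.getLogger(__name__)

SCENARIOS = ("paternal", "maternal", "random")


@dataclass(frozen=True)
class ParentalPhase:
    """Phased parental haplotypes and per-offspring transmissions for one
    full-sib family.

    ``sire_haps``/``dam_haps`` hold the allele carried by each parental
    haplotype (rows: haplotype 1 and 2) at every marker; at markers where
    a parent is homozygous the two rows coincide. ``pat_transmission``
    and ``mat_transmission`` record, per offspring and marker, which
    parental haplotype (1 or 2) the offspring inherited, or 0 when the
    transmission is unresolved (uninformative marker, missing call, or
    Mendelian inconsistency).
    """

    family: str
    sire_id: str
    dam_id: str
    markers: tuple[str, ...]
    positions: np.ndarray          # (m,) Mbp, non-decreasing
    sire_haps: np.ndarray          # (2, m) alleles
    dam_haps: np.ndarray           # (2, m)
    pat_informative: np.ndarray    # (m,) bool
    mat_informative: np.ndarray    # (m,) bool
    offspring_ids: tuple[str, ...]
    pat_transmission: np.ndarray   # (n, m) in {0, 1, 2}
    mat_transmission: np.ndarray   # (n, m)
    candidate_recombinants: tuple[str, ...] = ()
    n_inconsistent_calls: int = 0

    def haplotype_groups(self) -> dict[tuple[int, int], list[str]]:
        """Partition offspring into <=4 groups by (paternal, maternal)
        majority haplotype; offspring with an unresolved side are omitted."""
        groups: dict[tuple[int, int], list[str]] = {}
        for i, ind in enumerate(self.offspring_ids):
            p = _majority_label(self.pat_transmission[i])
            m = _majority_label(self.mat_transmission[i])
            if p and m:
                groups.setdefault((p, m), []).append(ind)
        return groups


@dataclass(frozen=True)
class SexGroupAssignment:
    """Offspring -> putative sex-group labels under a named scenario."""

    scenario: str                       # paternal / maternal / random
    groups: dict                        # individual -> "A" | "B"
    haplotypes: dict                    # individual -> inherited hap (1/2) or None
    unassignable: tuple[str, ...] = ()
    seed: int | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise InvalidConfigError(f"unknown scenario {self.scenario!r}")

    @property
    def group_sizes(self) -> dict:
        sizes = {"A": 0, "B": 0}
        for g in self.groups.values():
            sizes[g] += 1
        return sizes

    def samples(self, group: str) -> list[str]:
        return [i for i, g in self.groups.items() if g == group]


def _majority_label(labels: np.ndarray) -> int:
    ones = int(np.sum(labels == 1))
    twos = int(np.sum(labels == 2))
    if ones == twos == 0 or ones == twos:
        return 0
    return 1 if ones > twos else 2


def _resolve_transmission(off: np.ndarray, het: tuple[int, int],
                          other: tuple[int, int]) -> int:
    """Allele of the heterozygous parent ``het`` transmitted to offspring
    call ``off``, given the other parent's call; 0 when unresolvable or
    Mendelian-inconsistent."""
    o = (int(off[0]), int(off[1]))
    if MISSING in o:
        return 0
    candidates = set()
    for h in set(het):
        for d in set(other):
            if tuple(sorted((h, d))) == o:
                candidates.add(h)
    if len(candidates) == 1:
        return candidates.pop()
    return 0  # ambiguous (both parental alleles fit) or inconsistent (none)


def _informative(het_call: np.ndarray, other_call: np.ndarray) -> bool:
    """A marker is informative for the heterozygous parent iff that parent
    is heterozygous (non-missing) and transmission is resolvable for every
    possible offspring call: the other parent homozygous, or carrying no
    allele in common with the heterozygous parent."""
    a, b = int(het_call[0]), int(het_call[1])
    c, d = int(other_call[0]), int(other_call[1])
    if MISSING in (a, b, c, d) or a == b:
        return False
    return c == d or not ({a, b} & {c, d})


def _find_parents(table: GenotypeTable, family: str) -> tuple[int, int]:
    sire = dam = None
    for i, ind in enumerate(table.individuals):
        if ind.family != family:
            continue
        if ind.role == "sire":
            sire = i
        elif ind.role == "dam":
            dam = i
    if sire is None or dam is None:
        raise UnphaseableFamilyError(
            f"family {family!r}: both parents must be genotyped (rows with "
            "role 'sire' and 'dam'); reconstruction from offspring is not "
            "supported")
    return sire, dam


def phase_family(genotypes: GenotypeTable, marker_map: MarkerMap | None,
                 family: str, min_run: int = 3) -> ParentalPhase:
    """Phase the parental haplotypes of one full-sib family.

    Returns a :class:`ParentalPhase` with per-offspring transmitted
    haplotypes on both parental sides. Raises
    :class:`UnphaseableFamilyError` when no marker is paternally
    informative. Mendelian-inconsistent offspring calls are treated as
    missing for phasing and counted in ``n_inconsistent_calls``.
    """
    marker_map = marker_map or genotypes.marker_map
    fam = genotypes.subset_family(family)
    sire_i, dam_i = _find_parents(fam, family)
    off_idx = [i for i, ind in enumerate(fam.individuals)
               if ind.role == "offspring"]
    offspring_ids = tuple(fam.individuals[i].id for i in off_idx)
    m = len(fam.markers)
    sire_calls = fam.calls[sire_i]
    dam_calls = fam.calls[dam_i]

    if marker_map is not None:
        positions = np.array([marker_map.position(mk) for mk in fam.markers])
    else:
        positions = np.arange(m, dtype=float)

    pat_inf = np.array([_informative(sire_calls[j], dam_calls[j]) for j in range(m)])
    mat_inf = np.array([_informative(dam_calls[j], sire_calls[j]) for j in range(m)])
    if not pat_inf.any():
        raise UnphaseableFamilyError(
            f"family {family!r}: sire is homozygous or missing at every "
            "marker — no paternally informative marker")

    n_inconsistent = 0

    def transmissions(het_calls, other_calls, informative):
        nonlocal n_inconsistent
        # transmitted *allele* per (offspring, marker); 0 = unresolved
        alleles = np.zeros((len(off_idx), m), dtype=np.int32)
        for j in np.flatnonzero(informative):
            het = (int(het_calls[j][0]), int(het_calls[j][1]))
            other = (int(other_calls[j][0]), int(other_calls[j][1]))
            for k, i in enumerate(off_idx):
                off = fam.calls[i, j]
                a = _resolve_transmission(off, het, other)
                if a == 0 and MISSING not in (int(off[0]), int(off[1])):
                    # informative marker, non-missing call, yet unresolvable
                    if not _explainable(off, het_calls[j], other_calls[j]):
                        n_inconsistent += 1
                alleles[k, j] = a
        return alleles

    pat_alleles = transmissions(sire_calls, dam_calls, pat_inf)
    mat_alleles = transmissions(dam_calls, sire_calls, mat_inf)

    sire_haps, pat_trans = _chain_phase(sire_calls, pat_inf, pat_alleles)
    dam_haps, mat_trans = _chain_phase(dam_calls, mat_inf, mat_alleles)

    recombinants = tuple(
        offspring_ids[k] for k in range(len(off_idx))
        if _has_switch(pat_trans[k], pat_inf, min_run)
        or _has_switch(mat_trans[k], mat_inf, min_run))

    if n_inconsistent:
        logger.warning("family %s: %d Mendelian-inconsistent calls treated "
                       "as missing for phasing", family, n_inconsistent)

    return ParentalPhase(
        family=family, sire_id=fam.individuals[sire_i].id,
        dam_id=fam.individuals[dam_i].id, markers=fam.markers,
        positions=positions, sire_haps=sire_haps, dam_haps=dam_haps,
        pat_informative=pat_inf, mat_informative=mat_inf,
        offspring_ids=offspring_ids, pat_transmission=pat_trans,
        mat_transmission=mat_trans, candidate_recombinants=recombinants,
        n_inconsistent_calls=n_inconsistent)


def _explainable(off, het_call, other_call) -> bool:
    o = tuple(sorted((int(off[0]), int(off[1]))))
    for h in set((int(het_call[0]), int(het_call[1]))):
        for d in set((int(other_call[0]), int(other_call[1]))):
            if tuple(sorted((h, d))) == o:
                return True
    return False


def _chain_phase(parent_calls: np.ndarray, informative: np.ndarray,
                 trans_alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orient the parent's allele pair at each informative marker into two
    haplotypes by greedy chaining, and convert per-offspring transmitted
    alleles into haplotype labels (1/2, 0 unresolved)."""
    n, m = trans_alleles.shape
    haps = np.zeros((2, m), dtype=np.int32)
    labels = np.zeros((n, m), dtype=np.int32)
    for j in range(m):  # homozygous markers: both haplotypes carry the allele
        a, b = int(parent_calls[j][0]), int(parent_calls[j][1])
        if a == b:
            haps[:, j] = a
    inf_idx = list(np.flatnonzero(informative))
    if not inf_idx:
        return haps, labels

    # seed at the informative marker resolving the most offspring
    resolved = [(int(np.sum(trans_alleles[:, j] > 0)), -j) for j in inf_idx]
    seed_j = inf_idx[int(np.argmax([r for r, _ in resolved]))]

    def orient(j, hap1_allele):
        a, b = int(parent_calls[j][0]), int(parent_calls[j][1])
        hap2_allele = b if hap1_allele == a else a
        haps[0, j], haps[1, j] = hap1_allele, hap2_allele
        for k in range(n):
            t = trans_alleles[k, j]
            labels[k, j] = 0 if t == 0 else (1 if t == hap1_allele else 2)

    orient(seed_j, min(int(parent_calls[seed_j][0]), int(parent_calls[seed_j][1])))

    # extend outward from the seed in both directions
    pos_in_chain = inf_idx.index(seed_j)
    order = inf_idx[pos_in_chain + 1:] + inf_idx[:pos_in_chain][::-1]
    prev_for = {}
    for idx in range(pos_in_chain + 1, len(inf_idx)):
        prev_for[inf_idx[idx]] = inf_idx[idx - 1]
    for idx in range(pos_in_chain - 1, -1, -1):
        prev_for[inf_idx[idx]] = inf_idx[idx + 1]

    for j in order:
        pj = prev_for[j]
        a, b = int(parent_calls[j][0]), int(parent_calls[j][1])
        agree_a = agree_b = 0  # votes for hap1 = allele a vs allele b
        for k in range(n):
            prev_label = labels[k, pj]
            t = trans_alleles[k, j]
            if prev_label == 0 or t == 0:
                continue
            if (t == a) == (prev_label == 1):
                agree_a += 1
            else:
                agree_b += 1
        hap1 = a if agree_a >= agree_b else b
        if agree_a == agree_b:
            hap1 = min(a, b)  # no linkage evidence: deterministic tie-break
        orient(j, hap1)
    return haps, labels


def _has_switch(labels: np.ndarray, informative: np.ndarray, min_run: int) -> bool:
    """True when the offspring's haplotype-label sequence over informative
    markers contains >=min_run consecutive labels opposite to the starting
    haplotype (an accepted switch)."""
    seq = [int(x) for x in labels[informative] if x != 0]
    if not seq:
        return False
    start = seq[0]
    run = 0
    for x in seq:
        if x != start:
            run += 1
            if run >= min_run:
                return True
        else:
            run = 0
    return False


def assign_sex_groups(phase: ParentalPhase, scenario: str,
                      seed: int | None = None,
                      sdr_interval: tuple[float, float] | None = None
                      ) -> SexGroupAssignment:
    """Assign offspring to putative sex-groups A/B.

    ``paternal`` groups by the paternal haplotype carried across the SDR
    interval (the XY reading), ``maternal`` by the maternal haplotype (the
    ZW reading), and ``random`` draws a label permutation preserving the
    paternal-scenario group sizes using ``seed``.

    An offspring is ``unassignable`` when no informative marker inside the
    interval resolves its transmission, or when resolved markers inside
    the interval disagree (a crossover within the interval).
    """
    if scenario not in SCENARIOS:
        raise InvalidConfigError(f"unknown scenario {scenario!r}")

    def interval_labels(trans: np.ndarray, informative: np.ndarray):
        if sdr_interval is None:
            inside = np.ones(len(phase.positions), dtype=bool)
        else:
            lo, hi = sdr_interval
            inside = (phase.positions >= lo) & (phase.positions <= hi)
        use = inside & informative
        groups, haps, unassignable = {}, {}, []
        for k, ind in enumerate(phase.offspring_ids):
            vals = {int(x) for x in trans[k, use] if x != 0}
            if len(vals) == 1:
                hap = vals.pop()
                groups[ind] = "A" if hap == 1 else "B"
                haps[ind] = hap
            else:
                unassignable.append(ind)
        return groups, haps, unassignable

    if scenario == "paternal":
        groups, haps, un = interval_labels(phase.pat_transmission,
                                           phase.pat_informative)
    elif scenario == "maternal":
        groups, haps, un = interval_labels(phase.mat_transmission,
                                           phase.mat_informative)
    else:
        if seed is None:
            raise InvalidConfigError("random scenario needs a seed")
        base, _, un = interval_labels(phase.pat_transmission,
                                      phase.pat_informative)
        rng = np.random.default_rng(seed)
        inds = sorted(base)
        labels = [base[i] for i in inds]
        rng.shuffle(labels)
        groups = dict(zip(inds, labels))
        haps = {i: None for i in inds}

    if un:
        logger.info("scenario %s, family %s: %d offspring unassignable",
                    scenario, phase.family, len(un))
    return SexGroupAssignment(scenario=scenario, groups=groups,
                              haplotypes=haps, unassignable=tuple(un),
                              seed=seed if scenario == "random" else None)


def merge_assignments(assignments: Sequence[SexGroupAssignment]
                      ) -> SexGroupAssignment:
    """Pool per-family assignments of the same scenario into one.

    Group labels are arbitrary per family (haplotype 1 vs 2 has no
    cross-family meaning), so pooling is only meaningful when families
    were phased against a shared reference or when a single family is
    analysed; the caller is responsible for that.
    """
    scenarios = {a.scenario for a in assignments}
    if len(scenarios) != 1:
        raise InvalidConfigError("cannot merge assignments of mixed scenarios")
    groups, haps, un = {}, {}, []
    for a in assignments:
        groups.update(a.groups)
        haps.update(a.haplotypes)
        un.extend(a.unassignable)
    return SexGroupAssignment(scenario=scenarios.pop(), groups=groups,
                              haplotypes=haps, unassignable=tuple(un),
                              seed=assignments[0].seed)
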