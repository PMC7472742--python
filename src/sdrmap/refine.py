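"""Recombinant detection and SDR interval refinement.

Within a full-sib family whose members have known (or putatively
assigned) sexes, each marker gets a per-sex modal genotype; markers
where the two modes differ are sex-informative. An individual matching
the *opposite* sex's modal genotype over a run of adjacent
sex-informative markers evidences a crossover, and the margins of such
runs — taken over all individuals and families — delimit the
sex-determining region: the SDR must lie where every individual still
shows its own sex's pattern.

Conventions: missing calls and sex-uninformative markers neither extend
nor break a run; a non-missing call matching neither mode breaks a run
and counts as concordant (it is not the opposite pattern). The refined
interval is closed and bounded by the margin markers of the discordant
runs (the innermost marker of each run): the true crossover lies in the
gap beyond the margin, so the interval conservatively includes that gap
and never excludes the causal locus on error-free data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (ConsensusUndefinedError, InconsistentEventsError,
                     InvalidConfigError)
from .io import MISSING, GenotypeTable, MarkerMap, OrthologyMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SexConsensus:
    """Per-family, per-marker modal genotypes of each sex.

    ``modes[family][marker]`` is ``(male_mode, female_mode)`` where each
    mode is an allele pair or None (no calls / tie). A marker is
    sex-informative for a family iff both modes are defined and differ.
    """

    modes: dict           # family -> {marker: (male_mode, female_mode)}
    sexes: dict           # individual -> "male" | "female"
    markers: tuple[str, ...]
    positions: np.ndarray

    def informative(self, family: str, marker: str) -> bool:
        male, female = self.modes[family].get(marker, (None, None))
        return male is not None and female is not None and male != female

    def informative_markers(self, family: str) -> list[str]:
        return [m for m in self.markers if self.informative(family, m)]


@dataclass(frozen=True)
class RecombinationEvent:
    """A maximal opposite-sex run of adjacent sex-informative markers."""

    individual: str
    family: str
    run_markers: tuple[str, ...]     # informative discordant markers
    flank_left: str | None           # last concordant marker before the run
    flank_right: str | None          # first concordant marker after the run
    # inter-marker gaps (lo_mbp, hi_mbp) on each flanked side of the run
    breakpoints: tuple[tuple[float, float], ...]

    @property
    def run_length(self) -> int:
        return len(self.run_markers)


@dataclass(frozen=True)
class SDRInterval:
    linkage_group: str
    start_mbp: float
    end_mbp: float
    events: tuple[RecombinationEvent, ...] = ()
    n_markers: int = 0
    n_genes: int | None = None

    @property
    def width_mbp(self) -> float:
        return self.end_mbp - self.start_mbp


def build_consensus(genotypes: GenotypeTable,
                    sexes: dict[str, str] | None = None,
                    min_concordance: float = 0.0) -> SexConsensus:
    """Modal genotype per (family, marker, sex).

    ``sexes`` maps individual ids to phenotype (or putative) sex labels;
    when None, the table's own non-``unknown`` labels of offspring rows
    are used. Ties in the mode make the marker uninformative. A family
    represented by one sex only raises :class:`ConsensusUndefinedError`.

    ``min_concordance`` optionally drops markers whose modal genotype is
    carried by less than that fraction of each sex's non-missing calls —
    a marker-selection step emulating panels restricted to
    sex-associated markers; 0 keeps every marker with differing modes.
    """
    if sexes is None:
        sexes = {ind.id: ind.sex for ind in genotypes.individuals
                 if ind.sex in ("male", "female") and ind.role == "offspring"}
    for ind, s in sexes.items():
        if s not in ("male", "female"):
            raise InvalidConfigError(f"sex label {s!r} for {ind!r}")

    if genotypes.marker_map is not None:
        positions = np.array([genotypes.marker_map.position(m)
                              for m in genotypes.markers])
    else:
        positions = np.arange(len(genotypes.markers), dtype=float)

    modes: dict[str, dict] = {}
    fam_of = {ind.id: ind.family for ind in genotypes.individuals}
    families = sorted({fam_of[i] for i in sexes if i in fam_of})
    for family in families:
        members = [i for i in sexes if fam_of.get(i) == family]
        present = {sexes[i] for i in members}
        if present != {"male", "female"}:
            raise ConsensusUndefinedError(
                f"family {family!r} has individuals of one sex only; "
                "consensus undefined")
        fam_modes = {}
        for j, marker in enumerate(genotypes.markers):
            by_sex, support = {}, {}
            for sex in ("male", "female"):
                counts: dict[tuple[int, int], int] = {}
                for i in members:
                    if sexes[i] != sex:
                        continue
                    c = genotypes.calls[genotypes.index_of(i), j]
                    call = (int(c[0]), int(c[1]))
                    if MISSING in call:
                        continue
                    counts[call] = counts.get(call, 0) + 1
                if not counts:
                    by_sex[sex] = None
                    continue
                best = max(counts.values())
                top = [c for c, v in counts.items() if v == best]
                by_sex[sex] = top[0] if len(top) == 1 else None  # tie -> None
                support[sex] = best / sum(counts.values())
            mode_pair = (by_sex["male"], by_sex["female"])
            if (min_concordance > 0 and None not in mode_pair
                    and min(support.values()) < min_concordance):
                mode_pair = (None, None)  # not sex-associated enough
            fam_modes[marker] = mode_pair
        modes[family] = fam_modes
    return SexConsensus(modes=modes, sexes=dict(sexes),
                        markers=genotypes.markers, positions=positions)


def detect_recombinants(genotypes: GenotypeTable, consensus: SexConsensus,
                        min_run: int = 3) -> list[RecombinationEvent]:
    """Find every maximal opposite-sex run of length >= ``min_run``.

    Runs are measured over sex-informative markers only; missing calls
    skip a marker without breaking the run. Breakpoint gaps extend to the
    chromosome end on an unflanked side (no gap recorded there).
    """
    if min_run < 1:
        raise InvalidConfigError("min_run must be >= 1")
    fam_of = {ind.id: ind.family for ind in genotypes.individuals}
    pos_of = dict(zip(consensus.markers, consensus.positions))
    events: list[RecombinationEvent] = []

    for ind_id, sex in sorted(consensus.sexes.items()):
        family = fam_of.get(ind_id)
        if family is None or family not in consensus.modes:
            continue
        i = genotypes.index_of(ind_id)
        own = 0 if sex == "male" else 1
        opp = 1 - own
        # walk informative markers; build state sequence
        states: list[tuple[str, str]] = []  # (marker, "conc"|"disc")
        for j, marker in enumerate(genotypes.markers):
            if not consensus.informative(family, marker):
                continue
            modes = consensus.modes[family][marker]
            call = (int(genotypes.calls[i, j, 0]), int(genotypes.calls[i, j, 1]))
            if MISSING in call:
                continue
            states.append((marker, "disc" if call == modes[opp] else "conc"))

        k = 0
        while k < len(states):
            if states[k][1] != "disc":
                k += 1
                continue
            k2 = k
            while k2 + 1 < len(states) and states[k2 + 1][1] == "disc":
                k2 += 1
            run = tuple(s[0] for s in states[k:k2 + 1])
            if len(run) >= min_run:
                flank_left = states[k - 1][0] if k > 0 else None
                flank_right = states[k2 + 1][0] if k2 + 1 < len(states) else None
                gaps = []
                if flank_left is not None:
                    gaps.append((pos_of[flank_left], pos_of[run[0]]))
                if flank_right is not None:
                    gaps.append((pos_of[run[-1]], pos_of[flank_right]))
                events.append(RecombinationEvent(
                    individual=ind_id, family=family, run_markers=run,
                    flank_left=flank_left, flank_right=flank_right,
                    breakpoints=tuple(gaps)))
            k = k2 + 1
    return events


def _intersect(pieces_a: list[tuple[float, float]],
               pieces_b: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out = []
    for a0, a1 in pieces_a:
        for b0, b1 in pieces_b:
            lo, hi = max(a0, b0), min(a1, b1)
            if lo <= hi:
                out.append((lo, hi))
    return out


def _allowed_region(event: RecombinationEvent, span: tuple[float, float],
                    pos_of: dict) -> list[tuple[float, float]]:
    """Region consistent with this individual's sex: the concordant
    side(s) of the run, closed at the run's margin markers (the crossover
    lies in the gap just beyond the margin, so the gap is kept)."""
    lo, hi = span
    pieces = []
    if event.flank_left is not None:
        pieces.append((lo, pos_of[event.run_markers[0]]))
    if event.flank_right is not None:
        pieces.append((pos_of[event.run_markers[-1]], hi))
    return pieces  # empty when discordant across the whole chromosome


def refine_interval(events: list[RecombinationEvent], marker_map: MarkerMap,
                    ortho: OrthologyMap | None = None,
                    linkage_group: str | None = None) -> SDRInterval:
    """Intersect the sex-concordant complements of all events.

    With no events the full marker span is returned (no refinement). An
    empty intersection raises :class:`InconsistentEventsError`. When the
    intersection is disconnected the widest component is kept (logged).
    """
    mm = marker_map.ordered()
    run_markers = {m for e in events for m in e.run_markers}
    lgs = {mm.linkage_group(m) for m in run_markers}
    if linkage_group is None:
        if len(lgs) > 1:
            raise InvalidConfigError(f"events span several linkage groups: {sorted(lgs)}")
        linkage_group = lgs.pop() if lgs else str(mm.df["linkage_group"].iloc[0])
    sub = mm.df[mm.df["linkage_group"] == linkage_group]
    positions = sub["position_mbp"].astype(float)
    span = (float(positions.min()), float(positions.max()))
    pos_of = dict(zip(sub["marker_id"], positions))

    pieces = [span]
    for e in events:
        pieces = _intersect(pieces, _allowed_region(e, span, pos_of))
        if not pieces:
            raise InconsistentEventsError(
                "no interval is consistent with every individual's sex; "
                "check phenotypes and genotypes")
    if len(pieces) > 1:
        logger.warning("refined region is disconnected (%d components); "
                       "keeping the widest", len(pieces))
        pieces.sort(key=lambda p: p[1] - p[0])
    start, end = pieces[-1]
    n_markers = int(sum((positions >= start) & (positions <= end)))
    n_genes = (len(ortho.genes_in(linkage_group, start, end))
               if ortho is not None else None)
    return SDRInterval(linkage_group=linkage_group, start_mbp=start,
                       end_mbp=end, events=tuple(events),
                       n_markers=n_markers, n_genes=n_genes)


def events_frame(events: list[RecombinationEvent]) -> pd.DataFrame:
    rows = [(e.individual, e.family, ",".join(e.run_markers), e.run_length,
             e.flank_left or "", e.flank_right or "",
             ";".join(f"{a:.4g}-{b:.4g}" for a, b in e.breakpoints))
            for e in events]
    return pd.DataFrame(rows, columns=["individual", "family", "run_markers",
                                       "run_length", "flank_left",
                                       "flank_right", "breakpoint_gaps_mbp"])
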