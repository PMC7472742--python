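"""Exclusion-principle parentage testing over multi-allelic markers.

A candidate parent is excluded at a marker when no allele it carries can
explain the offspring's genotype: in the duo case, when it shares no
allele with the offspring; in the trio case (the other parent known),
when no pairing of one candidate allele with one known-parent allele
reproduces the offspring call. Markers with a missing call in either
individual never contribute. The default verdict threshold is one
mismatching marker (strict exclusion principle); raising it tolerates
genotyping error.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, ReferenceError_
from .io import MISSING, GenotypeTable

VERDICT_EXCLUDED = "excluded"
VERDICT_COMPATIBLE = "compatible"
VERDICT_UNTESTABLE = "untestable"


@dataclass(frozen=True)
class ExclusionReport:
    """Per (offspring, candidate) exclusion counts and verdicts.

    ``table`` columns: offspring, candidate, n_markers_tested,
    exclusion_count, verdict. A pair with zero co-genotyped markers is
    ``untestable`` — never ``compatible``.
    """

    table: pd.DataFrame
    threshold: int = 1

    def verdict(self, offspring: str, candidate: str) -> str:
        sub = self.table[(self.table["offspring"] == offspring)
                         & (self.table["candidate"] == candidate)]
        if sub.empty:
            raise ReferenceError_(f"no pair ({offspring!r}, {candidate!r})")
        return str(sub["verdict"].iloc[0])

    def exclusion_count(self, offspring: str, candidate: str) -> int:
        sub = self.table[(self.table["offspring"] == offspring)
                         & (self.table["candidate"] == candidate)]
        if sub.empty:
            raise ReferenceError_(f"no pair ({offspring!r}, {candidate!r})")
        return int(sub["exclusion_count"].iloc[0])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _marker_excluded(off: tuple[int, int], cand: tuple[int, int],
                     known: tuple[int, int] | None) -> bool:
    """Exclusion at one marker. ``known`` is the assumed other parent's
    call, or None for the duo test (also used when the known parent's
    call is missing)."""
    if known is None or MISSING in known:
        return not (set(cand) & set(off))
    for c in set(cand):
        for d in set(known):
            if tuple(sorted((c, d))) == tuple(sorted(off)):
                return False
    return True


def exclusion_counts(offspring: GenotypeTable, candidates: GenotypeTable,
                     known_parent: GenotypeTable | None = None,
                     threshold: int = 1) -> ExclusionReport:
    """Count exclusions for every (offspring, candidate) pair.

    All tables must share the marker panel (same ordered marker ids).
    When ``known_parent`` holds exactly one genotyped individual, the
    trio (conditional) test is applied at markers where that parent's
    call is non-missing; otherwise the duo test is used.
    """
    if threshold < 1:
        raise InvalidConfigError("exclusion threshold must be >= 1")
    if candidates.markers != offspring.markers:
        raise InvalidConfigError("offspring and candidates must share one "
                                 "ordered marker panel")
    known_calls = None
    if known_parent is not None:
        if known_parent.markers != offspring.markers:
            raise InvalidConfigError("known parent panel mismatch")
        if known_parent.n_individuals != 1:
            raise InvalidConfigError("known_parent must hold exactly one "
                                     "individual")
        known_calls = known_parent.calls[0]

    rows = []
    m = len(offspring.markers)
    for i, off in enumerate(offspring.individuals):
        for c, cand in enumerate(candidates.individuals):
            tested = 0
            excl = 0
            for j in range(m):
                o = (int(offspring.calls[i, j, 0]), int(offspring.calls[i, j, 1]))
                cc = (int(candidates.calls[c, j, 0]), int(candidates.calls[c, j, 1]))
                if MISSING in o or MISSING in cc:
                    continue
                tested += 1
                k = (None if known_calls is None
                     else (int(known_calls[j, 0]), int(known_calls[j, 1])))
                if _marker_excluded(o, cc, k):
                    excl += 1
            if tested == 0:
                verdict = VERDICT_UNTESTABLE
            elif excl >= threshold:
                verdict = VERDICT_EXCLUDED
            else:
                verdict = VERDICT_COMPATIBLE
            rows.append((off.id, cand.id, tested, excl, verdict))
    table = pd.DataFrame(rows, columns=["offspring", "candidate",
                                        "n_markers_tested", "exclusion_count",
                                        "verdict"])
    return ExclusionReport(table, threshold=threshold)


def assign_parent(report: ExclusionReport) -> dict[str, str]:
    """Assign each offspring to its unique compatible candidate.

    Returns offspring -> candidate id, or ``"ambiguous"`` when several
    candidates are compatible and ``"none"`` when none is.
    """
    out: dict[str, str] = {}
    for off, sub in report.table.groupby("offspring", sort=False):
        compatible = list(sub.loc[sub["verdict"] == VERDICT_COMPATIBLE,
                                  "candidate"])
        if len(compatible) == 1:
            out[str(off)] = compatible[0]
        elif compatible:
            out[str(off)] = "ambiguous"
        else:
            out[str(off)] = "none"
    return out
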