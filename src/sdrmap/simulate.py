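"""Synthetic study generator with known ground truth.

Emulates the three data layers of an SDR-mapping study in a species
without sexual dimorphism:

* full-sib families segregating an XY-type SDR on one linkage group,
  with occasional single crossovers per meiosis;
* a spawning group of one dam and several candidate sires genotyped on a
  small panel of multi-allelic (microsatellite-style) markers;
* a gene x sample count matrix for phenotype-less larvae in which a set
  fraction of the truly sex-biased genes — including all-or-nothing
  "sex-specific" genes — lies on the sex-determining linkage group.

Every generator is deterministic given (config, seed) and returns the
ground truth needed to score downstream inference.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .errors import InvalidConfigError
from .haplotypes import ParentalPhase
from .io import (MISSING, CountMatrix, GenotypeTable, Individual, MarkerMap,
                 OrthologyMap)
from .haplotypes import SexGroupAssignment


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the design being emulated: two full-sib mapping
    families genotyped on a 15-marker panel spanning the SDR region of
    the orthologous reference linkage group (tLG8 coordinates, SDR at
    0.96-1.85 Mbp); a spawning group of 45 larvae from one dam and three
    candidate sires typed on 6 microsatellites of 4 alleles; and a
    23-linkage-group transcriptome in which 48% of the truly sex-biased
    genes sit on the SD linkage group.
    """

    # family / SDR layer
    n_families: int = 2
    offspring_per_family: int = 24
    n_markers_sdr: int = 15
    marker_positions: tuple[float, ...] = tuple(
        round(0.10 + i * 0.235, 3) for i in range(15))  # 0.10 .. 3.39 Mbp
    sdr_interval: tuple[float, float] = (0.96, 1.85)
    crossover_rate: float = 0.1   # expected crossovers per meiosis per arm
    sd_lg: str = "tLG8"
    missing_rate: float = 0.0
    # parentage layer
    n_larvae: int = 45
    n_candidate_sires: int = 3
    n_parentage_markers: int = 6
    alleles_per_marker: int = 4
    # expression layer
    n_genes: int = 2300
    n_lgs: int = 23
    genes_per_lg: tuple[int, ...] = (100,) * 23
    n_de_genes: int = 100
    frac_de_on_sdlg: float = 0.48
    n_sex_specific: int = 20
    frac_ss_on_sdlg: float = 0.96
    n_expression_samples: int = 16
    effect_log2fc: float = 2.0
    dispersion: float = 0.1
    mean_library_size: int = 200_000
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_families=self.n_families,
                      offspring_per_family=self.offspring_per_family,
                      n_markers_sdr=self.n_markers_sdr,
                      n_candidate_sires=self.n_candidate_sires,
                      n_parentage_markers=self.n_parentage_markers,
                      alleles_per_marker=self.alleles_per_marker,
                      n_genes=self.n_genes, n_lgs=self.n_lgs,
                      mean_library_size=self.mean_library_size)
        for name, v in counts.items():
            if v <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {v}")
        for name in ("crossover_rate", "frac_de_on_sdlg", "frac_ss_on_sdlg",
                     "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidConfigError(f"{name} must be in [0,1], got {v}")
        if self.n_larvae < 0 or self.n_de_genes < 0 or self.n_sex_specific < 0:
            raise InvalidConfigError("counts must be non-negative")
        if len(self.marker_positions) != self.n_markers_sdr:
            raise InvalidConfigError("marker_positions length != n_markers_sdr")
        if np.any(np.diff(self.marker_positions) <= 0):
            raise InvalidConfigError("marker_positions must be strictly increasing")
        if len(self.genes_per_lg) != self.n_lgs:
            raise InvalidConfigError("genes_per_lg length != n_lgs")
        if sum(self.genes_per_lg) != self.n_genes:
            raise InvalidConfigError("sum(genes_per_lg) must equal n_genes")
        lo, hi = self.sdr_interval
        if lo >= hi:
            raise InvalidConfigError("sdr_interval must be a proper interval")
        if not any(lo <= p <= hi for p in self.marker_positions):
            raise InvalidConfigError(
                "SDR interval contains no marker: true sex transmission "
                "cannot be defined")
        if self.dispersion < 0:
            raise InvalidConfigError("dispersion must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("marker_positions", "genes_per_lg", "sdr_interval"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """What the generators planted, for scoring downstream inference."""

    true_sex: dict = field(default_factory=dict)          # offspring -> male/female
    true_parent: dict = field(default_factory=dict)       # offspring -> sire id
    true_dam: str | None = None
    # (individual, (left marker, right marker), "paternal"|"maternal")
    planted_crossovers: list = field(default_factory=list)
    low_power_panel: bool = False
    expected_nonexclusion: float | None = None            # per random non-parent
    true_de_genes: dict = field(default_factory=dict)     # gene -> info dict
    true_sex_specific_genes: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: v for k, v in asdict(self).items()}, fh, sort_keys=True)


def sdr_marker_map(config: SimConfig) -> MarkerMap:
    """The simulated SDR marker panel, all on the SD linkage group."""
    records = [(f"M{j + 1:02d}", config.sd_lg, p)
               for j, p in enumerate(config.marker_positions)]
    return MarkerMap.from_records(records)


# ---------------------------------------------------------------------------
# full-sib families over the SDR panel
# ---------------------------------------------------------------------------

def _meiosis(rng, n_markers: int, crossover_rate: float,
             forced_gap: int | None = None) -> tuple[np.ndarray, int | None]:
    """One parental meiosis: haplotype index (0/1) per marker, with at most
    one crossover placed uniformly over inter-marker gaps."""
    start = int(rng.integers(2))
    gap = forced_gap
    if gap is None and rng.random() < crossover_rate and n_markers > 1:
        gap = int(rng.integers(n_markers - 1))  # between markers gap and gap+1
    hap = np.full(n_markers, start)
    if gap is not None:
        hap[gap + 1:] = 1 - start
    return hap, gap


def _hap_at(hap: np.ndarray, gap: int | None, positions: np.ndarray,
            query: float) -> int:
    """Haplotype index carried at physical position ``query``; the switch
    point of a crossover in gap g is the midpoint of that gap."""
    if gap is None:
        return int(hap[0])
    switch = 0.5 * (positions[gap] + positions[gap + 1])
    return int(hap[0]) if query < switch else int(hap[-1])


def simulate_family(config: SimConfig, seed: int,
                    forced_crossovers: Sequence[tuple[int, int, int]] = ()
                    ) -> tuple[GenotypeTable, list[ParentalPhase], GroundTruth]:
    """Simulate ``config.n_families`` full-sib families over the SDR panel.

    The sire of every family is heterozygous X/Y across the paternally
    informative markers; each offspring's true sex is set by the paternal
    haplotype it carries at the causal locus (the SDR interval midpoint).
    ``forced_crossovers`` entries ``(family_index, offspring_index,
    gap_index)`` plant a paternal crossover between adjacent markers
    ``gap_index`` and ``gap_index + 1`` for that offspring.

    Returns the pooled genotype table (parents included, offspring sex
    labelled ``unknown``), the true per-family parental phases, and the
    ground truth.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    mmap = sdr_marker_map(config)
    positions = np.asarray(config.marker_positions, dtype=float)
    m = config.n_markers_sdr
    causal = 0.5 * (config.sdr_interval[0] + config.sdr_interval[1])
    forced = {(f, o): g for f, o, g in forced_crossovers}

    individuals: list[Individual] = []
    rows: list[np.ndarray] = []
    phases: list[ParentalPhase] = []
    truth = GroundTruth()

    for f in range(config.n_families):
        fam = f"F{f + 1}"
        # marker class per family: paternally informative (sire 1/2, dam 1/1),
        # maternally informative (dam 1/2, sire 1/1), or uninformative
        klass = rng.choice(3, size=m, p=(0.65, 0.25, 0.10))
        sire_haps = np.ones((2, m), dtype=np.int32)   # row 0 = X, row 1 = Y
        dam_haps = np.ones((2, m), dtype=np.int32)
        sire_haps[1, klass == 0] = 2
        dam_haps[1, klass == 1] = 2

        sire_id, dam_id = f"{fam}_sire", f"{fam}_dam"
        individuals.append(Individual(sire_id, fam, "male", "sire"))
        rows.append(np.sort(sire_haps, axis=0).T)
        individuals.append(Individual(dam_id, fam, "female", "dam"))
        rows.append(np.sort(dam_haps, axis=0).T)

        off_ids, pat_tr, mat_tr, recombinants = [], [], [], []
        for o in range(config.offspring_per_family):
            oid = f"{fam}_{o + 1:02d}"
            pat_hap, pat_gap = _meiosis(rng, m, config.crossover_rate,
                                        forced.get((f, o)))
            mat_hap, mat_gap = _meiosis(rng, m, config.crossover_rate)
            pat_allele = sire_haps[pat_hap, np.arange(m)]
            mat_allele = dam_haps[mat_hap, np.arange(m)]
            call = np.stack([np.minimum(pat_allele, mat_allele),
                             np.maximum(pat_allele, mat_allele)], axis=1)
            if config.missing_rate > 0:
                mask = rng.random(m) < config.missing_rate
                call[mask] = MISSING
            individuals.append(Individual(oid, fam, "unknown", "offspring"))
            rows.append(call)
            off_ids.append(oid)
            pat_tr.append(pat_hap + 1)
            mat_tr.append(mat_hap + 1)

            sex_hap = _hap_at(pat_hap, pat_gap, positions, causal)
            truth.true_sex[oid] = "male" if sex_hap == 1 else "female"
            truth.true_parent[oid] = sire_id
            for gap, parent in ((pat_gap, "paternal"), (mat_gap, "maternal")):
                if gap is not None:
                    truth.planted_crossovers.append(
                        (oid, (mmap.marker_ids[gap], mmap.marker_ids[gap + 1]),
                         parent))
                    recombinants.append(oid)

        phases.append(ParentalPhase(
            family=fam, sire_id=sire_id, dam_id=dam_id,
            markers=tuple(mmap.marker_ids), positions=positions,
            sire_haps=sire_haps, dam_haps=dam_haps,
            pat_informative=(klass == 0), mat_informative=(klass == 1),
            offspring_ids=tuple(off_ids),
            pat_transmission=np.array(pat_tr, dtype=np.int32).reshape(-1, m),
            mat_transmission=np.array(mat_tr, dtype=np.int32).reshape(-1, m),
            candidate_recombinants=tuple(dict.fromkeys(recombinants))))

    table = GenotypeTable(tuple(individuals), tuple(mmap.marker_ids),
                          np.array(rows, dtype=np.int32), mmap)
    return table, phases, truth


# ---------------------------------------------------------------------------
# parentage panel (spawning group)
# ---------------------------------------------------------------------------

def _draw_genotype(rng, freqs: np.ndarray) -> tuple[int, int]:
    a, b = rng.choice(len(freqs), size=2, p=freqs) + 1
    return (min(int(a), int(b)), max(int(a), int(b)))


def _trio_nonexclusion(freqs: np.ndarray, dam: tuple[int, int],
                       sire: tuple[int, int]) -> float:
    """Probability that a random non-parent candidate is compatible (not
    excluded) at this marker with a random offspring of (dam, sire), when
    the dam is known. Exhaustive enumeration over transmissions and
    candidate genotypes."""
    alleles = np.arange(1, len(freqs) + 1)
    compat = 0.0
    for p in sire:
        for mt in dam:
            off = tuple(sorted((p, mt)))
            # candidate compatible iff it carries an allele x with
            # {x, d} == off for some dam allele d
            ok_alleles = {x for x in alleles for d in dam
                          if tuple(sorted((int(x), d))) == off}
            p_has = 1.0 - (1.0 - sum(freqs[a - 1] for a in ok_alleles)) ** 2
            compat += 0.25 * p_has
    return compat


def simulate_parentage_panel(config: SimConfig, seed: int
                             ) -> tuple[GenotypeTable, GenotypeTable, GroundTruth]:
    """Simulate the spawning-group parentage design: ``n_larvae`` offspring
    of one dam and one true sire, plus non-parent candidate sires drawn
    from population allele frequencies, on a panel of multi-allelic
    markers.

    The ground truth records the true sire per larva and a low-power flag
    raised when the panel's expected per-candidate non-exclusion
    probability exceeds 5% (e.g. a single biallelic marker).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    k = config.n_parentage_markers
    markers = tuple(f"P{j + 1}" for j in range(k))
    freqs = [rng.dirichlet(np.full(config.alleles_per_marker, 2.0))
             for _ in range(k)]

    dam = [_draw_genotype(rng, freqs[j]) for j in range(k)]
    sires = [[_draw_genotype(rng, freqs[j]) for j in range(k)]
             for _ in range(config.n_candidate_sires)]
    true_idx = int(rng.integers(config.n_candidate_sires))

    truth = GroundTruth(true_dam="dam")
    nonexcl = 1.0
    for j in range(k):
        nonexcl *= _trio_nonexclusion(freqs[j], dam[j], sires[true_idx][j])
    truth.expected_nonexclusion = float(nonexcl)
    truth.low_power_panel = bool(nonexcl > 0.05)

    off_individuals, off_rows = [], []
    for o in range(config.n_larvae):
        oid = f"L{o + 1:02d}"
        calls = []
        for j in range(k):
            p = sires[true_idx][j][int(rng.integers(2))]
            mt = dam[j][int(rng.integers(2))]
            calls.append((min(p, mt), max(p, mt)))
        off_individuals.append(Individual(oid, "spawn", "unknown", "offspring"))
        off_rows.append(calls)
        truth.true_parent[oid] = f"PM{true_idx + 1}"

    cand_individuals = [Individual("dam", "spawn", "female", "dam")]
    cand_rows = [dam]
    for c in range(config.n_candidate_sires):
        cand_individuals.append(
            Individual(f"PM{c + 1}", "spawn", "male", "candidate"))
        cand_rows.append(sires[c])

    off_calls = (np.array(off_rows, dtype=np.int32).reshape(len(off_rows), k, 2)
                 if off_rows else np.zeros((0, k, 2), dtype=np.int32))
    offspring = GenotypeTable(tuple(off_individuals), markers, off_calls)
    candidates = GenotypeTable(tuple(cand_individuals), markers,
                               np.array(cand_rows, dtype=np.int32))
    return offspring, candidates, truth


# ---------------------------------------------------------------------------
# orthology map and counts
# ---------------------------------------------------------------------------

def simulate_orthology(config: SimConfig, seed: int) -> OrthologyMap:
    """Gene placements over ``n_lgs`` linkage groups with the configured
    per-LG totals; positions uniform within each LG."""
    config.validate()
    rng = np.random.default_rng(seed)
    records = []
    g = 0
    for i in range(config.n_lgs):
        lg = f"tLG{i + 1}"
        pos = np.sort(rng.uniform(0.05, 40.0, size=config.genes_per_lg[i]))
        for p in pos:
            g += 1
            records.append((f"G{g:05d}", lg, round(float(p), 4)))
    return OrthologyMap.from_records(records)


def simulate_counts(assignment: SexGroupAssignment, ortho: OrthologyMap,
                    config: SimConfig, seed: int
                    ) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a gene x sample count matrix with planted sex-biased genes.

    Non-differential genes follow one negative-binomial law shared across
    groups (gene-wise log-normal mean, common dispersion); truly
    sex-biased genes differ by ``effect_log2fc`` with direction split
    evenly between groups; sex-specific genes have expectation zero in
    one group. A fraction ``frac_de_on_sdlg`` of the sex-biased genes is
    drawn from the SD linkage group, the rest from other LGs in
    proportion to their gene totals. With ``effect_log2fc == 0`` the
    truth labels are kept but all distributions are identical between
    groups (a null matrix for type-I-error studies).
    """
    config.validate()
    if config.n_sex_specific > config.n_de_genes:
        raise InvalidConfigError("n_sex_specific cannot exceed n_de_genes")
    samples = sorted(assignment.groups)
    if not samples:
        raise InvalidConfigError("assignment has no grouped samples")
    rng = np.random.default_rng(seed)

    genes = list(ortho.df["gene_id"])
    lg_of = dict(zip(ortho.df["gene_id"], ortho.df["linkage_group"]))
    sd_genes = [g for g in genes if lg_of[g] == config.sd_lg]
    other_genes = [g for g in genes if lg_of[g] != config.sd_lg]

    n_sd = int(round(config.frac_de_on_sdlg * config.n_de_genes))
    n_other = config.n_de_genes - n_sd
    if n_sd > len(sd_genes) or n_other > len(other_genes):
        raise InvalidConfigError("not enough genes to place the DE set")
    de_sd = [str(g) for g in rng.choice(sd_genes, size=n_sd, replace=False)]
    de_other = [str(g) for g in rng.choice(other_genes, size=n_other,
                                           replace=False)]
    de_genes = de_sd + de_other

    n_ss_sd = min(int(round(config.frac_ss_on_sdlg * config.n_sex_specific)),
                  len(de_sd))
    n_ss_other = min(config.n_sex_specific - n_ss_sd, len(de_other))
    ss_genes = ([str(g) for g in rng.choice(de_sd, size=n_ss_sd, replace=False)]
                if n_ss_sd else [])
    ss_genes += ([str(g) for g in rng.choice(de_other, size=n_ss_other,
                                             replace=False)]
                 if n_ss_other else [])

    n_genes = len(genes)
    base_w = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base_w /= base_w.sum()
    gene_index = {g: i for i, g in enumerate(genes)}

    lfc = config.effect_log2fc
    factor = np.ones((n_genes, 2))  # columns: group A, group B
    truth = GroundTruth()
    for r, g in enumerate(de_genes):
        up = "A" if r % 2 == 0 else "B"
        i = gene_index[g]
        sex_specific = g in ss_genes
        if lfc > 0:
            if sex_specific:
                factor[i] = (1.0, 0.0) if up == "A" else (0.0, 1.0)
            else:
                hi, lo = 2.0 ** (lfc / 2.0), 2.0 ** (-lfc / 2.0)
                factor[i] = (hi, lo) if up == "A" else (lo, hi)
        truth.true_de_genes[g] = {
            "direction": up, "linkage_group": lg_of[g],
            "log2fc": float(lfc), "sex_specific": sex_specific}
    truth.true_sex_specific_genes = sorted(ss_genes)

    lib = config.mean_library_size * rng.uniform(0.8, 1.2, size=len(samples))
    group_col = np.array([0 if assignment.groups[s] == "A" else 1
                          for s in samples])
    mu = base_w[:, None] * factor[np.arange(n_genes)[:, None], group_col[None, :]]
    mu = mu * lib[None, :]

    if config.dispersion > 0:
        r_nb = 1.0 / config.dispersion
        counts = np.where(
            mu > 0,
            rng.negative_binomial(r_nb, r_nb / (r_nb + np.maximum(mu, 1e-300))),
            0)
    else:
        counts = rng.poisson(mu)
    matrix = CountMatrix(tuple(genes), tuple(samples),
                         counts.astype(np.int64))
    return matrix, truth
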