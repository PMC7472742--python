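"""Sex-biased differential expression and linkage-group enrichment.

The enrichment statistic is the relative abundance of sex-biased
differentially expressed (DE) genes on linkage group *i*:

    RA_i = (DE_i / DE_t) / (G_i / G_t) = DE_i * G_t / (DE_t * G_i)

where DE_i and G_i are the DE-gene and total-gene counts on LG *i* and
DE_t, G_t the corresponding totals; RA_i = 1 means no enrichment. DE
genes unplaced on the orthologous reference are reported but excluded
from DE_t, so sum_i RA_i * (G_i / G_t) = 1 identically.

The per-gene test is an exact conditional count test: conditioning on a
gene's pooled count, it asks whether the group-A share deviates from
group A's share of the total library size, using a double-tail
(minimum-likelihood) rejection region. A single overdispersion value,
estimated from the full matrix by Pearson-residual matching under
group-wise fitted means, widens the conditional law from binomial
(no overdispersion) to the negative-binomial analogue, so identically
distributed groups keep calibrated p-values at RNA-seq-like dispersion.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidConfigError
from .haplotypes import ParentalPhase, SexGroupAssignment, assign_sex_groups, merge_assignments
from .io import CountMatrix, OrthologyMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# small arithmetic helpers (shared by summaries and scenario tables)
# ---------------------------------------------------------------------------

def relative_abundance(de_i: int, de_t: int, g_i: int, g_t: int) -> float:
    """RA_i = DE_i * G_t / (DE_t * G_i)."""
    if de_t <= 0 or g_i <= 0:
        raise InvalidConfigError("DE_t and G_i must be positive")
    return de_i * g_t / (de_t * g_i)


def percent_of_total(part: int, total: int) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if total <= 0:
        raise InvalidConfigError("total must be positive")
    return int(math.floor(100.0 * part / total + 0.5))


def fold_ratio(a: int, b: int) -> float:
    """Ratio a/b reported to one decimal place."""
    if b <= 0:
        raise InvalidConfigError("denominator must be positive")
    return round(a / b, 1)


def expected_null_share_percent(n_lgs: int) -> float:
    """Analytic per-LG share (in %) under random placement over n LGs,
    to one decimal (23 LGs -> 4.3)."""
    if n_lgs <= 0:
        raise InvalidConfigError("n_lgs must be positive")
    return round(100.0 / n_lgs, 1)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def estimate_common_dispersion(counts: np.ndarray, lib: np.ndarray,
                               group_a: np.ndarray) -> float:
    """Common negative-binomial dispersion by Pearson-residual matching.

    Fits group-wise means with library-size offsets (so truly DE genes do
    not inflate the estimate) and solves for the dispersion phi at which
    sum (y - mu)^2 / (mu (1 + phi mu)) equals its residual degrees of
    freedom. Returns 0 for equi- or under-dispersed data.
    """
    masks = [group_a, ~group_a]
    mu = np.zeros_like(counts, dtype=float)
    n_params = np.zeros(counts.shape[0])
    for mask in masks:
        s = lib[mask].sum()
        q = counts[:, mask].sum(axis=1) / s
        mu[:, mask] = q[:, None] * lib[None, mask]
        n_params += (q > 0)
    use = mu > 0
    y = counts[use].astype(float)
    m = mu[use]
    df = use.sum() - n_params.sum()
    if df <= 0:
        return 0.0

    def pearson_gap(phi):
        return np.sum((y - m) ** 2 / (m * (1.0 + phi * m))) - df

    if pearson_gap(0.0) <= 0:
        return 0.0
    hi = 1.0
    while pearson_gap(hi) > 0 and hi < 1e4:
        hi *= 10.0
    if pearson_gap(hi) > 0:
        return float(hi)
    return float(optimize.brentq(pearson_gap, 0.0, hi, xtol=1e-8))


def _conditional_double_tail(y_a: int, y_b: int, s_a: float, s_b: float,
                             r_a: float | None, r_b: float | None) -> float:
    """Exact two-sided p-value for the split of the pooled count between
    groups, by minimum-likelihood double tail.

    With ``r_a``/``r_b`` None the groups are Poisson and the conditional
    law is Binomial(n, s_a/(s_a+s_b)); otherwise each group sum is
    treated as negative binomial with the given size, and the diagonal of
    the joint law is normalized.
    """
    n = y_a + y_b
    if n == 0:
        return 1.0
    k = np.arange(n + 1)
    if r_a is None:
        logw = stats.binom.logpmf(k, n, s_a / (s_a + s_b))
    else:
        q = n / (s_a + s_b)
        m_a, m_b = q * s_a, q * s_b
        logw = (stats.nbinom.logpmf(k, r_a, r_a / (r_a + m_a))
                + stats.nbinom.logpmf(n - k, r_b, r_b / (r_b + m_b)))
    logw -= logw.max()
    w = np.exp(logw)
    p = w[w <= w[y_a] * (1.0 + 1e-9)].sum() / w.sum()
    return float(min(p, 1.0))


def test_de(counts: CountMatrix, assignment: SexGroupAssignment,
            alpha: float = 0.01, min_total: int = 10,
            dispersion: float | None = None) -> pd.DataFrame:
    """Per-gene sex-biased DE between the assignment's groups A and B.

    Returns a frame with one row per gene: ``p_value``, BH ``fdr``,
    ``log2fc`` (normalized A over B, 0.5-count prior), ``direction``
    ('A'/'B'), ``significant`` (raw p < alpha, the paper-style rule) and
    ``filtered`` (pooled count < ``min_total``; not tested). Frame attrs
    record alpha, the dispersion used, and group sizes.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidConfigError("alpha must be in (0, 1)")
    sample_group = {s: g for s, g in assignment.groups.items()
                    if s in counts.sample_ids}
    cols = [i for i, s in enumerate(counts.sample_ids) if s in sample_group]
    if not cols:
        raise InvalidConfigError("no count sample appears in the assignment")
    sub = counts.counts[:, cols]
    samples = [counts.sample_ids[i] for i in cols]
    group_a = np.array([sample_group[s] == "A" for s in samples])
    n_a, n_b = int(group_a.sum()), int((~group_a).sum())
    if n_a < 2 or n_b < 2:
        raise InvalidConfigError(
            f"each group needs >= 2 samples (got A={n_a}, B={n_b})")

    lib = sub.sum(axis=0).astype(float)
    total = sub.sum(axis=1)
    tested = total >= min_total

    if dispersion is None:
        dispersion = (estimate_common_dispersion(sub[tested], lib, group_a)
                      if tested.any() else 0.0)

    s_a, s_b = lib[group_a].sum(), lib[~group_a].sum()
    y_a = sub[:, group_a].sum(axis=1)
    y_b = sub[:, ~group_a].sum(axis=1)
    if dispersion > 0:
        r_a = (s_a ** 2 / np.sum(lib[group_a] ** 2)) / dispersion
        r_b = (s_b ** 2 / np.sum(lib[~group_a] ** 2)) / dispersion
    else:
        r_a = r_b = None

    pvals = np.full(len(counts.gene_ids), np.nan)
    for g in np.flatnonzero(tested):
        pvals[g] = _conditional_double_tail(int(y_a[g]), int(y_b[g]),
                                            s_a, s_b, r_a, r_b)

    fdr = np.full_like(pvals, np.nan)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    log2fc = (np.log2((y_a + 0.5) / max(s_a, 1.0))
              - np.log2((y_b + 0.5) / max(s_b, 1.0)))
    out = pd.DataFrame({
        "gene_id": list(counts.gene_ids),
        "p_value": pvals,
        "fdr": fdr,
        "log2fc": log2fc,
        "direction": np.where(log2fc >= 0, "A", "B"),
        "significant": tested & (pvals < alpha),
        "filtered": ~tested,
    })
    out.attrs.update(alpha=alpha, dispersion=float(dispersion),
                     n_a=n_a, n_b=n_b)
    return out


def tag_sex_specific(counts: CountMatrix, assignment: SexGroupAssignment,
                     min_expr: int = 1,
                     de: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tag all-or-nothing genes: count >= ``min_expr`` in every sample of
    one group and exactly zero in every sample of the other. When a DE
    frame is supplied tagging is restricted to its significant genes,
    else applied genome-wide. Returns gene_id -> expressed_group rows.
    """
    sample_group = {s: g for s, g in assignment.groups.items()
                    if s in counts.sample_ids}
    cols_a = [i for i, s in enumerate(counts.sample_ids)
              if sample_group.get(s) == "A"]
    cols_b = [i for i, s in enumerate(counts.sample_ids)
              if sample_group.get(s) == "B"]
    if not cols_a or not cols_b:
        raise InvalidConfigError("assignment must cover both groups")
    allowed = None
    if de is not None:
        allowed = set(de.loc[de["significant"], "gene_id"])
    a = counts.counts[:, cols_a]
    b = counts.counts[:, cols_b]
    rows = []
    for g, gene in enumerate(counts.gene_ids):
        if allowed is not None and gene not in allowed:
            continue
        if a[g].min() >= min_expr and b[g].max() == 0:
            rows.append((gene, "A"))
        elif b[g].min() >= min_expr and a[g].max() == 0:
            rows.append((gene, "B"))
    out = pd.DataFrame(rows, columns=["gene_id", "expressed_group"])
    out.attrs["min_expr"] = min_expr
    return out


def collapse_transcripts(de: pd.DataFrame,
                         transcript_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse transcript-level DE records to one record per gene.

    The representative transcript is the one with the smallest p-value
    (ties broken by lexicographic transcript id); ids absent from the
    mapping pass through one-per-transcript with ``annotated = False``.
    """
    df = de.copy()
    df["transcript_id"] = df["gene_id"]
    df["annotated"] = df["transcript_id"].map(
        lambda t: t in transcript_to_gene)
    df["collapsed_gene"] = [
        transcript_to_gene.get(t, t) for t in df["transcript_id"]]
    df = df.sort_values(["p_value", "transcript_id"],
                        kind="stable", na_position="last")
    out = df.groupby("collapsed_gene", sort=False).head(1).copy()
    sizes = df.groupby("collapsed_gene", sort=False).size()
    out["n_transcripts"] = out["collapsed_gene"].map(sizes)
    out["gene_id"] = out["collapsed_gene"]
    out = out.drop(columns="collapsed_gene").reset_index(drop=True)
    out.attrs.update(de.attrs)
    return out


# ---------------------------------------------------------------------------
# enrichment summary (relative abundance per linkage group)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentSummary:
    """Per-LG DE counts, gene totals and relative abundances.

    ``table`` columns: linkage_group, de_count (DE_i), gene_count (G_i),
    relative_abundance (RA_i), percent (rounded 100*DE_i/DE_t). DE genes
    not placed by the orthology map are listed in ``unmapped`` and
    excluded from ``de_total``.
    """

    table: pd.DataFrame
    de_total: int
    gene_total: int
    unmapped: tuple[str, ...] = ()

    def __post_init__(self):
        t = self.table
        if int(t["de_count"].sum()) != self.de_total:
            raise InvalidConfigError("sum(DE_i) must equal DE_t")
        if int(t["gene_count"].sum()) != self.gene_total:
            raise InvalidConfigError("sum(G_i) must equal G_t")
        weighted = float(np.sum(t["relative_abundance"]
                                * t["gene_count"] / self.gene_total))
        if abs(weighted - 1.0) > 1e-12:
            raise InvalidConfigError(
                f"RA normalization violated: sum RA_i G_i/G_t = {weighted!r}")

    def relative_abundance_of(self, lg: str) -> float:
        sub = self.table.loc[self.table["linkage_group"] == lg]
        return float(sub["relative_abundance"].iloc[0]) if len(sub) else 0.0

    def percent_of(self, lg: str) -> int:
        sub = self.table.loc[self.table["linkage_group"] == lg]
        return int(sub["percent"].iloc[0]) if len(sub) else 0

    def argmax_lg(self) -> str:
        i = self.table["relative_abundance"].idxmax()
        return str(self.table.loc[i, "linkage_group"])

    @classmethod
    def from_counts(cls, de_by_lg: Mapping[str, int],
                    genes_by_lg: Mapping[str, int],
                    unmapped: Sequence[str] = ()) -> "EnrichmentSummary":
        de_t = int(sum(de_by_lg.values()))
        g_t = int(sum(genes_by_lg.values()))
        rows = []
        for lg, g_i in genes_by_lg.items():
            de_i = int(de_by_lg.get(lg, 0))
            rows.append((lg, de_i, int(g_i),
                         relative_abundance(de_i, de_t, int(g_i), g_t),
                         percent_of_total(de_i, de_t)))
        table = pd.DataFrame(rows, columns=[
            "linkage_group", "de_count", "gene_count",
            "relative_abundance", "percent"])
        return cls(table, de_t, g_t, tuple(unmapped))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def enrichment_summary(de_genes: Sequence[str],
                       ortho: OrthologyMap) -> EnrichmentSummary:
    """Map DE genes to linkage groups and compute RA_i per LG."""
    de_by_lg: dict[str, int] = {}
    unmapped = []
    for g in de_genes:
        lg = ortho.linkage_group_of(g)
        if lg is None:
            unmapped.append(g)
        else:
            de_by_lg[lg] = de_by_lg.get(lg, 0) + 1
    if unmapped:
        logger.warning("%d DE genes absent from the orthology map; "
                       "excluded from DE_t", len(unmapped))
    if not de_by_lg:
        raise InvalidConfigError("no DE gene could be placed on a linkage group")
    genes_by_lg = ortho.lg_gene_counts.to_dict()
    return EnrichmentSummary.from_counts(de_by_lg, genes_by_lg, unmapped)


# ---------------------------------------------------------------------------
# scenario comparison (XY vs ZW vs random control)
# ---------------------------------------------------------------------------

def compare_scenarios(counts: CountMatrix,
                      phases: ParentalPhase | Sequence[ParentalPhase],
                      ortho: OrthologyMap, sd_lg: str,
                      alpha: float = 0.01, seed: int = 0,
                      sdr_interval: tuple[float, float] | None = None,
                      min_total: int = 10) -> pd.DataFrame:
    """One row per scenario (paternal / maternal / random): DE genes on
    the SD linkage group, on other LGs, total, and the SD-LG percentage.
    Frame attrs carry the paternal/maternal total ratio (one decimal) and
    the random seed used for the control row.
    """
    if isinstance(phases, ParentalPhase):
        phases = [phases]
    rows = []
    totals = {}
    for scenario in ("paternal", "maternal", "random"):
        assignments = [assign_sex_groups(ph, scenario, seed=seed,
                                         sdr_interval=sdr_interval)
                       for ph in phases]
        assignment = (assignments[0] if len(assignments) == 1
                      else merge_assignments(assignments))
        de = test_de(counts, assignment, alpha=alpha, min_total=min_total)
        sig = list(de.loc[de["significant"], "gene_id"])
        if sig:
            summary = enrichment_summary(sig, ortho)
            sd = int(summary.table.set_index("linkage_group")
                     ["de_count"].get(sd_lg, 0))
            total = summary.de_total
            pct = percent_of_total(sd, total)
        else:
            sd, total, pct = 0, 0, 0
        totals[scenario] = total
        rows.append((scenario, sd, total - sd, total, pct))
    out = pd.DataFrame(rows, columns=["scenario", "sd_lg_count",
                                      "other_lg_count", "total",
                                      "percent_sd_lg"])
    out.attrs["paternal_maternal_ratio"] = (
        fold_ratio(totals["paternal"], totals["maternal"])
        if totals["maternal"] > 0 else float("nan"))
    out.attrs["random_seed"] = seed
    out.attrs["sd_lg"] = sd_lg
    return out
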