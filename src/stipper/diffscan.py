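"""Case/control allele-frequency differentiation scan.

Each site is tested with a two-binomial likelihood-ratio statistic

    G = 2 [ l(p1; a1, n1) + l(p2; a2, n2) - l(p0; a1, n1) - l(p0; a2, n2) ]

with p_i = a_i/n_i the per-cohort sample frequencies, p0 the pooled
frequency, and l the binomial log-likelihood (0*log 0 = 0).  p-values come
from the upper tail of chi^2 with 1 df; the genome-wide threshold is
Bonferroni over tested sites.  Allele counting is ploidy-aware on the Z
scaffold: ZW females contribute one allele, ZZ males two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel, GenomicInterval, Sample, VariantSite, VariantTable, Z_SCAFFOLD

log = logging.getLogger(__name__)

__all__ = [
    "SiteCounts",
    "ScanResult",
    "lrt_site",
    "genome_scan",
    "significance_threshold",
    "candidate_region",
    "fixed_difference_scan",
]


@dataclass(frozen=True)
class SiteCounts:
    """Alternate-allele counts at one site: a1/n1 in cases, a2/n2 in controls."""

    scaffold: str
    pos: int
    a1: int
    n1: int
    a2: int
    n2: int

    def __post_init__(self) -> None:
        for a, n, lab in ((self.a1, self.n1, "case"), (self.a2, self.n2, "control")):
            if n < 1:
                raise ValueError(f"{lab} allele total must be >= 1")
            if not 0 <= a <= n:
                raise ValueError(f"{lab} count {a} outside [0, {n}]")


@dataclass
class ScanResult:
    """Per-site scan table plus the genome-wide threshold used."""

    table: pd.DataFrame  # scaffold, pos, a1, n1, a2, n2, G, p, minus_log10_p
    alpha: float
    threshold: float  # Bonferroni p-threshold

    @property
    def n_sites(self) -> int:
        return len(self.table)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.threshold]


def _binom_loglik(a: float, n: float, p: float) -> float:
    ll = 0.0
    if a > 0:
        ll += a * np.log(p)
    if n - a > 0:
        ll += (n - a) * np.log(1.0 - p)
    return ll


def lrt_site(counts: SiteCounts) -> tuple[float, float]:
    """Likelihood-ratio G and chi^2_1 p-value for one site."""
    a1, n1, a2, n2 = counts.a1, counts.n1, counts.a2, counts.n2
    if a1 * n2 == a2 * n1:  # identical sample frequencies: G is exactly 0
        return 0.0, 1.0
    p1, p2, p0 = a1 / n1, a2 / n2, (a1 + a2) / (n1 + n2)
    G = 2.0 * (
        _binom_loglik(a1, n1, p1)
        + _binom_loglik(a2, n2, p2)
        - _binom_loglik(a1, n1, p0)
        - _binom_loglik(a2, n2, p0)
    )
    G = max(G, 0.0)  # clip tiny negative round-off
    p = float(stats.chi2.sf(G, df=1))
    return G, max(p, np.nextafter(0, 1))


def significance_threshold(n_sites: int, alpha: float = 0.05) -> float:
    """Bonferroni genome-wide p-value threshold."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return alpha / n_sites


def _hard_allele_counts(
    site: VariantSite, ploidy: np.ndarray, alt_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample alternate allele counts and contributed allele totals,
    hard-called by rounding ploidy x AD fraction; missing samples excluded."""
    ok = site.dp > 0
    frac = np.zeros(site.n_samples)
    frac[ok] = site.ad[ok, alt_index] / site.dp[ok]
    alt = np.clip(np.rint(ploidy * frac), 0, ploidy).astype(int)
    alt[~ok] = 0
    n = np.where(ok, ploidy, 0)
    return alt, n


def genome_scan(
    table: VariantTable,
    samples: list[Sample],
    case_ids: set[str],
    z_scaffolds: frozenset[str] = frozenset({Z_SCAFFOLD}),
    alpha: float = 0.05,
) -> ScanResult:
    """Scan every biallelic-reducible site for cohort differentiation.

    Multiallelic sites are reduced to ref vs the read-richest alternate.
    Sites where either cohort is entirely missing are dropped (logged).
    """
    by_id = {s.id: s for s in samples}
    if set(table.samples) - set(by_id):
        raise ValueError("variant table contains samples absent from sample sheet")
    is_case = np.array([sid in case_ids for sid in table.samples])
    if not is_case.any() or is_case.all():
        raise ValueError("both cohorts must be non-empty")
    sex_ploidy = np.array(
        [by_id[sid].z_baseline for sid in table.samples], dtype=int
    )
    rows = []
    for site in table.sites:
        ploidy = (
            sex_ploidy if site.scaffold in z_scaffolds
            else np.full(len(table.samples), 2)
        )
        alt_index = 1
        if len(site.alleles) > 2:  # most-supported alternate
            alt_index = 1 + int(np.argmax(site.ad[:, 1:].sum(axis=0)))
        alt, n = _hard_allele_counts(site, ploidy, alt_index)
        n1, n2 = int(n[is_case].sum()), int(n[~is_case].sum())
        if n1 == 0 or n2 == 0:
            log.info("skipping %s:%d: a cohort is all-missing", site.scaffold, site.pos)
            continue
        counts = SiteCounts(
            site.scaffold, site.pos,
            int(alt[is_case].sum()), n1, int(alt[~is_case].sum()), n2,
        )
        G, p = lrt_site(counts)
        rows.append(
            {
                "scaffold": site.scaffold, "pos": site.pos,
                "a1": counts.a1, "n1": n1, "a2": counts.a2, "n2": n2,
                "G": G, "p": p, "minus_log10_p": -np.log10(p),
            }
        )
    df = pd.DataFrame(rows)
    thr = significance_threshold(max(len(df), 1), alpha)
    return ScanResult(table=df, alpha=alpha, threshold=thr)


def candidate_region(
    scan: ScanResult, merge_gap: int = 10_000
) -> list[GenomicInterval]:
    """Merge significant sites within ``merge_gap`` bp into intervals,
    ranked by peak -log10(p) (ties broken by scaffold order then position)."""
    if scan.n_sites == 0:
        raise ValueError("empty scan")
    sig = scan.significant().sort_values(["scaffold", "pos"])
    intervals: list[tuple[GenomicInterval, float]] = []
    cur: list[tuple[str, int, float]] = []
    for r in sig.itertuples():
        if cur and (r.scaffold != cur[-1][0] or r.pos - cur[-1][1] > merge_gap):
            intervals.append(_close_interval(cur))
            cur = []
        cur.append((r.scaffold, int(r.pos), float(r.minus_log10_p)))
    if cur:
        intervals.append(_close_interval(cur))
    intervals.sort(key=lambda iv: (-iv[1], iv[0].scaffold, iv[0].start))
    return [iv for iv, _peak in intervals]


def _close_interval(
    sites: list[tuple[str, int, float]]
) -> tuple[GenomicInterval, float]:
    scaffold = sites[0][0]
    return (
        GenomicInterval(scaffold, sites[0][1], sites[-1][1]),
        max(s[2] for s in sites),
    )


def fixed_difference_scan(
    table: VariantTable,
    samples: list[Sample],
    case_ids: set[str],
    coding_mask: list[GeneModel],
) -> list[VariantSite]:
    """Coding sites where some alternate allele is carried by every case and
    by no control.  A missing genotype in any sample makes a site ineligible.
    """
    exons: list[GenomicInterval] = [e for g in coding_mask for e in g.exons]
    is_case = np.array([sid in case_ids for sid in table.samples])
    hits = []
    for site in table.sites:
        if not any(e.scaffold == site.scaffold and e.contains(site.pos) for e in exons):
            continue
        if np.any(site.dp < 0):
            continue
        present = site.ad >= 1  # (samples, alleles)
        for alt in range(1, len(site.alleles)):
            if present[is_case, alt].all() and not present[~is_case, alt].any():
                hits.append(site)
                break
    return hits
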