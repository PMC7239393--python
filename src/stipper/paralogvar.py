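"""Paralog-aware low-frequency variant scan inside the CNV.

When a locus is present in up to 14 copies per chromosome, a variant private
to one copy surfaces at an allelic fraction of only ~1/14 (~7%), far below a
diploid heterozygote.  The scan keeps any alternate allele whose per-sample
AD/DP fraction strictly exceeds a retention threshold (default 4%, chosen to
admit 1-of-14-copy variants while rejecting sequencing errors), then routes
sites by allele count: biallelic sites are compared by cohort frequency,
multiallelic sites by presence/absence recurrence across case birds, and
every candidate is finally cross-checked against the control cohort, where a
single supporting read disqualifies it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, Sample, VariantTable

__all__ = [
    "RetainedAllele",
    "PresenceMatrix",
    "filter_allelic_fraction",
    "biallelic_private_alleles",
    "recurrence_scan",
    "control_cross_check",
    "run_paralog_scan",
]

#: (scaffold, pos, allele) key identifying a candidate allele.
AlleleKey = tuple[str, int, str]


@dataclass(frozen=True)
class RetainedAllele:
    """One (site, allele, sample) observation passing the fraction filter."""

    scaffold: str
    pos: int
    allele: str
    sample: str
    fraction: float
    ad: int
    dp: int
    n_site_alleles: int

    @property
    def key(self) -> AlleleKey:
        return (self.scaffold, self.pos, self.allele)


@dataclass
class PresenceMatrix:
    """Binary (site, allele) x case-sample matrix; 1 iff >= 1 supporting read."""

    data: pd.DataFrame  # index: MultiIndex (scaffold, pos, allele); columns: cases

    def row_sums(self) -> pd.Series:
        return self.data.sum(axis=1)


def filter_allelic_fraction(
    table: VariantTable,
    region: GenomicInterval | None = None,
    min_frac: float = 0.04,
) -> list[RetainedAllele]:
    """Retain (site, alternate allele, sample) triples with AD/DP > min_frac.

    Strictly-greater comparison, evaluated per sample and per alternate
    allele; samples with DP = 0 (or missing) are skipped at that site.
    """
    retained: list[RetainedAllele] = []
    for site in table.in_region(region).sites:
        n_all = len(site.alleles)
        for s_idx, sid in enumerate(table.samples):
            dp = int(site.dp[s_idx])
            if dp <= 0:
                continue
            for a_idx in range(1, n_all):
                ad = int(site.ad[s_idx, a_idx])
                frac = ad / dp
                if frac > min_frac:
                    retained.append(
                        RetainedAllele(
                            scaffold=site.scaffold,
                            pos=site.pos,
                            allele=site.alleles[a_idx],
                            sample=sid,
                            fraction=frac,
                            ad=ad,
                            dp=dp,
                            n_site_alleles=n_all,
                        )
                    )
    return retained


def biallelic_private_alleles(
    retained: list[RetainedAllele],
    case_ids: set[str],
    control_ids: set[str],
) -> list[AlleleKey]:
    """Alternate alleles of biallelic sites retained in >= 1 case and 0 controls."""
    case_keys: set[AlleleKey] = set()
    control_keys: set[AlleleKey] = set()
    for r in retained:
        if r.n_site_alleles != 2:
            continue
        if r.sample in case_ids:
            case_keys.add(r.key)
        elif r.sample in control_ids:
            control_keys.add(r.key)
    return sorted(case_keys - control_keys)


def recurrence_scan(
    table: VariantTable,
    case_ids: set[str],
    region: GenomicInterval | None = None,
    min_cases: int = 3,
    retained: list[RetainedAllele] | None = None,
) -> list[AlleleKey]:
    """Multiallelic presence/absence recurrence across case birds.

    Builds the binary presence matrix (1 iff at least one read supports the
    allele; missing samples count as absent) over sites with more than two
    alleles and returns alleles present in >= ``min_cases`` cases.  When
    ``retained`` is given (the fraction-filtered output, which is what the
    presence coding operates on in the full scan), only alleles retained in
    at least one individual are considered.
    """
    matrix = presence_matrix(table, case_ids, region, retained)
    sums = matrix.row_sums()
    return sorted(sums[sums >= min_cases].index.tolist())


def presence_matrix(
    table: VariantTable,
    case_ids: set[str],
    region: GenomicInterval | None = None,
    retained: list[RetainedAllele] | None = None,
) -> PresenceMatrix:
    cases = [sid for sid in table.samples if sid in case_ids]  # sheet order
    keep: set[AlleleKey] | None = (
        None if retained is None else {r.key for r in retained}
    )
    rows: dict[AlleleKey, list[int]] = {}
    for site in table.in_region(region).sites:
        if len(site.alleles) <= 2:
            continue
        for a_idx in range(1, len(site.alleles)):
            key = (site.scaffold, site.pos, site.alleles[a_idx])
            if keep is not None and key not in keep:
                continue
            vals = []
            for sid in cases:
                s_idx = table.sample_index(sid)
                ok = site.dp[s_idx] >= 0
                vals.append(int(ok and site.ad[s_idx, a_idx] >= 1))
            rows[key] = vals
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["scaffold", "pos", "allele"])
    return PresenceMatrix(
        data=pd.DataFrame(list(rows.values()), index=idx, columns=cases, dtype=int)
    )


def control_cross_check(
    candidates: list[AlleleKey],
    table: VariantTable,
    control_ids: set[str],
) -> list[AlleleKey]:
    """Drop any candidate allele with >= 1 supporting read in any control."""
    ctrl_idx = [i for i, sid in enumerate(table.samples) if sid in control_ids]
    site_by_key = {(s.scaffold, s.pos): s for s in table.sites}
    survivors = []
    for scaffold, pos, allele in candidates:
        site = site_by_key.get((scaffold, pos))
        seen = False
        if site is not None and allele in site.alleles:
            a_idx = site.alleles.index(allele)
            seen = any(
                site.dp[i] >= 0 and site.ad[i, a_idx] >= 1 for i in ctrl_idx
            )
        if not seen:
            survivors.append((scaffold, pos, allele))
    return survivors


def run_paralog_scan(
    table: VariantTable,
    samples: list[Sample],
    case_ids: set[str],
    region: GenomicInterval | None = None,
    min_frac: float = 0.04,
    min_cases: int = 3,
) -> pd.DataFrame:
    """Full scan: fraction filter, biallelic/multiallelic routing, control
    cross-check.  Returns a tidy report, one row per candidate allele, with
    its verdict ('case_specific' or 'shared_with_controls')."""
    control_ids = {s.id for s in samples if s.id not in case_ids}
    retained = filter_allelic_fraction(table, region=region, min_frac=min_frac)
    bi = biallelic_private_alleles(retained, case_ids, control_ids)
    multi = recurrence_scan(
        table, case_ids, region=region, min_cases=min_cases, retained=retained
    )
    candidates = sorted(set(bi) | set(multi))
    survivors = set(control_cross_check(candidates, table, control_ids))
    site_by_key = {(s.scaffold, s.pos): s for s in table.sites}
    rows = []
    for key in candidates:
        scaffold, pos, allele = key
        site = site_by_key[(scaffold, pos)]
        a_idx = site.alleles.index(allele)
        case_idx = [i for i, sid in enumerate(table.samples) if sid in case_ids]
        ctrl_idx = [i for i, sid in enumerate(table.samples) if sid in control_ids]
        fr = [
            site.ad[i, a_idx] / site.dp[i]
            for i in case_idx
            if site.dp[i] > 0
        ]
        rows.append(
            {
                "scaffold": scaffold,
                "pos": pos,
                "allele": allele,
                "branch": "biallelic" if key in set(bi) else "multiallelic",
                "n_cases_present": int(
                    sum(site.dp[i] >= 0 and site.ad[i, a_idx] >= 1 for i in case_idx)
                ),
                "max_case_fraction": max(fr) if fr else 0.0,
                "n_controls_present": int(
                    sum(site.dp[i] >= 0 and site.ad[i, a_idx] >= 1 for i in ctrl_idx)
                ),
                "verdict": "case_specific" if key in survivors else "shared_with_controls",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold", "pos", "allele", "branch", "n_cases_present",
            "max_case_fraction", "n_controls_present", "verdict",
        ],
    )
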