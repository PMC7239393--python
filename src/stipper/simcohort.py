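"""Synthetic two-cohort ZW/ZZ populations with a known nested tandem CNV.

The generator emulates the statistical structure the downstream analyses
assume: a single Z-linked scaffold carrying the nested CNV at the published
coordinates (rescaled by a configurable offset so they fit a desk-scale
scaffold), Poisson windowed depth, breakpoint-spanning clipped reads,
copy-private SNVs at 1/k allelic fractions plus sequencing errors, cohort
allele-frequency divergence, and noisy TaqMan / qRT-PCR Ct measurements.
Every stochastic draw flows through one explicitly passed numpy Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    INNER_CNV,
    OUTER_CNV,
    Z_SCAFFOLD,
    ClipPile,
    DepthTrack,
    GenomicInterval,
    Sample,
    VariantSite,
    VariantTable,
)
from .dosagestats import AssayTable, CtTable

__all__ = [
    "SimConfig",
    "CnvTruth",
    "simulate_cohort",
    "simulate_depth",
    "simulate_clip_piles",
    "simulate_allele_depths",
    "simulate_assay",
    "simulate_expression",
    "simulate_differentiated_genotypes",
    "expected_allelic_fraction",
]

#: Per-affected-chromosome (outer, inner) copy counts by phenotype.  The
#: canonical Almond allele is the published 7/14 configuration; the other
#: series members are generator settings chosen to reproduce the qualitative
#: allelic-series gradation (no published per-allele copy counts exist).
DEFAULT_ALLELE_SERIES: dict[str, tuple[int, int]] = {
    "non-Almond": (1, 1),
    "Almond": (7, 14),
    "Qualmond": (2, 4),
    "Faded": (2, 4),
    "Frosty": (2, 4),
    "Chalky": (3, 6),
    "Sandy": (5, 10),
    "White Out": (6, 12),
}

#: Study-sized default cohort: 12 affected females vs a 109-bird panel.
DEFAULT_COHORT: dict[str, dict[str, int]] = {
    "Almond": {"female": 12},
    "non-Almond": {"male": 54, "female": 55},
}


@dataclass(frozen=True)
class CnvTruth:
    """Ground-truth CNV configuration for one simulated bird."""

    outer: GenomicInterval
    inner: GenomicInterval
    #: per-Z-chromosome (outer, inner) copy counts; 1 entry for ZW females,
    #: 2 for ZZ males
    copies: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.outer.contains_interval(self.inner):
            raise ValueError("inner segment must be nested in the outer segment")
        for o, i in self.copies:
            if o < 1:
                raise ValueError(f"outer copies must be >= 1, got {o}")
            if i < o:
                raise ValueError(f"inner copies ({i}) must be >= outer ({o})")

    @property
    def breakpoints(self) -> tuple[int, int, int, int]:
        """(outer-left, inner-left, inner-right, outer-right) positions."""
        return (self.outer.start, self.inner.start, self.inner.end, self.outer.end)

    @property
    def total_outer(self) -> int:
        return sum(o for o, _ in self.copies)

    @property
    def total_inner(self) -> int:
        return sum(i for _, i in self.copies)

    def is_expanded(self) -> bool:
        return any(i > 1 or o > 1 for o, i in self.copies)


@dataclass
class SimConfig:
    """All tunable study conditions for the synthetic cohort.

    Coordinates: the published CNV anchors shifted left by ``offset`` so they
    sit inside a ``scaffold_length`` bp synthetic scaffold, preserving the
    printed interval lengths and breakpoint spacing.
    """

    seed: int = 0
    scaffold: str = Z_SCAFFOLD
    scaffold_length: int = 400_000
    offset: int = 5_000_000
    window: int = 100
    coverage: float = 30.0  # haploid-baseline mean reads per window
    error_rate: float = 0.005  # per-base sequencing error rate
    n_private_snvs: int = 5
    n_paralog_background_sites: int = 50
    assay_sd: float = 0.15  # Ct units
    expression_sd: float = 0.25  # Ct units
    assay_replicates: int = 4
    expression_replicates: int = 2
    background_clip_rate: float = 1e-5  # sporadic 1-read clips per bp
    # differentiation-scan emulation
    n_background_sites: int = 2_000
    n_causal_sites: int = 20
    causal_case_freq: float = 1.0
    causal_control_freq: float = 0.0
    background_freq_range: tuple[float, float] = (0.05, 0.95)
    site_dp: float = 30.0
    cohort: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COHORT.items()}
    )
    allele_series: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_SERIES)
    )

    def __post_init__(self) -> None:
        for name, rate in (
            ("error_rate", self.error_rate),
            ("background_clip_rate", self.background_clip_rate),
            ("causal_case_freq", self.causal_case_freq),
            ("causal_control_freq", self.causal_control_freq),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.outer.end > self.scaffold_length:
            raise ValueError("CNV does not fit on the simulated scaffold")

    @property
    def outer(self) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold, OUTER_CNV.start - self.offset, OUTER_CNV.end - self.offset
        )

    @property
    def inner(self) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold, INNER_CNV.start - self.offset, INNER_CNV.end - self.offset
        )

    @property
    def control(self) -> GenomicInterval:
        """Depth-normalization region: scaffold start up to well before the CNV."""
        return GenomicInterval(self.scaffold, 1, self.outer.start - 30_000)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def expected_allelic_fraction(copies_bearing: int, total_copies: int) -> float:
    """Expected AD/DP for a variant on ``copies_bearing`` of ``total_copies``
    locus copies pooled onto one reference position."""
    if not 0 < copies_bearing <= total_copies:
        raise ValueError("need 0 < copies_bearing <= total_copies")
    return copies_bearing / total_copies


# ---------------------------------------------------------------------------
# cohort

def make_truth(
    config: SimConfig, phenotype: str, sex: str, homozygous: bool = False
) -> CnvTruth:
    """CNV truth for one bird of the given phenotype and sex.

    Males are heterozygous carriers (one expanded Z, one wild-type Z) unless
    ``homozygous``; females are hemizygous by construction.
    """
    if phenotype not in config.allele_series:
        raise ValueError(f"no allele-series entry for phenotype {phenotype!r}")
    o, i = config.allele_series[phenotype]
    if sex == "female":
        copies = ((o, i),)
    elif homozygous:
        copies = ((o, i), (o, i))
    else:
        copies = ((o, i), (1, 1))
    return CnvTruth(outer=config.outer, inner=config.inner, copies=copies)


def simulate_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[Sample], dict[str, CnvTruth]]:
    """Generate the cohort with per-sample CNV truth attached.

    Phenotype labels map to copy-number truths via ``config.allele_series``;
    wild-type chromosomes carry (1, 1).
    """
    del rng  # cohort composition is deterministic; kept for API symmetry
    total = sum(n for by_sex in config.cohort.values() for n in by_sex.values())
    if total == 0:
        raise ValueError("cohort is empty")
    samples: list[Sample] = []
    truths: dict[str, CnvTruth] = {}
    for phenotype, by_sex in config.cohort.items():
        for sex, n in by_sex.items():
            for k in range(n):
                sid = f"{phenotype.replace(' ', '')}_{sex[0]}{k:03d}"
                truth = make_truth(config, phenotype, sex)
                samples.append(
                    Sample(id=sid, phenotype=phenotype, sex=sex, st_truth=truth.copies)
                )
                truths[sid] = truth
    return samples, truths


# ---------------------------------------------------------------------------
# depth

def _window_copy_counts(config: SimConfig, truth: CnvTruth) -> np.ndarray:
    """Total copies of each window's sequence summed over Z chromosomes,
    using the window midpoint to place it relative to the CNV segments."""
    n_win = (config.scaffold_length + config.window - 1) // config.window
    mid = np.arange(n_win) * config.window + (config.window + 1) / 2.0
    counts = np.zeros(n_win)
    for o, i in truth.copies:
        per = np.ones(n_win)
        in_outer = (mid >= truth.outer.start) & (mid <= truth.outer.end)
        in_inner = (mid >= truth.inner.start) & (mid <= truth.inner.end)
        per[in_outer] = o
        per[in_inner] = i
        counts += per
    return counts


def simulate_depth(
    sample: Sample,
    truth: CnvTruth,
    config: SimConfig,
    rng: np.random.Generator,
    noiseless: bool = False,
) -> DepthTrack:
    """Windowed read counts: Poisson with mean coverage x copies / baseline.

    ``noiseless`` replaces the Poisson draw with its expectation, producing
    the exact step profile at the breakpoints.
    """
    lam = config.coverage * _window_copy_counts(config, truth) / sample.z_baseline
    values = lam if noiseless else rng.poisson(lam).astype(float)
    return DepthTrack(
        sample_id=sample.id,
        scaffold=config.scaffold,
        window_size=config.window,
        values=values,
    )


# ---------------------------------------------------------------------------
# clipped reads

def simulate_clip_piles(
    truth: CnvTruth, config: SimConfig, rng: np.random.Generator
) -> list[ClipPile]:
    """Soft-clip pileups at the tandem-junction positions plus background.

    A read spanning a novel tandem junction maps in two pieces that clip at
    the reference coordinates of the junction: outer-unit junctions (o-1 per
    chromosome) clip at the outer edges, extra inner repeats (i-o per
    chromosome) at the inner edges.  Pile counts are Poisson with mean
    coverage x junction copies; sporadic 1-read background clips occur at
    ``background_clip_rate`` per bp.
    """
    n_outer_j = sum(o - 1 for o, _ in truth.copies)
    n_inner_j = sum(i - o for o, i in truth.copies)
    piles: list[ClipPile] = []
    ol, il, ir, orr = truth.breakpoints
    for pos, side, mult in (
        (ol, "left", n_outer_j),
        (orr, "right", n_outer_j),
        (il, "left", n_inner_j),
        (ir, "right", n_inner_j),
    ):
        if mult <= 0:
            continue
        count = int(rng.poisson(config.coverage * mult))
        if count >= 1:
            piles.append(ClipPile(config.scaffold, pos, count, side))
    n_bg = rng.poisson(config.background_clip_rate * config.scaffold_length)
    for pos in rng.integers(1, config.scaffold_length + 1, size=n_bg):
        piles.append(
            ClipPile(
                config.scaffold,
                int(pos),
                1,
                "left" if rng.random() < 0.5 else "right",
            )
        )
    return sorted(piles, key=lambda p: p.pos)


# ---------------------------------------------------------------------------
# copy-private allelic depths

_BASES = ("A", "C", "G", "T")


def simulate_allele_depths(
    samples: list[Sample],
    truths: dict[str, CnvTruth],
    config: SimConfig,
    rng: np.random.Generator,
) -> VariantTable:
    """Allelic-depth table inside the CNV with planted copy-private SNVs.

    Each of ``n_private_snvs`` sites carries an alternate allele on exactly
    one repeat copy per expanded chromosome, shared across all expanded
    samples (the scenario the paralog scan hunts for): a carrier with k total
    copies of the inner sequence shows the allele at expected fraction
    (expanded chromosomes)/k.  DP scales with local copy number; sequencing
    errors are added as Binomial(DP, error_rate) reads spread over the other
    alternate bases, which is what makes real sites multiallelic.
    Additionally ``n_paralog_background_sites`` error-only sites are placed
    in the CNV as the null background.

    At planted sites, error reads in non-carrier samples are spread over the
    two bases that are neither reference nor the planted allele, so the
    planted allele is genuinely absent from the control cohort (the ground
    truth the recovery analysis conditions on); carrier errors and all
    background-site errors land on any non-reference base.
    """
    inner = config.inner
    n_sites = config.n_private_snvs + config.n_paralog_background_sites
    pos = rng.choice(
        np.arange(inner.start, inner.end + 1), size=n_sites, replace=False
    )
    private_pos = np.sort(pos[: config.n_private_snvs])
    background_pos = np.sort(pos[config.n_private_snvs :])
    sites: list[VariantSite] = []
    sample_ids = [s.id for s in samples]

    def build_site(p: int, planted: bool) -> VariantSite:
        ref_i = int(rng.integers(0, 4))
        alt_i = int((ref_i + 1 + rng.integers(0, 3)) % 4)
        ad = np.zeros((len(samples), 4), dtype=int)
        dp = np.zeros(len(samples), dtype=int)
        for s_idx, s in enumerate(samples):
            truth = truths[s.id]
            k_total = truth.total_inner
            depth = int(rng.poisson(config.coverage * k_total / s.z_baseline))
            n_exp = sum(1 for o, i in truth.copies if i > 1)
            alt_reads = 0
            if planted and n_exp > 0:
                frac = expected_allelic_fraction(n_exp, k_total)
                alt_reads = int(rng.binomial(depth, frac))
            err_reads = int(rng.binomial(depth - alt_reads, config.error_rate))
            if planted and n_exp == 0:
                err_bases = [b for b in range(4) if b not in (ref_i, alt_i)]
            else:
                err_bases = [b for b in range(4) if b != ref_i]
            k = len(err_bases)
            err_split = (
                rng.multinomial(err_reads, [1 / k] * k) if err_reads else [0] * k
            )
            ad[s_idx, ref_i] = depth - alt_reads - err_reads
            ad[s_idx, alt_i] += alt_reads
            for b, e in zip(err_bases, err_split):
                ad[s_idx, b] += e
            dp[s_idx] = depth
        # allele list: ref first, then any base with >= 1 read anywhere,
        # then (for planted sites) the designated alt even if unread
        order = [ref_i] + [b for b in range(4) if b != ref_i]
        present = [
            b for b in order if b == ref_i or ad[:, b].sum() > 0 or (planted and b == alt_i)
        ]
        if len(present) < 2:
            present = [ref_i, alt_i]
        alleles = tuple(_BASES[b] for b in present)
        return VariantSite(config.scaffold, int(p), alleles, ad[:, present], dp)

    for p in private_pos:
        sites.append(build_site(int(p), planted=True))
    for p in background_pos:
        sites.append(build_site(int(p), planted=False))
    sites.sort(key=lambda s: s.pos)
    return VariantTable(sample_ids, sites)


# ---------------------------------------------------------------------------
# assay & expression plates

def simulate_assay(
    samples: list[Sample],
    truths: dict[str, CnvTruth],
    config: SimConfig,
    rng: np.random.Generator,
    calibrator_id: str | None = None,
) -> AssayTable:
    """TaqMan-style copy-number plate targeting the inner (Mlana) region.

    Ct for the target probe drops by one cycle per doubling of total inner
    copies; the reference probe sits at a fixed 2 autosomal copies.  Gaussian
    plate noise (sd ``assay_sd``) on every replicate.
    """
    ids = {s.id for s in samples}
    if calibrator_id is None:
        wild = [s for s in samples if not truths[s.id].is_expanded()]
        if not wild:
            raise ValueError("no wild-type sample available as calibrator")
        calibrator_id = wild[0].id
    if calibrator_id not in ids:
        raise ValueError(f"calibrator {calibrator_id!r} not in the cohort")
    rows = []
    base = 25.0
    for s in samples:
        cn = truths[s.id].total_inner
        for probe, true_ct in (
            ("target", base - math.log2(cn)),
            ("reference", base - math.log2(2)),
        ):
            for rep in range(config.assay_replicates):
                rows.append(
                    {
                        "sample": s.id,
                        "phenotype": s.phenotype,
                        "sex": s.sex,
                        "probe": probe,
                        "replicate": rep + 1,
                        "ct": true_ct + rng.normal(0.0, config.assay_sd),
                    }
                )
    calibrator_copies = truths[calibrator_id].total_inner
    return AssayTable(
        data=pd.DataFrame(rows),
        calibrator_id=calibrator_id,
        calibrator_copies=calibrator_copies,
    )


def simulate_expression(
    group_sizes: dict[str, int],
    config: SimConfig,
    rng: np.random.Generator,
    effects: dict[str, dict[str, float]] | None = None,
    reference_gene: str = "actb",
) -> CtTable:
    """qRT-PCR plate: Ct = baseline + group effect + Gaussian noise, run in
    duplicate and normalized downstream to the reference gene.

    ``effects[gene][group]`` is a Ct shift: a group overexpressing a gene
    f-fold gets shift -log2(f).  The default emulates a strong (40-fold)
    upregulation of one CNV gene in all carrier groups.
    """
    if effects is None:
        shift = -math.log2(40.0)
        effects = {"Slc16a13": {"DA": shift, "LA": shift, "HA": shift}}
    rows = []
    base = {"ref": 18.0, "gene": 24.0}
    for group, n in group_sizes.items():
        for k in range(n):
            sid = f"{group}_{k:02d}"
            genes = list(effects.keys()) + [reference_gene]
            for gene in genes:
                if gene == reference_gene:
                    true_ct = base["ref"]
                else:
                    true_ct = base["gene"] + effects[gene].get(group, 0.0)
                for rep in range(config.expression_replicates):
                    rows.append(
                        {
                            "sample": sid,
                            "group": group,
                            "gene": gene,
                            "replicate": rep + 1,
                            "ct": true_ct + rng.normal(0.0, config.expression_sd),
                        }
                    )
    return CtTable(data=pd.DataFrame(rows), reference_gene=reference_gene)


# ---------------------------------------------------------------------------
# cohort genotypes for the differentiation scan

def simulate_differentiated_genotypes(
    samples: list[Sample],
    case_ids: set[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> VariantTable:
    """Biallelic Z-linked genotype table with a differentiated causal region.

    Background sites draw both cohorts' allele counts from one shared
    frequency (uniform over ``background_freq_range``); causal-region sites
    draw cases and controls from ``causal_case_freq`` / ``causal_control_freq``.
    Females contribute one allele per site, males two.  Allelic depths are
    then sampled around the genotype fraction at mean depth ``site_dp``.
    """
    n_bg, n_causal = config.n_background_sites, config.n_causal_sites
    causal = config.outer
    bg_space = np.concatenate(
        [
            np.arange(1, causal.start),
            np.arange(causal.end + 1, config.scaffold_length + 1),
        ]
    )
    bg_pos = np.sort(rng.choice(bg_space, size=n_bg, replace=False))
    causal_pos = (
        np.sort(
            rng.choice(
                np.arange(causal.start, causal.end + 1), size=n_causal, replace=False
            )
        )
        if n_causal
        else np.empty(0, dtype=int)
    )
    sample_ids = [s.id for s in samples]
    ploidy = np.array([s.z_baseline for s in samples])
    is_case = np.array([s.id in case_ids for s in samples])

    sites: list[VariantSite] = []

    def build(pos_arr: np.ndarray, case_f: np.ndarray, ctrl_f: np.ndarray) -> None:
        for p, fc, f0 in zip(pos_arr, case_f, ctrl_f):
            freq = np.where(is_case, fc, f0)
            geno = rng.binomial(ploidy, freq)
            dp = rng.poisson(config.site_dp, size=len(samples))
            alt = rng.binomial(dp, np.where(dp > 0, geno / ploidy, 0.0))
            ad = np.stack([dp - alt, alt], axis=1)
            sites.append(
                VariantSite(config.scaffold, int(p), ("A", "G"), ad, dp)
            )

    lo, hi = config.background_freq_range
    shared = rng.uniform(lo, hi, size=n_bg)
    build(bg_pos, shared, shared)
    build(
        causal_pos,
        np.full(n_causal, config.causal_case_freq),
        np.full(n_causal, config.causal_control_freq),
    )
    sites.sort(key=lambda s: s.pos)
    return VariantTable(sample_ids, sites)
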