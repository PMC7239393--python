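"""Copy-number quantification (ddCt), allelic-series association, and
qPCR relative-expression group statistics.

The copy-number assay model: per sample dCt = mean(Ct_target) - mean(Ct_ref);
ddCt = dCt_sample - dCt_calibrator; continuous copies = c0 * 2^(-ddCt) where
c0 is the calibrator's known copy count.  Group comparisons use the pairwise
Wilcoxon rank-sum test with Bonferroni correction (copy number) and one-way
ANOVA with Tukey HSD plus a compact letter display (expression), both on the
log2-scale dCt where variance is closest to homogeneous.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "AssayTable",
    "CtTable",
    "CopyNumberEstimate",
    "quantify_copies",
    "wilcoxon_rank_sum",
    "phenotype_association",
    "relative_expression",
    "group_comparison",
    "compact_letter_display",
]


@dataclass
class AssayTable:
    """Copy-number assay plate in long format.

    ``data`` columns: sample, phenotype, sex, probe ('target'|'reference'),
    replicate, ct.  A designated calibrator sample with known copy count
    anchors the ddCt quantification.
    """

    data: pd.DataFrame
    calibrator_id: str
    calibrator_copies: int

    def __post_init__(self) -> None:
        required = {"sample", "phenotype", "probe", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"assay table missing columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be > 0")
        if self.calibrator_id not in set(self.data["sample"]):
            raise ValueError(f"calibrator {self.calibrator_id!r} absent from plate")


@dataclass
class CtTable:
    """qRT-PCR plate in long format: sample, group, gene, replicate, ct.

    Rows with ``gene == reference_gene`` are the normalizer measurements.
    """

    data: pd.DataFrame
    reference_gene: str = "actb"

    def __post_init__(self) -> None:
        required = {"sample", "group", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return [g for g in self.data["gene"].unique() if g != self.reference_gene]


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample: str
    phenotype: str
    continuous: float
    integer: int

    def __post_init__(self) -> None:
        if self.continuous <= 0:
            raise ValueError("continuous estimate must be > 0")


# ---------------------------------------------------------------------------
# ddCt quantification

def quantify_copies(assay: AssayTable) -> list[CopyNumberEstimate]:
    """ddCt copy-number estimates for every sample on the plate."""
    df = assay.data
    if "reference" not in set(df["probe"]):
        raise ValueError("assay table has no reference-probe measurements")
    dct = (
        df.pivot_table(index="sample", columns="probe", values="ct", aggfunc="mean")
        .eval("target - reference")
        .rename("dct")
    )
    if assay.calibrator_id not in dct.index:
        raise ValueError(f"calibrator {assay.calibrator_id!r} missing target/reference")
    ddct = dct - dct.loc[assay.calibrator_id]
    phenotype = df.groupby("sample")["phenotype"].first()
    out = []
    for sample, d in ddct.items():
        cont = assay.calibrator_copies * 2.0 ** (-d)
        out.append(
            CopyNumberEstimate(
                sample=sample,
                phenotype=str(phenotype[sample]),
                continuous=float(cont),
                integer=int(round(cont)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by dynamic programming over midranks.

    Enumerates the permutation distribution of the rank sum of ``x`` under
    the null that all C(n, nx) assignments of the pooled midranks are equally
    likely; ties are handled exactly because midranks (doubled to integers)
    enter the subset-sum recursion directly.  Two-sided p is twice the
    smaller tail, capped at 1.
    """
    pooled = np.concatenate([x, y])
    ranks2 = np.round(stats.rankdata(pooled) * 2).astype(int)  # doubled midranks
    nx = len(x)
    w_obs = int(ranks2[:nx].sum())
    total = int(ranks2.sum())
    # dp[k][s] = number of k-subsets of the midranks with doubled-sum s
    dp = np.zeros((nx + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    dist = dp[nx]
    n_subsets = dist.sum()
    lo = dist[: w_obs + 1].sum() / n_subsets
    hi = dist[w_obs:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 25
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation enumeration (tie-aware) when both groups have at most
    ``exact_max_n`` observations; otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return _exact_ranksum_p(x, y)
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def phenotype_association(
    estimates: list[CopyNumberEstimate],
    baseline_phenotype: str = "non-Almond",
    exact_max_n: int = 25,
) -> pd.DataFrame:
    """All-pairs Wilcoxon comparison of copy-number by phenotype.

    Returns one row per phenotype pair with the raw two-sided p and two
    Bonferroni-corrected columns: over all pairs tested, and over the
    baseline-vs-other comparisons only (rows not involving the baseline get
    NaN there).  Pairs with an empty group are skipped with a logged reason.
    """
    by_phen: dict[str, list[float]] = {}
    for e in estimates:
        by_phen.setdefault(e.phenotype, []).append(e.continuous)
    groups = sorted(by_phen)
    if len(groups) < 2:
        raise ValueError("need >= 2 phenotype groups")
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        x, y = by_phen[g1], by_phen[g2]
        if not x or not y:
            log.warning("skipping pair (%s, %s): empty group", g1, g2)
            continue
        p = wilcoxon_rank_sum(np.array(x), np.array(y), exact_max_n=exact_max_n)
        rows.append({"group1": g1, "group2": g2, "n1": len(x), "n2": len(y), "p": p})
    out = pd.DataFrame(rows)
    n_pairs = len(out)
    n_vs_baseline = int(
        ((out["group1"] == baseline_phenotype) | (out["group2"] == baseline_phenotype)).sum()
    )
    out["p_bonferroni_all_pairs"] = (out["p"] * n_pairs).clip(upper=1.0)
    vs_base = (out["group1"] == baseline_phenotype) | (out["group2"] == baseline_phenotype)
    out["p_bonferroni_vs_baseline"] = np.where(
        vs_base, (out["p"] * max(n_vs_baseline, 1)).clip(upper=1.0), np.nan
    )
    return out


# ---------------------------------------------------------------------------
# relative expression

def _delta_ct(ct: CtTable) -> pd.DataFrame:
    """Per sample x gene dCt = mean Ct_gene - mean Ct_reference."""
    df = ct.data
    ref = (
        df[df["gene"] == ct.reference_gene]
        .groupby("sample")["ct"]
        .mean()
        .rename("ref_ct")
    )
    tgt = (
        df[df["gene"] != ct.reference_gene]
        .groupby(["sample", "gene", "group"])["ct"]
        .mean()
        .rename("gene_ct")
        .reset_index()
    )
    tgt = tgt.join(ref, on="sample")
    if tgt["ref_ct"].isna().any():
        missing = tgt.loc[tgt["ref_ct"].isna(), "sample"].unique()
        raise ValueError(f"no reference-gene Ct for samples {list(missing)}")
    tgt["dct"] = tgt["gene_ct"] - tgt["ref_ct"]
    return tgt


def relative_expression(ct: CtTable, baseline_group: str = "NA") -> pd.DataFrame:
    """Fold change per sample and gene vs the baseline group's mean dCt.

    fold = 2^-(dCt - mean dCt_baseline); the baseline group's mean sample has
    fold 1 by construction.
    """
    dct = _delta_ct(ct)
    rows = []
    for gene, sub in dct.groupby("gene"):
        base = sub[sub["group"] == baseline_group]
        if base.empty:
            raise ValueError(f"gene {gene!r}: baseline group {baseline_group!r} empty")
        base_mean = base["dct"].mean()
        for r in sub.itertuples():
            rows.append(
                {
                    "sample": r.sample,
                    "group": r.group,
                    "gene": gene,
                    "dct": r.dct,
                    "fold_change": 2.0 ** (-(r.dct - base_mean)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA + Tukey + compact letter display

def compact_letter_display(
    groups: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-absorb letter assignment: groups share a letter iff they are
    not significantly different under the supplied pair set."""
    sig = {tuple(sorted(p)) for p in significant_pairs}
    # start with one letter set holding everything; split on each sig pair
    sets: list[set[str]] = [set(groups)]
    for a, b in sorted(sig):
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [
            s
            for i, s in enumerate(new_sets)
            if s and not any(i != j and s < t for j, t in enumerate(new_sets))
        ]
        # dedupe
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    ordered = sorted(sets, key=lambda s: sorted(s))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", ordered):
        for g in sorted(s):
            letters[g] += letter
    return letters


def group_comparison(ct: CtTable, alpha: float = 0.05) -> dict[str, dict]:
    """Per-gene one-way ANOVA on dCt, Tukey HSD pairs, and letters.

    Groups with fewer than 2 samples are excluded with a logged warning.
    Returns ``{gene: {"anova_F", "anova_p", "tukey": DataFrame, "letters"}}``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    dct = _delta_ct(ct)
    out: dict[str, dict] = {}
    for gene, sub in dct.groupby("gene"):
        sizes = sub.groupby("group").size()
        small = sizes[sizes < 2].index.tolist()
        if small:
            log.warning("gene %s: excluding groups with <2 samples: %s", gene, small)
            sub = sub[~sub["group"].isin(small)]
        groups = sorted(sub["group"].unique())
        if len(groups) < 2:
            raise ValueError(f"gene {gene!r}: fewer than 2 usable groups")
        arrays = [sub.loc[sub["group"] == g, "dct"].to_numpy() for g in groups]
        F, p = stats.f_oneway(*arrays)
        tk = pairwise_tukeyhsd(
            sub["dct"].to_numpy(), sub["group"].to_numpy(), alpha=alpha
        )
        tukey = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        sig_pairs = {
            (str(r["group1"]), str(r["group2"]))
            for _, r in tukey.iterrows()
            if bool(r["reject"])
        }
        out[gene] = {
            "anova_F": float(F),
            "anova_p": float(p),
            "tukey": tukey,
            "letters": compact_letter_display(groups, sig_pairs),
        }
    return out
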