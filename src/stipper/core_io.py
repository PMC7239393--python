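"""Domain types and readers/writers for the tabular formats the pipeline touches.

Coordinates are 1-based inclusive throughout, matching how scaffold positions
are conventionally printed for this locus; BED input is converted on read and
BED output converted on write.  The module also pins the published anchor
coordinates of the *Stipper* CNV on the Z-linked scaffold ScoHet5_227, which
several downstream defaults reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Z_SCAFFOLD",
    "OUTER_CNV",
    "INNER_CNV",
    "CONTROL_REGION",
    "KNOWN_PHENOTYPES",
    "GenomicInterval",
    "Sample",
    "DepthTrack",
    "VariantSite",
    "VariantTable",
    "GeneModel",
    "ClipPile",
    "parse_region",
    "read_variant_table",
    "write_variant_table",
    "read_depth_table",
    "write_depth_table",
    "read_annotations_and_samples",
    "read_gene_models",
    "read_sample_sheet",
    "write_bed12",
    "write_sample_sheet",
    "read_clip_table",
    "write_clip_table",
]


# ---------------------------------------------------------------------------
# intervals

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed interval [start, end] on a scaffold, 1-based inclusive."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    def length(self) -> int:
        return self.end - self.start + 1

    def kb_label(self) -> str:
        """Floor-kilobase label, e.g. '77-kb' for a 77,790 bp interval."""
        return f"{self.length() // 1000}-kb"

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.end
            and other.start <= self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.scaffold, self.start + offset, self.end + offset)

    def __str__(self) -> str:  # SCAFFOLD:START-END, the CLI region syntax
        return f"{self.scaffold}:{self.start}-{self.end}"


#: Z-linked scaffold carrying the St locus.
Z_SCAFFOLD = "ScoHet5_227"
#: Published outer CNV segment (77-kb label under floor-kb reporting).
OUTER_CNV = GenomicInterval(Z_SCAFFOLD, 5_181_467, 5_259_256)
#: Published nested inner segment (25-kb label).
INNER_CNV = GenomicInterval(Z_SCAFFOLD, 5_201_091, 5_226_635)
#: Region used to normalize read depth (no coverage gain in affected birds).
CONTROL_REGION = GenomicInterval(Z_SCAFFOLD, 1, 5_000_000)

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse 'SCAFFOLD:START-END' (commas in numbers allowed)."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region {text!r}; expected SCAFFOLD:START-END")
    return GenomicInterval(
        m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", ""))
    )


# ---------------------------------------------------------------------------
# samples

#: Phenotype labels of the St allelic series plus the wild-type cohort label.
KNOWN_PHENOTYPES = frozenset(
    {
        "non-Almond",
        "Almond",
        "Qualmond",
        "Faded",
        "Sandy",
        "Frosty",
        "Chalky",
        "White Out",
    }
)

_SEX_ALIASES = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
}


@dataclass
class Sample:
    """One bird: id, phenotype cohort, sex, and (simulation only) CNV truth.

    Birds are ZW/ZZ: females carry a single Z so their baseline copy count for
    any Z-linked locus is 1, males' is 2.  ``st_truth`` holds the simulated
    per-Z-chromosome (outer, inner) copy counts when the sample was generated
    by :mod:`stipper.simcohort`.
    """

    id: str
    phenotype: str
    sex: str
    st_truth: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        sex = _SEX_ALIASES.get(str(self.sex).strip().lower())
        if sex is None:
            raise ValueError(f"sample {self.id!r}: unknown sex {self.sex!r}")
        self.sex = sex
        if self.st_truth is not None and len(self.st_truth) != self.z_baseline:
            raise ValueError(
                f"sample {self.id!r}: {len(self.st_truth)} Z-chromosome truths "
                f"for a {self.sex} (expected {self.z_baseline})"
            )

    @property
    def z_baseline(self) -> int:
        """Baseline Z copies: 1 for females (ZW), 2 for males (ZZ)."""
        return 1 if self.sex == "female" else 2


# ---------------------------------------------------------------------------
# depth tracks

@dataclass
class DepthTrack:
    """Per-window mean sequencing depth for one sample on one scaffold.

    Windows tile the scaffold from position 1 without overlap; window ``w``
    (0-based) covers positions ``[w*window_size + 1, (w+1)*window_size]``.
    """

    sample_id: str
    scaffold: str
    window_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if np.any(self.values < 0):
            raise ValueError("depths must be >= 0")

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def window_interval(self, idx: int) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold, idx * self.window_size + 1, (idx + 1) * self.window_size
        )

    def window_index(self, pos: int) -> int:
        return (pos - 1) // self.window_size

    def windows_overlapping(self, interval: GenomicInterval) -> np.ndarray:
        """Indices of windows overlapping ``interval`` (same scaffold only)."""
        if interval.scaffold != self.scaffold:
            return np.empty(0, dtype=int)
        first = (interval.start - 1) // self.window_size
        last = (interval.end - 1) // self.window_size
        last = min(last, self.n_windows - 1)
        if first > last:
            return np.empty(0, dtype=int)
        return np.arange(first, last + 1)


# ---------------------------------------------------------------------------
# variant tables

@dataclass
class VariantSite:
    """One (possibly multiallelic) site with per-sample AD vectors and DP.

    ``ad`` has shape (n_samples, n_alleles), reference allele first.  Missing
    per-sample data is flagged with ``dp == -1`` (AD row ignored).
    """

    scaffold: str
    pos: int
    alleles: tuple[str, ...]
    ad: np.ndarray
    dp: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = tuple(self.alleles)
        if len(self.alleles) < 2:
            raise ValueError(f"{self.scaffold}:{self.pos}: need >= 2 alleles")
        self.ad = np.asarray(self.ad, dtype=int)
        self.dp = np.asarray(self.dp, dtype=int)
        if self.ad.ndim != 2 or self.ad.shape[1] != len(self.alleles):
            raise ValueError(
                f"{self.scaffold}:{self.pos}: AD shape {self.ad.shape} does not "
                f"match {len(self.alleles)} alleles"
            )
        if self.ad.shape[0] != len(self.dp):
            raise ValueError("AD and DP sample dimensions differ")
        ok = self.dp >= 0
        if np.any(self.ad[ok].sum(axis=1) > self.dp[ok]):
            raise ValueError(
                f"{self.scaffold}:{self.pos}: sum(AD) exceeds DP for some sample"
            )

    @property
    def n_samples(self) -> int:
        return len(self.dp)

    def missing(self) -> np.ndarray:
        return self.dp < 0


@dataclass
class VariantTable:
    """Sites-by-samples container; sample order is the header/sheet order."""

    samples: list[str]
    sites: list[VariantSite]

    def __post_init__(self) -> None:
        for s in self.sites:
            if s.n_samples != len(self.samples):
                raise ValueError(
                    f"site {s.scaffold}:{s.pos} has {s.n_samples} sample columns, "
                    f"table has {len(self.samples)}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def in_region(self, region: GenomicInterval | None) -> "VariantTable":
        if region is None:
            return self
        keep = [
            s
            for s in self.sites
            if s.scaffold == region.scaffold and region.contains(s.pos)
        ]
        return VariantTable(list(self.samples), keep)


# ---------------------------------------------------------------------------
# gene models & clip piles

#: Gene placement classes relative to the CNV segments.
GENE_CLASSES = (
    "inside_inner",
    "inside_outer",
    "spans_left_outer",
    "spans_right_outer",
    "spans_inner_boundary",
    "outside",
)


@dataclass
class GeneModel:
    name: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    classification: str | None = None

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        if not self.exons:
            raise ValueError(f"gene {self.name!r}: no exons")
        scafs = {e.scaffold for e in self.exons}
        if len(scafs) > 1:
            raise ValueError(f"gene {self.name!r}: exons on multiple scaffolds")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"gene {self.name!r}: exons must be sorted and non-overlapping"
                )
        if self.classification is not None and self.classification not in GENE_CLASSES:
            raise ValueError(f"unknown gene classification {self.classification!r}")

    @property
    def scaffold(self) -> str:
        return self.exons[0].scaffold

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.scaffold, self.exons[0].start, self.exons[-1].end)


@dataclass(frozen=True)
class ClipPile:
    """Pileup of reads whose alignment is clipped at exactly one position."""

    scaffold: str
    pos: int
    count: int
    side: str  # 'left' | 'right'

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("clip pile count must be >= 1")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


# ---------------------------------------------------------------------------
# VCF I/O

def read_variant_table(
    path: str | Path, region: GenomicInterval | None = None
) -> VariantTable:
    """Read a VCF (4.2, per-sample AD and DP FORMAT fields) into a table.

    Multiallelic records are preserved un-split.  Samples missing AD or DP at
    a record get the per-sample missing flag (``dp == -1``) rather than
    failing the read.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    for i, rec in enumerate(vcf):
        try:
            scaffold = rec.CHROM
            pos = rec.POS
            if region is not None and not (
                scaffold == region.scaffold and region.contains(pos)
            ):
                continue
            alleles = tuple([rec.REF] + list(rec.ALT))
            n = len(samples)
            ad = rec.format("AD")
            dp = rec.format("DP")
            ad_arr = np.zeros((n, len(alleles)), dtype=int)
            dp_arr = np.full(n, -1, dtype=int)
            if ad is not None and dp is not None:
                ad = np.asarray(ad)
                dp = np.asarray(dp).reshape(n, -1)[:, 0]
                for s in range(n):
                    if dp[s] < 0 or np.any(ad[s] < 0):
                        continue  # missing for this sample
                    ad_arr[s] = ad[s][: len(alleles)]
                    dp_arr[s] = dp[s]
            sites.append(VariantSite(scaffold, pos, alleles, ad_arr, dp_arr))
        except Exception as exc:  # noqa: BLE001 - name the offending record
            raise ValueError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    return VariantTable(samples, sites)


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-free FORMAT ``AD:DP`` columns."""
    scaffolds: dict[str, int] = {}
    for s in table.sites:
        scaffolds[s.scaffold] = max(scaffolds.get(s.scaffold, 0), s.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=stipper\n')
        for scaf, maxpos in scaffolds.items():
            fh.write(f"##contig=<ID={scaf},length={maxpos + 1000}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref first)">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for site in sorted(table.sites, key=lambda s: (s.scaffold, s.pos)):
            alt = ",".join(site.alleles[1:])
            cols = [site.scaffold, str(site.pos), ".", site.alleles[0], alt, ".", ".",
                    ".", "AD:DP"]
            for s in range(site.n_samples):
                if site.dp[s] < 0:
                    cols.append(".:.")
                else:
                    cols.append(",".join(map(str, site.ad[s])) + f":{site.dp[s]}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# depth tables

def read_depth_table(
    path: str | Path, window: int = 100
) -> dict[str, dict[str, DepthTrack]]:
    """Read a per-position depth TSV into windowed tracks.

    Input columns: CHROM, POS, then one depth column per sample (the layout
    produced by per-site depth extraction tools).  Positions are aggregated
    into tiling windows by mean, with positions absent from the file counted
    as depth 0; the final partial window is averaged over its covered span.

    Returns ``{sample_id: {scaffold: DepthTrack}}``.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected CHROM, POS and >=1 sample column")
    chrom_col, pos_col = df.columns[0], df.columns[1]
    sample_cols = list(df.columns[2:])
    for col in sample_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise ValueError(
                f"{path}: non-numeric depth in column {col!r}, row {row + 2} "
                f"(value {df[col].iloc[row]!r})"
            )
        df[col] = numeric
    out: dict[str, dict[str, DepthTrack]] = {c: {} for c in sample_cols}
    for scaffold, sub in df.groupby(chrom_col, sort=False):
        pos = sub[pos_col].to_numpy(dtype=int)
        maxpos = int(pos.max())
        n_win = (maxpos + window - 1) // window
        widx = (pos - 1) // window
        # covered span of each window (full except possibly the last)
        span = np.full(n_win, window, dtype=float)
        span[-1] = maxpos - (n_win - 1) * window
        for col in sample_cols:
            sums = np.bincount(widx, weights=sub[col].to_numpy(dtype=float),
                               minlength=n_win)
            out[col][str(scaffold)] = DepthTrack(
                sample_id=col, scaffold=str(scaffold), window_size=window,
                values=sums / span,
            )
    return out


def write_depth_table(
    path: str | Path,
    tracks: Sequence[DepthTrack],
    scaffold_length: int | None = None,
) -> None:
    """Write tracks as a per-position depth TSV (CHROM, POS, one col/sample).

    Each window's mean depth is written at every position it covers, so
    re-reading with the same window size reproduces the values exactly.
    All tracks must share scaffold and window size.
    """
    if not tracks:
        raise ValueError("no tracks to write")
    scaffold = tracks[0].scaffold
    window = tracks[0].window_size
    n_win = max(t.n_windows for t in tracks)
    for t in tracks:
        if t.scaffold != scaffold or t.window_size != window:
            raise ValueError("all tracks must share scaffold and window size")
    length = scaffold_length or n_win * window
    pos = np.arange(1, length + 1)
    widx = (pos - 1) // window
    data = {"CHROM": scaffold, "POS": pos}
    for t in tracks:
        vals = np.zeros(n_win)
        vals[: t.n_windows] = t.values
        data[t.sample_id] = vals[widx]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (``.bed``) or a GFF3 subset (``.gff/.gff3``)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed12(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    raise ValueError(f"unsupported gene model format: {path.suffix!r}")


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 fields, got {len(f)}")
            scaffold, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ValueError(f"{path}:{ln}: blockCount mismatch")
            exons = tuple(
                GenomicInterval(scaffold, chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            genes.append(GeneModel(name=name, strand=strand, exons=exons))
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        name = g.attributes.get("Name", [g.id])[0]
        exons = sorted(
            db.children(g, featuretype="exon"), key=lambda e: (e.start, e.end)
        )
        if not exons:
            exons = [g]
        genes.append(
            GeneModel(
                name=name,
                strand=g.strand,
                exons=tuple(
                    GenomicInterval(e.seqid, e.start, e.end) for e in exons
                ),
            )
        )
    return genes


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            chrom_start = span.start - 1
            sizes = ",".join(str(e.length()) for e in g.exons)
            starts = ",".join(str(e.start - span.start) for e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.scaffold,
                        str(chrom_start),
                        str(span.end),
                        g.name,
                        "0",
                        g.strand,
                        str(chrom_start),
                        str(span.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# sample sheets

def read_sample_sheet(
    path: str | Path, allowed_phenotypes: frozenset[str] = KNOWN_PHENOTYPES
) -> list[Sample]:
    """Read a CSV sample sheet (columns: id, phenotype, sex)."""
    df = pd.read_csv(path, dtype=str)
    required = {"id", "phenotype", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    bad_rows = []
    samples = []
    for i, row in df.iterrows():
        sex = _SEX_ALIASES.get(str(row["sex"]).strip().lower())
        phen = str(row["phenotype"]).strip()
        if sex is None or phen not in allowed_phenotypes:
            bad_rows.append(f"row {i + 2}: id={row['id']!r} phenotype={phen!r} sex={row['sex']!r}")
            continue
        samples.append(Sample(id=str(row["id"]), phenotype=phen, sex=sex))
    if bad_rows:
        raise ValueError(
            f"{path}: unknown sex or phenotype label in rows:\n  " + "\n  ".join(bad_rows)
        )
    return samples


def write_sample_sheet(samples: Sequence[Sample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [s.id for s in samples],
            "phenotype": [s.phenotype for s in samples],
            "sex": [s.sex for s in samples],
        }
    ).to_csv(path, index=False)


def read_annotations_and_samples(
    gene_path: str | Path, sample_path: str | Path
) -> tuple[list[GeneModel], list[Sample]]:
    """Load gene models and the cohort sample sheet in one call."""
    return read_gene_models(gene_path), read_sample_sheet(sample_path)


# ---------------------------------------------------------------------------
# clip piles

def read_clip_table(path: str | Path) -> list[ClipPile]:
    df = pd.read_csv(path, sep="\t")
    return [
        ClipPile(str(r.scaffold), int(r.pos), int(r.count), str(r.side))
        for r in df.itertuples()
    ]


def write_clip_table(piles: Sequence[ClipPile], path: str | Path) -> None:
    pd.DataFrame(
        {
            "scaffold": [p.scaffold for p in piles],
            "pos": [p.pos for p in piles],
            "count": [p.count for p in piles],
            "side": [p.side for p in piles],
        }
    ).to_csv(path, sep="\t", index=False)
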