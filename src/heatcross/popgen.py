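"""Genotype-matrix filtering, identity-by-state distances and R-gene scanning.

The pipeline starts from a biallelic genotype matrix (typically read from a
VCF produced by an upstream caller). Calls are coded as alternate-allele
dosage 0/1/2 with ``-1`` for missing; per-site mean depth is optional, as
array-derived matrices carry no depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover - avoids an import cycle with io_formats
    from .io_formats import GeneCatalog

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")


class ConfigError(ValueError):
    """A filtering threshold outside its valid range."""


@dataclass(frozen=True)
class Locus:
    chrom: str
    pos: int  # 1-based
    ref: str = "N"
    alt: str = "N"


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci with dosage calls.

    calls[i, j] is the alternate-allele dosage of sample i at locus j
    (0, 1, 2) or ``MISSING`` (-1). ``depth`` holds per-site mean coverage
    when known.
    """

    sample_ids: list[str]
    loci: list[Locus]
    calls: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
            if self.depth.shape != (len(self.loci),):
                raise ValueError("depth must be one mean value per locus")
            if (self.depth < 0).any():
                raise ValueError("negative mean depth")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same_depth = (
            (self.depth is None and other.depth is None)
            or (
                self.depth is not None
                and other.depth is not None
                and np.allclose(self.depth, other.depth)
            )
        )
        return (
            self.sample_ids == other.sample_ids
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and same_depth
        )


@dataclass
class IbsMatrix:
    """Pairwise identity-by-state proportions with shared-locus counts."""

    sample_ids: list[str]
    values: np.ndarray  # square, symmetric, diagonal 1, NaN where undefined
    shared_loci: np.ndarray  # per-pair count of jointly non-missing loci

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def pair(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])


@dataclass
class ImpactTally:
    counts: dict[str, int]
    percentages: dict[str, float]
    formatted: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def filter_variants(
    m: GenotypeMatrix,
    max_missing: float = 0.5,
    min_mean_dp: float = 5.0,
    require_polymorphic: bool = True,
) -> GenotypeMatrix:
    """Site-level filtering with the usual vcftools flag semantics.

    ``max_missing`` keeps sites whose *non-missing* call fraction is at
    least the threshold (so 0.5 keeps sites with >=50% data). Sites with a
    mean depth below ``min_mean_dp`` are dropped; matrices without depth
    annotations pass the depth filter with a warning. Monomorphic sites
    (fewer than two observed genotype states) are removed. Site order is
    preserved and the operation is idempotent.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ConfigError(f"max_missing must be in [0, 1], got {max_missing}")
    if min_mean_dp < 0:
        raise ConfigError(f"min_mean_dp must be >= 0, got {min_mean_dp}")
    if m.n_loci == 0:
        raise ValueError("empty genotype matrix")

    present = 1.0 - m.missing_fraction()
    keep = present >= max_missing

    if m.depth is not None:
        keep &= m.depth >= min_mean_dp
    else:
        log.warning("no depth annotations: all sites pass the min-mean-DP filter")

    if require_polymorphic:
        poly = np.zeros(m.n_loci, dtype=bool)
        for j in range(m.n_loci):
            observed = m.calls[:, j]
            states = np.unique(observed[observed != MISSING])
            poly[j] = states.size >= 2
        keep &= poly

    idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        sample_ids=list(m.sample_ids),
        loci=[m.loci[j] for j in idx],
        calls=m.calls[:, idx].copy(),
        depth=None if m.depth is None else m.depth[idx].copy(),
    )


def ibs_matrix(m: GenotypeMatrix) -> IbsMatrix:
    """Pairwise IBS allele-sharing proportions.

    For a sample pair, IBS is the mean over jointly non-missing loci of
    ``(2 - |g_i - g_j|) / 2`` with dosage coding 0/1/2. Pairs sharing no
    locus get a NaN entry and a warning.
    """
    if m.n_samples < 2:
        raise ValueError("IBS needs at least two samples")
    calls = m.calls.astype(float)
    calls[m.calls == MISSING] = np.nan
    n = m.n_samples
    values = np.ones((n, n))
    shared = np.full((n, n), m.n_loci, dtype=int)
    for i in range(n):
        shared[i, i] = int(np.sum(~np.isnan(calls[i])))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(calls[i]) & ~np.isnan(calls[j])
            k = int(both.sum())
            shared[i, j] = shared[j, i] = k
            if k == 0:
                warnings.warn(
                    f"samples {m.sample_ids[i]!r} and {m.sample_ids[j]!r} share no "
                    "non-missing locus; IBS undefined",
                    stacklevel=2,
                )
                values[i, j] = values[j, i] = np.nan
                continue
            sharing = (2.0 - np.abs(calls[i][both] - calls[j][both])) / 2.0
            values[i, j] = values[j, i] = float(sharing.mean())
    return IbsMatrix(list(m.sample_ids), values, shared)


def prg_scan(
    m: GenotypeMatrix,
    catalog: "GeneCatalog",
) -> pd.DataFrame:
    """Per-genotype variability over a resistance-gene catalog.

    A genotype is polymorphic at a locus when it carries at least one
    alternate allele (dosage >= 1). For each sample the scan reports the
    genes containing such a locus, the number of such SNPs within catalog
    genes, and that count as a percentage of all catalog-gene SNPs in the
    matrix. Loci mapping outside every catalog interval are counted and
    reported as a warning.
    """
    intervals = [(g.gene_id, g.chromosome, g.start, g.end) for g in catalog.genes]

    locus_gene: list[str | None] = []
    outside = 0
    for locus in m.loci:
        hit = None
        for gene_id, chrom, start, end in intervals:
            if locus.chrom == chrom and start <= locus.pos <= end:
                hit = gene_id
                break
        if hit is None:
            outside += 1
        locus_gene.append(hit)
    if outside:
        warnings.warn(
            f"{outside} of {m.n_loci} loci fall outside every catalog interval",
            stacklevel=2,
        )

    in_gene = np.array([g is not None for g in locus_gene])
    total_snps = int(in_gene.sum())
    rows = []
    for i, sample in enumerate(m.sample_ids):
        alt = (m.calls[i] >= 1) & in_gene
        genes = sorted({locus_gene[j] for j in np.flatnonzero(alt)})
        n_snps = int(alt.sum())
        pct = 100.0 * n_snps / total_snps if total_snps else 0.0
        rows.append(
            {
                "genotype": sample,
                "polymorphic_genes": ";".join(genes),
                "n_genes": len(genes),
                "n_snps": n_snps,
                "pct_of_total_snps": pct,
            }
        )
    return pd.DataFrame(rows)


def prg_scan_fixture(
    catalog: "GeneCatalog", genotypes: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-genotype tallies straight from catalog SNP multiplicities.

    Mirrors :func:`prg_scan` for a catalog that carries per-genotype SNP
    counts instead of locus coordinates (the printed-table path). The
    denominator is the catalog's distinct-SNP total (per-gene maximum
    multiplicity summed over genes). Pass ``genotypes`` to report a fixed
    panel, including members absent from every gene (count 0).
    """
    total = catalog.total_snps()
    if genotypes is None:
        genotypes = sorted({g for gene in catalog.genes for g in gene.snp_counts})
    else:
        genotypes = list(genotypes)
    rows = []
    for geno in genotypes:
        genes = [g for g in catalog.genes if geno in g.snp_counts]
        n_snps = sum(g.snp_counts[geno] for g in genes)
        rows.append(
            {
                "genotype": geno,
                "polymorphic_genes": ";".join(g.gene_id for g in genes),
                "n_genes": len(genes),
                "n_snps": n_snps,
                "pct_of_total_snps": 100.0 * n_snps / total if total else 0.0,
                "pct_of_genes": 100.0 * len(genes) / catalog.n_genes,
            }
        )
    return pd.DataFrame(rows)


def format_percentage(value: float) -> str:
    """Half-up rounding, two decimals below 1% and one decimal otherwise."""
    places = Decimal("0.01") if value < 1.0 else Decimal("0.1")
    return str(Decimal(repr(value)).quantize(places, rounding=ROUND_HALF_UP))


def impact_tally(
    annotations: Iterable[tuple[object, str]] | Mapping[str, int],
) -> ImpactTally:
    """Tally predicted-effect classes and their percentages.

    Accepts (locus, class) pairs or a precomputed class->count mapping.
    Classes must come from the standard HIGH/MODERATE/LOW/MODIFIER set.
    """
    counts = dict.fromkeys(IMPACT_CLASSES, 0)
    if isinstance(annotations, Mapping):
        items = annotations.items()
        for cls, n in items:
            if cls not in IMPACT_CLASSES:
                raise ValueError(f"unknown impact class {cls!r}")
            counts[cls] += int(n)
    else:
        for _locus, cls in annotations:
            if cls not in IMPACT_CLASSES:
                raise ValueError(f"unknown impact class {cls!r}")
            counts[cls] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no annotations to tally")
    pct = {cls: 100.0 * n / total for cls, n in counts.items()}
    formatted = {cls: format_percentage(p) for cls, p in pct.items()}
    return ImpactTally(counts=counts, percentages=pct, formatted=formatted)


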