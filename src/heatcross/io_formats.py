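"""Readers and writers for the external formats the pipeline touches.

Covers delimited trait and cross tables, VCF genotype matrices, FASTA
templates, BED/GFF3 gene intervals, and loaders for the packaged fixture
tables (the resistance-gene SNP catalog, the parental and F1 marker-call
tables, and the hybrid heterosis table).

Genomic coordinates are 1-based inclusive internally (GFF convention);
BED input is converted on read.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .popgen import MISSING, GenotypeMatrix, Locus

TRAIT_COLUMNS = ("FS", "TNF", "FW", "YP", "TSSC", "TA")

MARKER_GENES = ("Mi-1.2", "Ph-3", "Sw-5", "Tm-2", "Ty-3", "Ve-1")

VALID_CALLS = ("RR", "RS", "SS", "NULL")


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


@dataclass(frozen=True)
class TraitRecord:
    """One genotype x environment phenotype row.

    FS fruit set (%), TNF fruits per plant, FW fruit weight (g), YP yield
    per plant (kg), TSSC total soluble solids (degrees Brix), TA titratable
    acidity (g citric acid / 100 g). Any trait may be absent (None).
    """

    genotype_id: str
    environment: str = ""
    year: int | None = None
    replicate: int | None = None
    FS: float | None = None
    TNF: float | None = None
    FW: float | None = None
    YP: float | None = None
    TSSC: float | None = None
    TA: float | None = None

    def __post_init__(self) -> None:
        if self.FS is not None and not 0.0 <= self.FS <= 100.0:
            raise ValidationError(f"FS={self.FS} outside [0, 100] for {self.genotype_id}")
        for name in ("TNF", "FW", "YP", "TSSC", "TA"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name}={v} negative for {self.genotype_id}")

    def trait(self, name: str) -> float | None:
        if name not in TRAIT_COLUMNS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class CrossDesign:
    """hybrid = parent1 x parent2."""

    hybrid_id: str
    parent1_id: str
    parent2_id: str

    def __post_init__(self) -> None:
        if self.parent1_id == self.parent2_id:
            raise ValidationError(f"{self.hybrid_id}: identical parents {self.parent1_id}")


@dataclass(frozen=True)
class GeneRecord:
    """A resistance-gene interval with per-genotype SNP multiplicities."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    function: str = ""
    effect: str = ""
    snp_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start {self.start} > end {self.end}")
        for geno, n in self.snp_counts.items():
            if n < 1:
                raise ValidationError(f"{self.gene_id}: multiplicity {n} for {geno}")

    @property
    def high_impact(self) -> bool:
        return "stop_gained" in self.effect or "stop_lost" in self.effect

    @property
    def distinct_snps(self) -> int:
        """Distinct SNPs in this gene = maximum multiplicity over genotypes."""
        return max(self.snp_counts.values(), default=0)


@dataclass
class GeneCatalog:
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate gene_id in catalog")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def total_snps(self) -> int:
        return sum(g.distinct_snps for g in self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneCatalog):
            return NotImplemented
        return self.genes == other.genes


@dataclass
class MarkerCallTable:
    """One call per (genotype, gene); NULL means the assay failed."""

    calls: dict[tuple[str, str], str]
    genes: tuple[str, ...] = MARKER_GENES

    def __post_init__(self) -> None:
        for (geno, gene), call in self.calls.items():
            if call not in VALID_CALLS:
                raise ValidationError(f"bad call {call!r} for ({geno}, {gene})")

    @property
    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for geno, _gene in self.calls:
            seen.setdefault(geno)
        return list(seen)

    def call(self, genotype: str, gene: str) -> str:
        return self.calls.get((genotype, gene), "NULL")

    def row(self, genotype: str) -> dict[str, str]:
        return {gene: self.call(genotype, gene) for gene in self.genes}

    def count_calls(self, gene: str, call: str) -> int:
        return sum(1 for g in self.genotypes if self.call(g, gene) == call)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerCallTable):
            return NotImplemented
        return self.calls == other.calls and self.genes == other.genes


# ---------------------------------------------------------------------------
# delimited tables


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text(encoding="utf-8")[:4096]
    return "\t" if "\t" in sample.splitlines()[0] else ","


def read_trait_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[TraitRecord]:
    """Read a delimited trait table into validated records, order preserved.

    ``column_map`` maps file header names onto the canonical trait and key
    columns when the file uses different labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delimiter = delimiter or _sniff_delimiter(path)
    records: list[TraitRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.DictReader(fh, delimiter=delimiter) if any(r.values())]
    if not rows:
        raise FormatError(f"{path}: empty trait table")
    remap = dict(column_map or {})
    header = [remap.get(h, h) for h in rows[0].keys()]
    if "genotype_id" not in header and "genotype" not in header:
        raise FormatError(f"{path}: missing mandatory column 'genotype_id'")
    for idx, raw in enumerate(rows):
        row = {remap.get(k, k): v for k, v in raw.items()}
        kwargs: dict[str, object] = {
            "genotype_id": row.get("genotype_id") or row.get("genotype") or "",
            "environment": row.get("environment", "") or "",
        }
        for key in ("year", "replicate"):
            if row.get(key):
                kwargs[key] = int(row[key])
        for trait in TRAIT_COLUMNS:
            value = row.get(trait, "")
            if value is None or value == "" or value.upper() == "NA":
                continue
            kwargs[trait] = float(value)
        try:
            records.append(TraitRecord(**kwargs))  # type: ignore[arg-type]
        except ValidationError as err:
            raise ValidationError(f"{path} row {idx + 1}: {err}") from err
    return records


def write_trait_table(records: Iterable[TraitRecord], path: str | Path) -> None:
    path = Path(path)
    cols = ["genotype_id", "environment", "year", "replicate", *TRAIT_COLUMNS]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(cols)
        for r in records:
            writer.writerow(["" if getattr(r, c) is None else getattr(r, c) for c in cols])


def read_cross_table(path: str | Path, delimiter: str | None = None) -> list[CrossDesign]:
    """Read a hybrid -> (parent1, parent2) design table."""
    path = Path(path)
    delimiter = delimiter or "\t"
    crosses = []
    with path.open(newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    for row in csv.DictReader(lines, delimiter=delimiter):
        crosses.append(
            CrossDesign(row["hybrid"].strip(), row["parent1"].strip(), row["parent2"].strip())
        )
    if not crosses:
        raise FormatError(f"{path}: no crosses")
    return crosses


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, multiallelic: str = "drop") -> GenotypeMatrix:
    """Read a VCF 4.x into a biallelic dosage matrix.

    ``multiallelic`` is "drop" (default; sites with >1 ALT discarded) or
    "split" (each ALT becomes its own biallelic pseudo-site). Any genotype
    containing an uncalled allele is treated as missing. Per-site mean DP
    is carried when the FORMAT declares DP.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("drop", "split"):
        raise ValueError(f"multiallelic policy {multiallelic!r}")
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples")
    loci: list[Locus] = []
    calls_rows: list[np.ndarray] = []
    depths: list[float] = []
    any_depth = False
    for variant in vcf:
        alts = variant.ALT
        if len(alts) != 1:
            if multiallelic == "drop" or not alts:
                continue
        gts = variant.genotypes  # [allele1, allele2, phased] per sample
        site_dp = np.nan
        try:
            dp = variant.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_depth = True
            dpv = np.asarray(dp, dtype=float).ravel()
            dpv = dpv[dpv >= 0]
            site_dp = float(dpv.mean()) if dpv.size else np.nan
        for ai, alt in enumerate(alts, start=1):
            if multiallelic == "drop" and ai > 1:
                break
            row = np.full(len(samples), MISSING, dtype=np.int8)
            for s in range(len(samples)):
                alleles = gts[s][:-1]  # last field is phasing
                if any(a < 0 for a in alleles):
                    continue  # half-calls and no-calls are missing
                row[s] = sum(1 for a in alleles if a == ai)
            loci.append(Locus(variant.CHROM, variant.POS, variant.REF, str(alt)))
            calls_rows.append(row)
            depths.append(site_dp)
    vcf.close()
    calls = (
        np.stack(calls_rows, axis=1) if calls_rows else np.empty((len(samples), 0), np.int8)
    )
    depth = np.array(depths) if any_depth else None
    return GenotypeMatrix(samples, loci, calls, depth)


def write_vcf(m: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 carrying GT (and DP when present)."""
    path = Path(path)
    has_dp = m.depth is not None
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with path.open("w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in dict.fromkeys(l.chrom for l in m.loci):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(m.sample_ids) + "\n")
        for j, locus in enumerate(m.loci):
            fmt = "GT:DP" if has_dp else "GT"
            fields = [locus.chrom, str(locus.pos), ".", locus.ref, locus.alt, ".", ".", ".", fmt]
            for i in range(m.n_samples):
                gt = gt_strings[int(m.calls[i, j])]
                if has_dp:
                    gt += f":{int(round(m.depth[j]))}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA and intervals


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_intervals(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Read gene intervals from BED (0-based half-open, converted) or GFF3.

    Returns (name, chromosome, start, end) with 1-based inclusive coordinates.
    """
    path = Path(path)
    out: list[tuple[str, str, int, int]] = []
    is_gff = path.suffix.lower() in (".gff", ".gff3")
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if is_gff:
                chrom, _src, _type, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
                attrs = parts[8] if len(parts) > 8 else ""
                match = re.search(r"(?:ID|Name)=([^;]+)", attrs)
                name = match.group(1) if match else f"{chrom}:{start}-{end}"
                out.append((name, chrom, int(start), int(end)))
            else:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
                out.append((name, chrom, start + 1, end))
    return out


# ---------------------------------------------------------------------------
# packaged fixtures

_SOLYC = re.compile(r"Solyc(\d{2})g(\d{6})")

_GENO_COUNT = re.compile(r"^(?P<geno>[A-Za-z0-9]+)(?:\s*\((?P<n>\d+)\))?$")


def _fixture_path(filename: str) -> Path:
    return Path(str(resources.files("heatcross.data").joinpath(filename)))


def _synthetic_interval(gene_id: str) -> tuple[str, int, int]:
    """Deterministic placeholder interval derived from the Solyc id.

    The printed catalog carries no coordinates, so fixtures get synthetic
    ones: chromosome from the id, a start proportional to the gene number
    and a nominal 3 kb span. Real analyses should supply real intervals.
    """
    match = _SOLYC.fullmatch(gene_id)
    if not match:
        raise FormatError(f"cannot derive interval from gene id {gene_id!r}")
    chrom = f"SL4.0ch{match.group(1)}"
    start = int(match.group(2)) * 100 + 1
    return chrom, start, start + 2999


def _parse_genotype_counts(cell: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for token in cell.split(","):
        token = token.strip()
        if not token:
            continue
        m = _GENO_COUNT.match(token)
        if not m:
            raise FormatError(f"cannot parse genotype cell token {token!r}")
        counts[m.group("geno")] = int(m.group("n") or 1)
    return counts


def _load_table1() -> GeneCatalog:
    genes = []
    with _fixture_path("table1_prg_snps.tsv").open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            chrom, start, end = _synthetic_interval(row["gene"])
            genes.append(
                GeneRecord(
                    gene_id=row["gene"],
                    chromosome=chrom,
                    start=start,
                    end=end,
                    function=row["protein_function"],
                    effect=row["predicted_effect"],
                    snp_counts=_parse_genotype_counts(row["mutated_genotypes"]),
                )
            )
    return GeneCatalog(genes)


def _load_marker_table(filename: str) -> MarkerCallTable:
    calls: dict[tuple[str, str], str] = {}
    with _fixture_path(filename).open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            geno = row["genotype"]
            for gene in MARKER_GENES:
                calls[(geno, gene)] = row[gene]
    return MarkerCallTable(calls)


def _load_table3() -> pd.DataFrame:
    df = pd.read_csv(_fixture_path("table3_heterosis.tsv"), sep="\t", index_col="hybrid")
    return df


def load_fixture(name: str):
    """Load a packaged fixture table.

    ``table1``: resistance-gene SNP catalog (GeneCatalog, 57 genes, with
    per-genotype SNP multiplicities and synthetic placeholder intervals).
    ``table2``: parental marker calls (MarkerCallTable, 15 genotypes x 6 genes).
    ``table3``: hybrid x trait mid-parent heterosis percentages (DataFrame).
    ``f1_markers``: F1 hybrid marker calls (MarkerCallTable).
    ``crosses``: synthetic reconstruction of the 13-cross design
    (list of CrossDesign; only two crosses are documented, the rest are
    assigned for Mendelian consistency with the marker tables).
    """
    loaders = {
        "table1": _load_table1,
        "table2": lambda: _load_marker_table("table2_parent_markers.tsv"),
        "table3": _load_table3,
        "f1_markers": lambda: _load_marker_table("f1_markers.tsv"),
        "crosses": lambda: read_cross_table(_fixture_path("synthetic_crosses.tsv")),
    }
    if name not in loaders:
        raise ValueError(f"unknown fixture {name!r}; expected one of {sorted(loaders)}")
    return loaders[name]()
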