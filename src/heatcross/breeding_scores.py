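"""Selection index, mid-parent heterosis and the three-score hybrid index.

The selection index (SI) sums arbitrary-scale bin scores over fruit set
(FS), fruit number (TNF) and yield per plant (YP, pre-scaled by 10). The
hybrid index combines a heat-tolerance score HTS = TNF/10 + 10*YP, a fruit
quality score QS = TA/0.3 + TSSC/5.5 + TSSC/(TA*12.5) built from the
literature optima for acidity, sugars and their ratio, and a resistance
score RGS = resistant loci / assayed marker loci. Elite hybrids are those
exceeding the mean of each score over the evaluated hybrid set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import CrossDesign, TraitRecord

log = logging.getLogger(__name__)


class MissingTraitError(ValueError):
    """A score was requested for a record lacking a required trait."""


class UndefinedHeterosisError(ZeroDivisionError):
    """Mid-parent value is zero, so relative heterosis is undefined."""


@dataclass
class ScoreCard:
    """Per-hybrid scores plus the elite classification."""

    genotype_id: str
    HTS: float | None = None
    QS: float | None = None
    RGS: float | None = None
    SI: dict[str, int] = field(default_factory=dict)  # per environment
    Het: dict[str, float] = field(default_factory=dict)  # per trait, percent
    elite: bool | None = None

    def complete(self) -> bool:
        return None not in (self.HTS, self.QS, self.RGS)


@dataclass(frozen=True)
class Thresholds:
    """Arithmetic means of each score over the evaluated hybrid set."""

    mean_HTS: float
    mean_QS: float
    mean_RGS: float


@dataclass(frozen=True)
class TitrationMeasurement:
    """A single NaOH titration of fruit supernatant.

    ``NaOH_normality`` in N, ``vol_NaOH`` in mL, ``m_sample`` in g. The
    citric-acid conversion factor 0.070 is fixed by the assay.
    """

    NaOH_normality: float
    vol_NaOH: float
    m_sample: float
    CA_factor: float = 0.070

    def __post_init__(self) -> None:
        if self.m_sample <= 0:
            raise ValueError(f"sample mass must be positive, got {self.m_sample}")
        if self.vol_NaOH < 0:
            raise ValueError(f"negative titrant volume {self.vol_NaOH}")


def titratable_acidity(m: TitrationMeasurement) -> float:
    """TA in g citric acid / 100 g: G1 = [NaOH]*vol/m * 1000/10, TA = 0.070*G1."""
    g1 = m.NaOH_normality * m.vol_NaOH / m.m_sample * 1000.0 / 10.0
    return g1 * m.CA_factor


def si_trait_score(value: float) -> int:
    """Arbitrary-scale bin score: [0,10] -> 0, (10,20] -> 1, (20,30] -> 2, ...

    The score is the smallest k with value <= 10*(k+1); bins are half-open
    above so that the printed integer mapping (11-20 -> 1, 21-30 -> 2) is
    preserved for non-integer values.
    """
    if value < 0:
        raise ValueError(f"trait value must be non-negative, got {value}")
    return max(0, math.ceil(value / 10.0) - 1)


def selection_index(
    FS: float | None,
    TNF: float | None,
    YP: float | None,
    yp_mode: str = "scaled",
) -> int:
    """SI = score(FS) + score(TNF) + score(10*YP).

    ``yp_mode`` "scaled" (default) bins the 10x yield like the other
    traits; "raw" adds 10*YP directly without binning (the alternative
    reading of the scale description).
    """
    if FS is None or TNF is None or YP is None:
        missing = [n for n, v in (("FS", FS), ("TNF", TNF), ("YP", YP)) if v is None]
        raise MissingTraitError(f"cannot score with missing trait(s): {', '.join(missing)}")
    if yp_mode == "scaled":
        yp_term = si_trait_score(10.0 * YP)
    elif yp_mode == "raw":
        yp_term = 10.0 * YP
    else:
        raise ValueError(f"unknown yp_mode {yp_mode!r}")
    return int(si_trait_score(FS) + si_trait_score(TNF) + yp_term)


def selection_index_table(
    records: Iterable[TraitRecord], yp_mode: str = "scaled"
) -> pd.DataFrame:
    """Per-genotype, per-environment SI on trait means across replicates.

    Environments are never pooled; a genotype grown in two areas gets two
    independent index values. Genotypes missing any of FS/TNF/YP in an
    environment are reported with a null SI rather than a silent zero.
    """
    df = trait_means(records, by_environment=True)
    rows = []
    for (geno, env), traits in df.iterrows():
        try:
            si = selection_index(traits.get("FS"), traits.get("TNF"), traits.get("YP"), yp_mode)
        except (MissingTraitError, TypeError):
            si = None
            log.warning("genotype %s in %s lacks FS/TNF/YP; SI not computed", geno, env)
        rows.append({"genotype": geno, "environment": env, "SI": si})
    return pd.DataFrame(rows)


def heterosis_pct(f1_value: float, p1_value: float, p2_value: float) -> float:
    """Mid-parent heterosis as a percentage: 100 * (F1 - PM) / PM."""
    pm = (p1_value + p2_value) / 2.0
    if pm == 0:
        raise UndefinedHeterosisError("mid-parent value is zero")
    return 100.0 * (f1_value - pm) / pm


def trait_means(
    records: Iterable[TraitRecord], by_environment: bool = False
) -> pd.DataFrame:
    """Genotype(-environment) trait means across replicates."""
    rows = []
    for r in records:
        rows.append(
            {
                "genotype": r.genotype_id,
                "environment": r.environment,
                **{t: r.trait(t) for t in ("FS", "TNF", "FW", "YP", "TSSC", "TA")},
            }
        )
    df = pd.DataFrame(rows)
    keys = ["genotype", "environment"] if by_environment else ["genotype"]
    return df.groupby(keys).mean(numeric_only=True)


def heterosis_table(
    records: Iterable[TraitRecord],
    crosses: Sequence[CrossDesign],
    traits: Sequence[str] = ("TNF", "FW", "YP", "TSSC", "TA"),
    include_ratio: bool = True,
) -> pd.DataFrame:
    """Het% per hybrid x trait, computed on genotype trait means.

    Hybrids whose mid-parent mean is zero for a trait get NaN (flagged in
    the log), never 0. When ``include_ratio`` the derived TSSC/TA ratio is
    scored as its own trait.
    """
    means = trait_means(records)
    if include_ratio:
        means = means.assign(**{"TSSC/TA": means["TSSC"] / means["TA"]})
        traits = [*traits, "TSSC/TA"]
    out: dict[str, dict[str, float]] = {}
    for cross in crosses:
        for who in (cross.hybrid_id, cross.parent1_id, cross.parent2_id):
            if who not in means.index:
                raise KeyError(f"{who} has no trait records")
        row: dict[str, float] = {}
        for trait in traits:
            f1 = means.loc[cross.hybrid_id, trait]
            p1 = means.loc[cross.parent1_id, trait]
            p2 = means.loc[cross.parent2_id, trait]
            try:
                row[trait] = heterosis_pct(f1, p1, p2)
            except UndefinedHeterosisError:
                log.warning("mid-parent zero for %s / %s", cross.hybrid_id, trait)
                row[trait] = float("nan")
        out[cross.hybrid_id] = row
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "hybrid"
    return df


def hts(TNF: float | None, YP: float | None) -> float:
    """Heat tolerance score: TNF/10 + 10*YP."""
    if TNF is None or YP is None:
        raise MissingTraitError("HTS needs TNF and YP")
    if TNF < 0 or YP < 0:
        raise ValueError("HTS inputs must be non-negative")
    return TNF / 10.0 + YP * 10.0


def qs(TSSC: float | None, TA: float | None) -> float:
    """Quality score: TA/0.3 + TSSC/5.5 + TSSC/(TA*12.5).

    The denominators are the literature optima: 0.3 g/100 g acidity,
    5.5 degrees Brix, and 12.5 for the sugar/acid ratio.
    """
    if TSSC is None or TA is None:
        raise MissingTraitError("QS needs TSSC and TA")
    if TA <= 0:
        raise ZeroDivisionError("QS undefined for TA <= 0")
    return TA / 0.3 + TSSC / 5.5 + TSSC / (TA * 12.5)


def rgs(
    calls: Mapping[str, str],
    assayed_genes: Sequence[str],
    counting: str = "locus",
    skip_null: bool = False,
    exclude_fixed: Sequence[str] = (),
) -> float:
    """Resistance-gene score: resistant fraction over the assayed loci.

    ``counting`` "locus" scores each assayed gene 1 when the call carries
    at least one resistant allele (RR or RS), bounding RGS in [0, 1];
    "dosage" counts resistant alleles (RR = 2, RS = 1) over assayed loci,
    so a fully homozygous-resistant genotype scores 2. Genes in
    ``exclude_fixed`` (e.g. loci monomorphic across the panel) are removed
    from the denominator. NULL calls raise unless ``skip_null``, which
    drops them from both counts.
    """
    if counting not in ("locus", "dosage"):
        raise ValueError(f"unknown counting mode {counting!r}")
    genes = [g for g in assayed_genes if g not in exclude_fixed]
    if not genes:
        raise ValueError("no assayed genes left after exclusions")
    numerator = 0.0
    denominator = 0
    for gene in genes:
        call = calls.get(gene, "NULL")
        if call == "NULL":
            if skip_null:
                continue
            raise ValueError(f"NULL call for assayed gene {gene}")
        denominator += 1
        if counting == "locus":
            numerator += 1.0 if call in ("RR", "RS") else 0.0
        else:
            numerator += {"RR": 2.0, "RS": 1.0, "SS": 0.0}[call]
    if denominator == 0:
        raise ValueError("all assayed calls were NULL")
    return numerator / denominator


ELITE_RULES = ("all", "two_of_three", "hts_qs")


def hybrid_index(
    scorecards: Sequence[ScoreCard], rule: str = "all"
) -> tuple[Thresholds, list[ScoreCard]]:
    """Mean thresholds over the hybrid set plus per-hybrid elite flags.

    The default rule flags hybrids strictly above the mean on all three
    scores; "two_of_three" and "hts_qs" relax it. Hybrids missing a score
    are excluded from the means (with a warning) and never flagged elite.
    """
    if rule not in ELITE_RULES:
        raise ValueError(f"unknown elite rule {rule!r}")
    usable = [sc for sc in scorecards if sc.complete()]
    for sc in scorecards:
        if not sc.complete():
            log.warning("hybrid %s missing a score; excluded from thresholds", sc.genotype_id)
    if len(usable) < 2:
        raise ValueError("need at least two fully scored hybrids")
    thresholds = Thresholds(
        mean_HTS=sum(sc.HTS for sc in usable) / len(usable),
        mean_QS=sum(sc.QS for sc in usable) / len(usable),
        mean_RGS=sum(sc.RGS for sc in usable) / len(usable),
    )
    for sc in scorecards:
        if not sc.complete():
            sc.elite = False
            continue
        above = (
            sc.HTS > thresholds.mean_HTS,
            sc.QS > thresholds.mean_QS,
            sc.RGS > thresholds.mean_RGS,
        )
        if rule == "all":
            sc.elite = all(above)
        elif rule == "two_of_three":
            sc.elite = sum(above) >= 2
        else:  # hts_qs
            sc.elite = above[0] and above[1]
    return thresholds, list(scorecards)


def score_table(scorecards: Sequence[ScoreCard]) -> pd.DataFrame:
    """Three-axis score table suitable for scatter plotting."""
    return pd.DataFrame(
        [
            {
                "hybrid": sc.genotype_id,
                "HTS": sc.HTS,
                "QS": sc.QS,
                "RGS": sc.RGS,
                "elite": sc.elite,
            }
            for sc in scorecards
        ]
    )
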