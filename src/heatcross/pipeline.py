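"""End-to-end demo pipeline wiring every stage on packaged + synthetic data.

Stages communicate only through files under the output directory; every
output carries a provenance header (tool version, config hash, seed) so a
rerun with the same seed and config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, breeding_scores, io_formats, popgen, synthetic
from .io_formats import MARKER_GENES, load_fixture

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "si_yp_mode",
    "rgs_counting",
    "elite_rule",
    "max_missing",
    "min_mean_dp",
    "n_loci",
    "noise_sd",
    "make_plot",
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results/pipeline"
    si_yp_mode: str = "scaled"
    rgs_counting: str = "locus"
    elite_rule: str = "all"
    max_missing: float = 0.5
    min_mean_dp: float = 5.0
    n_loci: int = 2000
    noise_sd: float = 0.0
    make_plot: bool = False

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = set(mapping) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k not in ("out_dir", "make_plot")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return f"# heatcross {__version__} config={config.digest()} seed={config.seed}\n"


def _write(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_full_pipeline(config: RunConfig) -> dict:
    """filter -> IBS -> PRG scan / impact tally -> SI & heterosis ->
    marker calls -> RGS -> hybrid index; returns a result summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2, sort_keys=True))
    summary: dict = {"seed": config.seed, "config": config.digest()}

    # --- genotype stage: synthetic matrix, filter, IBS ---------------------
    n_samples = 6
    targets = [0.95, 0.90, 0.85, 0.70, 0.54]
    geno = synthetic.gen_genotype_matrix(
        synthetic.GenoSimSpec(
            n_samples=n_samples,
            n_loci=config.n_loci,
            target_similarity=targets,
            missing_rate=0.05,
            seed=config.seed,
        )
    )
    log.info("genotype stage: %d samples x %d loci", geno.n_samples, geno.n_loci)
    filtered = popgen.filter_variants(geno, config.max_missing, config.min_mean_dp)
    log.info("filter: %d of %d sites survive", filtered.n_loci, geno.n_loci)
    ibs = popgen.ibs_matrix(filtered)
    _write(ibs.to_frame(), out / "ibs_matrix.tsv", config, index=True)
    summary["sites_after_filter"] = filtered.n_loci
    summary["min_ibs"] = float(pd.DataFrame(ibs.values).min().min())

    # --- resistance-gene stage: catalog scan and impact tally --------------
    catalog = load_fixture("table1")
    scan = popgen.prg_scan_fixture(catalog)
    _write(scan, out / "prg_scan.tsv", config)
    n_high_genes = sum(1 for g in catalog.genes if g.high_impact)
    effects = {
        "HIGH": n_high_genes,  # each flagged gene carries one stop variant
        "MODERATE": catalog.total_snps() - n_high_genes,
    }
    tally = popgen.impact_tally(effects)
    summary["catalog_genes"] = catalog.n_genes
    summary["catalog_snps"] = catalog.total_snps()
    summary["catalog_high_impact_pct"] = tally.formatted["HIGH"]

    # --- phenotype stage: synthetic traits, SI, heterosis ------------------
    spec = synthetic.demo_trait_spec(seed=config.seed, noise_sd=config.noise_sd)
    records, truth = synthetic.gen_trait_table(spec)
    io_formats.write_trait_table(records, out / "trait_table.tsv")
    si = breeding_scores.selection_index_table(records, yp_mode=config.si_yp_mode)
    _write(si, out / "selection_index.tsv", config)
    het = breeding_scores.heterosis_table(records, spec.crosses)
    _write(het.reset_index(), out / "heterosis.tsv", config)
    summary["n_hybrids"] = len(spec.crosses)

    # --- marker stage: fixture assays and genotype calls -------------------
    f1_calls = load_fixture("f1_markers")
    means = breeding_scores.trait_means(records)

    cards = []
    for cross in spec.crosses:
        hybrid = cross.hybrid_id
        row = means.loc[hybrid]
        card = breeding_scores.ScoreCard(
            genotype_id=hybrid,
            HTS=breeding_scores.hts(row["TNF"], row["YP"]),
            QS=breeding_scores.qs(row["TSSC"], row["TA"]),
            RGS=breeding_scores.rgs(
                f1_calls.row(hybrid), MARKER_GENES, counting=config.rgs_counting
            ),
        )
        cards.append(card)
    thresholds, cards = breeding_scores.hybrid_index(cards, rule=config.elite_rule)
    table = breeding_scores.score_table(cards)
    _write(table, out / "hybrid_index.tsv", config)
    elites = sorted(table.loc[table["elite"] == True, "hybrid"])  # noqa: E712
    summary["thresholds"] = asdict(thresholds)
    summary["elite_hybrids"] = elites

    if config.make_plot:
        _scatter_plot(table, thresholds, out / "hybrid_index_scatter.png")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary


def _scatter_plot(table: pd.DataFrame, thresholds, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    sizes = 40 + 300 * table["RGS"].astype(float)
    colors = ["tab:red" if e else "tab:gray" for e in table["elite"]]
    ax.scatter(table["HTS"], table["QS"], s=sizes, c=colors, alpha=0.8)
    for _, row in table.iterrows():
        ax.annotate(row["hybrid"], (row["HTS"], row["QS"]), fontsize=7)
    ax.axvline(thresholds.mean_HTS, ls="--", c="k", lw=0.8)
    ax.axhline(thresholds.mean_QS, ls="--", c="k", lw=0.8)
    ax.set_xlabel("heat tolerance score (HTS)")
    ax.set_ylabel("quality score (QS)")
    ax.set_title("hybrid index (marker size = RGS)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
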