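#!/usr/bin/env python
"""Hybrid index and elite classification of the 13 hybrids.

Runs the full demo pipeline (synthetic traits planted with the packaged
heterosis values, the packaged F1 marker calls for RGS), computes
HTS/QS/RGS per hybrid with mean thresholds, and reports the elite set
under the strict all-three rule. Writes results/05_hybrid_index.tsv.
"""

import shutil
from pathlib import Path

from heatcross.pipeline import RunConfig, run_full_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = RunConfig(seed=SEED, out_dir=str(OUT / "pipeline"), elite_rule="all")
    summary = run_full_pipeline(config)
    shutil.copy(OUT / "pipeline" / "hybrid_index.tsv", OUT / "05_hybrid_index.tsv")
    th = summary["thresholds"]
    print(f"mean thresholds: HTS {th['mean_HTS']:.1f}, QS {th['mean_QS']:.2f}, "
          f"RGS {th['mean_RGS']:.2f}")
    elites = summary["elite_hybrids"]
    print(f"elite hybrids (above all three means): {', '.join(elites) or 'none at this seed'}")
    print("note: with the printed marker calls only one hybrid (17H56) can "
          "exceed the RGS mean under locus counting, so the strict rule "
          "selects at most one hybrid whatever the trait draws")


if __name__ == "__main__":
    main()
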