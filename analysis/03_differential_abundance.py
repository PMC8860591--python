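"""Differential abundance: unique tsRNA features and chromatin-RNA genes.

Small-RNA features are tested Dicer-knockdown vs control (the |log2FC|>1
rule later defines Dicer dependence). Chromatin-RNA genes are tested per
knockdown at the study thresholds (padj < 0.005 for shDicer and shAgo2,
< 0.05 for shDrosha) and intersected into the working target universe:
up in Dicer AND Ago2, not up in Drosha.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, bundle, config

from tsrna_nrs.integrate import intersect_upregulated
from tsrna_nrs.pipeline import stage_chr_de, stage_srna_de


def main() -> None:
    cfg = config()
    b = bundle(cfg)
    collapsed = pd.read_csv(RESULTS / "collapsed.tsv", sep="\t")
    srna_de = stage_srna_de(collapsed, cfg)
    srna_de.to_csv(RESULTS / "srna_de.tsv", sep="\t")
    n_dep = int((srna_de["log2FoldChange"].abs() > 1).sum())
    print(f"sRNA features tested: {len(srna_de)}; |log2FC|>1: {n_dep}")

    tables, up = stage_chr_de(b.genes.counts, b.genes.condition_of, cfg)
    for cond, tab in tables.items():
        tab.to_csv(RESULTS / f"chr_de_{cond}.tsv", sep="\t")
        print(f"chrRNA up in {cond}: {len(up[cond])} genes")
    venn, universe = intersect_upregulated(
        up["shDicer"], up["shAgo2"], up["shDrosha"], exclude_drosha=cfg.exclude_drosha
    )
    pd.Series(venn).to_csv(RESULTS / "venn_counts.tsv", sep="\t", header=["genes"])
    pd.Series(sorted(universe)).to_csv(RESULTS / "universe.tsv", sep="\t", index=False, header=["gene_id"])
    print(f"Venn regions (Dicer/Ago2/Drosha): {venn}")
    print(f"working universe (Dicer & Ago2, minus Drosha): {len(universe)} genes")


if __name__ == "__main__":
    main()
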