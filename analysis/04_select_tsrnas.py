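"""PAR-CLIP tsRNA selection: equalize, threshold, cluster, Dicer-restrict.

Reads are equalized to their genomic (tRNA) sequence, reverting T->C
crosslink conversions; sequences 18-22 nt passing the occurrence rules
(>=25 in every Ago set; 323/41/19 in a Dicer replicate) are grouped into
near-identical clusters, and cluster representatives with |log2FC| > 1 in
small-RNA-seq form the Dicer-dependent working set.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, bundle, config

from tsrna_nrs.pipeline import stage_parclip


def main() -> None:
    cfg = config()
    b = bundle(cfg)
    srna_de = pd.read_csv(RESULTS / "srna_de.tsv", sep="\t", index_col=0)
    collapsed = pd.read_csv(RESULTS / "collapsed.tsv", sep="\t")
    candidates, reps, dependent = stage_parclip(
        b.parclip_sets, b.ref, srna_de, cfg, collapsed=collapsed
    )
    pd.DataFrame(
        [
            {
                "sequence": c.sequence,
                "cluster_id": c.cluster_id,
                "ago_bound": c.ago_bound,
                "dicer_bound": c.dicer_bound,
                "dicer_dependent": c.dicer_dependent,
                "log2fc": c.log2fc,
            }
            for c in candidates
        ]
    ).to_csv(RESULTS / "parclip_candidates.tsv", sep="\t", index=False)
    print(f"filtered PAR-CLIP sequences: {len(candidates)} "
          f"in {len(reps)} near-identical clusters")
    print(f"Dicer-dependent representatives (|log2FC| > 1): {len(dependent)}")
    seqs = {c.sequence for c in dependent}
    truth_dep = {s for s, l in b.truth.effects.items() if abs(l) > 1}
    print(f"  of which match a planted Dicer-dependent fragment: "
          f"{len(seqs & truth_dep)}")


if __name__ == "__main__":
    main()
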