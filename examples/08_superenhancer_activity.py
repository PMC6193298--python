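"""Super-enhancer association and per-cell group activity scoring.

Associates toy super-enhancers with their nearest gene within +/-100 kb,
then scores the planted SE co-regulation blocks of a simulated dual
transcriptome: Group_Exp is the per-cell median feature z-score, Group_Act
its min-max scaling to [0, 1].
"""

import numpy as np
import pandas as pd

from holoseq.io import GeneModel, GenomicInterval
from holoseq.superenhancer import associate_se, score_groups
from holoseq.synthetic import simulate_dual_transcriptome


def _gene(gid, start, end, strand="+"):
    iv = GenomicInterval("chr1", start, end, strand)
    return GeneModel(gid, iv, (iv,))


genes = [_gene("Sox2_like", 150_000, 155_000), _gene("far_gene", 500_000, 505_000)]
ses = [("SE_a", GenomicInterval("chr1", 100_000, 110_000, "."))]
(se,) = associate_se(ses, genes, [])
print(f"{se.se_id} -> nearest gene within 100 kb: {se.associated_gene}")

mrna, mirna, truth = simulate_dual_transcriptome(seed=10)
log = np.log2(pd.concat([mrna.values, mirna.values]) + 1.0)
groups = {se_id: members for se_id, members in truth.se_blocks[:2]}
for ga in score_groups(log, groups, log_transform=False):
    by_pop = {
        pop: ga.group_act[[c for c, p in truth.subpop_labels.items() if p == pop]].mean()
        for pop in ("I", "II", "III")
    }
    print(f"{ga.group_id}: mean activity I={by_pop['I']:.2f} "
          f"II={by_pop['II']:.2f} III={by_pop['III']:.2f}")
print("activity is 0 in the least-active cell and 1 in the most-active one; "
      "the planted blocks separate the three cell subpopulations.")
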