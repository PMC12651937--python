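"""Composite evidence scoring: Final Evidence Score, hotspots, single-cell score.

final_score = overall_importance + 0.5 * (cohorts with nominal DE p < 0.05);
single-cell contexts are ranked by significant-gene counts and genes by a
weighted sum of normalized DE breadth, peak |logFC| and peak significance.
"""

import pandas as pd

from sleepmr.evidence import (
    hotspot_counts,
    rank_evidence,
    select_candidates,
    sign_discordance,
    single_cell_evidence_score,
)
from sleepmr.simulate import simulate_celltype_de_table

importance = pd.Series({"GENE_A": 0.60, "GENE_B": 0.25, "GENE_C": 0.15})
de_tables = {
    "cohort1": pd.DataFrame({"pval": [0.01, 0.20, 0.90]},
                            index=["GENE_A", "GENE_B", "GENE_C"]),
    "cohort2": pd.DataFrame({"pval": [0.03, 0.04, 0.70]},
                            index=["GENE_A", "GENE_B", "GENE_C"]),
}
print(rank_evidence(importance, de_tables).to_string(index=False))

contexts = [("excitatory_neuron", "cortex", "male"),
            ("astrocyte", "cortex", "male"),
            ("microglia", "hippocampus", "female")]
table = simulate_celltype_de_table(
    40, contexts,
    {contexts[0]: [(0, 0.5), (1, 0.6), (2, 0.4)], contexts[1]: [(0, -0.5)]},
    seed=0,
)
print("\nhotspot ranking:")
print(hotspot_counts(table).to_string(index=False))
sc = single_cell_evidence_score(table)
print(f"\nsingle-cell candidates (score > 1.0): {select_candidates(sc)}")
disc = sign_discordance(table, cell_classes={"excitatory_neuron": "neuron",
                                             "astrocyte": "glia"})
print(f"neuron-glia sign-discordant genes: {disc['gene'].unique().tolist()}")
# GENE_A collects two significant cohorts (score 0.6 + 1.0); the neuron
# context with three planted genes tops the hotspot ranking; gene G0000 is
# up in neurons and down in astrocytes, so it is flagged discordant.
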