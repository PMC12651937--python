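"""SMR and HEIDI at two simulated loci: shared causal variant vs linkage.

The SMR test asks whether gene expression and a trait share a causal
variant; HEIDI distinguishes that pleiotropy model from two distinct
variants in LD.
"""

import pandas as pd

from sleepmr.simulate import QTLSimConfig, simulate_qtl_locus
from sleepmr.smr import heidi_test, smr_test

for model in ("pleiotropy", "linkage"):
    cfg = QTLSimConfig(model=model, b_qtl=0.5, b_gwas=0.1, r2_linkage=0.25,
                       seed=11)
    qtl, gwas, ld = simulate_qtl_locus(cfg)
    top_idx = (qtl["BETA"] / qtl["SE"]).abs().idxmax()
    top = qtl.loc[top_idx, "SNP"]
    q, g = qtl.set_index("SNP").loc[top], gwas.set_index("SNP").loc[top]
    res = smr_test(g["BETA"], g["SE"], q["BETA"], q["SE"])
    locus = pd.DataFrame({
        "SNP": qtl["SNP"],
        "b_gwas": gwas["BETA"].to_numpy(), "se_gwas": gwas["SE"].to_numpy(),
        "b_qtl": qtl["BETA"].to_numpy(), "se_qtl": qtl["SE"].to_numpy(),
    })
    heidi = heidi_test(locus, ld, top, seed=11)
    print(f"{model:11s} b_SMR={res.b_smr:+.3f}  p_SMR={res.p_smr:.2e}  "
          f"p_HEIDI={heidi.p_heidi:.3f} ({heidi.n_snp_used} SNPs)")
# Under pleiotropy b_SMR approximates b_gwas/b_qtl = 0.2 and HEIDI is quiet
# (p >= 0.05, retained); under linkage HEIDI rejects (p < 0.05, filtered).
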