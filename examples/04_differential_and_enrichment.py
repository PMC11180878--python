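"""Differential abundance, module-trait correlation and set enrichment.

Three-group differential abundance uses one-way ANOVA with Tukey-Kramer
pairwise p values (Welch/Bonferroni fallback below 1e-8.5); module
eigenproteins are correlated with neuropathological traits; cell-type lists,
biofluid differential-abundance sets and gene-level GWAS p values are tested
per module (one-tailed Fisher exact with BH FDR, and a permutation
normalized enrichment score for the GWAS risk).
"""

import pandas as pd

import vasc_protnet as vp

res = vp.run_pipeline({"simulate": True, "seed": 7,
                       "preservation": {"n_perm": 100}},
                      out_dir="example_run")

de = res["de"]
n_up = int(((de["p_AD_vs_control"] < 0.05) & (de["fc_AD_vs_control"] > 0)).sum())
n_dn = int(((de["p_AD_vs_control"] < 0.05) & (de["fc_AD_vs_control"] < 0)).sum())
print(f"AD vs control: {n_up} proteins up, {n_dn} down (p < 0.05)")

mt = res["me_trait"]
caa = mt[mt.trait == "caa"].sort_values("r", ascending=False)
print("strongest ME-CAA correlation:",
      caa.iloc[0]["module"], round(caa.iloc[0]["r"], 2))

ct = res["celltype_fet"]
print("cell types over-represented in modules (BH q < 0.05):")
print(ct[ct.q < 0.05][["module", "set", "overlap", "odds_ratio", "q"]]
      .round(3).to_string(index=False))

risk = res["risk"]
print("GWAS risk enrichment (permutation NES):")
print(risk[["module", "NES", "p", "q", "fdr_5pct"]].round(3).to_string(index=False))

print(f"classifier candidates (vascular-specific, all pairwise p < 0.05): "
      f"{len(res['classifiers'])}")
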