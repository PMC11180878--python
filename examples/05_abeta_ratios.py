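"""Amyloid-beta 40/42 quantitation from C-terminal tryptic peptides.

Abeta40 (DAEF...GGVV) and Abeta42 (...GGVVIA) share every tryptic peptide
except the C-terminal one, so GAIIGLMVGGVV and GAIIGLMVGGVVIA quantify the
two species separately.  Reporter intensities are loading-normalized (scaled
to the maximum summed channel), TAMPOR-corrected per fraction, and ratioed:
vascular amyloid is Abeta40-rich, parenchymal (bulk) amyloid Abeta42-rich,
and the vascular Abeta40/Abeta42 ratio rises in AD (cerebral amyloid
angiopathy).
"""

import vasc_protnet as vp

print("Abeta40:", vp.ABETA40, f"({len(vp.ABETA40)} residues)")
print("tryptic peptides:", vp.tryptic_digest(vp.ABETA40))

study = vp.generate_study(seed=7)
vasc, bulk = vp.generate_peptide_table(study.truth, study.meta, seed=11)
ratios = vp.abeta_ratios(vp.scale_reporter_intensities(vasc),
                         vp.scale_reporter_intensities(bulk), meta=study.meta)

print(f"median Abeta40 vascular/bulk: "
      f"{ratios['abeta40_vascular_over_bulk'].median():.2f}  (>4: vascular-enriched)")
print(f"median Abeta42 vascular/bulk: "
      f"{ratios['abeta42_vascular_over_bulk'].median():.2f}  (<0.25: bulk-enriched)")

dx = study.meta.set_index("sample_id").loc[ratios.index, "diagnosis"]
r = ratios["abeta40_over_42_vascular"]
fold = r[dx == "AD"].median() / r[dx == "control"].median()
print(f"vascular Abeta40/Abeta42, AD over control: {fold:.2f}  "
      "(~2-fold elevation, consistent with CAA)")
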