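"""In-silico tryptic digestion, reporter-ion scaling, and Abeta ratio tables.

Amyloid-beta 1-40 and 1-42 differ only at the C-terminus, so their unique
C-terminal tryptic peptides (GAIIGLMVGGVV and GAIIGLMVGGVVIA) quantify each
species separately.  Abeta40 predominates in vascular amyloid and Abeta42 in
parenchymal plaques; the vascular/bulk and Abeta40/Abeta42 reporter-ion
ratios capture that partitioning per sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import AbundanceMatrix
from .tampor import TamporParams, TamporResult, tampor

logger = logging.getLogger("vasc_protnet")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: amyloid-beta cleavage products (1-40 and 1-42)
ABETA40 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"
ABETA42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"
ABETA40_CTERM = "GAIIGLMVGGVV"
ABETA42_CTERM = "GAIIGLMVGGVVIA"


def tryptic_digest(sequence: str, allow_missed: int = 0) -> list[str]:
    """Strict-trypsin digestion: cleave after K or R except before P.

    With ``allow_missed = m`` the result also contains every concatenation of
    up to ``m + 1`` consecutive fully-tryptic peptides (missed cleavages),
    ordered by start position then length.  Invalid residues are a hard error
    naming the position (1-based).
    """
    for i, aa in enumerate(sequence):
        if aa not in AA_ALPHABET:
            raise ValueError(f"invalid residue {aa!r} at position {i + 1}")
    base: list[str] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 >= len(sequence) or sequence[i + 1] != "P"):
            base.append(sequence[start:i + 1])
            start = i + 1
    if start < len(sequence):
        base.append(sequence[start:])
    if allow_missed == 0:
        return base
    out = []
    for i in range(len(base)):
        for m in range(allow_missed + 1):
            if i + m < len(base):
                out.append("".join(base[i:i + m + 1]))
    return out


def scale_reporter_intensities(peptides: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-channel summed reporter intensity (sample-loading scaling).

    Each intensity is multiplied by the ratio of the maximum channel-summed
    intensity to its own channel's summed intensity, so every column sum
    equals the maximum afterwards.  Channels summing to zero are left
    unscaled with a warning.
    """
    if peptides.empty:
        raise ValueError("empty peptide table")
    totals = peptides.sum(axis=0, skipna=True)
    t_max = totals.max()
    factors = pd.Series(np.where(totals > 0, t_max / totals, 1.0), index=totals.index)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("scale_reporter_intensities: %d zero-sum channels left unscaled", n_zero)
    return peptides.mul(factors, axis=1)


def abeta_ratios(
    vascular: pd.DataFrame,
    bulk: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    batch_corrected: bool = True,
) -> pd.DataFrame:
    """Per-sample vascular/bulk and Abeta40/Abeta42 reporter-ion ratios.

    Inputs are (scaled) linear peptide x channel tables containing the two
    Abeta C-terminal tryptic peptides.  With ``batch_corrected`` the tables
    are first TAMPOR-corrected (GIS-only denominators) and ratios computed on
    the abundance-scale output; without it, raw intensities are used.
    Returns one row per paired sample with linear ratios and their log2.
    """
    for name, table in (("vascular", vascular), ("bulk", bulk)):
        for pep in (ABETA40_CTERM, ABETA42_CTERM):
            if pep not in table.index:
                raise ValueError(f"peptide {pep!r} missing from the {name} table")

    def corrected(table: pd.DataFrame) -> pd.DataFrame:
        if not batch_corrected:
            if meta is not None:
                bio = meta.loc[~meta["is_gis"], "sample_id"]
                return table[[s for s in table.columns if s in set(bio)]]
            return table
        if meta is None:
            raise ValueError("batch correction requires sample metadata")
        res: TamporResult = tampor(
            AbundanceMatrix(table, scale="linear"), meta, TamporParams(use_all_non_gis=False)
        )
        return np.exp2(res.corrected_abundance().data)

    v = corrected(vascular)
    b = corrected(bulk)
    paired = [s for s in v.columns if s in set(b.columns)]
    # The two fractions are separate TMT experiments, so their intensities
    # carry an arbitrary relative scale (e.g. from normalizing each to its
    # own maximum-summed channel).  Anchor the cross-fraction scale on the
    # typical peptide: divide by the median, over non-Abeta shared peptides,
    # of each peptide's median vascular/bulk ratio.
    others = [p for p in v.index if p in set(b.index) and p not in (ABETA40_CTERM, ABETA42_CTERM)]
    if others:
        med_ratios = [(v.loc[p, paired] / b.loc[p, paired]).median() for p in others]
        fraction_scale = float(np.nanmedian(med_ratios))
    else:
        fraction_scale = 1.0
    rows = []
    for s in paired:
        v40, v42 = v.at[ABETA40_CTERM, s], v.at[ABETA42_CTERM, s]
        b40, b42 = b.at[ABETA40_CTERM, s], b.at[ABETA42_CTERM, s]
        rows.append({
            "sample_id": s,
            "abeta40_vascular_over_bulk": v40 / b40 / fraction_scale,
            "abeta42_vascular_over_bulk": v42 / b42 / fraction_scale,
            "abeta40_over_42_vascular": v40 / v42,
            "abeta40_over_42_bulk": b40 / b42,
        })
    out = pd.DataFrame(rows).set_index("sample_id")
    for col in list(out.columns):
        out[f"log2_{col}"] = np.log2(out[col])
    return out
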