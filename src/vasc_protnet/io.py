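"""Tabular I/O, missingness filtering, and shared containers.

All stages of the pipeline exchange plain TSV files (UTF-8, tab-separated) for
abundance matrices, sample metadata, trait tables and results, and GMT files
for marker / gene sets.  Abundance matrices are protein x sample with the
protein identifier in the first column and sample identifiers in the header
row.  Missing values are represented internally as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("vasc_protnet")

#: tokens accepted as missing in input TSVs (case-insensitive; empty string too)
MISSING_TOKENS = ("", "na", "nan")


@dataclass
class AbundanceMatrix:
    """Protein x sample abundance table.

    Parameters
    ----------
    data
        DataFrame indexed by unique protein ids with unique sample-id columns.
        Missing values are NaN.
    scale
        Either ``"linear"`` (raw reporter-ion intensities, >= 0 where present)
        or ``"log2"`` (log2-transformed or log2-ratio values).
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.data = self.data.astype(float)
        if self.scale == "linear":
            vals = self.data.to_numpy()
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError("linear-scale abundances must be >= 0 where present")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.scale)


def read_abundance_table(
    path: str | Path,
    missing_token: str | tuple[str, ...] = MISSING_TOKENS,
    scale: str = "linear",
) -> AbundanceMatrix:
    """Read a protein x sample TSV into an :class:`AbundanceMatrix`.

    The first column holds protein ids, the header row sample ids.  Cells equal
    to one of ``missing_token`` (case-insensitive) become NaN; any other
    non-numeric cell is a hard error reporting its (protein, sample) coordinates.
    """
    tokens = (missing_token,) if isinstance(missing_token, str) else tuple(missing_token)
    tokens = tuple(t.lower() for t in tokens)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate protein id {dup!r}")
    data = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cell = raw[col].str.strip()
        is_missing = cell.str.lower().isin(tokens)
        numeric = pd.to_numeric(cell.where(~is_missing), errors="coerce")
        bad = numeric.isna() & ~is_missing
        if bad.any():
            prot = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-numeric cell at protein {prot!r}, sample {col!r}: "
                f"{cell[bad].iloc[0]!r}"
            )
        data[col] = numeric
    return AbundanceMatrix(data, scale=scale)


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="protein", na_rep="NA")


def zeros_to_missing(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Convert exact zeros in a linear-scale matrix to missing.

    TMT reporter intensities of exactly 0 denote non-quantified, and log2(0) is
    undefined downstream.
    """
    if matrix.scale != "linear":
        raise ValueError("zeros_to_missing applies to linear-scale matrices")
    data = matrix.data.mask(matrix.data == 0.0)
    n = int((matrix.data == 0.0).sum().sum())
    if n:
        logger.info("zeros_to_missing: converted %d zero cells to missing", n)
    return AbundanceMatrix(data, scale="linear")


def filter_missingness(
    matrix: AbundanceMatrix, max_missing_fraction: float = 0.5
) -> AbundanceMatrix:
    """Retain proteins whose missing fraction is strictly below the threshold.

    A protein missing in exactly half of the samples is removed (fraction 0.50
    is not < 0.50).  The sample set is unchanged.  Idempotent.
    """
    if matrix.data.empty:
        raise ValueError("filter_missingness: empty matrix")
    frac = matrix.data.isna().mean(axis=1)
    keep = frac < max_missing_fraction
    if not keep.any():
        raise ValueError("filter_missingness removed every protein")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_missingness: removed %d / %d proteins", n_drop, len(keep))
    return AbundanceMatrix(matrix.data.loc[keep], scale=matrix.scale)


# ---------------------------------------------------------------------------
# sample metadata and traits
# ---------------------------------------------------------------------------

META_COLUMNS = ("sample_id", "batch", "channel", "is_gis", "diagnosis", "age", "sex", "pmi")


def validate_sample_meta(meta: pd.DataFrame, matrix: AbundanceMatrix | None = None) -> pd.DataFrame:
    """Check the per-sample design table.

    Every abundance sample must have exactly one row, and every batch must
    contain at least one GIS (global internal standard) channel.
    """
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"sample metadata missing columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    meta = meta.copy()
    meta["is_gis"] = meta["is_gis"].astype(bool)
    if matrix is not None:
        missing = set(matrix.sample_ids) - set(meta["sample_id"])
        if missing:
            raise ValueError(f"samples absent from metadata: {sorted(missing)[:5]}")
    gis_per_batch = meta.groupby("batch", observed=True)["is_gis"].sum()
    if (gis_per_batch == 0).any():
        bad = gis_per_batch.index[gis_per_batch == 0][0]
        raise ValueError(f"batch {bad!r} has no GIS sample")
    return meta


def read_sample_meta(path: str | Path, matrix: AbundanceMatrix | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    return validate_sample_meta(meta, matrix)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


TRAIT_ORDINALS = {"caa": (0, 3), "apoe4_dose": (0, 2)}


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    if "sample_id" not in traits.columns:
        raise ValueError("trait table needs a sample_id column")
    for col, (lo, hi) in TRAIT_ORDINALS.items():
        if col in traits.columns:
            vals = traits[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise ValueError(f"trait {col!r} outside [{lo}, {hi}]")
    for col in ("is_ad", "is_psp", "is_control"):
        if col in traits.columns:
            vals = traits[col].dropna()
            if not vals.isin((0, 1)).all():
                raise ValueError(f"indicator {col!r} must be 0/1")
    return traits


def read_traits(path: str | Path) -> pd.DataFrame:
    return validate_traits(pd.read_csv(path, sep="\t"))


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# marker / gene sets (GMT dialect)
# ---------------------------------------------------------------------------


def read_marker_sets(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: ``name <tab> description <tab> member1 <tab> member2 ...``.

    Duplicate members within a line are collapsed (and logged); a line with
    fewer than three fields or an empty file is a hard error.
    """
    sets: dict[str, list[str]] = {}
    lines = Path(path).read_text().splitlines()
    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not content:
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in content:
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
        name = fields[0]
        members: list[str] = []
        seen = set()
        for sym in fields[2:]:
            if not sym:
                continue
            if sym in seen:
                logger.warning("GMT %s line %d: duplicate symbol %r collapsed", name, lineno, sym)
                continue
            seen.add(sym)
            members.append(sym)
        sets[name] = members
    return sets


def write_marker_sets(sets: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> dict:
    """Load a nested key/value YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def log_effective_params(stage: str, params: Mapping) -> None:
    logger.info("stage %s parameters: %s", stage, dict(params))
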