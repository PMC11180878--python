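"""TAMPOR: two-way median-polish batch correction of GIS-ratio abundances.

Multi-batch isobaric-tag (TMT) experiments carry per-protein, per-batch scale
distortions.  Each batch includes one or more pooled global internal standard
(GIS) channels; dividing every channel by the per-batch GIS median cancels any
per-batch multiplicative factor exactly, and an iterative two-way median
polish of the log2 ratios then centers every protein and every sample.

An *iteration* here is the full cycle denominator -> ratio -> two-way median
polish (the polish itself runs to tolerance inside the cycle).  With GIS-only
denominators the denominators never change, so the second cycle reproduces the
first exactly and the algorithm converges at ``n_iterations = 2`` — the
confirming pass is counted.  With ``use_all_non_gis`` the denominators are
re-derived from the current corrected matrix each cycle and more iterations
may be needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceMatrix

logger = logging.getLogger("vasc_protnet")


@dataclass
class TamporParams:
    use_all_non_gis: bool = False
    tol: float = 1e-8  # log2 scale
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 2:
            raise ValueError("max_iter must be >= 2")


@dataclass
class TamporResult:
    """Batch-corrected output.

    ``corrected`` is on log2 scale with GIS columns removed and every
    protein-wise and sample-wise median equal to 0 within ``tol`` (over
    observed entries).  ``row_scale`` holds the per-protein log2 central
    tendency (log2 of the protein-wise median of the raw linear matrix);
    adding it back to ``corrected`` restores an interpretable relative
    abundance scale (see :meth:`corrected_abundance`).
    """

    corrected: AbundanceMatrix
    n_iterations: int
    max_final_offset: float
    offset_trace: list = field(default_factory=list)
    row_scale: pd.Series | None = None

    def corrected_abundance(self) -> AbundanceMatrix:
        """Centered log2 values plus the per-protein scale restoration."""
        data = self.corrected.data.add(self.row_scale, axis=0)
        return AbundanceMatrix(data, scale="log2")


def _median_polish(x: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, list[float]]:
    """Alternate protein-wise and sample-wise median subtraction to tolerance.

    Operates on observed entries only; missing entries stay missing.
    """
    x = x.copy()
    offsets: list[float] = []
    for _ in range(max_iter):
        with np.errstate(all="ignore"):
            row_med = np.nanmedian(x, axis=1)
        row_med = np.where(np.isfinite(row_med), row_med, 0.0)
        x -= row_med[:, None]
        with np.errstate(all="ignore"):
            col_med = np.nanmedian(x, axis=0)
        col_med = np.where(np.isfinite(col_med), col_med, 0.0)
        x -= col_med[None, :]
        offset = max(np.abs(row_med).max(initial=0.0), np.abs(col_med).max(initial=0.0))
        offsets.append(float(offset))
        if offset < tol:
            break
    return x, offsets


def tampor(
    matrix: AbundanceMatrix,
    meta: pd.DataFrame,
    params: TamporParams | None = None,
) -> TamporResult:
    """Batch-correct a linear-scale abundance matrix.

    Per protein and batch the denominator is the median over that batch's GIS
    channels (or over all non-GIS channels when ``use_all_non_gis``); the
    log2 sample/denominator ratios are then two-way median polished.  The
    centered output is exactly invariant to multiplying any batch of the
    linear input by a positive scalar (bit-exact for power-of-two factors).
    """
    params = params or TamporParams()
    if matrix.scale != "linear":
        raise ValueError("tampor expects a linear-scale matrix")
    meta = meta.set_index("sample_id").loc[matrix.sample_ids]
    batches = meta["batch"].to_numpy()
    is_gis = meta["is_gis"].to_numpy().astype(bool)
    uniq_batches = pd.unique(batches)
    if not params.use_all_non_gis:
        for b in uniq_batches:
            if not (is_gis & (batches == b)).any():
                raise ValueError(f"batch {b!r} has no GIS sample (use_all_non_gis=False)")

    a = matrix.values.astype(float)
    a = np.where(a == 0.0, np.nan, a)  # zeros denote non-quantified
    with np.errstate(all="ignore"):
        row_scale = np.log2(np.nanmedian(a, axis=1))

    bio_cols = ~is_gis

    def denominators(current_linear: np.ndarray) -> np.ndarray:
        """Per-protein linear denominator for each column's batch.

        Computed in linear space so that a power-of-two per-batch rescaling of
        the input scales the denominator exactly and cancels bit-for-bit in
        the ratio.
        """
        d = np.empty_like(current_linear)
        for b in uniq_batches:
            cols = (batches == b) & (is_gis if not params.use_all_non_gis else ~is_gis)
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", "All-NaN slice")
                med = np.nanmedian(current_linear[:, cols], axis=1)
            n_empty = int(np.isnan(med).sum())
            if n_empty:
                logger.warning(
                    "tampor: %d proteins with all-missing denominator in batch %s; "
                    "values set missing for that batch", n_empty, b)
            d[:, batches == b] = med[:, None]
        return d

    prev = None
    trace: list[dict] = []
    n_iter = 0
    max_delta = np.inf
    current = a
    for n_iter in range(1, params.max_iter + 1):
        d = denominators(current)
        with np.errstate(all="ignore"):
            ratio = np.log2(a / d)
        polished, offsets = _median_polish(ratio[:, bio_cols], params.tol, params.max_iter)
        trace.append({"iteration": n_iter, "polish_offsets": offsets})
        if prev is not None:
            with np.errstate(all="ignore"):
                delta = np.abs(polished - prev)
            max_delta = float(np.nanmax(delta)) if np.isfinite(delta).any() else 0.0
            trace[-1]["max_change"] = max_delta
            if max_delta < params.tol:
                break
        prev = polished
        if params.use_all_non_gis:
            # re-derive denominators from the partially corrected matrix
            full = np.full_like(a, np.nan)
            full[:, bio_cols] = np.exp2(polished)
            full[:, ~bio_cols] = (a / d)[:, ~bio_cols]
            current = full
    if max_delta >= params.tol:
        logger.warning("tampor did not converge within %d iterations", params.max_iter)

    corrected = AbundanceMatrix(
        pd.DataFrame(prev, index=matrix.protein_ids,
                     columns=np.array(matrix.sample_ids)[bio_cols]),
        scale="log2",
    )
    logger.info("tampor converged in %d iterations (max final change %.3g)", n_iter, max_delta)
    return TamporResult(
        corrected=corrected,
        n_iterations=n_iter,
        max_final_offset=max_delta,
        offset_trace=trace,
        row_scale=pd.Series(row_scale, index=matrix.protein_ids, name="log2_row_scale"),
    )
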