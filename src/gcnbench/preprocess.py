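"""Replicate aggregation and noisy/low-signal gene filtering.

Expression compendia assembled from many experiments carry genes whose
replicate measurements scatter widely (hybridization noise) and genes
whose signal sits near the detection floor; both bias co-expression
estimates and are removed before reconstruction. Replicates within a
condition are collapsed to their median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["aggregate_replicates", "filter_genes"]


def _check_design(matrix: pd.DataFrame, design: pd.DataFrame) -> None:
    missing = [s for s in matrix.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing[:5]}")
    if design.index.has_duplicates:
        dups = design.index[design.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in design: {dups[:5]}")


def _condition_groups(matrix: pd.DataFrame, design: pd.DataFrame) -> dict[str, list[str]]:
    """Condition → sample columns, ordered by first appearance in the matrix."""
    groups: dict[str, list[str]] = {}
    for s in matrix.columns:
        groups.setdefault(str(design.loc[s, "condition_id"]), []).append(s)
    return groups


def aggregate_replicates(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate samples to one median column per condition.

    Missing values within a replicate group are excluded from that
    median; a gene with all replicates missing in some condition is an
    error. Gene order is preserved; aggregation is idempotent on
    already-aggregated matrices.
    """
    _check_design(matrix, design)
    groups = _condition_groups(matrix, design)
    out = {}
    for cond, samples in groups.items():
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
        block = matrix[samples]
        if block.isna().all(axis=1).any():
            bad = block.index[block.isna().all(axis=1)][0]
            raise ValueError(f"gene {bad!r} has no non-missing replicate in condition {cond!r}")
        out[cond] = block.median(axis=1, skipna=True)
    return pd.DataFrame(out, index=matrix.index)


def filter_genes(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    cv_max: float = 0.5,
    low_quantile: float = 0.05,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Remove noisy and low-signal genes; applied before aggregation.

    A gene is *noisy* when the median (across conditions) of its
    replicate coefficient of variation exceeds ``cv_max``, and *low
    signal* when its median expression falls below the global
    ``low_quantile`` quantile of the matrix. Returns the surviving matrix
    and a list of ``(gene, reason)`` removals.
    """
    if cv_max <= 0:
        raise ConfigurationError("cv_max must be positive")
    if not 0.0 <= low_quantile < 1.0:
        raise ConfigurationError("low_quantile must lie in [0, 1)")
    _check_design(matrix, design)
    groups = _condition_groups(matrix, design)

    cvs = np.full((matrix.shape[0], len(groups)), np.nan)
    for j, samples in enumerate(groups.values()):
        block = matrix[samples].to_numpy(dtype=float)
        if block.shape[1] < 2:
            cvs[:, j] = 0.0  # single replicate: no dispersion to judge
            continue
        mean = np.nanmean(block, axis=1)
        sd = np.nanstd(block, axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cvs[:, j] = np.where(mean != 0, sd / np.abs(mean), np.inf)
    median_cv = np.nanmedian(cvs, axis=1)

    floor = np.nanquantile(matrix.to_numpy(dtype=float), low_quantile) if low_quantile > 0 else -np.inf
    median_signal = matrix.median(axis=1).to_numpy()

    removed: list[tuple[str, str]] = []
    keep: list[str] = []
    for i, gene in enumerate(matrix.index):
        reasons = []
        if np.isfinite(cv_max) and median_cv[i] > cv_max:
            reasons.append("noisy expression")
        if median_signal[i] < floor:
            reasons.append("low signal")
        if reasons:
            removed.append((str(gene), " + ".join(reasons)))
        else:
            keep.append(gene)
    return matrix.loc[keep], removed
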