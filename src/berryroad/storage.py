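"""Storage Index (SI) computation.

The SI of a quality trait is the log2 ratio of its value after cold storage
to its value at harvest: positive values mean the trait was enhanced during
storage, negative values mean it was lost. SI is computed on cultivar means
(fruit or replicate averages) and then summarized across the cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Values below this floor are replaced by it before taking the ratio, so
#: trace-level measurements reported as 0 still yield a finite index.
DEFAULT_FLOOR = 1e-3


def storage_index(q_harvest: float, q_post: float, floor: float = DEFAULT_FLOOR) -> float:
    """log2(q_post / q_harvest) with flooring of trace-level values.

    Returns NaN (a missing SI) when either input is still non-positive
    after flooring, e.g. for genuinely negative readings.
    """
    qh = max(float(q_harvest), floor) if q_harvest > 0 else (floor if q_harvest == 0 else np.nan)
    qp = max(float(q_post), floor) if q_post > 0 else (floor if q_post == 0 else np.nan)
    if not (np.isfinite(qh) and np.isfinite(qp)) or qh <= 0 or qp <= 0:
        logger.warning("storage_index: non-positive input (%r, %r) -> missing", q_harvest, q_post)
        return float("nan")
    return float(np.log2(qp / qh))


def si_matrix(
    harvest: pd.DataFrame, post: pd.DataFrame, floor: float = DEFAULT_FLOOR
) -> pd.DataFrame:
    """Cultivar x trait SI matrix from two cultivar x trait mean matrices.

    Rows are aligned on the intersection of cultivars, columns on the
    intersection of traits. Cells where either timepoint is missing or
    non-positive after flooring come out as NaN.
    """
    cultivars = harvest.index.intersection(post.index)
    traits = harvest.columns.intersection(post.columns)
    dropped = (len(harvest.index.symmetric_difference(post.index)),
               len(harvest.columns.symmetric_difference(post.columns)))
    if any(dropped):
        logger.warning("si_matrix: %d cultivars / %d traits present at one timepoint only", *dropped)
    qh = harvest.loc[cultivars, traits].astype(float).clip(lower=floor)
    qp = post.loc[cultivars, traits].astype(float).clip(lower=floor)
    qh = qh.where(harvest.loc[cultivars, traits] >= 0)
    qp = qp.where(post.loc[cultivars, traits] >= 0)
    si = np.log2(qp / qh)
    return si


def si_summary(si: pd.DataFrame) -> pd.DataFrame:
    """Per-trait (min, max, mean, n_missing) over cultivars.

    Missing entries are excluded; an all-missing trait is dropped with a
    warning.
    """
    if si.shape[0] < 1:
        raise ValueError("si_summary needs at least one cultivar")
    rows = {}
    for trait in si.columns:
        col = si[trait].astype(float)
        n_missing = int(col.isna().sum())
        valid = col.dropna()
        if valid.empty:
            logger.warning("si_summary: trait %r has no non-missing SI; dropped", trait)
            continue
        rows[trait] = {
            "min": float(valid.min()),
            "max": float(valid.max()),
            "mean": float(valid.mean()),
            "n_missing": n_missing,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[["min", "max", "mean", "n_missing"]]
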