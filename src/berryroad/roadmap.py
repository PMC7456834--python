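"""Quantile-binned parental-selection roadmap.

Each quality trait, at harvest and after storage separately, is cut at
its cohort 25/50/75th percentiles and every cultivar is assigned a bin —
low, middle-low, middle-high or high — giving breeders a sortable table
from which parents with the desired trait combination can be picked
without modelling trait weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

BIN_LABELS = ("low", "middle-low", "middle-high", "high")

#: Curated trait subset for the compact roadmap: the three most
#: informative texture parameters plus six marker volatiles (methanol,
#: acetaldehyde, ethanol, hexenal isomers, ethyl isobutanoate, monoterpenes).
DEFAULT_TRAITS = (
    "gradient", "max_force", "max_force_strain",
    33.033, 45.031, 47.043, 99.08, 117.092, 137.134,
)


def quantile_bins(values: pd.Series) -> tuple[pd.Series, np.ndarray]:
    """Assign quartile bins to a vector of cultivar trait values.

    Edges are the 25/50/75th percentiles (linear interpolation); a value
    exactly on an edge falls into the lower bin; missing values are
    labelled ``missing``. A constant vector degenerates to a single bin
    (``middle-low``) with a warning.
    """
    v = pd.Series(values).astype(float)
    valid = v.dropna()
    if len(valid) < 4:
        raise InputError(f"quantile_bins needs >= 4 non-missing values, got {len(valid)}")
    edges = np.percentile(valid.values, [25, 50, 75])
    labels = pd.Series("missing", index=v.index, dtype=object)
    if edges[0] == edges[2]:
        logger.warning("quantile_bins: degenerate (constant) trait; single bin")
        labels[valid.index] = BIN_LABELS[1]
        return labels, edges
    # side='left': a value equal to an edge stays in the lower bin
    idx = np.searchsorted(edges, valid.values, side="left")
    labels[valid.index] = [BIN_LABELS[i] for i in idx]
    return labels, edges


@dataclass
class RoadmapTable:
    """Long-form cultivar x trait x timepoint bin assignments."""

    table: pd.DataFrame                      # cultivar, trait, timepoint, bin
    edges: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot_table(index="cultivar", columns=["trait", "timepoint"],
                                      values="bin", aggfunc="first")


def _match_trait(requested, columns) -> object:
    """Resolve a requested trait against matrix columns (floats within 0.005)."""
    if requested in columns:
        return requested
    try:
        mz = float(requested)
    except (TypeError, ValueError):
        return None
    floats = [c for c in columns if isinstance(c, (int, float, np.floating))]
    if floats:
        best = min(floats, key=lambda c: abs(float(c) - mz))
        if abs(float(best) - mz) <= 0.005:
            return best
    return None


def build_roadmap(
    harvest: pd.DataFrame, post: pd.DataFrame,
    traits: tuple | list | None = DEFAULT_TRAITS,
) -> RoadmapTable:
    """Quantile roadmap over two cultivar x trait matrices.

    Bins are computed independently per trait and per timepoint. By
    default the table is restricted to the curated subset
    (:data:`DEFAULT_TRAITS`, intersected with the available columns);
    pass an empty subset (or None) for the full-trait table. Unknown
    requested traits raise an error listing the known ones.
    """
    cultivars = harvest.index.intersection(post.index)
    if len(cultivars) == 0:
        raise InputError("harvest and post matrices share no cultivars")
    known = list(harvest.columns.intersection(post.columns))
    if traits is None or len(traits) == 0:
        use = known
    else:
        use = []
        for t in traits:
            m = _match_trait(t, known)
            if m is None:
                if tuple(traits) == DEFAULT_TRAITS:
                    continue  # curated defaults: silently skip absent traits
                raise InputError(f"unknown trait {t!r}; known traits: {known}")
            use.append(m)
        if not use:
            raise InputError(f"no requested trait found; known traits: {known}")
    rows = []
    edges: dict[tuple[str, str], np.ndarray] = {}
    for label, matrix in (("harvest", harvest), ("postharvest", post)):
        for trait in use:
            labels, e = quantile_bins(matrix.loc[cultivars, trait])
            edges[(str(trait), label)] = e
            for c in cultivars:
                rows.append({"cultivar": c, "trait": str(trait),
                             "timepoint": label, "bin": labels[c]})
    return RoadmapTable(table=pd.DataFrame(rows), edges=edges)
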