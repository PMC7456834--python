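"""Volatile (PTR-ToF-MS) peak-table reduction and annotation.

Direct-injection proton-transfer-reaction mass spectrometry yields one
headspace concentration per protonated m/z peak and no chromatographic
separation, so the raw sample x m/z table mixes real volatiles with
instrument noise and isotopologue shadows of monoisotopic peaks. Two
filters reduce it:

1. **Noise filter** — a peak is kept only if its concentration in fruit
   samples is significantly higher than in blank (no-fruit) headspace
   measurements. A one-sided Welch test on log concentrations is used.
2. **Correlation filter** — peaks correlated above a threshold (default
   r > 0.99) are mostly isotopes of the same ion; each group of
   near-perfectly correlated peaks is collapsed to one representative,
   the lightest member (a monoisotopic parent is lighter than its
   isotopologues).

Retained peaks can be annotated with tentative identities from a packaged
m/z library of blueberry headspace ions (GC-MS-backed assignments).
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .errors import InputError

logger = logging.getLogger(__name__)

META_COLUMNS = ("sample", "cultivar", "timepoint", "replicate", "is_blank")
CONC_FLOOR = 1e-3  # µg/kg; trace-level reporting floor


@dataclass
class PeakTable:
    """Samples x m/z concentration matrix with sample metadata.

    ``meta`` carries one row per sample (columns ``sample``, ``cultivar``,
    ``timepoint``, ``replicate``, ``is_blank``); ``conc`` shares the row
    index and has one float m/z per column, concentrations in µg/kg.
    """

    meta: pd.DataFrame
    conc: pd.DataFrame

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        self.conc = self.conc.reset_index(drop=True)
        self.conc.columns = [float(c) for c in self.conc.columns]

    @property
    def mz(self) -> list[float]:
        return list(self.conc.columns)

    def validate(self) -> None:
        if len(self.meta) != len(self.conc):
            raise InputError("metadata and concentration row counts differ")
        if len(set(self.mz)) != len(self.mz):
            raise InputError("duplicate m/z columns")
        if (self.conc.values < 0).any():
            raise InputError("negative concentrations")
        nb = self.meta[~self.meta["is_blank"].astype(bool)]
        if nb[["cultivar", "timepoint"]].isna().any().any():
            raise InputError("non-blank samples must carry cultivar and timepoint")

    @property
    def n_blanks(self) -> int:
        return int(self.meta["is_blank"].astype(bool).sum())

    def subset_peaks(self, mz: list[float]) -> "PeakTable":
        return PeakTable(self.meta.copy(), self.conc[list(mz)].copy())

    def drop_blanks(self) -> "PeakTable":
        keep = ~self.meta["is_blank"].astype(bool)
        return PeakTable(self.meta[keep], self.conc[keep.values])


@dataclass
class PeakFilterReport:
    """Bookkeeping of which peaks survived which filter.

    ``retained``, ``removed_noise`` and ``removed_correlated`` always
    partition the input m/z set.
    """

    retained: list[float] = field(default_factory=list)
    removed_noise: dict[float, dict] = field(default_factory=dict)  # mz -> {stat, p}
    removed_correlated: dict[float, dict] = field(default_factory=dict)  # mz -> {partner, r}
    test_name: str = "welch-one-sided-log"

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "retained": self.retained,
            "removed_noise": {str(k): v for k, v in self.removed_noise.items()},
            "removed_correlated": {str(k): v for k, v in self.removed_correlated.items()},
        }


def noise_filter(table: PeakTable, alpha: float = 0.05) -> tuple[list[float], dict[float, dict]]:
    """Split peaks into (kept, removed) by blank comparison.

    For each m/z a one-sided Welch two-sample t test of
    mean(log fruit conc) > mean(log blank conc) is computed; peaks with
    p >= ``alpha`` are indistinguishable from blank headspace and removed.
    No multiplicity correction is applied by default.
    """
    table.validate()
    is_blank = table.meta["is_blank"].astype(bool).values
    if is_blank.sum() < 2:
        raise InputError("noise_filter needs >= 2 blank samples; supply blank headspace runs")
    if (~is_blank).sum() < 2:
        raise InputError("noise_filter needs >= 2 non-blank samples")
    logc = np.log(np.maximum(table.conc.values, CONC_FLOOR))
    kept: list[float] = []
    removed: dict[float, dict] = {}
    for j, mz in enumerate(table.mz):
        x = logc[~is_blank, j]
        b = logc[is_blank, j]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # near-constant channels trip scipy's precision-loss warning
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = stats.ttest_ind(x, b, equal_var=False, alternative="greater")
        if not np.isfinite(p):  # zero variance in both groups: no evidence of signal
            stat, p = float("nan"), 1.0
        if p < alpha:
            kept.append(mz)
        else:
            removed[mz] = {"stat": float(stat), "p": float(p)}
    return kept, removed


def correlation_filter(
    table: PeakTable, threshold: float = 0.99
) -> tuple[list[float], dict[float, dict]]:
    """Collapse groups of near-perfectly correlated peaks.

    Pairwise product-moment correlation of log concentrations across all
    samples; pairs with r strictly greater than ``threshold`` are joined
    in a graph and each connected component keeps exactly one
    representative: the lowest m/z, ties broken by higher mean
    concentration. Constant peaks have undefined correlation and are
    treated as uncorrelated (logged).
    """
    table.validate()
    if len(table.meta) < 3:
        raise InputError("correlation_filter needs >= 3 samples")
    mzs = table.mz
    logc = np.log(np.maximum(table.conc.values, CONC_FLOOR))
    sd = logc.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning("correlation_filter: %d constant peaks treated as uncorrelated",
                       int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(logc, rowvar=False)
    corr[np.ix_(constant, np.arange(len(mzs)))] = 0.0
    corr[np.ix_(np.arange(len(mzs)), constant)] = 0.0
    np.fill_diagonal(corr, 1.0)
    adj = sparse.csr_matrix(np.abs(np.nan_to_num(corr)) > threshold)
    n_comp, labels = connected_components(adj, directed=False)
    kept: list[float] = []
    removed: dict[float, dict] = {}
    mean_conc = table.conc.values.mean(axis=0)
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        # representative: lightest m/z, ties -> higher mean concentration
        rep = min(idx, key=lambda i: (mzs[i], -mean_conc[i]))
        kept.append(mzs[rep])
        for i in idx:
            if i != rep:
                removed[mzs[i]] = {"partner": mzs[rep], "r": float(corr[i, rep])}
    return sorted(kept), removed


def reduce_peaks(
    table: PeakTable, alpha: float = 0.05, threshold: float = 0.99
) -> tuple[PeakTable, PeakFilterReport]:
    """Noise filter, then correlation filter on the survivors.

    Returns the reduced table (blanks dropped, retained m/z only) and a
    report whose three sets partition the input m/z exactly.
    """
    kept_noise, removed_noise = noise_filter(table, alpha=alpha)
    report = PeakFilterReport(removed_noise=removed_noise)
    if kept_noise:
        # correlation is assessed on fruit samples only: the fruit/blank
        # level split would otherwise make every strong peak pair look
        # near-perfectly correlated
        survivors = table.subset_peaks(kept_noise).drop_blanks()
        kept, removed_corr = correlation_filter(survivors, threshold=threshold)
        report.retained = kept
        report.removed_correlated = removed_corr
    reduced = table.subset_peaks(report.retained).drop_blanks()
    n_in = len(table.mz)
    n_out = len(report.retained) + len(report.removed_noise) + len(report.removed_correlated)
    assert n_in == n_out, "filter report does not partition the input"
    logger.info("reduce_peaks: %d -> %d peaks (%d blank-like, %d correlated)",
                n_in, len(report.retained), len(report.removed_noise),
                len(report.removed_correlated))
    return reduced, report


# ---------------------------------------------------------------------------
# Annotation


def _load_library() -> pd.DataFrame:
    path = importlib.resources.files("berryroad.data") / "voc_annotations.tsv"
    with importlib.resources.as_file(path) as p:
        lib = pd.read_csv(p, sep="\t", dtype={"mz": float, "formula": str, "identification": str})
    return lib.fillna("")


def annotate(mz_list: list[float], tolerance: float = 0.005) -> pd.DataFrame:
    """Tentative identities for a list of m/z values.

    Nearest library match within ``tolerance`` Th; peaks with no match (or
    a matching library ion that itself has no assignment) are labelled
    ``unknown``. Returns a frame with columns mz, library_mz, formula,
    identification.
    """
    lib = _load_library()
    rows = []
    for mz in mz_list:
        d = (lib["mz"] - mz).abs()
        i = int(d.idxmin()) if len(lib) else -1
        if i >= 0 and d[i] <= tolerance:
            rec = lib.loc[i]
            rows.append({
                "mz": mz,
                "library_mz": float(rec["mz"]),
                "formula": rec["formula"] or "",
                "identification": rec["identification"] or "unknown",
            })
        else:
            rows.append({"mz": mz, "library_mz": float("nan"),
                         "formula": "", "identification": "unknown"})
    return pd.DataFrame(rows)
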