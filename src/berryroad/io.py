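"""TSV dialects shared by the pipeline stages.

Curves travel as long-form tables (cultivar, timepoint, fruit,
strain_pct, force_N); peak tables as samples x m/z with leading metadata
columns; genotypes as one row per cultivar x locus with allele_1..allele_6.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mechanogram import MechCurve
from .voc import META_COLUMNS, PeakTable


def write_curves(curves: list[MechCurve], path) -> None:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "cultivar": c.cultivar, "timepoint": c.timepoint, "fruit": c.fruit,
            "strain_pct": c.strain, "force_N": c.force,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_curves(path) -> list[MechCurve]:
    df = pd.read_csv(path, sep="\t")
    curves = []
    for (cultivar, timepoint, fruit), grp in df.groupby(
            ["cultivar", "timepoint", "fruit"], sort=False):
        curves.append(MechCurve(
            strain=grp["strain_pct"].values, force=grp["force_N"].values,
            cultivar=str(cultivar), timepoint=str(timepoint), fruit=str(fruit)))
    return curves


def write_peak_table(table: PeakTable, path) -> None:
    conc = table.conc.copy()
    conc.columns = [f"{c:.4f}" for c in conc.columns]
    pd.concat([table.meta.reset_index(drop=True), conc.reset_index(drop=True)],
              axis=1).to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> PeakTable:
    df = pd.read_csv(path, sep="\t")
    meta = df[list(META_COLUMNS)].copy()
    conc = df.drop(columns=list(META_COLUMNS))
    conc.columns = [float(c) for c in conc.columns]
    return PeakTable(meta, conc)


def write_matrix(matrix: pd.DataFrame, path, index_label: str = "cultivar") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [float(c) if _is_float(c) else c for c in df.columns]
    return df


def _is_float(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, seed: int, files: list[str], extra: dict | None = None) -> None:
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "seed": seed,
        "version": __version__,
        "files": {f: file_sha256(out_dir / f) for f in files},
    }
    if extra:
        manifest.update(extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
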