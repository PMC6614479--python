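"""Tabular output with self-describing metadata headers.

All tables are plain TSV.  Each file starts with '#'-prefixed comment lines
carrying the package version, the configuration hash and the root seed, so
any table can be traced back to the run that produced it.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .landscape import FitnessTarget, ParameterSetCollection
from .params import MUTABLE_FIELDS, LacParams

__all__ = [
    "write_tsv",
    "read_tsv",
    "collection_to_frame",
    "write_collection",
    "read_collection",
]


def write_tsv(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    """Write a DataFrame as TSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def collection_to_frame(coll: ParameterSetCollection) -> pd.DataFrame:
    rows = []
    for i, (params, fit) in enumerate(coll):
        row = {"set_id": i}
        row.update({n: getattr(params, n) for n in MUTABLE_FIELDS})
        row.update(
            fitness=fit,
            fraction=coll.target.fraction,
            fmax_used=coll.fmax_used,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_collection(coll: ParameterSetCollection, path: str | Path,
                     metadata: Mapping[str, object] | None = None) -> None:
    meta = dict(metadata or {})
    meta.setdefault("fraction", coll.target.fraction)
    meta.setdefault("fmax_used", coll.fmax_used)
    meta.setdefault("shortfall", coll.shortfall)
    write_tsv(collection_to_frame(coll), path, meta)


def read_collection(path: str | Path, template: LacParams) -> ParameterSetCollection:
    """Rebuild a collection from a find-sets TSV (fixed params off template)."""
    df = read_tsv(path)
    required = set(MUTABLE_FIELDS) | {"fitness", "fraction", "fmax_used"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"collection table missing columns: {sorted(missing)}")
    sets = [
        template.with_mutables([row[n] for n in MUTABLE_FIELDS])
        for _, row in df.iterrows()
    ]
    target = FitnessTarget(fraction=float(df["fraction"].iloc[0]), count=len(sets))
    return ParameterSetCollection(
        sets=sets,
        fitness=[float(v) for v in df["fitness"]],
        target=target,
        fmax_used=float(df["fmax_used"].iloc[0]),
    )
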