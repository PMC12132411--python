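"""Readers and writers for count tables, compositions and fit outputs.

TSV is the canonical interchange format (CSV accepted by extension).
Count tables are samples-by-taxa with a header row of taxon ids and the
sample ids in the first column; QIIME-style taxa-by-samples files are
transposed on request.  All numeric output is written with 12+ significant
digits so compositions round-trip within 1e-10.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import BMDDError, Composition, CountTable, Hyperparams


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_count_table(path: str | Path, orientation: str = "samples-by-taxa") -> CountTable:
    """Load and validate a count table.

    ``orientation='taxa-by-samples'`` transposes the file first.  Rejects
    NA cells, non-integer or negative counts, duplicate ids and zero-depth
    samples with specific messages.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if orientation == "taxa-by-samples":
        df = df.T
    elif orientation != "samples-by-taxa":
        raise BMDDError(f"unknown orientation {orientation!r}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().values)[0]
        raise BMDDError(
            f"NA cell at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
        )
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise BMDDError("duplicate sample or taxon ids")
    values = df.values.astype(float)
    bad = values != np.floor(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise BMDDError(
            f"non-integer count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
        )
    neg = values < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise BMDDError(
            f"negative count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
        )
    return CountTable(
        counts=values.astype(np.int64),
        sample_ids=list(df.index.astype(str)),
        taxon_ids=list(df.columns.astype(str)),
    )


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=table.taxon_ids)
    df.to_csv(path, sep=_sep(path))


def read_composition(path: str | Path) -> Composition:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return Composition(
        values=df.values.astype(float),
        sample_ids=list(df.index.astype(str)),
        taxon_ids=list(df.columns.astype(str)),
    )


def write_composition(comp: Composition, path: str | Path) -> None:
    """Full-precision TSV so a read-back matches within 1e-10."""
    df = pd.DataFrame(comp.values, index=comp.sample_ids, columns=comp.taxon_ids)
    df.to_csv(path, sep=_sep(path), float_format="%.15g")


def write_hyperparams(
    hyper: Hyperparams, path: str | Path, taxon_ids: list[str] | None = None
) -> None:
    ids = taxon_ids or [f"taxon{j + 1}" for j in range(hyper.n_taxa)]
    df = pd.DataFrame(
        {"taxon": ids, "pi": hyper.pi, "alpha0": hyper.alpha0, "alpha1": hyper.alpha1}
    )
    df.to_csv(path, sep=_sep(path), index=False, float_format="%.15g")


def read_hyperparams(path: str | Path) -> Hyperparams:
    df = pd.read_csv(path, sep=_sep(path))
    return Hyperparams(
        pi=df["pi"].values, alpha0=df["alpha0"].values, alpha1=df["alpha1"].values
    )


def write_elbo_trace(trace: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(
        {"iteration": np.arange(1, len(trace) + 1), "elbo": np.asarray(trace)}
    )
    df.to_csv(path, sep=_sep(path), index=False, float_format="%.15g")
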