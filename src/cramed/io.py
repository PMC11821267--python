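"""Reading count/metadata tables and writing result tables.

The internal convention is samples x taxa; taxa-by-samples tables (the other
common shipping orientation of microbiome count tables) are transposed on
read.  Counts and metadata are aligned on their sample identifiers and must
describe the same sample set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Dataset", "read_dataset", "write_results", "read_results"]

_RESULT_COLUMNS = [
    "taxon", "p1", "p2", "pmax", "p_adj", "selected", "nie", "niep", "niea",
    "nie_lower", "nie_upper", "niep_lower", "niep_upper",
    "niea_lower", "niea_upper", "flags",
]


@dataclass
class Dataset:
    """An aligned counts + metadata pair ready for the pipeline."""

    counts: pd.DataFrame        # samples x taxa, integer
    metadata: pd.DataFrame      # samples x columns, aligned to counts
    treatment_col: str
    outcome_col: str
    covariate_cols: list

    @property
    def Y(self) -> np.ndarray:
        return self.metadata[self.outcome_col].to_numpy(dtype=float)

    @property
    def T(self) -> np.ndarray:
        return self.metadata["_treatment_encoded"].to_numpy(dtype=np.int64)

    @property
    def X(self) -> Optional[np.ndarray]:
        if not self.covariate_cols:
            return None
        return self.metadata[self.covariate_cols].to_numpy(dtype=float)

    @property
    def M(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=np.int64)


def _read_table(path):
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_dataset(counts_path, metadata_path, treatment_col, outcome_col,
                 covariate_cols=None, orientation="samples-by-taxa",
                 prevalence=0.10) -> Dataset:
    """Load and align a count table and a per-sample metadata table.

    Taxa observed in fewer than ``prevalence`` of samples are dropped
    (set ``prevalence=0`` to keep everything).  Metadata rows with missing
    treatment/outcome/covariate values are dropped with their samples.
    """
    counts = _read_table(counts_path)
    meta = _read_table(metadata_path)
    if orientation == "taxa-by-samples":
        counts = counts.T
    elif orientation != "samples-by-taxa":
        raise ValueError(f"unknown orientation {orientation!r}")
    counts.index = counts.index.astype(str)
    meta.index = meta.index.astype(str)
    if counts.index.has_duplicates or meta.index.has_duplicates:
        raise ValueError("duplicate sample identifiers")

    covariate_cols = list(covariate_cols or [])
    for col in [treatment_col, outcome_col, *covariate_cols]:
        if col not in meta.columns:
            raise ValueError(f"metadata is missing column {col!r}")

    needed = [treatment_col, outcome_col, *covariate_cols]
    n_missing = int(meta[needed].isna().any(axis=1).sum())
    if n_missing:
        meta = meta.dropna(subset=needed)

    only_counts = sorted(set(counts.index) - set(meta.index))
    only_meta = sorted(set(meta.index) - set(counts.index))
    if only_counts or (only_meta and not n_missing):
        raise ValueError(
            "sample identifiers do not align; counts-only="
            f"{only_counts[:5]}, metadata-only={only_meta[:5]}")
    counts = counts.loc[meta.index]

    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.any(vals < 0) \
            or not np.all(np.equal(np.mod(vals, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(np.int64)

    if prevalence > 0:
        keep = (counts > 0).mean(axis=0) >= prevalence
        counts = counts.loc[:, keep]

    levels = sorted(meta[treatment_col].unique())
    if len(levels) != 2:
        raise ValueError(
            f"treatment column must be binary, found levels {levels}")
    meta = meta.copy()
    meta["_treatment_encoded"] = (meta[treatment_col] == levels[1]).astype(np.int64)
    meta[outcome_col] = pd.to_numeric(meta[outcome_col])
    return Dataset(counts=counts, metadata=meta, treatment_col=treatment_col,
                   outcome_col=outcome_col, covariate_cols=covariate_cols)


def results_frame(result, taxon_names=None) -> pd.DataFrame:
    """Flatten a CramedResult into a tidy per-taxon table."""
    rows = []
    for r in result.results:
        name = taxon_names[r.taxon] if taxon_names is not None else r.taxon
        row = {
            "taxon": name, "p1": r.p1, "p2": r.p2, "pmax": r.pmax,
            "p_adj": r.p_adj, "selected": r.selected,
            "nie": r.nie, "niep": r.niep, "niea": r.niea,
            "nie_lower": np.nan, "nie_upper": np.nan,
            "niep_lower": np.nan, "niep_upper": np.nan,
            "niea_lower": np.nan, "niea_upper": np.nan,
            "flags": ";".join(r.flags),
        }
        if r.ci is not None:
            for key in ("nie", "niep", "niea"):
                row[f"{key}_lower"] = r.ci[key].lower
                row[f"{key}_upper"] = r.ci[key].upper
        rows.append(row)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(result, path, taxon_names=None) -> pd.DataFrame:
    """Write the per-taxon result table as TSV (full float precision)."""
    df = results_frame(result, taxon_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return df


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
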