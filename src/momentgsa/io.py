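"""Readers and writers for the delimited-text interfaces.

Expression: delimited text (tab or comma autodetected), first column gene
identifiers, header row of sample identifiers.  Phenotype: one value per
line, or two columns (sample id, value) reconciled against the expression
matrix by id.  Gene sets: standard GMT (name, description, members).
Results: TSV, one row per set, fixed column order, full-precision p-values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import GMTParseError, ShapeError
from .preprocess import ExpressionMatrix, GeneSet, Phenotype

__all__ = [
    "read_expression",
    "read_phenotype",
    "read_gmt",
    "read_weights",
    "write_results",
    "read_results",
]

RESULT_COLUMNS = [
    "set_name", "n_genes_matched", "statistic_kind", "stat_value",
    "p_left", "p_right", "p_central", "p_q", "p_adjusted",
    "epsilon_used", "degenerate",
]


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_expression(path) -> ExpressionMatrix:
    df = _read_table(path)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicated gene identifiers")
    return ExpressionMatrix(tuple(map(str, df.index)),
                            tuple(map(str, df.columns)),
                            df.to_numpy(dtype=float))


def read_phenotype(path, sample_ids=None) -> Phenotype:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.replace(",", "\t").split())
    widths = {len(r) for r in rows}
    if widths == {1}:
        values = np.array([float(r[0]) for r in rows])
        if sample_ids is not None and len(values) != len(sample_ids):
            raise ShapeError(f"{path}: {len(values)} phenotype values for "
                             f"{len(sample_ids)} samples")
    elif widths == {2}:
        mapping = {r[0]: float(r[1]) for r in rows}
        if sample_ids is None:
            values = np.array([float(r[1]) for r in rows])
        else:
            missing = [s for s in sample_ids if s not in mapping]
            if missing:
                raise ShapeError(f"{path}: no phenotype for samples {missing[:5]}")
            values = np.array([mapping[s] for s in sample_ids])
    else:
        raise ShapeError(f"{path}: phenotype must have one or two columns")
    return Phenotype(values)


def read_gmt(path) -> list:
    """Parse a GMT gene set collection (one set per tab-separated line)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}")
            name, _desc, *members = fields
            members = [m for m in (m.strip() for m in members) if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"{path}:{lineno}: set {name!r} has duplicated "
                              f"members; deduplicated", stacklevel=2)
            sets.append(GeneSet(name, tuple(deduped)))
    return sets


def read_weights(path) -> dict:
    """Two-column (gene, weight) file -> mapping."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     comment="#")
    if df.shape[1] != 2:
        raise ShapeError(f"{path}: weights file must have two columns")
    return {str(g): float(w) for g, w in zip(df.iloc[:, 0], df.iloc[:, 1])}


def write_results(results, path) -> None:
    """Write a results table (list of GeneSetResult or DataFrame) as TSV."""
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    if df.empty:
        raise ValueError("no results to write")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def results_frame(results) -> pd.DataFrame:
    """Fixed-column-order DataFrame from GeneSetResult records."""
    rows = []
    for r in results:
        rows.append({c: getattr(r, c) for c in RESULT_COLUMNS})
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
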