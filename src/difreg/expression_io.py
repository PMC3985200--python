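"""Reading, validation and probe collapse of two-condition expression matrices.

The central container is :class:`ExpressionMatrix`: a genes × samples table of
real-valued expression measurements together with a condition label (``"A"``
for the normal/control group, ``"B"`` for the disease group) for every sample.
Values are used on whatever scale they arrive on; no log transformation is
applied or assumed.

Missing values are not supported: any non-finite cell is a validation error.
Microarray series matrices are typically complete, and downstream correlation
and t statistics are only well defined on complete vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("A", "B")

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "read_condition_table",
    "read_probe_map",
    "collapse_probes",
    "write_expression_matrix",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with per-sample condition labels.

    Parameters
    ----------
    data:
        DataFrame indexed by gene (or probe) identifier, one column per
        sample. Must be finite and free of duplicate row/column labels.
    conditions:
        Series mapping each sample id in ``data.columns`` to ``"A"`` or
        ``"B"``.
    """

    data: pd.DataFrame
    conditions: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        missing = [s for s in self.data.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples missing a condition label: {missing[:5]}")
        self.conditions = self.conditions.reindex(self.data.columns)
        bad = sorted(set(self.conditions.unique()) - set(CONDITIONS))
        if bad:
            raise ValueError(f"condition labels must be one of {CONDITIONS}, got {bad}")
        if not np.issubdtype(self.data.values.dtype, np.number):
            self._raise_non_numeric()
        if not np.isfinite(self.data.values).all():
            r, c = np.argwhere(~np.isfinite(self.data.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    def _raise_non_numeric(self) -> None:
        coerced = self.data.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & self.data.notna()
        if bad.any().any():
            r, c = np.argwhere(bad.values)[0]
            raise ValueError(
                f"non-numeric value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}: {self.data.iat[r, c]!r}"
            )
        self.data = coerced.astype(float)
        if self.data.isna().any().any():
            r, c = np.argwhere(self.data.isna().values)[0]
            raise ValueError(
                f"missing value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def samples_in(self, condition: str) -> list[str]:
        """Sample ids carrying the given condition label, in column order."""
        return [s for s in self.data.columns if self.conditions[s] == condition]

    def values_in(self, condition: str, genes: Iterable[str] | None = None) -> np.ndarray:
        """Expression values (genes × samples) restricted to one condition."""
        cols = self.samples_in(condition)
        block = self.data[cols] if genes is None else self.data.loc[list(genes), cols]
        return block.to_numpy(dtype=float)

    def n_samples(self, condition: str) -> int:
        return len(self.samples_in(condition))

    def require_min_samples(self, k: int) -> None:
        for cond in CONDITIONS:
            n = self.n_samples(cond)
            if n < k:
                raise ValueError(
                    f"condition {cond} has {n} samples; at least {k} required"
                )


def read_condition_table(path: str | Path) -> pd.Series:
    """Read a two-column TSV of ``sample_id<TAB>condition`` (A or B)."""
    table = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "condition"],
                        dtype=str, comment="#")
    if table["sample_id"].duplicated().any():
        dupes = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in condition table: {dupes[:5]}")
    bad = sorted(set(table["condition"]) - set(CONDITIONS))
    if bad:
        raise ValueError(f"conditions must be in {CONDITIONS}, got {bad}")
    return pd.Series(table["condition"].values, index=table["sample_id"].values)


def read_expression_matrix(path: str | Path, condition_table: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix plus its condition table.

    The matrix has a header row of sample ids, first column header ``id``,
    and one row per probe or gene. Row and column order are preserved.
    """
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dupes = [s for s in header if s in seen or seen.add(s)]
    if dupes:
        raise ValueError(f"duplicate sample ids in {path}: {dupes[:5]}")
    data = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    data = data.astype(str)
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell in {path} at row {data.index[r]!r}, "
            f"column {data.columns[c]!r}: {data.iat[r, c]!r}"
        )
    conditions = read_condition_table(condition_table)
    return ExpressionMatrix(numeric.astype(float), conditions)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            float_format: str = "%.10g") -> None:
    matrix.data.to_csv(path, sep="\t", index_label="id", float_format=float_format)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``probe_id<TAB>gene_symbol``.

    Lines with an empty symbol are ignored (unmapped probes). Each probe may
    map to at most one symbol; a probe appearing twice with different symbols
    is an error.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            probe = parts[0]
            symbol = parts[1] if len(parts) > 1 else ""
            if not symbol:
                continue
            if probe in mapping and mapping[probe] != symbol:
                raise ValueError(
                    f"probe {probe!r} maps to both {mapping[probe]!r} and {symbol!r}"
                )
            mapping[probe] = symbol
    return mapping


def collapse_probes(matrix: ExpressionMatrix, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse a probe-keyed matrix to gene symbols by per-sample averaging.

    Each output gene row is the unweighted arithmetic mean, per sample, of all
    probe rows mapping to that symbol. Probes without a mapping are dropped.
    Output rows are ordered by first appearance of each symbol in the input.
    """
    mapped = [p for p in matrix.data.index if p in probe_map]
    if not mapped:
        raise ValueError("no probe in the matrix is present in the probe map")
    symbols = pd.Series([probe_map[p] for p in mapped], index=mapped)
    grouped = matrix.data.loc[mapped].groupby(symbols, sort=False).mean()
    return ExpressionMatrix(grouped, matrix.conditions)
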