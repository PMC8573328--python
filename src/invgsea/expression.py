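"""Expression matrices and TSV readers.

The pipeline consumes a gene x sample matrix of counts (or normalized
expression) plus a sample -> group map; upstream read alignment and
quantification are outside its scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input files; message names the file and line."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a sample->group assignment.

    Gene identifiers are canonicalized to upper case with surrounding
    whitespace stripped; duplicate gene rows are collapsed by summation at
    load time.  A contrast uses exactly two of the groups.
    """

    values: pd.DataFrame  # genes x samples, non-negative
    group_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("expression matrix is empty")
        idx = self.values.index.astype(str).str.strip().str.upper()
        self.values = self.values.set_axis(idx, axis=0)
        if idx.has_duplicates:
            self.values = self.values.groupby(level=0, sort=False).sum()
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.group_map]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")

    @property
    def genes(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        out = [s for s in self.samples if self.group_map[s] == group]
        if not out:
            raise ValueError(f"no samples in group {group!r}")
        return out

    def subset(self, groups: list[str]) -> "ExpressionMatrix":
        cols = [s for s in self.samples if self.group_map[s] in groups]
        return ExpressionMatrix(
            self.values[cols], {s: self.group_map[s] for s in cols}
        )

    def cpm(self) -> "ExpressionMatrix":
        """Counts-per-million library-size normalization (optional)."""
        lib = self.values.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("zero library size in at least one sample")
        return ExpressionMatrix(self.values / lib * 1e6, dict(self.group_map))


def read_expression(
    counts_path: str | Path,
    group_map_path: str | Path,
    allow_extra: bool = False,
) -> ExpressionMatrix:
    """Read a counts TSV (first column ``gene``) and a two-column group map.

    The sample sets of the two files must agree (with ``allow_extra`` the
    group map may also cover samples from other matrices, e.g. a second
    contrast); the matrix keeps the column order of the counts file.
    """
    counts_path, group_map_path = Path(counts_path), Path(group_map_path)
    try:
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{counts_path}: cannot parse counts TSV: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"{counts_path}: empty expression matrix")
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        for col in bad:
            nonnum = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(np.argmax(nonnum.to_numpy())) + 2  # header is line 1
            raise ParseError(
                f"{counts_path}: non-numeric value in column {col!r} near line {line}"
            )

    try:
        gm = pd.read_csv(group_map_path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{group_map_path}: cannot parse group map: {exc}") from exc
    if gm.shape[1] < 2:
        raise ParseError(f"{group_map_path}: expected two columns (sample, group)")
    gm = gm.iloc[:, :2].dropna()
    group_map = dict(zip(gm.iloc[:, 0].str.strip(), gm.iloc[:, 1].str.strip()))

    absent = sorted(set(group_map) - set(df.columns))
    if absent:
        if not allow_extra:
            raise ParseError(
                f"{group_map_path}: samples not present in {counts_path.name}: "
                f"{absent}"
            )
        group_map = {s: g for s, g in group_map.items() if s in set(df.columns)}
    mat = ExpressionMatrix(df, group_map)
    log.info(
        "read %d genes x %d samples from %s", mat.values.shape[0], mat.values.shape[1],
        counts_path,
    )
    return mat
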