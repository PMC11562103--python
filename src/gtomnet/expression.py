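"""Expression matrices: the genes × samples container and its file formats.

The container is deliberately thin: a float array plus gene/sample identifier
lists and a unit tag.  The orientation is fixed everywhere in the package as
genes on rows and samples on columns; transposition happens only inside
correlation computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: recognised unit tags
UNITS = ("tpm", "log2_fpkm_plus1", "arbitrary")


@dataclass
class ExpressionMatrix:
    """A genes × samples real matrix with identifiers and a unit tag.

    Parameters
    ----------
    values
        Array of shape ``(d, n)`` — *d* genes (rows) by *n* samples (columns).
    gene_ids, sample_ids
        Unique row and column labels.
    unit
        One of ``"tpm"``, ``"log2_fpkm_plus1"`` or ``"arbitrary"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        d, n = self.values.shape
        if d != len(self.gene_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids / {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != d:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, unit: str = "arbitrary") -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            unit=unit,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict rows to ``gene_ids`` in the given order (all must exist)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"{len(missing)} gene ids not in matrix: {missing[:10]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(self.values[rows], list(gene_ids), self.sample_ids, self.unit)


def read_expression(path: str | Path, unit: str = "arbitrary", sep: str = "\t") -> ExpressionMatrix:
    """Read a gene-by-sample delimited text file (optionally gzipped).

    The first column holds gene identifiers, the header row sample
    identifiers.  Duplicate gene ids are collapsed by taking the per-sample
    maximum, with a logged warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if frame.isna().any().any():
        bad = int(frame.isna().sum().sum())
        raise ValueError(f"{path}: {bad} missing/non-numeric cells")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cells ({exc})") from exc
    frame.index = frame.index.map(str)
    if frame.index.duplicated().any():
        n_dup = int(frame.index.duplicated().sum())
        logger.warning("%s: %d duplicated gene ids collapsed by max", path, n_dup)
        frame = frame.groupby(level=0, sort=False).max()
    return ExpressionMatrix.from_frame(frame, unit=unit)


def write_expression(x: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write as delimited text; inverse of :func:`read_expression`.

    Values are written with shortest round-trip repr so read-back is exact.
    """
    x.to_frame().to_csv(Path(path), sep=sep)


def convert_log2fpkm_to_tpm(x: ExpressionMatrix) -> ExpressionMatrix:
    """Invert a log2(1+FPKM) transform and renormalise each sample to TPM.

    FPKM = 2**v − 1 (clipped at zero), then each sample column is scaled to
    sum to 1e6.  A sample whose FPKM column is all zero cannot be
    renormalised and raises.
    """
    if x.unit != "log2_fpkm_plus1":
        raise ValueError(f"expected unit 'log2_fpkm_plus1', got {x.unit!r}")
    fpkm = np.clip(np.exp2(x.values) - 1.0, 0.0, None)
    colsum = fpkm.sum(axis=0)
    zero = colsum <= 0
    if np.any(zero):
        bad = [x.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero sample columns, cannot renormalise: {bad}")
    tpm = fpkm / colsum * 1e6
    return ExpressionMatrix(tpm, x.gene_ids, x.sample_ids, unit="tpm")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text identifier list, one id per line, blanks skipped."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token:
            out.append(token)
    return out


def restrict_to_tf_list(x: ExpressionMatrix, tf_list: Iterable[str] | str | Path) -> ExpressionMatrix:
    """Restrict the matrix to a transcription-factor list, in list order.

    ``tf_list`` may be a path to a one-id-per-line file or any iterable of
    ids.  Ids absent from the matrix are counted and logged; an empty
    intersection raises.
    """
    if isinstance(tf_list, (str, Path)):
        wanted = read_gene_list(tf_list)
    else:
        wanted = [str(g) for g in tf_list]
    if not wanted:
        raise ValueError("empty transcription-factor list")
    present = set(x.gene_ids)
    kept = [g for g in wanted if g in present]
    n_missing = len(wanted) - len(kept)
    if n_missing:
        logger.warning("%d listed ids not found in the expression matrix", n_missing)
    if not kept:
        raise ValueError("no listed ids found in the expression matrix")
    return x.subset_genes(kept)
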