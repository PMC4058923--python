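"""Reading and writing count matrices, sample sheets and result tables.

The canonical interchange format is TSV (UTF-8, header row); CSV is accepted
via ``sep=","``.  A count matrix file has gene identifiers in the first
column and one column per sample; a sample sheet has columns
``sample_id``, ``condition``, ``replicate`` and ``time_h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "ResultTable",
    "read_counts",
    "read_sample_sheet",
    "write_counts",
    "write_sample_sheet",
    "write_results",
    "expressed_genes",
]


class ValidationError(ValueError):
    """An input violates a documented invariant."""


@dataclass
class CountMatrix:
    """Gene × sample matrix of non-negative integer read counts.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    counts : ndarray of int, shape (n_genes, n_samples)
        Raw read counts.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    """

    gene_ids: list[str]
    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D gene × sample matrix")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids but {self.counts.shape[0]} count rows"
            )
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {self.counts.shape[1]} count columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            rounded = np.rint(as_float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != rounded):
                i, j = _first_offender(~np.isfinite(as_float) | (as_float != np.rint(as_float)))
                raise ValidationError(
                    f"non-integer count at gene {self.gene_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}: {as_float[i, j]}"
                )
            self.counts = rounded.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = _first_offender(self.counts < 0)
            raise ValidationError(
                f"negative count at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.counts[i, j]}"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def reorder_samples(self, sample_ids: list[str]) -> "CountMatrix":
        """Return a copy with columns in the given sample order."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), self.counts[:, idx], list(sample_ids))


@dataclass
class SampleSheet:
    """Experimental design: condition, replicate and timepoint per sample.

    Timepoints are stored in hours.  Within a condition all replicates must
    share the same timepoint grid, and every condition must have at least
    two distinct timepoints.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "condition", "replicate", "time_h")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing column(s): {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["replicate"] = df["replicate"].astype(str)
        df["time_h"] = pd.to_numeric(df["time_h"], errors="raise").astype(float)
        if (df["time_h"] < 0).any():
            bad = df.loc[df["time_h"] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"negative time_h for sample {bad!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        key = df[["condition", "replicate", "time_h"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                "duplicate (condition, replicate, time_h) triple: "
                f"({dup['condition']!r}, {dup['replicate']!r}, {dup['time_h']})"
            )
        for cond, sub in df.groupby("condition"):
            times = sorted(sub["time_h"].unique())
            if len(times) < 2:
                raise ValidationError(
                    f"condition {cond!r} has fewer than 2 distinct timepoints"
                )
            for rep, rsub in sub.groupby("replicate"):
                if sorted(rsub["time_h"]) != times:
                    raise ValidationError(
                        f"replicate {rep!r} of condition {cond!r} does not cover the "
                        f"condition's timepoint grid {times}"
                    )
        # canonical internal order: (condition, replicate, time_h)
        self.frame = df.sort_values(
            ["condition", "replicate", "time_h"], kind="stable"
        ).reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    def replicates(self, condition: str) -> list[str]:
        sub = self.frame[self.frame["condition"] == condition]
        return sorted(sub["replicate"].unique())

    def times(self, condition: str | None = None) -> np.ndarray:
        df = self.frame
        if condition is not None:
            df = df[df["condition"] == condition]
        return np.array(sorted(df["time_h"].unique()))

    def samples_for(self, condition: str, replicate: str) -> pd.DataFrame:
        df = self.frame
        sub = df[(df["condition"] == condition) & (df["replicate"] == replicate)]
        return sub.sort_values("time_h")


@dataclass
class ResultTable:
    """Per-gene differential-dynamics results.

    One row per tested gene with the log10 Bayes factor, the maximum
    absolute log2 fold change over timepoints, the boolean differential
    call, and one column per (condition, replicate) holding the
    posterior-mode time difference (hours) at the last design timepoint.
    The reference replicate's time difference is exactly 0.
    """

    frame: pd.DataFrame

    CORE = ("gene_id", "log10_bf", "max_abs_log2_fc", "differential")

    def __post_init__(self) -> None:
        missing = [c for c in self.CORE if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"result table missing column(s): {missing}")
        if self.frame["gene_id"].duplicated().any():
            raise ValidationError("result table has duplicate gene ids")


def _first_duplicate(items) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise AssertionError("no duplicate present")


def _first_offender(mask: np.ndarray) -> tuple[int, int]:
    i, j = np.argwhere(mask)[0]
    return int(i), int(j)


def read_counts(path, sep: str = "\t") -> CountMatrix:
    """Read a count matrix TSV (gene ids in the first column).

    Raises
    ------
    ValidationError
        On negative, non-integer or missing cells (naming the offending
        cell) or duplicate identifiers.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        i = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(
            f"missing count at gene {df.index[i[0]]!r}, sample {df.columns[i[1]]!r}"
        )
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        counts=df.to_numpy(),
        sample_ids=[str(s) for s in df.columns],
    )


def write_counts(cm: CountMatrix, path, sep: str = "\t") -> None:
    df = cm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep)


def read_sample_sheet(path, sep: str = "\t") -> SampleSheet:
    """Read and validate a sample sheet TSV (sample_id, condition, replicate, time_h)."""
    return SampleSheet(pd.read_csv(path, sep=sep))


def write_sample_sheet(sheet: SampleSheet, path, sep: str = "\t") -> None:
    sheet.frame.to_csv(path, sep=sep, index=False)


def write_results(table: ResultTable, path, sep: str = "\t") -> None:
    """Write a result table as TSV with ≥ 6 significant digits on floats."""
    if len(table.frame) < 1:
        raise ValidationError("result table is empty")
    table.frame.to_csv(path, sep=sep, index=False, float_format="%.8g")


def read_results(path, sep: str = "\t") -> ResultTable:
    return ResultTable(pd.read_csv(path, sep=sep))


def expressed_genes(cm: CountMatrix, sheet: SampleSheet) -> np.ndarray:
    """Boolean mask of genes with at least one read in every condition.

    Genes failing the filter carry no information for a between-condition
    comparison and are excluded from testing (and flagged in the output).
    """
    order = {s: k for k, s in enumerate(cm.sample_ids)}
    mask = np.ones(cm.n_genes, dtype=bool)
    for cond in sheet.conditions:
        cols = [order[s] for s in sheet.frame.loc[sheet.frame["condition"] == cond, "sample_id"]]
        mask &= cm.counts[:, cols].sum(axis=1) > 0
    return mask
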