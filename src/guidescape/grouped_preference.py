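"""Group-by-k-mer average activity, representation profiling and pairwise
cross-dataset correlation.

The central move: group the guides of a dataset by a short sequence window —
either the genomic nucleotide 3' of the NGG PAM ("pam4") or the PAM-proximal
k spacer positions — average activity per group, and correlate those group
averages between datasets.  Because Pearson is scale-invariant, each dataset
is compared on its own (min-max) activity scale with no cross-dataset
harmonization.  Strong pam4 agreement across species flags an effect
intrinsic to the nuclease; spacer-window agreement only *within* a species
flags an effect of the genomic context the complex searches through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import SPACER_LENGTH, Dataset
from .errors import (
    EmptyDatasetError,
    IncompatibleTablesError,
    MissingContextError,
    ParameterError,
)

#: Window over the genomic nucleotide immediately 3' of the NGG PAM.
PAM4 = "pam4"

Window = Union[str, tuple[int, int]]


def proximal_window(k: int) -> tuple[int, int]:
    """Spacer window of the k PAM-proximal positions, i.e. (21-k, 20)."""
    if not 1 <= k <= SPACER_LENGTH:
        raise ParameterError(f"k must be in 1..{SPACER_LENGTH}")
    return (SPACER_LENGTH - k + 1, SPACER_LENGTH)


def _check_window(window: Window, k: int | None) -> int:
    if window == PAM4:
        if k not in (None, 1):
            raise ParameterError("pam4 window implies k=1")
        return 1
    start, end = window
    if not (1 <= start <= end <= SPACER_LENGTH):
        raise ParameterError(f"window {window} outside spacer positions 1..20")
    width = end - start + 1
    if k is not None and k != width:
        raise ParameterError(f"k={k} inconsistent with window {window}")
    return width


@dataclass
class KmerGroupTable:
    """Per-k-mer (mean activity, count) at a fixed position window.

    ``entries`` maps each *observed* k-mer to its arithmetic-mean activity
    and count; unobserved k-mers are simply absent.  This doubles as the
    trained contiguous-k-mer predictor.
    """

    window: Window
    k: int
    entries: dict[str, tuple[float, int]]
    label: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_total(self) -> int:
        return sum(n for _, n in self.entries.values())

    def coverage(self) -> float:
        """Fraction of the 4**k possible k-mers observed."""
        return len(self.entries) / 4**self.k

    def global_mean(self) -> float:
        """Count-weighted mean activity over all groups (= pooled mean)."""
        tot = self.n_total
        return sum(m * n for m, n in self.entries.values()) / tot

    def means(self, kmers: Sequence[str]) -> np.ndarray:
        return np.array([self.entries[m][0] for m in kmers], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [(m, v[0], v[1]) for m, v in sorted(self.entries.items())]
        return pd.DataFrame(rows, columns=["kmer", "mean_activity", "n"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, path: str | Path, window: Window, k: int, label: str = ""
    ) -> "KmerGroupTable":
        df = pd.read_csv(path, sep="\t")
        entries = {
            r.kmer: (float(r.mean_activity), int(r.n))
            for r in df.itertuples(index=False)
        }
        return cls(window=window, k=k, entries=entries, label=label)


def extract_window(d: Dataset, window: Window, k: int | None = None) -> pd.Series:
    """The k-mer each guide shows in the window (pam4 or spacer positions)."""
    width = _check_window(window, k)
    if window == PAM4:
        contexts = d.df["pam_context"]
        if (contexts.str.len() < 4).any():
            raise MissingContextError(
                f"{d.dataset_id}: pam4 analysis needs 4-nt PAM contexts"
            )
        return contexts.str.slice(3, 4)
    start, end = window
    del width
    return d.df["spacer"].str.slice(start - 1, end)


def group_mean_by_kmer(d: Dataset, window: Window, k: int | None = None) -> KmerGroupTable:
    """Mean activity per observed k-mer in the given window."""
    if len(d) == 0:
        raise EmptyDatasetError(f"{d.dataset_id} has no records")
    width = _check_window(window, k)
    kmers = extract_window(d, window, k)
    grouped = d.df.groupby(kmers.rename("kmer"), sort=True)["activity"].agg(
        ["mean", "size"]
    )
    entries = {
        str(km): (float(row["mean"]), int(row["size"]))
        for km, row in grouped.iterrows()
    }
    return KmerGroupTable(window=window, k=width, entries=entries, label=d.dataset_id)


def has_pam4_variability(d: Dataset) -> bool:
    """True when all PAM contexts carry a 4th nt and it is not constant.

    Datasets failing this are flagged ``no_pam4_variability`` and excluded
    from pam4 group analyses.
    """
    contexts = d.df["pam_context"]
    if (contexts.str.len() < 4).any():
        return False
    return contexts.str.slice(3, 4).nunique() > 1


def kmer_representation(d: Dataset, k_max: int = 10) -> np.ndarray:
    """Fraction of possible k-mers observed at the PAM-proximal window,
    for each k in 1..k_max (window anchored at position 20)."""
    if not 1 <= k_max <= 10:
        raise ParameterError("k_max must be in 1..10")
    spacers = d.df["spacer"]
    out = np.empty(k_max, dtype=float)
    for k in range(1, k_max + 1):
        distinct = spacers.str.slice(SPACER_LENGTH - k, SPACER_LENGTH).nunique()
        out[k - 1] = distinct / 4**k
    return out


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson over matched k-mer group means, plus shared counts."""

    labels: tuple[str, ...]
    r: np.ndarray
    n_shared: np.ndarray
    window: Window = field(default=PAM4)
    k: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.labels), columns=list(self.labels))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="dataset")

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.r[i, j])


def pairwise_group_correlation(
    tables: Sequence[KmerGroupTable], min_shared: int = 3
) -> CorrelationMatrix:
    """Pearson between group-mean vectors of every pair of tables.

    Only k-mers present in both tables enter a pair's correlation (designed
    exclusions, e.g. T-free proximal libraries, leave groups absent); pairs
    sharing fewer than ``min_shared`` k-mers — or with a zero-variance mean
    vector — are reported as NaN.
    """
    if len(tables) < 2:
        raise IncompatibleTablesError("need at least 2 tables")
    w, k = tables[0].window, tables[0].k
    for t in tables[1:]:
        if t.window != w or t.k != k:
            raise IncompatibleTablesError(
                f"table {t.label!r} has window/k ({t.window}, {t.k}) != ({w}, {k})"
            )
    m = len(tables)
    r = np.eye(m)
    n_shared = np.zeros((m, m), dtype=int)
    for i in range(m):
        n_shared[i, i] = len(tables[i])
        for j in range(i + 1, m):
            shared = sorted(set(tables[i].entries) & set(tables[j].entries))
            n_shared[i, j] = n_shared[j, i] = len(shared)
            if len(shared) < min_shared:
                rij = np.nan
            else:
                x = tables[i].means(shared)
                y = tables[j].means(shared)
                if x.std() == 0 or y.std() == 0:
                    rij = np.nan
                else:
                    rij = stats.pearsonr(x, y).statistic
            r[i, j] = r[j, i] = rij
    return CorrelationMatrix(
        labels=tuple(t.label for t in tables), r=r, n_shared=n_shared, window=w, k=k
    )
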