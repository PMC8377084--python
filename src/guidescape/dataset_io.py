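"""Reading, validation, normalization and filtering of gRNA activity tables.

A dataset is a TSV file with header columns ``spacer`` (20-nt targeting
sequence, position 20 adjacent to the PAM), ``pam_context`` (the NGG PAM plus,
when known, the genomic nucleotide immediately 3' of it) and ``activity``
(a numeric readout on the dataset's native scale).  An optional ``guide_id``
column supplies stable identifiers; any extra numeric column is carried along
as a named continuous feature for downstream feature-importance analysis.

Activities stay on their native scale until explicitly normalized: datasets
whose readout decreases with activity are sign-inverted first, and datasets
are min-max scaled to [0, 1] before any cross-dataset comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .errors import (
    DegenerateScaleWarning,
    EmptyDatasetError,
    FormatError,
    InputError,
    SizeError,
    StateError,
)

logger = logging.getLogger(__name__)

SPACER_LENGTH = 20
DNA_ALPHABET = frozenset("ACGT")
REQUIRED_COLUMNS = ("spacer", "pam_context", "activity")
CORE_COLUMNS = ("guide_id", "spacer", "pam_context", "activity")

#: Scale states a dataset moves through: native scale, sign-flipped native
#: scale, and min-max normalized to [0, 1].
RAW = "raw"
SIGN_INVERTED = "sign_inverted"
MINMAX = "minmax"


@dataclass(frozen=True)
class GuideRecord:
    """One gRNA: spacer, PAM context, activity and provenance.

    Spacer positions are indexed 1..20 with position 20 PAM-proximal, so the
    "PAM-proximal 5 bp" are positions 16-20 (the seed-adjacent end).
    """

    guide_id: str
    spacer: str
    pam_context: str
    activity: float
    features: Mapping[str, float] = field(default_factory=dict)


@dataclass
class Dataset:
    """A named, ordered collection of guide records plus metadata.

    The records live in a pandas DataFrame with the core columns
    ``guide_id, spacer, pam_context, activity`` followed by any feature
    columns.  ``scale_state`` tracks normalization (raw / sign_inverted /
    minmax); operations that require a particular state raise
    :class:`~guidescape.errors.StateError` otherwise.
    """

    dataset_id: str
    df: pd.DataFrame
    species: str = ""
    meta: dict = field(default_factory=dict)
    scale_state: str = RAW

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"dataset {self.dataset_id!r} missing columns {missing}")
        if self.df["guide_id"].duplicated().any():
            dup = self.df.loc[self.df["guide_id"].duplicated(), "guide_id"].iloc[0]
            raise FormatError(
                f"dataset {self.dataset_id!r} has duplicate guide_id {dup!r}"
            )
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def activities(self) -> np.ndarray:
        return self.df["activity"].to_numpy(dtype=float)

    @property
    def spacers(self) -> np.ndarray:
        return self.df["spacer"].to_numpy(dtype=object)

    @property
    def pam_contexts(self) -> np.ndarray:
        return self.df["pam_context"].to_numpy(dtype=object)

    @property
    def feature_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.df.columns if c not in CORE_COLUMNS)

    def records(self) -> Iterator[GuideRecord]:
        feats = self.feature_columns
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield GuideRecord(
                guide_id=d["guide_id"],
                spacer=d["spacer"],
                pam_context=d["pam_context"],
                activity=float(d["activity"]),
                features={c: d[c] for c in feats},
            )

    def evolve(self, **changes) -> "Dataset":
        """Return a copy with the given fields replaced (meta is copied)."""
        changes.setdefault("meta", dict(self.meta))
        return replace(self, **changes)


def _valid_spacer(s: str) -> bool:
    return len(s) == SPACER_LENGTH and set(s) <= DNA_ALPHABET


def _valid_pam_context(p: str) -> bool:
    return len(p) in (3, 4) and set(p) <= DNA_ALPHABET


def load_dataset(
    path: str | Path,
    dataset_id: str | None = None,
    species: str = "",
    meta: Mapping | None = None,
) -> Dataset:
    """Load a TSV activity table, rejecting malformed rows with a count.

    Rows are rejected (and logged, with the total stored under
    ``meta['n_rejected']``) when the spacer is not a 20-nt ACGT string, the
    PAM context is not a 3- or 4-nt ACGT string, or the activity is not a
    finite number.  Extra numeric columns become named continuous features;
    non-numeric extras are dropped with a log message.

    Raises
    ------
    FormatError
        If a required column is absent or guide ids are duplicated.
    EmptyDatasetError
        If the file has no data rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"{path} is empty") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} missing required column(s) {missing}")
    if df.empty:
        raise EmptyDatasetError(f"{path} has a header but no records")

    dataset_id = dataset_id or path.stem
    df["spacer"] = df["spacer"].astype(str).str.upper()
    df["pam_context"] = df["pam_context"].astype(str).str.upper()
    df["activity"] = pd.to_numeric(df["activity"], errors="coerce")

    ok = (
        df["spacer"].map(_valid_spacer)
        & df["pam_context"].map(_valid_pam_context)
        & np.isfinite(df["activity"].to_numpy(dtype=float))
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "%s: rejected %d malformed row(s) of %d", dataset_id, n_rejected, len(df)
        )
    df = df.loc[ok].reset_index(drop=True)
    if df.empty:
        raise EmptyDatasetError(f"{path}: no valid records after validation")

    if "guide_id" not in df.columns:
        df.insert(0, "guide_id", [f"g{i:06d}" for i in range(len(df))])
    else:
        df["guide_id"] = df["guide_id"].astype(str)

    extra = [c for c in df.columns if c not in CORE_COLUMNS]
    keep, dropped = [], []
    for c in extra:
        as_num = pd.to_numeric(df[c], errors="coerce")
        if np.isfinite(as_num.to_numpy(dtype=float)).all():
            df[c] = as_num
            keep.append(c)
        else:
            dropped.append(c)
    if dropped:
        logger.info("%s: dropped non-numeric extra column(s) %s", dataset_id, dropped)
        df = df.drop(columns=dropped)
    df = df[list(CORE_COLUMNS) + keep]

    full_meta = dict(meta or {})
    full_meta["n_rejected"] = n_rejected
    return Dataset(
        dataset_id=dataset_id, df=df, species=species, meta=full_meta, scale_state=RAW
    )


def write_dataset(d: Dataset, path: str | Path) -> None:
    """Write a dataset back to the TSV dialect :func:`load_dataset` reads."""
    d.df.to_csv(path, sep="\t", index=False)


def invert_activity(d: Dataset) -> Dataset:
    """Negate every activity so that larger numbers mean more active guides.

    Some assays report depletion scores or similar quantities where more
    negative means more active; those datasets are sign-inverted before any
    comparison.  Inverting twice restores the original (the state toggles
    between raw and sign_inverted); min-max scaled data cannot be inverted.
    """
    if d.scale_state == MINMAX:
        raise StateError("cannot sign-invert an already min-max scaled dataset")
    df = d.df.copy()
    df["activity"] = -df["activity"]
    new_state = SIGN_INVERTED if d.scale_state == RAW else RAW
    return d.evolve(df=df, scale_state=new_state)


def minmax_scale(d: Dataset) -> Dataset:
    """Rescale activities to [0, 1] via (a - min) / (max - min).

    Degenerate datasets (all activities equal) map to all zeros with a
    :class:`DegenerateScaleWarning` instead of erroring, so batch pipelines
    keep running.  Reapplication is idempotent up to floating tolerance.
    """
    if len(d) < 2:
        raise SizeError("min-max scaling needs at least 2 records")
    a = d.activities
    lo, hi = a.min(), a.max()
    df = d.df.copy()
    if hi == lo:
        warnings.warn(
            f"{d.dataset_id}: all activities equal; scaled to 0", DegenerateScaleWarning
        )
        df["activity"] = 0.0
    else:
        df["activity"] = (a - lo) / (hi - lo)
    return d.evolve(df=df, scale_state=MINMAX)


def _has_ngg_target(seq: str, spacer: str) -> bool:
    # Exact match of spacer immediately followed by NGG (N = any real base).
    start = 0
    n = len(seq)
    while True:
        i = seq.find(spacer, start)
        if i < 0:
            return False
        end = i + SPACER_LENGTH
        if end + 3 <= n and seq[end + 1 : end + 3] == "GG" and seq[end] in DNA_ALPHABET:
            return True
        start = i + 1


def filter_valid_targets(d: Dataset, genome: str | Path) -> Dataset:
    """Keep guides with an exact spacer+NGG target site in the genome.

    The spacer followed immediately by NGG must occur at least once on the
    forward or reverse-complement strand of some sequence in the FASTA file
    (case- and line-wrapping-insensitive; ambiguity codes never match).
    Records whose own ``pam_context`` is not NGG are dropped as well.  The
    number removed is logged and stored under ``meta['n_removed_no_target']``.
    """
    genome = Path(genome)
    try:
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")]
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read FASTA {genome}: {exc}") from exc
    if not seqs:
        raise OSError(f"{genome}: no FASTA records found")
    search_space = seqs + [reverse_complement(s) for s in seqs]

    found: dict[str, bool] = {}
    for spacer in pd.unique(d.df["spacer"]):
        found[spacer] = any(_has_ngg_target(s, spacer) for s in search_space)

    ngg = d.df["pam_context"].str.slice(1, 3) == "GG"
    keep = d.df["spacer"].map(found) & ngg
    n_removed = int((~keep).sum())
    logger.info("%s: target filter removed %d of %d guides", d.dataset_id, n_removed, len(d))
    out = d.evolve(df=d.df.loc[keep].reset_index(drop=True))
    out.meta["n_removed_no_target"] = n_removed
    return out


def remove_redundant(d: Dataset, reference: Dataset) -> Dataset:
    """Drop guides whose spacer also appears in ``reference``.

    Used to exclude guides replicated across library designs before
    cross-dataset comparisons, so shared guides do not inflate agreement.
    """
    ref = set(reference.df["spacer"])
    keep = ~d.df["spacer"].isin(ref)
    n_dropped = int((~keep).sum())
    logger.info(
        "%s: removed %d guide(s) shared with %s", d.dataset_id, n_dropped,
        reference.dataset_id,
    )
    out = d.evolve(df=d.df.loc[keep].reset_index(drop=True))
    out.meta["n_removed_redundant"] = n_dropped
    return out


def collapse_base_edit(
    per_position_table: pd.DataFrame,
    dataset_id: str = "base_edit",
    species: str = "",
    meta: Mapping | None = None,
) -> Dataset:
    """Collapse per-position base-editing frequencies to one activity per guide.

    Base-editor screens report an editing frequency at each position within
    the protospacer; as a measure of how active the guide is (rather than of
    the editing outcome) all frequencies are summed per guide.  The table
    needs columns ``guide_id, position, edit_frequency`` plus constant
    ``spacer`` and ``pam_context`` columns per guide.
    """
    required = ("guide_id", "position", "edit_frequency", "spacer", "pam_context")
    missing = [c for c in required if c not in per_position_table.columns]
    if missing:
        raise FormatError(f"per-position table missing column(s) {missing}")
    t = per_position_table
    if (t["edit_frequency"].to_numpy(dtype=float) < 0).any():
        raise InputError("edit frequencies must be >= 0")
    if t.duplicated(subset=["guide_id", "position"]).any():
        raise InputError("duplicate (guide_id, position) rows")
    for col in ("spacer", "pam_context"):
        if (t.groupby("guide_id")[col].nunique() > 1).any():
            raise InputError(f"{col} not constant within a guide")

    agg = (
        t.groupby("guide_id", sort=False)
        .agg(
            spacer=("spacer", "first"),
            pam_context=("pam_context", "first"),
            activity=("edit_frequency", "sum"),
        )
        .reset_index()
    )
    agg["spacer"] = agg["spacer"].str.upper()
    agg["pam_context"] = agg["pam_context"].str.upper()
    return Dataset(
        dataset_id=dataset_id,
        df=agg[list(CORE_COLUMNS)],
        species=species,
        meta=dict(meta or {}),
        scale_state=RAW,
    )
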