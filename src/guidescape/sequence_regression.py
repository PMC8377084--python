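"""Dinucleotide one-hot regression of activity on spacer sequence, with
Monte-Carlo cross-validation and leave-out-5-bp ablation.

The 20-nt spacer is digitized as overlapping dinucleotides: for each adjacent
position pair (i, i+1), i = 1..19, one of 16 indicator columns is set, giving
a 304-column binary design matrix.  Activity is regressed on it by ordinary
least squares (intercept included, minimum-norm solve under collinearity),
and predictive power is the Pearson correlation between predicted and actual
activity on held-out guides, averaged over 10 independent random 80/20
splits.

The ablation repeats this with one 5-bp quarter of the spacer masked at a
time (any dinucleotide feature touching a masked position is dropped) and
reports each masked run's mean Pearson as a fraction of the full-sequence
value: the quarter whose removal costs the most predictive power is where
the sequence signal lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression

from .dataset_io import Dataset
from .errors import ParameterError, SizeError

SPACER_LENGTH = 20
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

#: The four 5-bp quarters of the spacer, PAM-distal (1-5) to PAM-proximal (16-20).
QUARTERS = ((1, 5), (6, 10), (11, 15), (16, 20))

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i


@dataclass(frozen=True)
class EncodingSpec:
    """Which spacer positions are masked out of the dinucleotide encoding.

    Feature order: adjacent pairs (i, i+1) with both positions unmasked, in
    increasing i, each contributing 16 indicator columns in AA..TT order.
    """

    masked_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        bad = [p for p in self.masked_positions if not 1 <= p <= SPACER_LENGTH]
        if bad:
            raise ParameterError(f"masked positions outside 1..20: {sorted(bad)}")

    @property
    def position_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (i, i + 1)
            for i in range(1, SPACER_LENGTH)
            if i not in self.masked_positions and i + 1 not in self.masked_positions
        )

    @property
    def n_features(self) -> int:
        return 16 * len(self.position_pairs)

    def feature_names(self) -> list[str]:
        return [
            f"p{i}{i + 1}_{d}" for i, _ in self.position_pairs for d in DINUCLEOTIDES
        ]


def mask_quarter(start: int, end: int) -> EncodingSpec:
    return EncodingSpec(masked_positions=frozenset(range(start, end + 1)))


def encode_matrix(spacers: Sequence[str], spec: EncodingSpec = EncodingSpec()) -> np.ndarray:
    """One-hot dinucleotide design matrix for a batch of 20-nt spacers."""
    n = len(spacers)
    joined = "".join(spacers)
    if len(joined) != n * SPACER_LENGTH:
        raise ParameterError("all spacers must be 20 nt")
    codes = _LUT[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ParameterError("spacers contain characters outside ACGT")
    codes = codes.reshape(n, SPACER_LENGTH).astype(np.intp)

    pairs = spec.position_pairs
    X = np.zeros((n, 16 * len(pairs)))
    rows = np.arange(n)
    for p_idx, (i, j) in enumerate(pairs):
        dinuc = 4 * codes[:, i - 1] + codes[:, j - 1]
        X[rows, 16 * p_idx + dinuc] = 1.0
    return X


def encode_dinucleotide(spacer: str, spec: EncodingSpec = EncodingSpec()) -> np.ndarray:
    """One-hot dinucleotide vector of a single spacer."""
    return encode_matrix([spacer], spec)[0]


@dataclass
class RegressionResult:
    """Held-out Pearson per split plus summary; the full-sequence run is the
    dataset's 'Pearson(full)'."""

    per_split_pearson: tuple[float, ...]
    n_train: int
    n_test: int
    n_features: int
    mean_pearson: float = field(init=False)
    sd_pearson: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_split_pearson, dtype=float)
        self.mean_pearson = float(arr.mean())
        self.sd_pearson = float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def _split_pearson(pred: np.ndarray, actual: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(actual) == 0:
        return np.nan
    return float(stats.pearsonr(pred, actual).statistic)


def crossval_regression(
    d: Dataset,
    spec: EncodingSpec = EncodingSpec(),
    n_splits: int = 10,
    train_frac: float = 0.8,
    seed: int = 0,
) -> RegressionResult:
    """Monte-Carlo cross-validated OLS of activity on the dinucleotide encoding.

    Each split draws an independent random train/test partition
    (``train_frac`` of the guides train), fits ordinary least squares with an
    intercept, and scores Pearson(predicted, actual) on the held-out guides.
    Splits are keyed by (seed, split index); records are canonically sorted
    by guide_id first, so the result is invariant to input record order.
    """
    n = len(d)
    if n < 25:
        raise SizeError(f"need >= 25 records, got {n}")
    if not 0.0 < train_frac < 1.0:
        raise ParameterError("train_frac must be in (0, 1)")

    order = np.argsort(d.df["guide_id"].to_numpy(), kind="stable")
    X = encode_matrix(list(d.spacers[order]), spec)
    y = d.activities[order]

    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 3)  # keep >= 3 test guides for Pearson
    per_split = []
    for s in range(n_splits):
        rng = np.random.default_rng([seed, s])
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = LinearRegression().fit(X[tr], y[tr])
        per_split.append(_split_pearson(model.predict(X[te]), y[te]))
    return RegressionResult(
        per_split_pearson=tuple(per_split),
        n_train=n_train,
        n_test=n - n_train,
        n_features=spec.n_features,
    )


@dataclass
class QuarterAblation:
    mean_pearson_partial: float
    fraction_of_full: float
    result: RegressionResult


@dataclass
class AblationResult:
    """Leave-out-5-bp ablation: full-sequence run plus one run per masked
    quarter, each expressed as a fraction of the full-sequence mean Pearson.

    ``excluded`` flags datasets whose full-sequence Pearson is below the
    threshold — sequence is not predictive there, so the fractions are not
    meaningful."""

    full: RegressionResult
    quarters: dict[str, QuarterAblation]
    excluded: bool
    exclusion_threshold: float


def quarter_key(start: int, end: int) -> str:
    return f"{start}-{end}"


def ablation_quarters(
    d: Dataset,
    n_splits: int = 10,
    seed: int = 0,
    exclusion_threshold: float = 0.1,
    train_frac: float = 0.8,
) -> AblationResult:
    """Run the full-sequence regression and one masked run per 5-bp quarter.

    The same seed keys the splits of every run, so full and masked runs are
    compared on identical train/test partitions.
    """
    full = crossval_regression(
        d, EncodingSpec(), n_splits=n_splits, train_frac=train_frac, seed=seed
    )
    quarters: dict[str, QuarterAblation] = {}
    for start, end in QUARTERS:
        res = crossval_regression(
            d, mask_quarter(start, end), n_splits=n_splits, train_frac=train_frac,
            seed=seed,
        )
        frac = (
            res.mean_pearson / full.mean_pearson if full.mean_pearson != 0 else np.nan
        )
        quarters[quarter_key(start, end)] = QuarterAblation(
            mean_pearson_partial=res.mean_pearson,
            fraction_of_full=float(frac),
            result=res,
        )
    excluded = not np.isfinite(full.mean_pearson) or full.mean_pearson < exclusion_threshold
    return AblationResult(
        full=full,
        quarters=quarters,
        excluded=bool(excluded),
        exclusion_threshold=exclusion_threshold,
    )
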