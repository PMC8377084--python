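"""The contiguous PAM-proximal k-mer predictor and its upper-bound residual
analysis.

Rationale: a Cas9/gRNA complex probes candidate sites zipper-like from the
PAM-proximal end, so the time spent on non-target interactions — and with it
the ceiling of achievable activity — depends on the PAM-proximal spacer
sequence as one *contiguous* word, not as a bag of dinucleotides.  The
predictor is therefore a plain lookup: pool training datasets (on the common
min-max scale), group guides by their contiguous PAM-proximal 5-mer, average
activity per group, and predict any guide by its group mean.

Because everything else (accessibility, structure, repair, ...) only pushes
activity *below* that ceiling, the interesting statistics are one-sided:
residual skewness and the fraction of guides whose measured activity exceeds
the prediction by more than a margin delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import MINMAX, Dataset
from .errors import SizeError, StateError
from .grouped_preference import KmerGroupTable, group_mean_by_kmer, proximal_window


def _require_minmax(d: Dataset) -> None:
    if d.scale_state != MINMAX:
        raise StateError(
            f"{d.dataset_id}: expected min-max scaled data, got {d.scale_state!r}"
        )


def build_kmer_predictor(
    training: Dataset | list[Dataset], k: int = 5
) -> KmerGroupTable:
    """Train the lookup predictor on pooled guides from the training datasets.

    Guides from all datasets are pooled into one collection *before* grouping
    (pooled-guide weighting, not a mean of per-dataset means), then grouped
    by spacer positions (21-k)..20.  The returned table's ``coverage()``
    reports the fraction of the 4**k k-mers observed.
    """
    datasets = [training] if isinstance(training, Dataset) else list(training)
    if not datasets:
        raise SizeError("no training datasets")
    for d in datasets:
        _require_minmax(d)
    if len(datasets) == 1:
        pooled = datasets[0]
    else:
        frames = [d.df.assign(guide_id=d.dataset_id + ":" + d.df["guide_id"]) for d in datasets]
        pooled = Dataset(
            dataset_id="pooled(" + "+".join(d.dataset_id for d in datasets) + ")",
            df=pd.concat(frames, ignore_index=True)[
                ["guide_id", "spacer", "pam_context", "activity"]
            ],
            scale_state=MINMAX,
        )
    table = group_mean_by_kmer(pooled, proximal_window(k), k)
    table.label = pooled.dataset_id
    return table


def _suffix_marginal(table: KmerGroupTable) -> dict[str, tuple[float, int]]:
    # Count-weighted (k-1)-mer means, marginalizing the PAM-distal position
    # of the window (the suffix stays PAM-proximal).
    acc: dict[str, list[float]] = {}
    for kmer, (mean, n) in table.entries.items():
        key = kmer[1:]
        s = acc.setdefault(key, [0.0, 0])
        s[0] += mean * n
        s[1] += n
    return {key: (tot / n, n) for key, (tot, n) in acc.items()}


@dataclass
class PredictionResult:
    """Per-guide predicted vs actual activity plus the overall Pearson.

    ``frame`` columns: guide_id, kmer, predicted, actual, residual
    (= actual - predicted).  ``pearson`` is NaN when predictions (or
    actuals) have zero variance.  Fallback counts record how many guides
    needed the (k-1)-mer marginal or the global training mean because their
    k-mer was unseen in training.
    """

    frame: pd.DataFrame
    pearson: float
    n: int
    n_fallback_suffix: int
    n_fallback_global: int

    @property
    def residuals(self) -> np.ndarray:
        return self.frame["residual"].to_numpy(dtype=float)


def predict_activity(table: KmerGroupTable, d: Dataset) -> PredictionResult:
    """Predict each guide's activity as its PAM-proximal k-mer's trained mean.

    Unseen k-mers fall back to the (k-1)-mer marginal mean, then to the
    global training mean, so a prediction always exists.
    """
    _require_minmax(d)
    k = table.k
    suffix = _suffix_marginal(table)
    global_mean = table.global_mean()

    kmers = d.df["spacer"].str.slice(20 - k, 20)
    predicted = np.empty(len(d), dtype=float)
    n_fb_suffix = n_fb_global = 0
    for i, km in enumerate(kmers):
        hit = table.entries.get(km)
        if hit is not None:
            predicted[i] = hit[0]
            continue
        sub = suffix.get(km[1:])
        if sub is not None:
            predicted[i] = sub[0]
            n_fb_suffix += 1
        else:
            predicted[i] = global_mean
            n_fb_global += 1

    actual = d.activities
    if np.std(predicted) == 0 or np.std(actual) == 0:
        pearson = np.nan
    else:
        pearson = float(stats.pearsonr(predicted, actual).statistic)
    frame = pd.DataFrame(
        {
            "guide_id": d.df["guide_id"],
            "kmer": kmers,
            "predicted": predicted,
            "actual": actual,
            "residual": actual - predicted,
        }
    )
    return PredictionResult(
        frame=frame,
        pearson=pearson,
        n=len(d),
        n_fallback_suffix=n_fb_suffix,
        n_fallback_global=n_fb_global,
    )


@dataclass
class ResidualSummary:
    """Shape statistics of the residual distribution.

    Negative ``skewness`` plus a small ``exceedance_fraction`` (residuals
    above ``delta``) is the upper-bound signature: the predictor
    over-predicts attenuated guides often but is rarely beaten by more than
    the margin."""

    skewness: float
    exceedance_fraction: float
    delta: float
    quantiles: dict[int, float]
    n: int


def residual_stats(p: PredictionResult, delta: float = 0.1) -> ResidualSummary:
    """Skewness (adjusted Fisher-Pearson), exceedance fraction and quantiles."""
    if p.n < 10:
        raise SizeError(f"need >= 10 residuals, got {p.n}")
    res = p.residuals
    q = np.percentile(res, [5, 25, 50, 75, 95])
    return ResidualSummary(
        skewness=float(stats.skew(res, bias=False)),
        exceedance_fraction=float(np.mean(res > delta)),
        delta=delta,
        quantiles={5: q[0], 25: q[1], 50: q[2], 75: q[3], 95: q[4]},
        n=p.n,
    )
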