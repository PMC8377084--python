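"""Assessment of reported sequence features: thirds log-odds for discrete
features, Pearson for continuous ones, and cross-dataset sign consistency.

A discrete feature (say, G at spacer position 20) is scored within one
dataset by the log odds ratio of its frequency in the most-active third of
guides versus the least-active third; a continuous feature (say, GC content)
by its Pearson correlation with activity.  A feature has a consistent impact
across a set of datasets when the sign of its statistic agrees in all of
them — the cross-species version of that check is what separates effects
intrinsic to the nuclease from effects of the genomic context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import Dataset, GuideRecord
from .errors import ParameterError, SizeError


@dataclass(frozen=True)
class FeatureDefinition:
    """A named, deterministic map from a guide record to a feature value.

    ``kind`` is "discrete" (evaluator returns 0/1) or "continuous"
    (evaluator returns a real number).
    """

    name: str
    kind: str
    evaluator: Callable[[GuideRecord], float] = field(compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ParameterError(f"kind must be discrete|continuous, got {self.kind!r}")

    def evaluate(self, d: Dataset) -> np.ndarray:
        return np.array([self.evaluator(r) for r in d.records()], dtype=float)


# ---------------------------------------------------------------- built-ins

def nucleotide_at(position: int, base: str) -> FeatureDefinition:
    """Indicator of ``base`` at spacer position ``position`` (1..20)."""
    if not 1 <= position <= 20:
        raise ParameterError("position must be in 1..20")
    base = base.upper()
    return FeatureDefinition(
        name=f"{base}{position}",
        kind="discrete",
        evaluator=lambda r, p=position, b=base: float(r.spacer[p - 1] == b),
    )


def kmer_present(kmer: str, name: str | None = None) -> FeatureDefinition:
    """Indicator of ``kmer`` occurring anywhere in the spacer."""
    kmer = kmer.upper()
    return FeatureDefinition(
        name=name or f"{kmer}_present",
        kind="discrete",
        evaluator=lambda r, km=kmer: float(km in r.spacer),
    )


def tttt_present() -> FeatureDefinition:
    """Four contiguous thymines (a Pol III pause signal in U6-driven guides)."""
    return kmer_present("TTTT")


def gc_content() -> FeatureDefinition:
    return FeatureDefinition(
        name="gc_content",
        kind="continuous",
        evaluator=lambda r: (r.spacer.count("G") + r.spacer.count("C")) / len(r.spacer),
    )


def column_feature(column: str) -> FeatureDefinition:
    """Pass-through of a precomputed numeric column (e.g. a folding energy
    or melting temperature computed by an external tool)."""
    return FeatureDefinition(
        name=column,
        kind="continuous",
        evaluator=lambda r, c=column: float(r.features[c]),
    )


def builtin_catalog() -> list[FeatureDefinition]:
    """A small default catalog of commonly reported features."""
    return [
        nucleotide_at(20, "G"),
        nucleotide_at(20, "C"),
        nucleotide_at(1, "G"),
        tttt_present(),
        gc_content(),
    ]


# ------------------------------------------------------------------ scoring

def thirds_log_odds(d: Dataset, f: FeatureDefinition) -> float:
    """Natural-log odds ratio of the feature between activity tertiles.

    Guides are stably sorted by activity (descending); with m = floor(n/3),
    a = feature count in the top third and b = in the bottom third, the
    statistic is ln[ (a+0.5)/(m-a+0.5) / ((b+0.5)/(m-b+0.5)) ]
    (Haldane-Anscombe 0.5 correction, so zero counts are defined).
    """
    if f.kind != "discrete":
        raise ParameterError(f"{f.name} is not a discrete feature")
    n = len(d)
    if n < 9:
        raise SizeError(f"need >= 9 records, got {n}")
    values = f.evaluate(d)
    order = d.df["activity"].sort_values(ascending=False, kind="stable").index.to_numpy()
    m = n // 3
    a = float(values[order[:m]].sum())
    b = float(values[order[-m:]].sum())
    return math.log(((a + 0.5) / (m - a + 0.5)) / ((b + 0.5) / (m - b + 0.5)))


def continuous_feature_pearson(d: Dataset, f: FeatureDefinition) -> float:
    """Pearson correlation of a continuous feature with activity (NaN when
    either vector has zero variance)."""
    if f.kind != "continuous":
        raise ParameterError(f"{f.name} is not a continuous feature")
    if len(d) < 3:
        raise SizeError("need >= 3 records")
    x = f.evaluate(d)
    y = d.activities
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def score_feature(d: Dataset, f: FeatureDefinition) -> float:
    return thirds_log_odds(d, f) if f.kind == "discrete" else continuous_feature_pearson(d, f)


def evaluate_features(
    datasets: Sequence[Dataset], features: Sequence[FeatureDefinition]
) -> pd.DataFrame:
    """Tidy (feature, dataset, kind, statistic, sign) table over all pairs."""
    rows = []
    for f in features:
        for d in datasets:
            s = score_feature(d, f)
            rows.append(
                {
                    "feature": f.name,
                    "dataset": d.dataset_id,
                    "species": d.species,
                    "kind": f.kind,
                    "statistic": s,
                    "sign": int(np.sign(s)) if np.isfinite(s) else 0,
                }
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- consistency

@dataclass
class FeatureConsistency:
    consistent_all: bool | None
    per_species: dict[str, bool | None]
    n_datasets: int
    n_missing: int


@dataclass
class ConsistencyReport:
    per_feature: dict[str, FeatureConsistency]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, c in self.per_feature.items():
            row = {
                "feature": name,
                "consistent_all": c.consistent_all,
                "n_datasets": c.n_datasets,
                "n_missing": c.n_missing,
            }
            for sp, v in c.per_species.items():
                row[f"consistent_{sp}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _signs_agree(signs: np.ndarray) -> bool | None:
    # None when fewer than 2 defined statistics; zeros count as their own sign.
    if len(signs) < 2:
        return None
    return bool(np.all(signs == signs[0]))


def consistency_across(
    statistics: Mapping[str, Mapping[str, float]],
    species_labels: Mapping[str, str],
) -> ConsistencyReport:
    """Sign agreement of each feature's statistic across datasets.

    ``statistics`` maps feature -> {dataset_id -> statistic}; NaNs are
    excluded (counted as missing).  Global consistency requires every
    defined sign to agree; per-species consistency is computed for species
    with at least two datasets carrying a defined statistic, and reported as
    None otherwise.
    """
    report: dict[str, FeatureConsistency] = {}
    for feature, per_ds in statistics.items():
        items = [(ds, v) for ds, v in per_ds.items() if np.isfinite(v)]
        n_missing = len(per_ds) - len(items)
        signs = np.sign([v for _, v in items])
        per_species: dict[str, bool | None] = {}
        for sp in sorted(set(species_labels.values())):
            sp_signs = np.sign(
                [v for ds, v in items if species_labels.get(ds) == sp]
            )
            per_species[sp] = _signs_agree(sp_signs)
        report[feature] = FeatureConsistency(
            consistent_all=_signs_agree(signs),
            per_species=per_species,
            n_datasets=len(items),
            n_missing=n_missing,
        )
    return ConsistencyReport(per_feature=report)


def consistency_from_frame(scores: pd.DataFrame) -> ConsistencyReport:
    """Convenience wrapper taking the tidy frame from :func:`evaluate_features`."""
    stats_map: dict[str, dict[str, float]] = {}
    for row in scores.itertuples(index=False):
        stats_map.setdefault(row.feature, {})[row.dataset] = row.statistic
    species = {row.dataset: row.species for row in scores.itertuples(index=False)}
    return consistency_across(stats_map, species)
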