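"""Manifest-driven orchestration of the full analysis, plus the standard
synthetic fixture constellation.

A manifest (YAML or an in-memory :class:`Manifest`) lists datasets with
metadata and toggles; :func:`run_pipeline` then runs ingest -> normalize ->
grouped preference (PAM 4th-nt + PAM-proximal dinucleotide + k-mer
representation) -> regression/ablation -> contiguous predictor ->
feature importance, writing TSV/JSON outputs and a log that records every
exclusion decision (no pam4 variability, low full-sequence Pearson,
redundancy drops) with counts.  All randomness is keyed by manifest seeds,
and the JSON report is byte-stable across reruns of the same manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .contiguous_predictor import build_kmer_predictor, predict_activity, residual_stats
from .dataset_io import (
    Dataset,
    filter_valid_targets,
    invert_activity,
    load_dataset,
    minmax_scale,
    remove_redundant,
    write_dataset,
)
from .errors import StageError, ValidationError
from .feature_importance import (
    builtin_catalog,
    column_feature,
    consistency_from_frame,
    evaluate_features,
)
from .grouped_preference import (
    PAM4,
    group_mean_by_kmer,
    has_pam4_variability,
    kmer_representation,
    pairwise_group_correlation,
    proximal_window,
)
from .sequence_regression import ablation_quarters
from .synthetic_data import (
    SimulationParams,
    sample_context,
    shrink_context,
    simulate_dataset,
)

logger = logging.getLogger(__name__)


@dataclass
class DatasetEntry:
    path: str
    dataset_id: str
    species: str = ""
    invert_sign: bool = False
    genome: str | None = None
    remove_redundant_with: str | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class Manifest:
    """Datasets plus analysis configuration for one pipeline run."""

    datasets: list[DatasetEntry]
    out_dir: str
    seed: int = 0
    proximal_k: int = 2
    predictor_k: int = 5
    n_splits: int = 10
    train_frac: float = 0.8
    delta: float = 0.1
    exclusion_threshold: float = 0.1
    filters_before_scaling: bool = True
    train_datasets: list[str] = field(default_factory=list)
    min_regression_n: int = 25

    def validate(self) -> None:
        ids = [e.dataset_id for e in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValidationError("dataset_ids must be unique")
        if not self.datasets:
            raise ValidationError("manifest lists no datasets")
        for e in self.datasets:
            if not Path(e.path).exists():
                raise ValidationError(f"dataset file not found: {e.path}")
        for t in self.train_datasets:
            if t not in ids:
                raise ValidationError(f"train dataset {t!r} not in manifest")
        refs = [e.remove_redundant_with for e in self.datasets if e.remove_redundant_with]
        for r in refs:
            if r not in ids:
                raise ValidationError(f"redundancy reference {r!r} not in manifest")


def load_manifest(path: str | Path) -> Manifest:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "datasets" not in raw:
        raise ValidationError(f"{path}: not a manifest (no 'datasets' key)")
    base = Path(path).parent
    entries = []
    for item in raw["datasets"]:
        item = dict(item)
        p = Path(item["path"])
        item["path"] = str(p if p.is_absolute() else base / p)
        if item.get("genome"):
            g = Path(item["genome"])
            item["genome"] = str(g if g.is_absolute() else base / g)
        entries.append(DatasetEntry(**item))
    cfg = dict(raw.get("config", {}))
    out_dir = Path(raw.get("out_dir", cfg.pop("out_dir", "guidescape_out")))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    m = Manifest(datasets=entries, out_dir=str(out_dir), **cfg)
    m.validate()
    return m


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def run_pipeline(manifest: Manifest | str | Path) -> dict:
    """Execute all stages and write the report bundle under ``out_dir``.

    Returns the report dict (also written as ``report.json``).  A failing
    stage raises :class:`StageError` naming the stage; outputs of completed
    stages are preserved on disk.
    """
    if not isinstance(manifest, Manifest):
        manifest = load_manifest(manifest)
    manifest.validate()
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("guidescape")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    report: dict = {
        "version": __version__,
        "seed": manifest.seed,
        "config": {
            "proximal_k": manifest.proximal_k,
            "predictor_k": manifest.predictor_k,
            "n_splits": manifest.n_splits,
            "train_frac": manifest.train_frac,
            "delta": manifest.delta,
            "exclusion_threshold": manifest.exclusion_threshold,
        },
        "exclusions": {"no_pam4_variability": [], "low_pearson": [], "redundancy": {}},
        "datasets": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    logger.error("stage %s FAILED: %s", name, exc)
                    raise StageError(name, exc) from exc
                logger.info("stage %s finished in %.2fs", name, timings[name])

        return _Stage()

    try:
        # ---------------------------------------------------------- ingest
        with stage("ingest"):
            datasets: dict[str, Dataset] = {}
            for e in manifest.datasets:
                d = load_dataset(e.path, dataset_id=e.dataset_id, species=e.species,
                                 meta=e.meta)
                if manifest.filters_before_scaling and e.genome:
                    d = filter_valid_targets(d, e.genome)
                if e.invert_sign:
                    d = invert_activity(d)
                datasets[e.dataset_id] = d
            # redundancy removal against reference datasets (raw scale)
            for e in manifest.datasets:
                if e.remove_redundant_with:
                    d = remove_redundant(
                        datasets[e.dataset_id], datasets[e.remove_redundant_with]
                    )
                    datasets[e.dataset_id] = d
                    report["exclusions"]["redundancy"][e.dataset_id] = {
                        "reference": e.remove_redundant_with,
                        "n_dropped": d.meta.get("n_removed_redundant", 0),
                    }
            for ds_id, d in datasets.items():
                scaled = minmax_scale(d)
                if not manifest.filters_before_scaling:
                    e = next(x for x in manifest.datasets if x.dataset_id == ds_id)
                    if e.genome:
                        scaled = filter_valid_targets(scaled, e.genome)
                datasets[ds_id] = scaled
                report["datasets"][ds_id] = {
                    "n": len(scaled),
                    "species": scaled.species,
                    "n_rejected": scaled.meta.get("n_rejected", 0),
                }
            order = [e.dataset_id for e in manifest.datasets]

        # ------------------------------------------------- pam4 preference
        with stage("pam4_preference"):
            pam4_tables = []
            for ds_id in order:
                d = datasets[ds_id]
                if not has_pam4_variability(d):
                    report["exclusions"]["no_pam4_variability"].append(ds_id)
                    logger.info("excluded %s from pam4 analysis (no variability)", ds_id)
                    continue
                t = group_mean_by_kmer(d, PAM4)
                t.write_tsv(out / f"pam4_groups_{ds_id}.tsv")
                pam4_tables.append(t)
            if len(pam4_tables) >= 2:
                cm = pairwise_group_correlation(pam4_tables)
                cm.write_tsv(out / "pam4_correlation.tsv")
                report["pam4_correlation"] = {
                    "labels": list(cm.labels),
                    "r": cm.r.tolist(),
                }

        # ------------------------------------- proximal k-mer preference
        with stage("proximal_preference"):
            win = proximal_window(manifest.proximal_k)
            tables = []
            rep_rows = {}
            for ds_id in order:
                d = datasets[ds_id]
                t = group_mean_by_kmer(d, win, manifest.proximal_k)
                t.write_tsv(out / f"proximal{manifest.proximal_k}_groups_{ds_id}.tsv")
                tables.append(t)
                rep_rows[ds_id] = kmer_representation(d, 10).tolist()
            if len(tables) >= 2:
                cm = pairwise_group_correlation(tables)
                cm.write_tsv(out / f"proximal{manifest.proximal_k}_correlation.tsv")
                report["proximal_correlation"] = {
                    "labels": list(cm.labels),
                    "k": manifest.proximal_k,
                    "r": cm.r.tolist(),
                }
            report["kmer_representation"] = rep_rows

        # -------------------------------------------- regression/ablation
        with stage("regression"):
            reg_report = {}
            for ds_id in order:
                d = datasets[ds_id]
                if len(d) < manifest.min_regression_n:
                    logger.info("skipped regression for %s (n=%d too small)", ds_id, len(d))
                    continue
                ab = ablation_quarters(
                    d,
                    n_splits=manifest.n_splits,
                    seed=manifest.seed,
                    exclusion_threshold=manifest.exclusion_threshold,
                    train_frac=manifest.train_frac,
                )
                if ab.excluded:
                    report["exclusions"]["low_pearson"].append(ds_id)
                    logger.info(
                        "flagged %s excluded (full-sequence Pearson %.3f < %.3f)",
                        ds_id, ab.full.mean_pearson, manifest.exclusion_threshold,
                    )
                reg_report[ds_id] = {
                    "mean_pearson_full": ab.full.mean_pearson,
                    "sd_pearson_full": ab.full.sd_pearson,
                    "per_split": list(ab.full.per_split_pearson),
                    "excluded": ab.excluded,
                    "quarters": {
                        q: {
                            "mean_pearson_partial": v.mean_pearson_partial,
                            "fraction_of_full": v.fraction_of_full,
                        }
                        for q, v in ab.quarters.items()
                    },
                }
            report["regression"] = reg_report

        # ------------------------------------------- contiguous predictor
        with stage("predictor"):
            train_ids = manifest.train_datasets or [
                max(order, key=lambda i: len(datasets[i]))
            ]
            table = build_kmer_predictor(
                [datasets[i] for i in train_ids], k=manifest.predictor_k
            )
            table.write_tsv(out / f"predictor_k{manifest.predictor_k}.tsv")
            pred_report = {"train_datasets": train_ids, "coverage": table.coverage(),
                           "per_dataset": {}}
            for ds_id in order:
                p = predict_activity(table, datasets[ds_id])
                p.frame.to_csv(out / f"predictions_{ds_id}.tsv", sep="\t", index=False)
                entry = {
                    "pearson": p.pearson,
                    "n": p.n,
                    "n_fallback_suffix": p.n_fallback_suffix,
                    "n_fallback_global": p.n_fallback_global,
                }
                if p.n >= 10:
                    rs = residual_stats(p, delta=manifest.delta)
                    entry.update(
                        skewness=rs.skewness,
                        exceedance_fraction=rs.exceedance_fraction,
                        delta=rs.delta,
                    )
                pred_report["per_dataset"][ds_id] = entry
            report["predictor"] = pred_report

        # ------------------------------------------------ feature importance
        with stage("feature_importance"):
            features = builtin_catalog()
            shared_cols = set.intersection(
                *(set(datasets[i].feature_columns) for i in order)
            ) if order else set()
            features += [column_feature(c) for c in sorted(shared_cols)]
            scores = evaluate_features([datasets[i] for i in order], features)
            scores.to_csv(out / "feature_scores.tsv", sep="\t", index=False)
            consistency = consistency_from_frame(scores)
            consistency.to_frame().to_csv(
                out / "feature_consistency.tsv", sep="\t", index=False
            )
            report["feature_importance"] = {
                f: {
                    "consistent_all": c.consistent_all,
                    "per_species": c.per_species,
                }
                for f, c in consistency.per_feature.items()
            }

        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        logger.info("stage timings: %s", {k: round(v, 3) for k, v in timings.items()})
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


# ------------------------------------------------------------------ fixtures

def generate_fixture_suite(
    seed: int, out_dir: str | Path, n_guides: int = 4000, n_tiny: int = 100
) -> Path:
    """Write the standard synthetic test constellation and return the manifest.

    Contents: 2 species x 2 replicate libraries, one shrunk-context library
    (reduced context impact), one analog of a nuclease-null assay (lower
    p_full: extra requirements attenuate more guides), one library designed
    without T at the four PAM-proximal spacer positions, and one tiny
    (n=``n_tiny``) library; plus ``truth.json`` holding every generator
    parameter (the recovery target) and ``manifest.yaml`` wired to run the
    whole pipeline over them.  All files are deterministic given ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    intrinsic = seed
    map_a = sample_context(species_seed=seed + 1, intrinsic_seed=intrinsic)
    map_b = sample_context(species_seed=seed + 2, intrinsic_seed=intrinsic)
    shrunk = shrink_context(map_a, 0.5)

    spec = [
        ("A1", map_a, dict(n_guides=n_guides, seed=seed + 11)),
        ("A2", map_a, dict(n_guides=n_guides, seed=seed + 12)),
        ("B1", map_b, dict(n_guides=n_guides, seed=seed + 13)),
        ("B2", map_b, dict(n_guides=n_guides, seed=seed + 14)),
        ("A_shrunk", shrunk, dict(n_guides=n_guides, seed=seed + 15)),
        ("A_null", map_a, dict(n_guides=n_guides, seed=seed + 16, p_full=0.3)),
        ("A_noT", map_a, dict(n_guides=n_guides, seed=seed + 17,
                              design_filter="no_T_proximal4")),
        ("A_fixedpam", map_a, dict(n_guides=n_guides, seed=seed + 19,
                                   design_filter="fixed_pam4")),
        ("tiny", map_a, dict(n_guides=n_tiny, seed=seed + 18)),
    ]
    truth = {"seed": seed, "intrinsic_seed": intrinsic,
             "note": "synthetic ground truth for parameter recovery",
             "contexts": {m.species_id: m.to_manifest()
                          for m in (map_a, map_b, shrunk)},
             "datasets": {}}
    entries = []
    for ds_id, cmap, kw in spec:
        params = SimulationParams(**kw)
        d = simulate_dataset(cmap, params, dataset_id=ds_id)
        write_dataset(d, out / f"{ds_id}.tsv")
        truth["datasets"][ds_id] = dict(d.meta)
        entries.append(
            {"path": f"{ds_id}.tsv", "dataset_id": ds_id, "species": cmap.species_id}
        )
    with open(out / "truth.json", "w") as fh:
        json.dump(_jsonable(truth), fh, indent=2, sort_keys=True)
    manifest = {
        "out_dir": "results",
        "datasets": entries,
        "config": {
            "seed": seed,
            "train_datasets": ["A1"],
        },
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
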