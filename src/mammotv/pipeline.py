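"""End-to-end experiment orchestration and the ablation harness.

A full run executes: patches (synthetic or MIAS-style directory) -> three
frozen CNN branches -> stage-1 TV per block -> fusion -> stage-2 TV ->
nested subset sweep -> MSVM evaluation, for every requested tissue subset
(D / F / G / All) and training fraction (70 / 80 / 90 %), logging the
8192 -> 3500 -> 600 column progression.

The ablation harness re-runs the pipeline with exactly one component
removed while the others stay fixed: one study per dropped backbone (the two
remaining blocks are fused and reduced to 600 columns) plus one study that
drops the TV cascade entirely (all 8192 raw features go straight to the
MSVM), alongside the unmodified baseline.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .backbones import (
    BACKBONE_NAMES,
    BackboneSpec,
    FeatureMatrix,
    default_specs,
    extract_all,
    extract_features,
)
from .errors import ConfigurationError, MammoTVError, ValidationError
from .evaluate import EvalReport, SplitSpec, SvmConfig, evaluate_split, split_dataset
from .mias import Patch, load_patches
from .synthetic import SyntheticSpec, generate_patches
from .tv import SelectionPlan, rank, select_top_k, stage1_select, stage2_select, subset_slices

__all__ = [
    "PipelineConfig",
    "RunRecord",
    "run_full",
    "run_single_cnn",
    "run_ablation",
    "write_reports",
    "ABLATION_STUDIES",
]

TISSUE_SUBSETS = ("D", "F", "G", "All")
ABLATION_STUDIES = ("wo_inception_v3", "wo_resnet50", "wo_alexnet", "wo_tv")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a run bit-identically."""

    data_dir: Optional[str] = None  # MIAS-style directory; None -> synthetic
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    patch_side: int = 256
    normals_per_image: int = 1
    backbones: tuple[BackboneSpec, ...] = field(default_factory=default_specs)
    plan: SelectionPlan = field(default_factory=SelectionPlan)
    svm: SvmConfig = field(default_factory=SvmConfig)
    train_fractions: tuple[float, ...] = (0.70, 0.80, 0.90)
    tissues: tuple[str, ...] = ("All",)
    seed: int = 0

    def validate(self) -> None:
        if len(self.backbones) != 3 or sorted(s.name for s in self.backbones) != sorted(
            BACKBONE_NAMES
        ):
            raise ConfigurationError(
                "default mode requires exactly the three standard backbones"
            )
        if not self.tissues:
            raise ConfigurationError("tissue filter must be non-empty")
        for t in self.tissues:
            if t not in TISSUE_SUBSETS:
                raise ConfigurationError(f"unknown tissue subset {t!r}")
        for f in self.train_fractions:
            if not 0.0 < f < 1.0:
                raise ConfigurationError(f"train fraction {f} outside (0, 1)")
        self.plan.validate()
        if self.data_dir is None:
            self.synthetic.validate()

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Copy with both the split seed and the synthetic-data seed set."""
        return replace(self, seed=seed, synthetic=replace(self.synthetic, seed=seed))

    def to_dict(self) -> dict:
        return {
            "data_dir": self.data_dir,
            "synthetic": {
                "counts": {f"{t}:{c}": n for (t, c), n in self.synthetic.counts.items()},
                "patch_side": self.synthetic.patch_side,
                "separability": self.synthetic.separability,
                "seed": self.synthetic.seed,
            },
            "patch_side": self.patch_side,
            "normals_per_image": self.normals_per_image,
            "backbones": [dataclasses.asdict(s) for s in self.backbones],
            "plan": {
                "stage1_counts": dict(self.plan.stage1_counts),
                "fusion_order": list(self.plan.fusion_order),
                "stage2_count": self.plan.stage2_count,
                "subset_steps": list(self.plan.subset_steps),
            },
            "svm": dataclasses.asdict(self.svm),
            "train_fractions": list(self.train_fractions),
            "tissues": list(self.tissues),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs: dict = {}
        if "data_dir" in d:
            kwargs["data_dir"] = d["data_dir"]
        syn = dict(d.get("synthetic", {}))
        syn_kwargs: dict = {}
        if "counts" in syn:
            counts = {}
            for key, n in syn["counts"].items():
                tissue, cls_ = key.split(":")
                counts[(tissue, cls_)] = int(n)
            syn_kwargs["counts"] = counts
        for k in ("patch_side", "separability", "seed"):
            if k in syn:
                syn_kwargs[k] = syn[k]
        kwargs["synthetic"] = SyntheticSpec(**syn_kwargs)
        for k in ("patch_side", "normals_per_image", "seed"):
            if k in d:
                kwargs[k] = d[k]
        if "backbones" in d:
            kwargs["backbones"] = tuple(BackboneSpec(**b) for b in d["backbones"])
        if "plan" in d:
            p = d["plan"]
            kwargs["plan"] = SelectionPlan(
                stage1_counts=dict(p.get("stage1_counts", {"inception_v3": 1500, "resnet50": 600, "alexnet": 1400})),
                fusion_order=tuple(p.get("fusion_order", ("inception_v3", "resnet50", "alexnet"))),
                stage2_count=int(p.get("stage2_count", 600)),
                subset_steps=tuple(p.get("subset_steps", (100, 200, 300, 400, 500, 600))),
            )
        if "svm" in d:
            kwargs["svm"] = SvmConfig(**d["svm"])
        if "train_fractions" in d:
            kwargs["train_fractions"] = tuple(float(f) for f in d["train_fractions"])
        if "tissues" in d:
            kwargs["tissues"] = tuple(d["tissues"])
        config = cls(**kwargs)
        if "seed" in d and "synthetic" not in d:
            config = config.with_seed(int(d["seed"]))
        return config


@dataclass
class RunRecord:
    """Config snapshot, stage-wise column counts, reports, and the run log."""

    config: dict
    stage_counts: dict[str, int]
    reports: list[EvalReport]
    seed: int
    log: list[str] = field(default_factory=list)
    wall_seconds: float = 0.0  # informational; excluded from to_dict

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "stage_counts": dict(self.stage_counts),
            "reports": [r.to_dict() for r in self.reports],
            "seed": self.seed,
            "log": list(self.log),
        }


def _stage(name: str, exc: Exception) -> MammoTVError:
    if isinstance(exc, MammoTVError):
        return type(exc)(f"[stage {name}] {exc}")
    return MammoTVError(f"[stage {name}] {exc}")


def _load_pipeline_patches(config: PipelineConfig) -> list[Patch]:
    try:
        if config.data_dir is not None:
            return load_patches(
                config.data_dir,
                patch_side=config.patch_side,
                seed=config.seed,
                normals_per_image=config.normals_per_image,
            )
        return generate_patches(config.synthetic)
    except Exception as exc:
        raise _stage("data", exc) from exc


def _tissue_indices(patches: Sequence[Patch], tissue: str) -> list[int]:
    if tissue == "All":
        return list(range(len(patches)))
    return [i for i, p in enumerate(patches) if p.tissue == tissue]


def _evaluate_sweep(
    subsets: Mapping[int, FeatureMatrix],
    patches: Sequence[Patch],
    config: PipelineConfig,
    tissue: str,
) -> list[EvalReport]:
    labels = [p.label for p in patches]
    reports: list[EvalReport] = []
    for fraction in config.train_fractions:
        try:
            train_idx, test_idx = split_dataset(patches, SplitSpec(fraction, seed=config.seed))
        except Exception as exc:
            raise _stage("split", exc) from exc
        for width, fm in subsets.items():
            try:
                reports.append(
                    evaluate_split(
                        fm.values, labels, train_idx, test_idx, config.svm,
                        tissue=tissue, train_fraction=fraction, seed=config.seed,
                        subset_width=width,
                    )
                )
            except Exception as exc:
                raise _stage("classify", exc) from exc
    return reports


def run_full(
    config: PipelineConfig,
    *,
    patches: Optional[Sequence[Patch]] = None,
    blocks: Optional[Mapping[str, FeatureMatrix]] = None,
) -> RunRecord:
    """Execute the complete pipeline for every tissue subset and fraction.

    ``patches``/``blocks`` may be supplied to reuse an earlier extraction
    (they must correspond to this config); otherwise they are produced here.
    """
    t0 = time.perf_counter()
    config.validate()
    log: list[str] = []
    if patches is None:
        patches = _load_pipeline_patches(config)
    log.append(f"patches: {len(patches)} (seed {config.seed})")
    if blocks is None:
        try:
            blocks = extract_all(patches, config.backbones)
        except Exception as exc:
            raise _stage("extract", exc) from exc
    raw_width = sum(b.n_cols for b in blocks.values())
    log.append(f"raw features: {raw_width} = " +
               " + ".join(f"{n}:{blocks[n].n_cols}" for n in config.plan.fusion_order))
    stage_counts = {"raw": raw_width, "stage1": 0, "stage2": 0}
    reports: list[EvalReport] = []
    for tissue in config.tissues:
        idx = _tissue_indices(patches, tissue)
        if not idx:
            raise ValidationError(f"tissue subset {tissue!r} selects no patches")
        sub_blocks = {n: b.subset_rows(idx) for n, b in blocks.items()}
        try:
            fused = stage1_select(sub_blocks, config.plan)
            selected = stage2_select(fused, config.plan)
            subsets = subset_slices(selected, config.plan)
        except Exception as exc:
            raise _stage("select", exc) from exc
        stage_counts["stage1"] = fused.n_cols
        stage_counts["stage2"] = selected.n_cols
        log.append(
            f"tissue {tissue}: {raw_width} -> {fused.n_cols} -> {selected.n_cols} columns"
        )
        reports.extend(
            _evaluate_sweep(subsets, [patches[i] for i in idx], config, tissue)
        )
    record = RunRecord(
        config=config.to_dict(),
        stage_counts=stage_counts,
        reports=reports,
        seed=config.seed,
        log=log,
        wall_seconds=time.perf_counter() - t0,
    )
    return record


def run_single_cnn(
    config: PipelineConfig,
    backbone: str,
    *,
    patches: Optional[Sequence[Patch]] = None,
    block: Optional[FeatureMatrix] = None,
) -> RunRecord:
    """Single-branch variant: one backbone -> TV top-k -> MSVM."""
    t0 = time.perf_counter()
    config.validate()
    if backbone not in BACKBONE_NAMES:
        raise ConfigurationError(f"unknown backbone {backbone!r}")
    spec = next(s for s in config.backbones if s.name == backbone)
    if patches is None:
        patches = _load_pipeline_patches(config)
    if block is None:
        try:
            block = extract_features(patches, spec)
        except Exception as exc:
            raise _stage("extract", exc) from exc
    k = config.plan.stage1_counts[backbone]
    log = [f"patches: {len(patches)}", f"{backbone}: {block.n_cols} -> {k} columns"]
    reports: list[EvalReport] = []
    stage_counts = {"raw": block.n_cols, "stage1": k}
    for tissue in config.tissues:
        idx = _tissue_indices(patches, tissue)
        sub = block.subset_rows(idx)
        try:
            selected = select_top_k(rank(sub), k)
        except Exception as exc:
            raise _stage("select", exc) from exc
        reports.extend(
            _evaluate_sweep({k: selected}, [patches[i] for i in idx], config, tissue)
        )
    return RunRecord(
        config=config.to_dict(),
        stage_counts=stage_counts,
        reports=reports,
        seed=config.seed,
        log=log,
        wall_seconds=time.perf_counter() - t0,
    )


def run_ablation(
    config: PipelineConfig,
    *,
    patches: Optional[Sequence[Patch]] = None,
    blocks: Optional[Mapping[str, FeatureMatrix]] = None,
) -> dict[str, RunRecord]:
    """Baseline plus the four single-component-removal studies.

    Studies: ``wo_<backbone>`` for each of the three branches (the two
    remaining blocks are fused and reduced to 600 columns by TV) and
    ``wo_tv`` (all raw features straight to the MSVM).  Each study runs at
    every configured tissue subset and training fraction; no subset sweep —
    the classifier sees the study's final width.
    """
    t0 = time.perf_counter()
    config.validate()
    if patches is None:
        patches = _load_pipeline_patches(config)
    if blocks is None:
        try:
            blocks = extract_all(patches, config.backbones)
        except Exception as exc:
            raise _stage("extract", exc) from exc

    def study_record(study: str) -> RunRecord:
        reports: list[EvalReport] = []
        log: list[str] = [f"study: {study}"]
        stage_counts: dict[str, int] = {}
        for tissue in config.tissues:
            idx = _tissue_indices(patches, tissue)
            sub_patches = [patches[i] for i in idx]
            sub_blocks = {n: b.subset_rows(idx) for n, b in blocks.items()}
            try:
                if study == "baseline":
                    plan = config.plan
                    fused = stage1_select(sub_blocks, plan)
                    final = stage2_select(fused, plan)
                    stage_counts = {"raw": sum(b.n_cols for b in sub_blocks.values()),
                                    "stage1": fused.n_cols, "stage2": final.n_cols}
                elif study == "wo_tv":
                    final = FeatureMatrix.hstack(
                        [sub_blocks[n] for n in config.plan.fusion_order]
                    )
                    stage_counts = {"raw": final.n_cols}
                else:
                    dropped = study[len("wo_"):]
                    plan = config.plan.without(dropped)
                    kept = {n: sub_blocks[n] for n in plan.fusion_order}
                    fused = stage1_select(kept, plan)
                    final = stage2_select(fused, plan)
                    stage_counts = {"raw": sum(b.n_cols for b in kept.values()),
                                    "stage1": fused.n_cols, "stage2": final.n_cols}
            except Exception as exc:
                raise _stage(f"select[{study}]", exc) from exc
            log.append(f"tissue {tissue}: classifier width {final.n_cols}")
            reports.extend(
                _evaluate_sweep({final.n_cols: final}, sub_patches, config, tissue)
            )
        return RunRecord(
            config=config.to_dict(),
            stage_counts=stage_counts,
            reports=reports,
            seed=config.seed,
            log=log,
            wall_seconds=time.perf_counter() - t0,
        )

    return {study: study_record(study) for study in ("baseline",) + ABLATION_STUDIES}


def _accuracy_table(reports: Sequence[EvalReport]) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "tissue": r.tissue,
            "train_fraction": r.train_fraction,
            "subset_width": r.subset_width,
            "accuracy": round(r.accuracy, 2),
        }
        for r in reports
    )
    pivot = frame.pivot_table(
        index=["train_fraction", "subset_width"], columns="tissue", values="accuracy"
    )
    cols = [t for t in TISSUE_SUBSETS if t in pivot.columns]
    pivot = pivot[cols]
    per_tissue = [t for t in ("D", "F", "G") if t in pivot.columns]
    if per_tissue:
        pivot["Avg_CA_DFG"] = pivot[per_tissue].mean(axis=1).round(2)
    pivot["Avg_CA_all_subsets"] = pivot[cols].mean(axis=1).round(2)
    return pivot


def write_reports(record: RunRecord, directory) -> list[Path]:
    """Persist a run: JSON record, metric/confusion CSV tables, text log."""
    if not record.reports:
        raise ValidationError("record contains no reports to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    record_path = directory / "run_record.json"
    record_path.write_text(json.dumps(record.to_dict(), indent=2))
    paths.append(record_path)

    rows = []
    for r in record.reports:
        row = {
            "tissue": r.tissue,
            "train_fraction": r.train_fraction,
            "subset_width": r.subset_width,
            "accuracy": round(r.accuracy, 2),
            "n_train": r.n_train,
            "n_test": r.n_test,
        }
        for metric, v in r.macro.items():
            row[f"macro_{metric}"] = round(v, 2) if not np.isnan(v) else ""
        for cls, metrics in r.per_class.items():
            for metric, v in metrics.items():
                row[f"{cls}_{metric}"] = round(v, 2) if not np.isnan(v) else ""
        rows.append(row)
    metrics_path = directory / "metrics.csv"
    pd.DataFrame(rows).to_csv(metrics_path, index=False)
    paths.append(metrics_path)

    acc_path = directory / "accuracy_table.csv"
    _accuracy_table(record.reports).to_csv(acc_path)
    paths.append(acc_path)

    for r in record.reports:
        name = f"confusion_{r.tissue}_{int(round(r.train_fraction * 100))}_{r.subset_width}.csv"
        cm_path = directory / name
        pd.DataFrame(
            r.confusion.counts,
            index=[f"true_{c}" for c in r.confusion.class_order],
            columns=[f"pred_{c}" for c in r.confusion.class_order],
        ).to_csv(cm_path)
        paths.append(cm_path)

    log_path = directory / "log.txt"
    log_path.write_text("\n".join(record.log) + "\n")
    paths.append(log_path)
    return paths
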