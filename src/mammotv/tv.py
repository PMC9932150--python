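"""Term-Variance (TV) feature selection and the two-stage selection cascade.

TV is an unsupervised filter score: the population variance of each feature
(column) across the N patches,

    TV(f_j) = Var(f_j) = (1/N) * sum_i (f_ij - fbar_j)^2 ,

with divisor N (not N-1).  High-variance features are ranked as more
discriminative.  The cascade applies TV twice:

* **stage 1** — per backbone block, keep the top-k columns
  (defaults 1500 / 600 / 1400 for inception_v3 / resnet50 / alexnet), then
  concatenate the blocks into one fused matrix (default width 3500);
* **stage 2** — recompute TV on the fused matrix and keep the top 600.

The stage-2 ranking also defines nested rank-prefix subsets (default widths
100, 200, ..., 600) for the classifier sweep.  Ties in the score are broken
by ascending original column index, which makes every ranking deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .backbones import EXPECTED_DIMS, FeatureMatrix
from .errors import AlignmentError, ConfigurationError, ValidationError

__all__ = [
    "TVRanking",
    "SelectionPlan",
    "tv_scores",
    "rank",
    "select_top_k",
    "stage1_select",
    "stage2_select",
    "subset_slices",
]


@dataclass
class TVRanking:
    """Per-column TV scores plus the induced total order over columns."""

    scores: np.ndarray  # (M,) all >= 0
    order: np.ndarray  # permutation of column indices, score-descending
    source: FeatureMatrix

    def __post_init__(self) -> None:
        if sorted(self.order.tolist()) != list(range(len(self.scores))):
            raise ValidationError("order is not a permutation of the column indices")
        ordered = self.scores[self.order]
        if np.any(np.diff(ordered) > 0):
            raise ValidationError("scores along the ranking order must be non-increasing")


@dataclass(frozen=True)
class SelectionPlan:
    """Counts for the two-stage cascade and the classifier subset sweep."""

    stage1_counts: Mapping[str, int] = field(
        default_factory=lambda: {"inception_v3": 1500, "resnet50": 600, "alexnet": 1400}
    )
    fusion_order: tuple[str, ...] = ("inception_v3", "resnet50", "alexnet")
    stage2_count: int = 600
    subset_steps: tuple[int, ...] = (100, 200, 300, 400, 500, 600)

    def validate(self) -> None:
        for name, k in self.stage1_counts.items():
            if name in EXPECTED_DIMS and k > EXPECTED_DIMS[name]:
                raise ConfigurationError(
                    f"stage1 count {k} for {name} exceeds its block width {EXPECTED_DIMS[name]}"
                )
            if k < 1:
                raise ConfigurationError(f"stage1 count for {name} must be >= 1, got {k}")
        if set(self.fusion_order) != set(self.stage1_counts):
            raise ConfigurationError("fusion_order must list exactly the stage1_counts backbones")
        if self.stage2_count > sum(self.stage1_counts.values()):
            raise ConfigurationError("stage2_count exceeds the fused width")
        steps = list(self.subset_steps)
        if steps != sorted(steps) or len(set(steps)) != len(steps):
            raise ConfigurationError("subset_steps must be strictly ascending")
        if steps and steps[-1] > self.stage2_count:
            raise ConfigurationError("largest subset step exceeds stage2_count")

    def without(self, backbone: str) -> "SelectionPlan":
        """Plan for an ablation run that drops one backbone block."""
        if backbone not in self.stage1_counts:
            raise ConfigurationError(f"{backbone!r} is not part of this plan")
        counts = {k: v for k, v in self.stage1_counts.items() if k != backbone}
        order = tuple(n for n in self.fusion_order if n != backbone)
        return SelectionPlan(
            stage1_counts=counts,
            fusion_order=order,
            stage2_count=min(self.stage2_count, sum(counts.values())),
            subset_steps=self.subset_steps,
        )


def tv_scores(features: FeatureMatrix) -> np.ndarray:
    """Population variance of each column (divisor N)."""
    if features.n_rows < 1:
        raise ValidationError("tv_scores requires at least one row")
    # FeatureMatrix construction already rejects non-finite values
    return np.var(features.values.astype(np.float64), axis=0)


def rank(features: FeatureMatrix) -> TVRanking:
    """Rank columns by TV score, descending; ties by ascending column index."""
    scores = tv_scores(features)
    order = np.lexsort((np.arange(scores.size), -scores))
    return TVRanking(scores=scores, order=order, source=features)


def select_top_k(ranking: TVRanking, k: int) -> FeatureMatrix:
    """The k highest-TV columns, in ranking order, provenance preserved."""
    m = len(ranking.scores)
    if not 1 <= k <= m:
        raise ValidationError(f"k must be in [1, {m}], got {k}")
    return ranking.source.select_columns(ranking.order[:k])


def stage1_select(
    blocks: Mapping[str, FeatureMatrix], plan: SelectionPlan
) -> FeatureMatrix:
    """Per-backbone TV top-k, then concatenation in ``plan.fusion_order``."""
    plan.validate()
    if set(blocks) != set(plan.fusion_order):
        raise ConfigurationError(
            f"blocks {sorted(blocks)} do not match plan backbones {sorted(plan.fusion_order)}"
        )
    ids = None
    selected = []
    for name in plan.fusion_order:
        block = blocks[name]
        if ids is None:
            ids = block.row_ids
        elif block.row_ids != ids:
            raise AlignmentError(f"block {name!r} rows are not aligned with the others")
        k = plan.stage1_counts[name]
        if k > block.n_cols:
            raise ConfigurationError(
                f"stage1 count {k} for {name} exceeds its block width {block.n_cols}"
            )
        selected.append(select_top_k(rank(block), k))
    return FeatureMatrix.hstack(selected)


def stage2_select(fused: FeatureMatrix, plan: SelectionPlan) -> FeatureMatrix:
    """Fresh TV ranking on the fused matrix; keep the top ``stage2_count``."""
    if fused.n_cols < plan.stage2_count:
        raise ValidationError(
            f"fused width {fused.n_cols} is smaller than stage2_count {plan.stage2_count}"
        )
    return select_top_k(rank(fused), plan.stage2_count)


def subset_slices(
    selected: FeatureMatrix, plan: SelectionPlan
) -> dict[int, FeatureMatrix]:
    """Nested rank-prefix subsets of the stage-2 output, one per sweep step."""
    out: dict[int, FeatureMatrix] = {}
    for step in plan.subset_steps:
        if step > selected.n_cols:
            raise ValidationError(
                f"subset step {step} exceeds the selected width {selected.n_cols}"
            )
        out[step] = selected.select_columns(range(step))
    return out
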