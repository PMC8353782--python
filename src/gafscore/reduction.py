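"""Empirically driven item-reduction pipeline.

Stage A removes local dependence: fit a (pooled) graded response model,
and while any item shows residual correlations beyond the threshold,
remove the worst offender and re-fit.  Stage B removes practically
significant between-group DIF: run the iterative Wald procedure and, while
any item's wABC exceeds the threshold, remove the largest and re-run.
Each removal is logged in a trace that fully determines the final bank.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import ResponseMatrix
from .dif import iterative_wald_dif
from .estimation import _coerce_matrix, fit_grm
from .fitstats import limited_info_fit

__all__ = ["ReductionStage", "ReductionTrace", "item_reduction_pipeline"]


@dataclasses.dataclass(frozen=True)
class ReductionStage:
    action: str          # "residual_removal" or "dif_removal"
    item: object
    criterion: float     # worst residual |r| or wABC
    threshold: float


@dataclasses.dataclass
class ReductionTrace:
    stages: list
    final_items: list

    def removed(self) -> list:
        return [s.item for s in self.stages]


def _worst_residual_item(resid: np.ndarray, items, threshold: float):
    """Item with the most |r| > threshold violations (ties: largest |r|)."""
    viol = np.abs(resid) > threshold
    counts = viol.sum(axis=1)
    if counts.max() == 0:
        return None, 0.0
    worst_abs = np.abs(resid).max(axis=1)
    order = np.lexsort((worst_abs, counts))
    j = order[-1]
    return items[j], float(worst_abs[j])


def item_reduction_pipeline(
    data,
    groups=None,
    resid_threshold: float = 0.1,
    wabc_threshold: float = 0.30,
    reference=None,
    min_items: int = 4,
    **dif_kwargs,
) -> tuple[ReductionTrace, list]:
    """Run residual screening then DIF screening; returns (trace, bank).

    ``data`` is a two-group response matrix; stage A fits pooled
    single-group models, stage B runs the iterative Wald DIF analysis
    between the two groups.
    """
    rm = _coerce_matrix(data, groups)
    if rm.J < min_items:
        raise ValueError(f"need at least {min_items} items")
    current = rm
    stages: list[ReductionStage] = []

    # stage A: local-dependence cleanup on the pooled sample
    while True:
        model = fit_grm(ResponseMatrix(current.values, current.items, None))
        fs = limited_info_fit(model)
        item, worst = _worst_residual_item(
            fs.residual_correlations, current.items, resid_threshold
        )
        if item is None:
            break
        stages.append(
            ReductionStage("residual_removal", item, worst, resid_threshold)
        )
        keep = [l for l in current.items if l != item]
        if len(keep) < min_items:
            raise RuntimeError(
                f"residual screening would leave < {min_items} items; "
                f"trace so far: {stages}"
            )
        current = current.subset_items(keep)

    # stage B: DIF cleanup between the two groups
    if current.group is not None and len(set(current.group.tolist())) == 2:
        while True:
            res = iterative_wald_dif(current, reference=reference, **dif_kwargs)
            worst = max(res.items, key=lambda it: it.wabc)
            if worst.wabc <= wabc_threshold:
                break
            stages.append(
                ReductionStage("dif_removal", worst.item, worst.wabc,
                               wabc_threshold)
            )
            keep = [l for l in current.items if l != worst.item]
            if len(keep) < min_items:
                raise RuntimeError(
                    f"DIF screening would leave < {min_items} items; "
                    f"trace so far: {stages}"
                )
            current = current.subset_items(keep)

    final_model = fit_grm(ResponseMatrix(current.values, current.items, None))
    return ReductionTrace(stages=stages, final_items=list(current.items)), \
        final_model.items_
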