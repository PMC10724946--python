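"""Recovery metrics against the generator's planted ground truth."""

from __future__ import annotations

from collections.abc import Iterable

from sklearn.metrics import adjusted_rand_score

from .network import ModuleHierarchy
from .simulate import PlantedTruth

__all__ = ["module_recovery_ari", "set_precision_recall", "jaccard"]


def module_recovery_ari(
    hierarchy: ModuleHierarchy,
    truth: PlantedTruth,
    cohort: str,
    alpha: float = 1.0,
) -> float:
    """Adjusted Rand index of detected vs planted module labels.

    Evaluated over the genes belonging to planted modules active in the
    cohort; a planted gene absent from every detected module counts as
    its own singleton cluster (penalizing dropped genes).
    """
    labels = truth.module_labels(cohort)
    if not labels:
        raise ValueError(f"no planted modules active in cohort {cohort!r}")
    pred = {g: m for m, gs in hierarchy.modules_at(alpha).items() for g in gs}
    genes = sorted(labels)
    y_true = [labels[g] for g in genes]
    y_pred = [pred.get(g, f"__unassigned_{g}") for g in genes]
    return float(adjusted_rand_score(y_true, y_pred))


def set_precision_recall(called: Iterable[str], truth: Iterable[str]
                         ) -> tuple[float, float]:
    called, truth = set(called), set(truth)
    tp = len(called & truth)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(truth) if truth else 0.0
    return precision, recall


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    a, b = set(a), set(b)
    union = a | b
    return len(a & b) / len(union) if union else 0.0
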