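"""Scoring suggested annotations against gold annotations.

Two complementary views of quality:

* the set F-score (exact-identity precision/recall) — strict, gives no
  credit for proposing a parent or sibling of a gold concept;
* the semantic score — the BMA-Lin groupwise similarity between suggestion
  and gold, which still credits near-miss concepts.

A parent-for-child substitution therefore hurts the F-score much more than
the semantic score; both are reported per document and macro-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .objective import sim_bma
from .ontology import Ontology, build_sim_matrix

__all__ = [
    "EvaluationResult",
    "set_fscore",
    "semantic_score",
    "evaluate_corpus",
    "paired_ttest",
]


@dataclass(frozen=True)
class EvaluationResult:
    doc_id: str
    precision: float
    recall: float
    fscore: float
    semantic_score: float
    suggested_size: int
    gold_size: int


def set_fscore(
    suggested: frozenset[str], gold: frozenset[str]
) -> tuple[float, float, float]:
    """Precision, recall and F1 under exact concept-identifier identity."""
    if not gold:
        raise ValueError("empty gold annotation")
    inter = len(suggested & gold)
    precision = inter / len(suggested) if suggested else 0.0
    recall = inter / len(gold)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def semantic_score(
    suggested: frozenset[str], gold: frozenset[str], ontology: Ontology
) -> float:
    """BMA-Lin similarity between suggestion and gold, in [0, 1]."""
    if not suggested or not gold:
        raise ValueError("both annotation sets must be non-empty")
    pool = sorted(suggested | gold)
    m = build_sim_matrix(ontology, pool)
    return sim_bma(suggested, gold, m)


def evaluate_corpus(
    results: Sequence[tuple[str, frozenset[str], frozenset[str]]],
    ontology: Ontology,
) -> tuple[pd.DataFrame, dict]:
    """Per-document scores and macro-averages over (doc_id, suggested, gold).

    Macro-averaging (per-document scores, then their mean) keeps the
    per-document vectors needed for paired significance tests between two
    methods.
    """
    if not results:
        raise ValueError("no documents to evaluate")
    rows = []
    for doc_id, suggested, gold in results:
        p, r, f = set_fscore(suggested, gold)
        s = semantic_score(suggested, gold, ontology)
        rows.append(
            EvaluationResult(
                doc_id=doc_id,
                precision=p,
                recall=r,
                fscore=f,
                semantic_score=s,
                suggested_size=len(suggested),
                gold_size=len(gold),
            )
        )
    table = pd.DataFrame([vars(r) for r in rows])
    summary = {
        "n": len(rows),
        "mean_precision": float(table["precision"].mean()),
        "mean_recall": float(table["recall"].mean()),
        "mean_f": float(table["fscore"].mean()),
        "mean_semantic": float(table["semantic_score"].mean()),
        "mean_suggested_size": float(table["suggested_size"].mean()),
        "median_suggested_size": float(table["suggested_size"].median()),
    }
    return table, summary


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Two-sided paired t-test p-value with a zero-variance guard.

    When every per-document difference is zero the methods are identical and
    p = 1; a constant non-zero difference gives p = 0.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs two equal-length score vectors (n >= 2)")
    diff = a - b
    if np.allclose(diff.std(), 0.0):
        return 1.0 if np.allclose(diff, 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)
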