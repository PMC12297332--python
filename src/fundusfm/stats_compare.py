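"""Paired-bootstrap model comparison: bootstrap the test set 100 times with
the same index sets for every model, report the median AUC, and test the best
against the second best with a two-sided Wilcoxon signed-rank test across the
paired bootstrap AUCs. Wins and ties are tallied per target without
aggregating p-values across targets, and no confidence intervals are
produced (bootstrap AUCs of different models share the resampling noise, so
interval overlap is not meaningful).

Zero paired differences are discarded (the classic signed-rank convention);
if every difference is zero the comparison is a tie with p = 1. Resamples are
plain with-replacement draws at full test-set size; a resample that lacks one
of the classes is redrawn.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon as _wilcoxon
from sklearn.metrics import roc_auc_score

__all__ = [
    "BootstrapAUCs",
    "ComparisonResult",
    "bootstrap_auc",
    "wilcoxon_signed_rank",
    "compare_best_vs_second",
    "tally_wins",
]


@dataclass
class BootstrapAUCs:
    aucs: np.ndarray  # [n_boot x n_models]
    model_names: list[str]
    seed: int

    @property
    def n_boot(self) -> int:
        return self.aucs.shape[0]

    def median(self) -> dict[str, float]:
        med = np.median(self.aucs, axis=0)
        return dict(zip(self.model_names, med.tolist()))


@dataclass
class ComparisonResult:
    best: str
    second: str
    p_value: float
    verdict: str  # "win" iff p < alpha else "tie"
    alpha: float
    median_auc: dict[str, float]


def bootstrap_auc(scores: dict[str, np.ndarray], labels, n_boot: int = 100,
                  seed: int = 0) -> BootstrapAUCs:
    """Per-model AUCs on `n_boot` shared with-replacement resamples of the
    test set (identical index sets across models, enabling the paired test)."""
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("test set must contain both classes")
    names = list(scores)
    cols = [np.asarray(scores[m], dtype=float) for m in names]
    n = labels.size
    for c in cols:
        if c.size != n:
            raise ValueError("score vector length must match labels")
    rng = np.random.default_rng(seed)
    aucs = np.empty((n_boot, len(names)))
    for b in range(n_boot):
        for attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            if np.unique(labels[idx]).size == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample "
                               "after 1000 attempts")
        y = labels[idx]
        for j, c in enumerate(cols):
            aucs[b, j] = roc_auc_score(y, c[idx])
    return BootstrapAUCs(aucs=aucs, model_names=names, seed=seed)


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples, discarding
    zero differences; p = 1 when all differences are zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.all(d == 0):
        return 1.0
    res = _wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)


def compare_best_vs_second(boot: BootstrapAUCs, alpha: float = 0.05) -> ComparisonResult:
    """Rank models by median bootstrap AUC and test best vs second best."""
    if len(boot.model_names) < 2:
        raise ValueError("need at least two models to compare")
    medians = np.median(boot.aucs, axis=0)
    order = np.argsort(-medians, kind="stable")
    i_best, i_second = order[0], order[1]
    p = wilcoxon_signed_rank(boot.aucs[:, i_best], boot.aucs[:, i_second])
    return ComparisonResult(
        best=boot.model_names[i_best],
        second=boot.model_names[i_second],
        p_value=p,
        verdict="win" if p < alpha else "tie",
        alpha=alpha,
        median_auc=boot.median(),
    )


def tally_wins(results: dict[str, ComparisonResult]) -> dict[str, dict[str, int]]:
    """Per-model statistically-significant win and tie counts over targets
    (one comparison per target; p-values are never aggregated)."""
    wins: Counter = Counter()
    ties: Counter = Counter()
    for res in results.values():
        if res.verdict == "win":
            wins[res.best] += 1
        else:
            ties[res.best] += 1
            ties[res.second] += 1
    models = set(wins) | set(ties)
    for res in results.values():
        models.update(res.median_auc)
    return {m: {"wins": wins.get(m, 0), "ties": ties.get(m, 0)} for m in sorted(models)}
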