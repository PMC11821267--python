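"""Scoring a selected-mediator set against simulation ground truth.

Selection quality is summarized by the confusion counts of selected vs truly
causal taxa and by Recall = TP/(TP+FN), Precision = TP/(TP+FP) and their
harmonic mean F1.  When a method selects nothing (TP+FP = 0) precision and
F1 are undefined; such replicates are excluded from the aggregate means with
a reported count rather than coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .pipeline import CramedConfig, run_cramed, run_naive_cramed
from .simulate import (
    simulate_zinb_dataset, simulate_hurdle_dataset, simulate_confounded_dataset,
)

__all__ = ["MetricsReport", "confusion", "metrics", "run_benchmark"]


@dataclass
class MetricsReport:
    """Aggregated confusion counts and Recall/Precision/F1 over replicates."""

    tp: float
    fp: float
    tn: float
    fn: float
    recall: float
    precision: float
    f1: float
    fdr_level: float
    n_replicates: int
    n_undefined_precision: int = 0
    n_failed: int = 0
    per_replicate: list = field(default_factory=list)


def confusion(selected, truth):
    """2x2 confusion counts (tp, fp, tn, fn) of a selection against truth."""
    s = np.asarray(selected, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape:
        raise ValueError("selected and truth must have equal length")
    tp = int(np.sum(s & t))
    fp = int(np.sum(s & ~t))
    tn = int(np.sum(~s & ~t))
    fn = int(np.sum(~s & t))
    return tp, fp, tn, fn


def metrics(tp, fp, tn, fn):
    """(recall, precision, f1); NaN marks an undefined ratio (empty margin).

    Precision is undefined (NaN) when nothing was selected.  F1 is 0, not
    undefined, whenever no true positive exists but positives do (zero
    recall forces the harmonic mean to its zero limit); it is undefined only
    when there are neither selections nor causal taxa to find.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    recall = tp / (tp + fn) if tp + fn > 0 else np.nan
    precision = tp / (tp + fp) if tp + fp > 0 else np.nan
    if tp > 0:
        f1 = 2 * recall * precision / (recall + precision)
    elif fp + fn > 0:
        f1 = 0.0
    else:
        f1 = np.nan
    return recall, precision, f1


_GENERATORS = {
    "zinb": lambda n, m, seed, kw: simulate_zinb_dataset(n, m, seed),
    "hurdle_poisson": lambda n, m, seed, kw: simulate_hurdle_dataset(n, m, "poisson", seed),
    "hurdle_nb": lambda n, m, seed, kw: simulate_hurdle_dataset(n, m, "nb", seed),
    "confounded": lambda n, m, seed, kw: simulate_confounded_dataset(
        n, m, kw.get("h", 1), kw.get("d", 3), seed),
}


def run_benchmark(n, m, method="cramed", generator="zinb", n_replicates=20,
                  config: Optional[CramedConfig] = None, seed=0,
                  permute_treatment=False, **gen_kwargs) -> MetricsReport:
    """Simulate -> run -> score, replicated.

    Each replicate draws a fresh dataset from ``generator``, runs the chosen
    method with the true simulated log depths as the count-model offset, and
    scores the selected taxa against the generating truth.  With
    ``permute_treatment=True`` the treatment labels are shuffled after
    generation, severing every causal path (a null benchmark: any selection
    is a false positive).  Fully deterministic given ``seed``.
    """
    if method not in ("cramed", "naive"):
        raise ValueError("method must be 'cramed' or 'naive'")
    if generator not in _GENERATORS:
        raise ValueError(f"unknown generator {generator!r}")
    base = config or CramedConfig(B=100, fdr=0.05)
    per = []
    n_undef = 0
    n_failed = 0
    for r in range(n_replicates):
        rep_seed = [seed % (2**31), r]
        data = _GENERATORS[generator](n, m, rep_seed, gen_kwargs)
        T = data.T
        if permute_treatment:
            perm_rng = np.random.default_rng(rep_seed + [104729])
            T = perm_rng.permutation(T)
        from dataclasses import replace as _replace
        cfg = _replace(base, seed=(seed % (2**15)) * 100003 + r,
                       offset_mode="provided", compute_ci=False)
        runner = run_cramed if method == "cramed" else run_naive_cramed
        try:
            res = runner(data.Y, T, data.M, None, cfg, offset=data.log_depth)
        except Exception:
            n_failed += 1
            continue
        tp, fp, tn, fn = confusion(res.selected_mask(m), data.truth)
        rec, prec, f1 = metrics(tp, fp, tn, fn)
        if np.isnan(prec):
            n_undef += 1
        per.append({"tp": tp, "fp": fp, "tn": tn, "fn": fn,
                    "recall": rec, "precision": prec, "f1": f1})
    if not per:
        raise RuntimeError("every replicate failed")

    def _mean(key):
        vals = np.array([p[key] for p in per], dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else np.nan

    return MetricsReport(
        tp=_mean("tp"), fp=_mean("fp"), tn=_mean("tn"), fn=_mean("fn"),
        recall=_mean("recall"), precision=_mean("precision"), f1=_mean("f1"),
        fdr_level=base.fdr, n_replicates=len(per),
        n_undefined_precision=n_undef, n_failed=n_failed, per_replicate=per,
    )
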