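"""Repeated-split benchmarking of tuned estimators.

Each method is tuned by internal cross-validation on the training portion of
every split and scored on the held-out portion; per-split values, summary
means and standard errors, and paired Wilcoxon signed-rank p-values against a
reference method are reported.  Methods can be the built-in penalized-GLM
presets (each a configuration of the same solver), or arbitrary callables —
e.g. predictions produced by an external tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from . import model_selection, solver
from .metrics import auc, pmse, r_squared

__all__ = ["MetricsReport", "benchmark", "METHOD_PRESETS", "make_method"]

#: Built-in method presets: all are configurations of the same penalized-GLM
#: engine.  "sics" = MCP + inverse-correlation penalty; "sls" = MCP +
#: sparsified-Laplacian penalty; "enet"/"mnet" = MCP + ridge (identity
#: structure); "mcp" = sparsity only; "lasso" = sparsity only with a huge
#: MCP concavity (soft thresholding).
METHOD_PRESETS = {
    "sics": dict(structure="omega"),
    "sls": dict(structure="laplacian", laplacian_sparsity=0.9),
    "sls0": dict(structure="laplacian", laplacian_sparsity=0.0),
    "enet": dict(structure="identity"),
    "mnet": dict(structure="identity"),
    "mcp": dict(structure="none"),
    "lasso": dict(structure="none", gamma=1e6),
}


@dataclass
class MetricsReport:
    """Per-split metric values, their summary, and paired-test p-values."""

    per_replicate: pd.DataFrame   # columns: split, method, metric, value
    summary: pd.DataFrame         # columns: method, metric, mean, se
    pvalues: pd.DataFrame         # columns: method, metric, p_value (vs reference)
    reference: str


def make_method(preset: str, grid: model_selection.TuningGrid | None = None):
    """Return a tuned-fit callable for a named preset configuration.

    The callable signature is ``(X_train, y_train, X_test, context) ->
    predictions`` where ``context`` carries the distance matrix, family and
    split seed.
    """
    if preset not in METHOD_PRESETS:
        raise KeyError(f"unknown preset {preset!r}; options: {sorted(METHOD_PRESETS)}")
    kw = dict(METHOD_PRESETS[preset])

    def _run(X_tr, y_tr, X_te, context):
        res = model_selection.cross_validate(
            X_tr, y_tr, D=context.get("D"), family=context["family"],
            grid=grid, k=context.get("inner_folds", 5),
            seed=context["seed"], **kw,
        )
        return solver.predict(res.fit, X_te)

    return _run


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value; 1.0 for identical pairs."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.all(d == 0):
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    try:
        return float(stats.wilcoxon(d, method=method, correction=True).pvalue)
    except TypeError:  # exact method disallows correction in some versions
        return float(stats.wilcoxon(d, method=method).pvalue)


def benchmark(
    X: np.ndarray,
    y: np.ndarray,
    methods: dict,
    D=None,
    family: str = "linear",
    n_splits: int = 10,
    split_rule: str = "kfold",
    k: int = 5,
    test_size: float = 0.2,
    seed: int = 0,
    reference: str | None = None,
    inner_folds: int = 5,
) -> MetricsReport:
    """Run the repeated-split comparison harness.

    Parameters
    ----------
    methods : dict
        Name -> preset string or callable ``(X_tr, y_tr, X_te, context) ->
        predictions``.  Needs at least two entries (or one plus the implicit
        null baseline, added automatically as ``"null"``).
    split_rule : {"kfold", "holdout"}
        ``"kfold"`` draws a fresh k-fold partition per repetition and uses
        one fold for testing (k - 1 for training); ``"holdout"`` draws a
        random train/test split of the given test fraction.
    reference : str
        Method name the Wilcoxon tests compare against (default: first).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    resolved = {}
    for name, m in methods.items():
        resolved[name] = make_method(m) if isinstance(m, str) else m
    if len(resolved) < 2:
        def _null(X_tr, y_tr, X_te, context):
            return np.full(X_te.shape[0], y_tr.mean())
        resolved["null"] = _null
    names = list(resolved)
    if reference is None:
        reference = names[0]
    if reference not in resolved:
        raise KeyError(f"reference {reference!r} not among methods")

    if family == "logistic":
        metric_fns = {"R2": r_squared, "Brier": pmse, "AUC": auc}
    else:
        metric_fns = {"R2": r_squared, "PMSE": pmse}

    rng = np.random.default_rng(seed)
    rows = []
    for split in range(n_splits):
        split_seed = int(rng.integers(0, 2**31 - 1))
        if split_rule == "kfold":
            cls = StratifiedKFold if family == "logistic" else KFold
            folds = cls(n_splits=k, shuffle=True, random_state=split_seed)
            strat = y if family == "logistic" else None
            tr, te = next(iter(folds.split(X, strat)))
        elif split_rule == "holdout":
            strat = y if family == "logistic" else None
            tr, te = train_test_split(
                np.arange(y.size), test_size=test_size,
                random_state=split_seed, stratify=strat,
            )
        else:
            raise ValueError(f"unknown split_rule {split_rule!r}")
        context = {"D": D, "family": family, "seed": split_seed,
                   "inner_folds": inner_folds}
        for name in names:
            pred = np.asarray(resolved[name](X[tr], y[tr], X[te], context))
            for mname, fn in metric_fns.items():
                rows.append((split, name, mname, float(fn(y[te], pred))))

    per_rep = pd.DataFrame(rows, columns=["split", "method", "metric", "value"])
    summary = (
        per_rep.groupby(["method", "metric"])["value"]
        .agg(mean="mean", se=lambda v: np.std(v, ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    prow = []
    for name in names:
        if name == reference:
            continue
        for mname in metric_fns:
            a = per_rep.query("method == @reference and metric == @mname")
            b = per_rep.query("method == @name and metric == @mname")
            p = _wilcoxon(a.sort_values("split")["value"].to_numpy(),
                          b.sort_values("split")["value"].to_numpy())
            prow.append((name, mname, p))
    pvalues = pd.DataFrame(prow, columns=["method", "metric", "p_value"])
    return MetricsReport(per_replicate=per_rep, summary=summary,
                         pvalues=pvalues, reference=reference)
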