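"""Null-model simulation: uniform levels, uniform classes, no signal.

The generator draws ``n`` rows with ``p`` categorical predictors, each
allocated uniformly with replacement from ``k`` levels, and a response drawn
uniformly from ``n_classes`` (default 3) classes — by construction there is
no relationship between predictors and response. 80% of rows (simple random
sample, unstratified) train a forest; the withheld 20% estimate the true
misclassification rate, which under this balanced null is 2/3 for three
classes regardless of ``n``, ``k`` or encoding.

:func:`run_experiment` sweeps a factorial grid of sample size × level count
× encoding method × encoding timing, recording per replicate the OOB error,
the independent-test error, and the five variable-importance measures. Any
departure of a mean from its null value (2/3 for the errors, 0 for the
importances) is bias introduced by the estimator itself — in particular by
target information leaking through encodings fitted before bagging.

Seeds are hierarchical (master → cell → replicate → tree), so any replicate
can be regenerated in isolation and a rerun with the same master seed is
bit-identical.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .forest import ForestParams, fit_forest
from .importance import (
    air_importance,
    holdout_importance,
    mda_importance,
    mdi_importance,
    oob_error,
    test_error,
)

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "generate_null_dataset",
    "run_experiment",
    "summarize",
    "plot_summary",
]

logger = logging.getLogger(__name__)

ALL_VIMS = ("MDI", "MDA", "AIR", "Holdout", "IndependentHoldout")

CELL_COLS = ["n", "k", "p", "encoding", "timing"]


@dataclass(frozen=True)
class SimulationConfig:
    """Factorial design of the null experiment.

    Defaults are the full study conditions: 99 replicates of 500-tree forests
    over n ∈ {20,…,400} and k ∈ {1,…,200} with a single predictor and three
    equiprobable classes. :meth:`reduced` gives a small profile for quick
    runs.
    """

    n_grid: tuple[int, ...] = (20, 50, 100, 150, 200, 400)
    k_grid: tuple[int, ...] = (1, 5, 10, 35, 50, 100, 150, 200)
    p: int = 1
    n_classes: int = 3
    train_frac: float = 0.8
    replicates: int = 99
    forest: ForestParams = field(default_factory=lambda: ForestParams(n_trees=500))
    encodings: tuple[str, ...] = ("integer_alpha", "target_pca")
    timing: tuple[str, ...] = ("before_bagging",)
    vims: tuple[str, ...] = ALL_VIMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(v < 1 for v in (*self.n_grid, *self.k_grid, self.p)):
            raise ValueError("grid values must be positive")
        unknown = set(self.vims) - set(ALL_VIMS)
        if unknown:
            raise ValueError(f"unknown importance methods: {sorted(unknown)}")

    @classmethod
    def reduced(cls, **overrides) -> "SimulationConfig":
        """Small profile: n ∈ {50,100}, k ∈ {5,50,200}, 20 × 200-tree forests."""
        base = dict(
            n_grid=(50, 100),
            k_grid=(5, 50, 200),
            replicates=20,
            forest=ForestParams(n_trees=200),
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["forest"] = asdict(self.forest)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "forest" in d and isinstance(d["forest"], dict):
            d["forest"] = ForestParams(**d["forest"])
        for key in ("n_grid", "k_grid", "encodings", "timing", "vims"):
            if key in d and not isinstance(d[key], tuple):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationSummary:
    """Per-cell replicate means/SDs plus the raw replicate table."""

    summary: pd.DataFrame      # long: cell cols + metric, mean, sd, n_reps
    replicates: pd.DataFrame   # long: cell cols + replicate, metric, value
    config: SimulationConfig


def generate_null_dataset(
    n: int,
    k: int,
    p: int,
    n_classes: int,
    rng: np.random.Generator,
    *,
    train_frac: float = 0.8,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Draw one null dataset and an unstratified train/test split.

    Returns ``(frame, train_idx, test_idx)`` where the frame holds predictor
    columns ``x1..xp`` (string levels ``L001..L{k}``) and response ``y``
    (classes ``c1..c{n_classes}``); ``⌈train_frac·n⌉`` rows train.
    """
    if n < 5:
        raise ValueError("n must be >= 5")
    if k < 1 or p < 1:
        raise ValueError("k and p must be >= 1")
    if n_classes < 2:
        raise ValueError("need at least 2 response classes")
    width = len(str(k))
    levels = np.array([f"L{i + 1:0{width}d}" for i in range(k)], dtype=object)
    classes = np.array([f"c{i + 1}" for i in range(n_classes)], dtype=object)
    cols = {
        f"x{j + 1}": levels[rng.integers(0, k, size=n)] for j in range(p)
    }
    cols["y"] = classes[rng.integers(0, n_classes, size=n)]
    frame = pd.DataFrame(cols)
    n_train = int(np.ceil(train_frac * n))
    perm = rng.permutation(n)
    return frame, np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _replicate_metrics(
    frame: pd.DataFrame,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    params: ForestParams,
    vims: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, float]:
    train = frame.iloc[train_idx].reset_index(drop=True)
    test = frame.iloc[test_idx].reset_index(drop=True)
    forest = fit_forest(train, params, response="y")
    out: dict[str, float] = {
        "oob_error": oob_error(forest),
        "test_error": test_error(forest, test),
    }

    def record(res) -> None:
        out[res.method] = res.mean()
        if len(res.values) > 1:
            for var, v in res.values.items():
                out[f"{res.method}:{var}"] = v

    if "MDI" in vims:
        record(mdi_importance(forest))
    if "MDA" in vims:
        record(mda_importance(forest, rng))
    if "AIR" in vims:
        # shadow candidates alter tree growth, so AIR gets its own forest and
        # the error/MDA/MDI numbers above stay shadow-free
        shadow_forest = fit_forest(train, replace(params, air_shadows=True), response="y")
        record(air_importance(shadow_forest))
    if "Holdout" in vims:
        record(holdout_importance(train, params, rng, encode_per_fold=False))
    if "IndependentHoldout" in vims:
        record(holdout_importance(train, params, rng, encode_per_fold=True))
    return out


def run_experiment(config: SimulationConfig) -> SimulationSummary:
    """Run the full factorial null experiment.

    Cells with ``k = 1`` are retained: the lone level admits no split, so
    every tree is a majority-vote stump; errors remain defined and every
    importance is exactly zero.
    """
    enc_idx = {e: i for i, e in enumerate(config.encodings)}
    tim_idx = {t: i for i, t in enumerate(config.timing)}
    rows = []
    for n, k, enc, tim in itertools.product(
        config.n_grid, config.k_grid, config.encodings, config.timing
    ):
        logger.info("cell n=%d k=%d encoding=%s timing=%s", n, k, enc, tim)
        for rep in range(config.replicates):
            rng = np.random.default_rng(
                [config.seed, n, k, config.p, enc_idx[enc], tim_idx[tim], rep]
            )
            frame, tr, te = generate_null_dataset(
                n, k, config.p, config.n_classes, rng, train_frac=config.train_frac
            )
            params = replace(
                config.forest,
                seed=int(rng.integers(2**31)),
                encoding_method=enc,
                encoding_timing=tim,
                air_shadows=False,
            )
            metrics = _replicate_metrics(frame, tr, te, params, config.vims, rng)
            for metric, value in metrics.items():
                rows.append(
                    dict(
                        n=n, k=k, p=config.p, encoding=enc, timing=tim,
                        replicate=rep, metric=metric, value=value,
                    )
                )
    replicates = pd.DataFrame(rows)
    return SimulationSummary(
        summary=summarize(replicates), replicates=replicates, config=config
    )


def summarize(replicates: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long replicate table to per-cell mean/SD/count."""
    if len(replicates) == 0:
        raise ValueError("no replicate results to summarise")
    g = replicates.groupby(CELL_COLS + ["metric"], sort=True)["value"]
    out = g.agg(mean="mean", sd="std", n_reps="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


def plot_summary(
    summary: pd.DataFrame, metric: str, path: str, *, reference: float | None = None
) -> None:
    """Line plot of a metric vs k, one panel per n, styled by encoding."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[summary["metric"] == metric]
    ns = sorted(sub["n"].unique())
    fig, axes = plt.subplots(1, len(ns), figsize=(3.2 * len(ns), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, n in zip(axes, ns):
        for (enc, tim), grp in sub[sub["n"] == n].groupby(["encoding", "timing"]):
            grp = grp.sort_values("k")
            ax.errorbar(
                grp["k"], grp["mean"], yerr=grp["sd"] / np.sqrt(grp["n_reps"]),
                marker="o", label=f"{enc}/{tim}",
            )
        if reference is not None:
            ax.axhline(reference, ls=":", c="grey")
        ax.set_title(f"n = {n}")
        ax.set_xlabel("k (levels)")
    axes[0].set_ylabel(metric)
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
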