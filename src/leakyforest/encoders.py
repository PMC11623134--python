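"""Ordinal encodings of categorical predictors for tree ensembles.

A nominal predictor with ``k`` levels must be mapped to numbers before a
CART-style threshold split can be searched. Two families of encodings are
provided:

* **target-agnostic** — :func:`fit_integer_encoding` orders levels
  alphabetically; the response is never consulted.
* **target-based** — :func:`fit_target_encoding_twoclass` orders levels by
  the proportion of the second response class within each level (for binary
  responses this makes ordered threshold search equivalent to exhaustive
  search over all level bipartitions); :func:`fit_target_encoding_multiclass`
  orders levels by their projection onto the first principal component of the
  weighted covariance matrix of per-level class-probability vectors.

Every fitted :class:`LevelEncoding` records *where* it was fitted
(``fit_scope``): on the full training set (before bagging), on one tree's
bootstrap sample (after bagging), or on one cross-validation fold. This
provenance is what distinguishes a leaky target encoding (fitted before
bagging, so out-of-bag rows contributed their targets to the level ordering)
from a clean one.

Levels that appear at prediction time but were absent when the encoding was
fitted are handled per ``absent_policy``: ``strict`` raises, while
``majority_child`` (default) emits a NaN sentinel that split routing sends to
the child with more in-bag samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ABSENT_SENTINEL",
    "ClassProbabilityProfile",
    "LevelEncoding",
    "fit_integer_encoding",
    "fit_target_encoding_twoclass",
    "fit_target_encoding_multiclass",
    "class_probability_profiles",
    "apply_encoding",
]

#: Sentinel emitted for absent levels under the ``majority_child`` policy.
#: NaN compares false against every threshold, so routing handles it explicitly.
ABSENT_SENTINEL: float = float("nan")

_METHODS = ("integer_alpha", "target_twoclass", "target_pca")
_POLICIES = ("strict", "majority_child")

# Eigenvalues below this are treated as zero covariance (degenerate profiles).
_EIG_TOL = 1e-12


@dataclass(frozen=True)
class ClassProbabilityProfile:
    """Per-level class distribution used by the multiclass target encoding.

    Attributes
    ----------
    level : str
        The categorical label.
    count : int
        Number of fitting observations carrying this level (``n_l``).
    probs : tuple of float
        Within-level class proportions, ordered by ``class_order``; sums to 1
        when ``count > 0``.
    weight : float
        ``n_l / n`` — the level's share of the fitting sample.
    """

    level: str
    count: int
    probs: tuple[float, ...]
    weight: float


@dataclass(frozen=True)
class LevelEncoding:
    """A fitted map from categorical level to integer rank ``1..k_observed``.

    ``ranks`` is a bijection onto ``1..k_observed``; consecutive integer ranks
    (rather than raw projection scores) are used because threshold splits
    depend only on the induced order.
    """

    method: str
    ranks: Mapping[str, int]
    fit_scope: str = "full_train"
    absent_policy: str = "majority_child"
    class_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown encoding method {self.method!r}")
        if self.absent_policy not in _POLICIES:
            raise ValueError(f"unknown absent policy {self.absent_policy!r}")
        got = sorted(self.ranks.values())
        if got != list(range(1, len(self.ranks) + 1)):
            raise ValueError("ranks must be a bijection onto 1..k_observed")

    @property
    def k_observed(self) -> int:
        return len(self.ranks)

    def apply(self, x: Iterable[str]) -> np.ndarray:
        """Encode a vector of levels; absent levels follow ``absent_policy``."""
        x = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=object)
        out = np.empty(x.shape[0], dtype=float)
        ranks = self.ranks
        strict = self.absent_policy == "strict"
        for i, v in enumerate(x):
            r = ranks.get(v)
            if r is None:
                if strict:
                    raise KeyError(
                        f"absent level {v!r}: not seen when encoding was fitted "
                        f"(fit_scope={self.fit_scope})"
                    )
                out[i] = ABSENT_SENTINEL
            else:
                out[i] = r
        return out

    # -- JSON round-trip -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "ranks": dict(self.ranks),
                "fit_scope": self.fit_scope,
                "absent_policy": self.absent_policy,
                "class_order": list(self.class_order),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "LevelEncoding":
        d = json.loads(s)
        return cls(
            method=d["method"],
            ranks={str(k): int(v) for k, v in d["ranks"].items()},
            fit_scope=d["fit_scope"],
            absent_policy=d["absent_policy"],
            class_order=tuple(d["class_order"]),
        )


def _as_str_array(x: Sequence) -> np.ndarray:
    return np.asarray([str(v) for v in x], dtype=object)


def _resolve_class_order(y: np.ndarray, class_order) -> tuple[str, ...]:
    if class_order is not None:
        return tuple(class_order)
    return tuple(sorted(set(y.tolist())))


def fit_integer_encoding(
    levels: Iterable[str],
    *,
    fit_scope: str = "full_train",
    absent_policy: str = "majority_child",
) -> LevelEncoding:
    """Rank levels by lexicographic order of their string labels.

    Target-agnostic: the response never enters, so permuting targets cannot
    change the encoding. Note the ordering is string-lexicographic, hence
    ``"10" < "2"``.
    """
    lv = sorted({str(v) for v in levels})
    if not lv:
        raise ValueError("cannot encode a predictor with no observed levels")
    return LevelEncoding(
        method="integer_alpha",
        ranks={v: i + 1 for i, v in enumerate(lv)},
        fit_scope=fit_scope,
        absent_policy=absent_policy,
    )


def fit_target_encoding_twoclass(
    x: Sequence,
    y: Sequence,
    *,
    class_order: Sequence[str] | None = None,
    fit_scope: str = "full_train",
    absent_policy: str = "majority_child",
) -> LevelEncoding:
    """Rank levels ascending by the within-level proportion of the second class.

    With two response classes, treating the resulting ordered variable as
    ordinal and searching thresholds finds the same optimal Gini split as an
    exhaustive search over all ``2^(k-1) - 1`` level bipartitions. Ties in the
    proportion break lexicographically on the level label.
    """
    x = _as_str_array(x)
    y = _as_str_array(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"x and y lengths differ ({x.shape[0]} vs {y.shape[0]})")
    order = _resolve_class_order(y, class_order)
    observed = set(y.tolist())
    if len(observed) != 2 or not observed.issubset(order) or len(order) != 2:
        raise ValueError(
            "target_twoclass requires exactly 2 response classes; "
            "use fit_target_encoding_multiclass for more"
        )
    second = order[1]
    levels = sorted(set(x.tolist()))
    prop = {
        lev: float(np.mean(y[x == lev] == second)) for lev in levels
    }
    ranked = sorted(levels, key=lambda lev: (prop[lev], lev))
    return LevelEncoding(
        method="target_twoclass",
        ranks={v: i + 1 for i, v in enumerate(ranked)},
        fit_scope=fit_scope,
        absent_policy=absent_policy,
        class_order=order,
    )


def class_probability_profiles(
    x: Sequence, y: Sequence, class_order: Sequence[str] | None = None
) -> list[ClassProbabilityProfile]:
    """Per-level class-probability profiles with sample-share weights."""
    x = _as_str_array(x)
    y = _as_str_array(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"x and y lengths differ ({x.shape[0]} vs {y.shape[0]})")
    order = _resolve_class_order(y, class_order)
    n = x.shape[0]
    profiles = []
    for lev in sorted(set(x.tolist())):
        mask = x == lev
        cnt = int(mask.sum())
        probs = tuple(float(np.mean(y[mask] == c)) for c in order)
        profiles.append(
            ClassProbabilityProfile(level=lev, count=cnt, probs=probs, weight=cnt / n)
        )
    return profiles


def fit_target_encoding_multiclass(
    x: Sequence,
    y: Sequence,
    *,
    class_order: Sequence[str] | None = None,
    fit_scope: str = "full_train",
    absent_policy: str = "majority_child",
) -> LevelEncoding:
    """Rank levels by the first principal component of the weighted covariance
    of class probabilities.

    For each level ``l`` with ``n_l`` observations let ``p_l`` be its vector of
    class proportions and ``w_l = n_l / n``. With ``p̄ = Σ_l w_l p_l`` the
    weighted covariance is ``Σ = Σ_l w_l (p_l − p̄)(p_l − p̄)ᵀ``. Levels are
    ranked ascending by the projection ``(p_l − p̄)·v`` onto the leading
    eigenvector ``v`` of ``Σ``.

    Determinism: ``v``'s sign is fixed so its first nonzero coordinate (in
    ``class_order``) is positive; projection ties, and the degenerate case of a
    (numerically) zero covariance matrix, fall back to lexicographic order.
    """
    x = _as_str_array(x)
    y = _as_str_array(y)
    order = _resolve_class_order(y, class_order)
    if len(set(y.tolist())) < 2:
        raise ValueError("target encoding requires at least 2 response classes")
    profiles = class_probability_profiles(x, y, order)
    levels = [p.level for p in profiles]

    P = np.array([p.probs for p in profiles], dtype=float)        # L x C
    w = np.array([p.weight for p in profiles], dtype=float)
    pbar = w @ P
    centered = P - pbar
    cov = (centered * w[:, None]).T @ centered                    # C x C

    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[-1] <= _EIG_TOL:
        ranked = sorted(levels)  # zero covariance: all profiles identical
    else:
        v = eigvecs[:, -1]
        nz = np.flatnonzero(np.abs(v) > _EIG_TOL)
        if nz.size and v[nz[0]] < 0:
            v = -v
        score = centered @ v
        ranked = [lev for _, lev in sorted(zip(score, levels), key=lambda t: (t[0], t[1]))]
    return LevelEncoding(
        method="target_pca",
        ranks={v_: i + 1 for i, v_ in enumerate(ranked)},
        fit_scope=fit_scope,
        absent_policy=absent_policy,
        class_order=order,
    )


def apply_encoding(enc: LevelEncoding, x: Iterable[str]) -> np.ndarray:
    """Functional alias for :meth:`LevelEncoding.apply`."""
    return enc.apply(x)
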