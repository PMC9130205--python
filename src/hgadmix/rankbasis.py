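"""Selection of jointly propagating haplogroups by rank correlation.

Haplogroups that spread together during major migration or admixture events
leave correlated frequency variation across groups of populations.  High
correlation cannot be expected over *all* populations (later demography
erodes it), so for every haplogroup pair we search for a population subset in
which the Spearman rank correlation is high: starting from all populations we
greedily remove, one at a time, the population whose removal raises the
correlation most, until the correlation reaches ``rho_min`` or the subset
shrinks to ``min_pops``.  A pair is accepted when a subset of at least
``min_pops`` populations reaches ``rho_min`` (defaults 10 and 0.8).  The
selected basis consists of every haplogroup with at least one accepted
partner.

The greedy leave-one-out shrink is one reconstruction of an iterative
rank-correlation search; ``rho_min``, ``min_pops`` and the removal budget are
exposed so alternatives can be explored, and every accepted pair records the
supporting population subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .freqmatrix import FrequencyMatrix
from .nomenclature import HgBasis

__all__ = [
    "PairCorrelationResult",
    "BasisSelectionResult",
    "spearman_rho",
    "best_subset",
    "select_correlating_hgs",
    "CorrelatingHgSelector",
]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises ``ValueError`` on constant input, where the correlation is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _rho_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    rx = stats.rankdata(x) - (len(x) + 1) / 2.0
    ry = stats.rankdata(y) - (len(y) + 1) / 2.0
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return np.nan
    return float(rx @ ry / denom)


def _leave_one_out_rhos(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """rho for every subset obtained by dropping one element (vectorized)."""
    m = len(x)
    mask = ~np.eye(m, dtype=bool)
    xs = np.broadcast_to(x, (m, m))[mask].reshape(m, m - 1)
    ys = np.broadcast_to(y, (m, m))[mask].reshape(m, m - 1)
    rx = stats.rankdata(xs, axis=1)
    ry = stats.rankdata(ys, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx * rx).sum(axis=1) * (ry * ry).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (rx * ry).sum(axis=1) / denom
    rhos[denom == 0] = np.nan
    return rhos


@dataclass
class PairCorrelationResult:
    """Outcome of the subset search for one haplogroup pair."""

    hg_a: str
    hg_b: str
    rho: float
    support: list
    accepted: bool


@dataclass
class BasisSelectionResult:
    """Selected basis plus the accepted pair list backing the selection."""

    basis: HgBasis
    pairs: list[PairCorrelationResult]
    rho_min: float
    min_pops: int


def best_subset(
    x: Sequence[float],
    y: Sequence[float],
    rho_min: float = 0.8,
    min_pops: int = 10,
    populations: Optional[Sequence] = None,
    hg_a: str = "x",
    hg_b: str = "y",
) -> PairCorrelationResult:
    """Greedy population-subset search maximizing the Spearman correlation.

    Starting from all populations, while the correlation is below ``rho_min``
    and more than ``min_pops`` populations remain, remove the single
    population whose removal maximizes the correlation (ties broken by
    lowest population index).  Accepted iff the final correlation reaches
    ``rho_min`` on at least ``min_pops`` populations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if populations is None:
        populations = list(range(n))
    if min_pops < 3:
        raise ValueError("min_pops must be >= 3")
    if n < min_pops:
        raise ValueError(f"need at least min_pops={min_pops} populations, got {n}")
    keep = list(range(n))
    rho = _rho_or_nan(x, y)
    # best configuration seen so far (largest support wins ties via ordering)
    seen_rho, seen_keep = rho, list(keep)
    while (np.isnan(rho) or rho < rho_min) and len(keep) > min_pops:
        rhos = _leave_one_out_rhos(x[keep], y[keep])
        if np.all(np.isnan(rhos)):
            break  # every candidate subset is constant
        # ties broken by lowest population index (argmax takes the first max)
        best_drop = int(np.nanargmax(rhos))
        best_rho = float(rhos[best_drop])
        keep.pop(best_drop)
        rho = best_rho
        if np.isnan(seen_rho) or rho > seen_rho:
            seen_rho, seen_keep = rho, list(keep)
    accepted = (
        (not np.isnan(seen_rho)) and seen_rho >= rho_min and len(seen_keep) >= min_pops
    )
    return PairCorrelationResult(
        hg_a=hg_a,
        hg_b=hg_b,
        rho=float(seen_rho) if not np.isnan(seen_rho) else np.nan,
        support=[populations[i] for i in seen_keep],
        accepted=bool(accepted),
    )


def select_correlating_hgs(
    freq: Union[FrequencyMatrix, pd.DataFrame],
    rho_min: float = 0.8,
    min_pops: int = 10,
) -> BasisSelectionResult:
    """Restrict a frequency matrix's basis to haplogroups with at least one
    accepted correlation partner.

    Every unordered column pair runs :func:`best_subset`; a haplogroup is
    kept when it participates in at least one accepted pair.
    """
    if isinstance(freq, FrequencyMatrix):
        values = freq.usable_values()
    else:
        values = freq
    pops = list(values.index)
    if len(pops) < min_pops:
        raise ValueError(
            f"only {len(pops)} usable populations; need at least {min_pops}"
        )
    cols = list(values.columns)
    X = values.to_numpy(dtype=float)
    pairs: list[PairCorrelationResult] = []
    keep: set[str] = set()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            res = best_subset(
                X[:, i],
                X[:, j],
                rho_min=rho_min,
                min_pops=min_pops,
                populations=pops,
                hg_a=cols[i],
                hg_b=cols[j],
            )
            if res.accepted:
                pairs.append(res)
                keep.add(cols[i])
                keep.add(cols[j])
    basis = HgBasis([c for c in cols if c in keep])
    return BasisSelectionResult(
        basis=basis, pairs=pairs, rho_min=rho_min, min_pops=min_pops
    )


class CorrelatingHgSelector(SelectorMixin, BaseEstimator):
    """Feature selector keeping haplogroup columns with a correlating partner.

    scikit-learn style: ``fit`` on a populations x haplogroups matrix,
    ``transform`` drops the columns without any accepted rank-correlation
    partner.  Fitted attributes: ``support_mask_``, ``pairs_``,
    ``selected_labels_`` (when fed a DataFrame or FrequencyMatrix).

    Parameters
    ----------
    rho_min : float, default=0.8
        Minimal Spearman correlation for an accepted pair.
    min_pops : int, default=10
        Minimal size of the supporting population subset.
    """

    def __init__(self, rho_min: float = 0.8, min_pops: int = 10):
        self.rho_min = rho_min
        self.min_pops = min_pops

    def fit(self, X, y=None):
        if isinstance(X, FrequencyMatrix):
            df = X.usable_values()
        elif isinstance(X, pd.DataFrame):
            df = X
        else:
            X = np.asarray(X, dtype=float)
            df = pd.DataFrame(X, columns=[f"hg{i}" for i in range(X.shape[1])])
        result = select_correlating_hgs(
            df, rho_min=self.rho_min, min_pops=self.min_pops
        )
        selected = set(result.basis.raw_labels)
        self.n_features_in_ = df.shape[1]
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.support_mask_ = np.array([c in selected for c in df.columns])
        self.pairs_ = result.pairs
        self.selected_labels_ = result.basis.raw_labels
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_
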