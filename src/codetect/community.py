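"""Community statistics for monthly encounter records.

The monthly community encountered by a focal transceiver is summarised as an
abundance vector: unique individuals weighted by detection-days (the number
of distinct calendar days in the month on which the individual was heard),
or unique-individual counts per species normalised by the number of active
tags in the regional network.  On these vectors we compute

* Bray-Curtis similarity between months (1 minus the Bray-Curtis
  dissimilarity over the union of units, absent units counting as zero),
* Shannon's diversity index ``H = -sum p_i ln p_i`` on detection-days,
* an individual-accumulation rarefaction curve over month orderings, and
* chi-square goodness-of-fit tests of encountered sex ratio / size-bin
  composition against the tagged population, with a Monte Carlo p-value
  when expected counts fall below the classical threshold of 5.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, UndefinedMetricError

__all__ = [
    "bray_curtis_similarity",
    "similarity_matrix",
    "consecutive_similarity",
    "shannon_diversity",
    "rarefaction_curve",
    "composition_chisq",
    "CompositionTestResult",
    "size_binning",
    "size_bin_labels",
    "coverage_percent",
]


def _as_series(v: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(v, dtype=float)
    if (s < 0).any():
        raise ValueError("abundances must be non-negative")
    return s


def bray_curtis_similarity(
    a: Mapping[str, float] | pd.Series, b: Mapping[str, float] | pd.Series
) -> float:
    """Bray-Curtis similarity ``1 - sum|a_i - b_i| / sum(a_i + b_i)``.

    The sum runs over the union of units; a unit absent from one vector
    contributes zero abundance there.  Raises
    :class:`~codetect.errors.UndefinedMetricError` when both vectors have
    zero total, where the index is undefined.
    """
    sa, sb = _as_series(a), _as_series(b)
    units = sa.index.union(sb.index)
    av = sa.reindex(units, fill_value=0.0).to_numpy()
    bv = sb.reindex(units, fill_value=0.0).to_numpy()
    denom = float((av + bv).sum())
    if denom == 0.0:
        raise UndefinedMetricError("Bray-Curtis undefined: both vectors empty")
    return 1.0 - float(np.abs(av - bv).sum()) / denom


def similarity_matrix(
    vectors: Mapping[object, Mapping[str, float] | pd.Series],
) -> pd.DataFrame:
    """All-pairs Bray-Curtis similarity between keyed abundance vectors.

    Pairs where both vectors are empty are reported as NaN rather than
    raising, so an empty month does not abort a matrix.
    """
    keys = list(vectors)
    out = pd.DataFrame(np.eye(len(keys)), index=keys, columns=keys)
    for i, ki in enumerate(keys):
        for kj in keys[i + 1 :]:
            try:
                s = bray_curtis_similarity(vectors[ki], vectors[kj])
            except UndefinedMetricError:
                s = np.nan
            out.loc[ki, kj] = out.loc[kj, ki] = s
    return out


def consecutive_similarity(
    vectors: Mapping[object, Mapping[str, float] | pd.Series],
) -> pd.DataFrame:
    """Bray-Curtis similarity between consecutive keys (months in order)."""
    keys = list(vectors)
    rows = []
    for ka, kb in zip(keys, keys[1:]):
        try:
            s = bray_curtis_similarity(vectors[ka], vectors[kb])
        except UndefinedMetricError:
            s = np.nan
        rows.append({"from": ka, "to": kb, "similarity": s})
    return pd.DataFrame(rows, columns=["from", "to", "similarity"])


def shannon_diversity(
    abundances: Mapping[str, float] | pd.Series | Sequence[float],
    base: float | None = None,
) -> float:
    """Shannon's diversity index on an abundance vector.

    ``H = -sum p_i log p_i`` with ``p_i`` the relative abundance; natural
    log by default (community-ecology convention), another base via
    ``base``.  Zero-abundance units contribute nothing (``0 log 0 = 0``).
    """
    if isinstance(abundances, (Mapping, pd.Series)):
        x = _as_series(abundances).to_numpy()
    else:
        x = np.asarray(list(abundances), dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise UndefinedMetricError("Shannon index undefined for all-zero vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def rarefaction_curve(
    monthly_sets: Sequence[Iterable[str]],
    n_perm: int = 100,
    seed: int | np.random.Generator | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Individual-accumulation rarefaction over sampling-period orderings.

    For each permutation of the month order, the cumulative number of unique
    individuals after m months is recorded; the curve reports the mean, sd
    and a normal-approximation 95% band (mean +/- 1.96 sd, clipped to
    [0, total uniques]) at each m.

    ``method`` is ``"random"`` (``n_perm`` random orderings), ``"exact"``
    (all M! orderings, each once), or ``"auto"`` (exact when M <= 8).  The
    mean at m = M always equals the total number of uniques.
    """
    sets = [frozenset(s) for s in monthly_sets]
    m_total = len(sets)
    if m_total < 1:
        raise ValueError("need at least one sampling period")
    if method == "auto":
        method = "exact" if m_total <= 8 else "random"
    if method == "exact":
        orders: Iterable[tuple[int, ...]] = itertools.permutations(range(m_total))
    elif method == "random":
        rng = np.random.default_rng(seed)
        orders = (tuple(rng.permutation(m_total)) for _ in range(n_perm))
    else:
        raise ValueError(f"unknown method {method!r}")

    counts: list[np.ndarray] = []
    for order in orders:
        seen: set[str] = set()
        row = np.empty(m_total)
        for m, idx in enumerate(order):
            seen |= sets[idx]
            row[m] = len(seen)
        counts.append(row)
    arr = np.vstack(counts)
    total = len(frozenset().union(*sets))
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    lo = np.clip(mean - 1.96 * sd, 0, total)
    hi = np.clip(mean + 1.96 * sd, 0, total)
    return pd.DataFrame(
        {
            "m": np.arange(1, m_total + 1),
            "mean": mean,
            "sd": sd,
            "ci_lo": lo,
            "ci_hi": hi,
        }
    )


@dataclass
class CompositionTestResult:
    """Outcome of a goodness-of-fit test of counts against null proportions."""

    statistic: float
    df: int | None
    p_value: float
    method: str  # "asymptotic" | "monte_carlo"
    n_sim: int
    observed: np.ndarray = field(repr=False)
    expected: np.ndarray = field(repr=False)
    categories: list = field(default_factory=list, repr=False)


def composition_chisq(
    observed: Mapping[str, int] | pd.Series | Sequence[int],
    expected_props: Mapping[str, float] | pd.Series | Sequence[float],
    monte_carlo: bool | None = None,
    n_sim: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> CompositionTestResult:
    """Chi-square goodness of fit with an optional Monte Carlo p-value.

    ``X^2 = sum (O_i - E_i)^2 / E_i`` with ``E_i = N * prop_i``.  With
    ``monte_carlo=None`` the test auto-switches to simulation whenever any
    expected count falls below 5 (the classical validity threshold for the
    chi-square approximation); pass True/False to force either method.
    The Monte Carlo p-value uses the add-one estimator
    ``(1 + #{X^2_sim >= X^2_obs}) / (n_sim + 1)`` over multinomial draws
    under the null, so it is never exactly zero.
    """
    if isinstance(observed, (Mapping, pd.Series)):
        obs_s = pd.Series(observed, dtype=float)
        categories = list(obs_s.index)
        obs = obs_s.to_numpy()
        if isinstance(expected_props, (Mapping, pd.Series)):
            props = pd.Series(expected_props, dtype=float).reindex(obs_s.index)
            if props.isna().any():
                missing = list(props.index[props.isna()])
                raise ValueError(f"expected_props missing categories: {missing}")
            props = props.to_numpy()
        else:
            props = np.asarray(list(expected_props), dtype=float)
    else:
        obs = np.asarray(list(observed), dtype=float)
        props = np.asarray(list(expected_props), dtype=float)
        categories = list(range(len(obs)))
    if obs.shape != props.shape:
        raise ValueError("observed and expected_props must have equal length")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    if not math.isclose(props.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("expected proportions must sum to 1")
    n = obs.sum()
    if n <= 0:
        raise ValueError("total observed count must be positive")
    if ((props == 0) & (obs > 0)).any():
        raise ValueError("observed count in a category with null probability 0")

    # drop zero-probability (necessarily zero-count) categories
    keep = props > 0
    obs_k, props_k = obs[keep], props[keep]
    expected = n * props_k
    x2 = float(((obs_k - expected) ** 2 / expected).sum())

    if monte_carlo is None:
        monte_carlo = bool((expected < 5).any())

    if monte_carlo:
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(int(round(n)), props_k, size=n_sim)
        x2_sim = ((sims - expected) ** 2 / expected).sum(axis=1)
        p = (1.0 + float((x2_sim >= x2 - 1e-9).sum())) / (n_sim + 1.0)
        return CompositionTestResult(
            statistic=x2,
            df=None,
            p_value=p,
            method="monte_carlo",
            n_sim=n_sim,
            observed=obs_k,
            expected=expected,
            categories=[c for c, k in zip(categories, keep) if k],
        )
    df = len(obs_k) - 1
    p = float(stats.chi2.sf(x2, df)) if df > 0 else 1.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return CompositionTestResult(
        statistic=x2,
        df=df,
        p_value=p,
        method="asymptotic",
        n_sim=0,
        observed=obs_k,
        expected=expected,
        categories=[c for c, k in zip(categories, keep) if k],
    )


#: Size-bin centers in cm: nearest multiple of 25 within [75, 225], with an
#: open top bin for animals rounding above 225.
SIZE_BIN_MIN = 75
SIZE_BIN_MAX = 225
SIZE_BIN_WIDTH = 25
OUT_OF_RANGE = "out_of_range"


def size_bin_labels(include_out_of_range: bool = False) -> list[str]:
    """Ordered labels of the 25-cm fork-length bins ("75" ... "225+")."""
    labels = [str(c) for c in range(SIZE_BIN_MIN, SIZE_BIN_MAX, SIZE_BIN_WIDTH)]
    labels.append(f"{SIZE_BIN_MAX}+")
    if include_out_of_range:
        labels.append(OUT_OF_RANGE)
    return labels


def size_binning(fork_length_cm: float) -> str:
    """Assign a fork length to its 25-cm size bin.

    Values round to the nearest multiple of 25 cm (ties at x.5 round up);
    bins run 75-225 with everything rounding above 225 pooled as "225+".
    Lengths that round below 75 (i.e. < 62.5 cm) are flagged out of range;
    non-positive lengths are an error.
    """
    fl = float(fork_length_cm)
    if fl <= 0 or not math.isfinite(fl):
        raise ValueError(f"fork length must be positive, got {fork_length_cm}")
    center = math.floor(fl / SIZE_BIN_WIDTH + 0.5) * SIZE_BIN_WIDTH
    if center < SIZE_BIN_MIN:
        return OUT_OF_RANGE
    if center > SIZE_BIN_MAX:
        return f"{SIZE_BIN_MAX}+"
    return str(center)


def coverage_percent(n_detected: int, n_active: int, decimals: int = 1) -> float:
    """Percentage of the active tagged population detected by a focal.

    Rounded to ``decimals`` places, matching how coverage is reported.
    """
    if n_active <= 0:
        raise ConfigError("active tag count must be positive")
    if n_detected < 0 or n_detected > n_active:
        raise ValueError("detected count must lie in [0, n_active]")
    return round(100.0 * n_detected / n_active, decimals)
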