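"""Replicate-shuffling false-discovery analyses.

Two empirical null procedures guard the window test against spurious
differential methylation:

* re-running the (beta-binomial or Welch t) window test under balanced
  relabelings of the 8 libraries (4 vs 4), excluding the true labeling;
  with 8 libraries there are C(8,4)/2 = 35 unordered splits, 34 of them
  non-identity;
* the 100-iteration t-test procedure, which resamples relabelings with
  replacement (the space of distinct balanced splits is smaller than 100)
  and counts BH-significant windows per iteration.

The observed significant-window count is then compared to the null count
distribution: empirical p = (1 + #{null >= observed}) / (1 + n_perms) and
a fold-over-null-mean summary.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .calling import bh_fdr


def balanced_relabelings(samples: list[str], side_a: list[str]) -> list[tuple[str, ...]]:
    """All unordered balanced splits of ``samples`` except the true one.

    Each relabeling is returned as the tuple of names assigned to side A;
    the mirror of a split is the same split, so each unordered split
    appears once.
    """
    n = len(samples)
    k = len(side_a)
    if 2 * k != n:
        raise ValueError("relabelings require equally sized sides")
    anchor = samples[0]
    true_a = frozenset(side_a)
    true_b = frozenset(samples) - true_a
    out = []
    for combo in combinations(samples, k):
        if anchor not in combo:  # fix the anchor to side A: kills mirrors
            continue
        s = frozenset(combo)
        if s == true_a or s == true_b:
            continue
        out.append(tuple(sorted(combo)))
    return out


def shuffle_replicates(
    samples: list[str],
    side_a: list[str],
    n_perms: int,
    seed: int,
    with_replacement: bool = False,
) -> list[tuple[str, ...]]:
    """Seeded selection of balanced relabelings.

    Without replacement, ``n_perms`` must not exceed the number of distinct
    non-identity splits; with replacement (the 100-iteration t-test
    procedure) schemes repeat.
    """
    pool = balanced_relabelings(samples, side_a)
    rng = np.random.default_rng(seed)
    if with_replacement:
        idx = rng.integers(0, len(pool), size=n_perms)
        return [pool[i] for i in idx]
    if n_perms > len(pool):
        raise ValueError(
            f"n_perms={n_perms} exceeds the {len(pool)} distinct balanced "
            f"non-identity relabelings"
        )
    idx = rng.permutation(len(pool))[:n_perms]
    return [pool[i] for i in sorted(idx)]


def ttest_window_significance(
    wcounts: pd.DataFrame,
    side_a: list[str],
    side_b: list[str],
    q_thresh: float = 0.05,
    diff_thresh: float = 0.15,
    arcsine: bool = False,
) -> int:
    """Number of windows significant under a Welch t test on replicate
    methylation fractions, BH-corrected, with the same effect-size filter
    as the beta-binomial path."""

    def fracs(side):
        m = wcounts[[f"m_{s}" for s in side]].to_numpy(dtype=float)
        u = wcounts[[f"u_{s}" for s in side]].to_numpy(dtype=float)
        n = m + u
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, m / np.maximum(n, 1), np.nan)
        return p

    pa, pb = fracs(side_a), fracs(side_b)
    ok = (np.sum(~np.isnan(pa), axis=1) >= 2) & (np.sum(~np.isnan(pb), axis=1) >= 2)
    if not ok.any():
        return 0
    pa, pb = pa[ok], pb[ok]
    xa, xb = (np.arcsin(np.sqrt(pa)), np.arcsin(np.sqrt(pb))) if arcsine else (pa, pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_ind(xa, xb, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(t.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    q = bh_fdr(p)
    diff = np.nanmean(pa, axis=1) - np.nanmean(pb, axis=1)
    return int(np.sum((q < q_thresh) & (np.abs(diff) > diff_thresh)))


def permuted_dmr_counts(
    wcounts: pd.DataFrame,
    schemes: list[tuple[str, ...]],
    samples: list[str],
    test: str = "ttest",
    count_fn=None,
    **kwargs,
) -> np.ndarray:
    """Significant-window counts under each relabeling scheme.

    ``count_fn(wcounts, side_a, side_b)`` may override the counting
    routine; by default the Welch-t path is used (``test='ttest'``) or the
    beta-binomial path (``test='betabin'``).  Observed and permuted runs
    share this single code path — the filtering and thresholds applied to
    the real labeling are exactly those applied to every shuffle.
    """
    if count_fn is None:
        if test == "ttest":
            def count_fn(w, a, b):
                return ttest_window_significance(w, a, b, **kwargs)
        elif test == "betabin":
            from .diffmeth import test_windows

            def count_fn(w, a, b):
                return int(test_windows(w, a, b, **kwargs)["significant"].sum())
        else:
            raise ValueError(f"unknown test {test!r}")
    counts = np.empty(len(schemes), dtype=int)
    all_set = set(samples)
    for i, scheme in enumerate(schemes):
        a = list(scheme)
        b = sorted(all_set - set(scheme))
        counts[i] = count_fn(wcounts, a, b)
    return counts


def empirical_excess(observed_count: int, null_counts) -> dict[str, float]:
    """Observed significant-window count against the shuffle null.

    empirical p = (1 + #{null >= observed}) / (1 + n); fold over the null
    mean (floored at 1 so an empty null never divides by zero).
    """
    null = np.asarray(null_counts, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    p = (1 + np.sum(null >= observed_count)) / (1 + null.size)
    fold = observed_count / max(float(null.mean()), 1.0)
    return {
        "observed": float(observed_count),
        "null_mean": float(null.mean()),
        "null_max": float(null.max()),
        "empirical_p": float(p),
        "fold_over_null": float(fold),
    }
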