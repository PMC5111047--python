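"""Spike-in-calibrated binomial methylation calling.

Each CpG dyad is tested per library with a one-sided binomial test: under
the null of no methylation, every unconverted read is a bisulfite
conversion failure, so the number of methylated-looking reads m out of
coverage n is Binomial(n, e) with e the conversion-error (deamination)
rate estimated from the fully unmethylated lambda spike-in.  P-values are
Benjamini-Hochberg corrected within each library over its testable sites;
a site is "methylated" when q < alpha (default 0.01) with coverage above
the minimum (default: more than 3 reads, i.e. >= 4).

Fractional methylation of a site is m/(m+u); of a feature it is the
coverage-weighted pooled fraction sum(m)/sum(m+u) over its CpGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
UNTESTABLE = "untestable"


@dataclass
class ConversionControl:
    """Unconverted/total cytosine read counts from an unmethylated control."""

    unconverted_reads: int
    total_read_cytosines: int

    def __post_init__(self) -> None:
        if self.total_read_cytosines <= 0:
            raise ValueError("control has no read cytosines")
        if self.unconverted_reads > self.total_read_cytosines:
            raise ValueError("unconverted exceeds total")

    @property
    def rate(self) -> float:
        return self.unconverted_reads / self.total_read_cytosines


def estimate_conversion_error(
    control: ConversionControl,
    noncpg_control: ConversionControl | None = None,
    floor: float = 1e-6,
) -> float:
    """Deamination (conversion-error) rate from the unmethylated spike-in.

    When an independent estimate from non-genic non-CpG cytosines is
    supplied the two are compared and a >2-fold discrepancy raises a
    warning — a concordance check on the spike-in calibration.
    The rate is floored at ``floor`` so a perfectly converted control still
    yields a usable null success probability.
    """
    rate = max(control.rate, floor)
    if noncpg_control is not None:
        alt = max(noncpg_control.rate, floor)
        hi, lo = max(rate, alt), min(rate, alt)
        if lo > 0 and hi / lo > 2:
            warnings.warn(
                f"lambda conversion-error rate {rate:.2e} and non-CpG rate "
                f"{alt:.2e} differ by >2x",
                stacklevel=2,
            )
    return rate


def binomial_p(m, cov, err: float):
    """Upper-tail binomial probability P(X >= m | n=cov, p=err).

    Vectorized over m and cov.  By construction p = 1 whenever m = 0.
    """
    if not 0 <= err <= 1:
        raise ValueError(f"error rate {err} outside [0, 1]")
    m = np.asarray(m)
    cov = np.asarray(cov)
    if (m < 0).any() or (m > cov).any():
        raise ValueError("need 0 <= m <= cov")
    return stats.binom.sf(m - 1, cov, err)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in the original order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_sites(
    counts: pd.DataFrame,
    err: float,
    alpha: float = 0.01,
    min_cov: int = 3,
    sample: str | None = None,
) -> pd.DataFrame:
    """Call methylation status per site for one library.

    ``counts`` has columns scaffold, pos, m, u.  Sites with coverage
    <= ``min_cov`` are untestable; BH runs over the testable sites only.
    """
    df = counts[["scaffold", "pos", "m", "u"]].copy()
    cov = df["m"].to_numpy() + df["u"].to_numpy()
    df["cov"] = cov
    with np.errstate(invalid="ignore"):
        df["fraction"] = np.where(cov > 0, df["m"] / np.maximum(cov, 1), np.nan)
    testable = cov > min_cov
    p = np.full(len(df), np.nan)
    q = np.full(len(df), np.nan)
    p[testable] = binomial_p(df.loc[testable, "m"], cov[testable], err)
    q[testable] = bh_fdr(p[testable])
    df["p"] = p
    df["q"] = q
    status = np.where(testable, np.where(q < alpha, METHYLATED, UNMETHYLATED), UNTESTABLE)
    df["status"] = status
    if sample is not None:
        df.insert(0, "sample", sample)
    return df


def call_all_samples(
    wide: pd.DataFrame,
    samples: list[str],
    err: float,
    alpha: float = 0.01,
    min_cov: int = 3,
) -> dict[str, pd.DataFrame]:
    """Per-library calls from a wide m_<s>/u_<s> count table."""
    out = {}
    for s in samples:
        counts = wide[["scaffold", "pos"]].copy()
        counts["m"] = wide[f"m_{s}"]
        counts["u"] = wide[f"u_{s}"]
        out[s] = call_sites(counts, err, alpha=alpha, min_cov=min_cov, sample=s)
    return out


def pool_counts(wide: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Sum raw counts across libraries (pooling precedes testing)."""
    out = wide[["scaffold", "pos"]].copy()
    out["m"] = sum(wide[f"m_{s}"] for s in samples)
    out["u"] = sum(wide[f"u_{s}"] for s in samples)
    return out


def site_support(calls: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-site count of libraries in which the site is called methylated."""
    first = next(iter(calls.values()))
    out = first[["scaffold", "pos"]].copy()
    out["n_methylated"] = sum(
        (df["status"] == METHYLATED).to_numpy().astype(int) for df in calls.values()
    )
    out["n_testable"] = sum(
        (df["status"] != UNTESTABLE).to_numpy().astype(int) for df in calls.values()
    )
    return out


def gene_methylation_status(
    pooled_calls: pd.DataFrame,
    genes,
    include_introns: bool = False,
) -> pd.DataFrame:
    """Gene-level status from pooled calls.

    A gene is methylated when at least one exon (optionally exon or intron)
    contains a methylated CpG.  Genes with no covered (testable) CpG get a
    missing status and are excluded from denominators downstream.
    """
    rows = []
    by_scaf: dict[str, pd.DataFrame] = {
        k: v for k, v in pooled_calls.groupby("scaffold")
    }
    for g in genes:
        sub = by_scaf.get(g.scaffold)
        feats = list(g.exons) + (list(g.introns) if include_introns else [])
        meth = False
        covered = False
        if sub is not None and feats:
            pos = sub["pos"].to_numpy()
            mask = np.zeros(len(sub), dtype=bool)
            for s, e in feats:
                mask |= (pos >= s) & (pos < e)
            region = sub[mask]
            covered = (region["status"] != UNTESTABLE).any()
            meth = (region["status"] == METHYLATED).any()
        rows.append(
            {
                "gene": g.id,
                "status": (METHYLATED if meth else UNMETHYLATED) if covered else np.nan,
            }
        )
    return pd.DataFrame(rows)


def consensus_report(
    calls: dict[str, pd.DataFrame], k_min: int
) -> dict[str, int | float]:
    """How many sites are methylated in at least ``k_min`` libraries."""
    n = len(calls)
    if k_min > n:
        raise ValueError(f"k_min={k_min} exceeds {n} samples")
    supp = site_support(calls)
    tested = supp[supp["n_testable"] > 0]
    n_k = int((tested["n_methylated"] >= k_min).sum())
    return {
        "n_sites_tested": int(len(tested)),
        "k_min": k_min,
        "n_methylated_ge_k": n_k,
        "fraction_methylated_ge_k": n_k / max(len(tested), 1),
    }


def feature_methylation(counts: pd.DataFrame, features) -> pd.DataFrame:
    """Fractional methylation per feature.

    ``features`` is an iterable of (id, scaffold, [(start, end), ...]).
    Emits both the coverage-weighted pooled fraction sum(m)/sum(m+u) and
    the unweighted mean of per-site fractions; features without covered
    CpGs get missing values, not zero.
    """
    by_scaf = {k: v for k, v in counts.groupby("scaffold")}
    rows = []
    for fid, scaffold, ivs in features:
        sub = by_scaf.get(scaffold)
        weighted = unweighted = np.nan
        n_sites = 0
        if sub is not None:
            pos = sub["pos"].to_numpy()
            mask = np.zeros(len(sub), dtype=bool)
            for s, e in ivs:
                mask |= (pos >= s) & (pos < e)
            m = sub["m"].to_numpy()[mask]
            u = sub["u"].to_numpy()[mask]
            cov = m + u
            covered = cov > 0
            n_sites = int(covered.sum())
            if n_sites:
                weighted = m[covered].sum() / cov[covered].sum()
                unweighted = float(np.mean(m[covered] / cov[covered]))
        rows.append(
            {
                "feature": fid,
                "weighted_fraction": weighted,
                "mean_site_fraction": unweighted,
                "n_covered_sites": n_sites,
            }
        )
    return pd.DataFrame(rows)
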