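"""Window- and site-level differential methylation.

The genome is tiled into 200-bp windows; per window and library the CpG
counts are summed.  Differential methylation between two groups of
libraries is assessed with a beta-binomial likelihood-ratio test: replicate
counts (m_i, n_i) in group g are modelled as
m_i ~ BetaBinomial(n_i, alpha=pi_g*theta, beta=(1-pi_g)*theta), with a
common precision theta (alpha+beta) shared by the groups and estimated by
method of moments from replicate fractions over the window plus its
flanking windows (locally pooled dispersion).  The LRT statistic
2(l_alt - l_null) is referred to chi-square with 1 df; BH correction runs
per comparison.  Significance requires q < 0.05 and an absolute group
methylation difference > 15% for regions; the confident single-CpG (DMC)
set uses q < 0.01 and > 20%.

Adjacent significant windows hypermethylated in the same group merge into
DMRs, each assigned the genic feature it overlaps most; genes containing
at least one DMR are the differentially methylated genes (DMGs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .calling import METHYLATED, bh_fdr

THETA_FLOOR = 1.0
THETA_CEIL = 1e6
_EPS = 1e-9

FEATURE_PRIORITY = ["exon", "promoter", "intron", "downstream", "intergenic"]


def tile_windows(lengths: dict[str, int], width: int = 200) -> pd.DataFrame:
    """Half-open tiles from 0; the terminal partial window is retained."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    rows = []
    for scaffold in sorted(lengths):
        L = lengths[scaffold]
        for start in range(0, L, width):
            rows.append((scaffold, start, min(start + width, L)))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def window_counts(
    wide: pd.DataFrame, samples: list[str], width: int = 200
) -> pd.DataFrame:
    """Sum per-library dyad counts into tiling windows.

    A CpG belongs to the window containing the 0-based position of its
    plus-strand C.  Returns one row per window that contains any CpG, with
    m_<s>/u_<s> columns and the member CpG count.
    """
    df = wide.copy()
    df["start"] = (df["pos"] // width) * width
    agg = {f"{k}_{s}": "sum" for s in samples for k in ("m", "u")}
    agg["pos"] = "count"
    out = (
        df.groupby(["scaffold", "start"], as_index=False)
        .agg(agg)
        .rename(columns={"pos": "n_cpg"})
    )
    out["end"] = out["start"] + width
    cols = ["scaffold", "start", "end", "n_cpg"]
    cols += [f"{k}_{s}" for s in samples for k in ("m", "u")]
    return out[cols].sort_values(
        ["scaffold", "start"], kind="mergesort", ignore_index=True
    )


def filter_testable(
    wcounts: pd.DataFrame,
    calls: dict[str, pd.DataFrame],
    side_a: list[str],
    side_b: list[str],
    min_reps: int = 3,
    min_reads: int = 5,
    meth_in_at_least: int | None = None,
    width: int = 200,
) -> pd.DataFrame:
    """Windows eligible for testing.

    A window is kept iff at least ``min_reps`` of the libraries on each
    side have summed window coverage >= ``min_reads`` (the "more than 4
    reads" rule) and at least one member CpG is called methylated in at
    least half of all libraries (``meth_in_at_least`` overrides the
    half-of-samples default).
    """
    if len(side_a) < 3 or len(side_b) < 3:
        raise ValueError("each comparison side needs at least 3 libraries")
    n_samples = len(side_a) + len(side_b)
    if meth_in_at_least is None:
        meth_in_at_least = -(-n_samples // 2)  # ceil(n/2)

    cov_ok_a = sum(
        (
            (wcounts[f"m_{s}"] + wcounts[f"u_{s}"]) >= min_reads
        ).to_numpy().astype(int)
        for s in side_a
    )
    cov_ok_b = sum(
        (
            (wcounts[f"m_{s}"] + wcounts[f"u_{s}"]) >= min_reads
        ).to_numpy().astype(int)
        for s in side_b
    )
    keep = (cov_ok_a >= min_reps) & (cov_ok_b >= min_reps)

    # per-site support: methylated in >= meth_in_at_least of all libraries
    first = next(iter(calls.values()))
    support = sum(
        (df["status"] == METHYLATED).to_numpy().astype(int) for df in calls.values()
    )
    sites = first[["scaffold", "pos"]].copy()
    sites["supported"] = support >= meth_in_at_least
    sites["start"] = (sites["pos"] // width) * width
    win_support = sites.groupby(["scaffold", "start"])["supported"].any()
    idx = pd.MultiIndex.from_frame(wcounts[["scaffold", "start"]])
    supported = win_support.reindex(idx, fill_value=False).to_numpy()

    return wcounts[keep & supported].reset_index(drop=True)


def betabin_loglik(m, n, pi: float, theta: float) -> float:
    """Beta-binomial log-likelihood in mean/precision parameterization."""
    pi = min(max(pi, _EPS), 1 - _EPS)
    a, b = pi * theta, (1 - pi) * theta
    ll = stats.betabinom.logpmf(np.asarray(m), np.asarray(n), a, b)
    return float(np.sum(ll))


def _fit_pi(m, n, theta: float) -> tuple[float, float]:
    """ML methylation proportion for one group at fixed precision."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    use = n > 0
    m, n = m[use], n[use]
    if len(m) == 0:
        raise ValueError("no replicate with coverage")
    res = minimize_scalar(
        lambda pi: -betabin_loglik(m, n, pi, theta),
        bounds=(_EPS, 1 - _EPS),
        method="bounded",
        options={"xatol": 1e-8},
    )
    ll = -res.fun
    if not np.isfinite(ll):
        raise ValueError("non-finite beta-binomial likelihood")
    return float(res.x), ll


def betabin_fit(group_a, group_b, theta: float) -> dict:
    """LRT ingredients for one window.

    ``group_a``/``group_b`` are sequences of per-replicate (m, u) pairs.
    Returns the per-group and pooled ML proportions and the log-likelihoods
    under the alternative (two proportions) and the null (common one).
    """
    ma, ua = np.array([g[0] for g in group_a]), np.array([g[1] for g in group_a])
    mb, ub = np.array([g[0] for g in group_b]), np.array([g[1] for g in group_b])
    na, nb = ma + ua, mb + ub
    pi_a, ll_a = _fit_pi(ma, na, theta)
    pi_b, ll_b = _fit_pi(mb, nb, theta)
    pi_0, ll_0 = _fit_pi(np.concatenate([ma, mb]), np.concatenate([na, nb]), theta)
    return {
        "pi_a": pi_a,
        "pi_b": pi_b,
        "pi_null": pi_0,
        "ll_alt": ll_a + ll_b,
        "ll_null": ll_0,
    }


def mom_dispersion(cells) -> float:
    """Method-of-moments beta-binomial precision from replicate counts.

    ``cells`` is an iterable of (m, n) count vectors; each cell holds the
    replicate counts of one window-by-group combination, whose residuals
    around its own pooled mean contribute to a shared intraclass
    correlation.  With k replicates and pooled mean pi_hat, the model is
    Var(p_i) = pi(1-pi)(1 + (n_i - 1) rho)/n_i; using pi_hat instead of pi
    loses one degree of freedom per cell, absorbed by the (1 - 1/k)
    factor.  Returns theta = 1/rho - 1 clipped to [1, 1e6]; replicates
    with no excess variance hit the ceiling.
    """
    resid = 0.0
    denom = 0.0
    for m, n in cells:
        m = np.asarray(m, dtype=float)
        n = np.asarray(n, dtype=float)
        use = n > 0
        m, n = m[use], n[use]
        k = len(m)
        if k < 2:
            continue
        pi = m.sum() / n.sum()
        v = pi * (1 - pi)
        if v <= 0:
            continue
        p = m / n
        c = 1.0 - 1.0 / k
        resid += np.sum((p - pi) ** 2) - c * v * np.sum(1.0 / n)
        denom += c * v * np.sum((n - 1.0) / n)
    if denom <= 0 or resid <= 0:
        return THETA_CEIL
    rho = min(resid / denom, 1 - _EPS)
    return float(np.clip(1.0 / rho - 1.0, THETA_FLOOR, THETA_CEIL))


def local_dispersion(
    wcounts: pd.DataFrame,
    samples: list[str],
    groups: tuple[list[str], list[str]] | None = None,
    width: int = 200,
    flank: int = 200,
) -> np.ndarray:
    """Per-window precision estimated from the window plus flanking windows.

    Each window within ``flank`` bp contributes its replicate fractions as
    a separate cell (per comparison group when ``groups`` is given, so a
    true group difference does not inflate the dispersion); windows whose
    flanks are empty fall back to the window-only estimate.
    """
    n_flank = max(1, flank // width)
    group_list = list(groups) if groups is not None else [samples]
    mats = [
        (
            wcounts[[f"m_{s}" for s in g]].to_numpy(dtype=float),
            wcounts[[f"u_{s}" for s in g]].to_numpy(dtype=float),
        )
        for g in group_list
    ]
    thetas = np.empty(len(wcounts))
    scaffolds = wcounts["scaffold"].to_numpy()
    starts = wcounts["start"].to_numpy()
    for i in range(len(wcounts)):
        near = np.flatnonzero(
            (scaffolds == scaffolds[i])
            & (np.abs(starts - starts[i]) <= n_flank * width)
        )
        cells = []
        for m_mat, u_mat in mats:
            for j in near:
                cells.append((m_mat[j], m_mat[j] + u_mat[j]))
        thetas[i] = mom_dispersion(cells)
    return thetas


def test_windows(
    wcounts: pd.DataFrame,
    side_a: list[str],
    side_b: list[str],
    theta: np.ndarray | float | None = None,
    q_thresh: float = 0.05,
    diff_thresh: float = 0.15,
    label_a: str = "A",
    label_b: str = "B",
    width: int = 200,
) -> pd.DataFrame:
    """Beta-binomial LRT per window with BH correction.

    ``theta`` may be a scalar, a per-window array, or None (then estimated
    by :func:`local_dispersion`).  Significance combines the FDR cut with
    the absolute-difference filter.
    """
    if theta is None:
        theta = local_dispersion(
            wcounts, side_a + side_b, groups=(side_a, side_b), width=width
        )
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (len(wcounts),))

    out = wcounts[["scaffold", "start", "end"]].copy()
    if "n_cpg" in wcounts:
        out["n_cpg"] = wcounts["n_cpg"]
    pi_a = np.empty(len(wcounts))
    pi_b = np.empty(len(wcounts))
    lrt = np.empty(len(wcounts))
    ma = wcounts[[f"m_{s}" for s in side_a]].to_numpy(dtype=float)
    ua = wcounts[[f"u_{s}" for s in side_a]].to_numpy(dtype=float)
    mb = wcounts[[f"m_{s}" for s in side_b]].to_numpy(dtype=float)
    ub = wcounts[[f"u_{s}" for s in side_b]].to_numpy(dtype=float)
    for i in range(len(wcounts)):
        fit = betabin_fit(
            list(zip(ma[i], ua[i])), list(zip(mb[i], ub[i])), theta[i]
        )
        pi_a[i] = fit["pi_a"]
        pi_b[i] = fit["pi_b"]
        lrt[i] = max(0.0, 2.0 * (fit["ll_alt"] - fit["ll_null"]))
    out["pi_a"] = pi_a
    out["pi_b"] = pi_b
    out["diff"] = pi_a - pi_b
    out["theta"] = theta
    out["lrt"] = lrt
    out["p"] = stats.chi2.sf(lrt, df=1)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["direction"] = np.where(out["diff"] >= 0, f"hyper-{label_a}", f"hyper-{label_b}")
    out["significant"] = (out["q"] < q_thresh) & (out["diff"].abs() > diff_thresh)
    return out


def confident_dmcs(
    site_results: pd.DataFrame, q_thresh: float = 0.01, diff_thresh: float = 0.20
) -> pd.DataFrame:
    """Confident DMC set: FDR < 0.01 and absolute change > 20%."""
    keep = (site_results["q"] < q_thresh) & (site_results["diff"].abs() > diff_thresh)
    return site_results[keep].reset_index(drop=True)


def merge_dmrs(results: pd.DataFrame) -> pd.DataFrame:
    """Merge bookended significant windows that share a direction."""
    sig = results[results["significant"]].sort_values(
        ["scaffold", "start"], kind="mergesort"
    )
    rows = []
    cur = None
    for w in sig.itertuples():
        if (
            cur is not None
            and w.scaffold == cur["scaffold"]
            and w.start == cur["end"]
            and w.direction == cur["direction"]
        ):
            cur["end"] = w.end
            cur["n_windows"] += 1
            cur["min_q"] = min(cur["min_q"], w.q)
            cur["max_abs_diff"] = max(cur["max_abs_diff"], abs(w.diff))
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "scaffold": w.scaffold,
                "start": w.start,
                "end": w.end,
                "direction": w.direction,
                "n_windows": 1,
                "min_q": w.q,
                "max_abs_diff": abs(w.diff),
            }
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold",
            "start",
            "end",
            "direction",
            "n_windows",
            "min_q",
            "max_abs_diff",
        ],
    )


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def assign_features(
    dmrs: pd.DataFrame, annotation, downstream_bp: int = 2000
) -> pd.DataFrame:
    """Assign each DMR the genic feature type it overlaps most.

    Ties break by priority exon > promoter > intron > downstream-2kb >
    intergenic.  The assigned gene is the gene contributing the winning
    overlap (or, for intergenic DMRs, none).
    """
    genes_by_scaf: dict[str, list] = {}
    for g in annotation.genes:
        genes_by_scaf.setdefault(g.scaffold, []).append(g)

    feats = []
    gene_ids = []
    for r in dmrs.itertuples():
        best = {"feature": "intergenic", "gene": "", "bp": 0}
        for g in genes_by_scaf.get(r.scaffold, []):
            cand: dict[str, int] = {}
            cand["exon"] = sum(_overlap(r.start, r.end, s, e) for s, e in g.exons)
            cand["intron"] = sum(_overlap(r.start, r.end, s, e) for s, e in g.introns)
            if g.promoter is not None:
                cand["promoter"] = _overlap(r.start, r.end, *g.promoter)
            if g.strand == "+":
                ds = (g.end, g.end + downstream_bp)
            else:
                ds = (max(0, g.start - downstream_bp), g.start)
            cand["downstream"] = _overlap(r.start, r.end, *ds)
            for ftype, bp in cand.items():
                if bp > best["bp"] or (
                    bp == best["bp"]
                    and bp > 0
                    and FEATURE_PRIORITY.index(ftype)
                    < FEATURE_PRIORITY.index(best["feature"])
                ):
                    best = {"feature": ftype, "gene": g.id, "bp": bp}
        feats.append(best["feature"])
        gene_ids.append(best["gene"])
    out = dmrs.copy()
    out["feature"] = feats
    out["gene"] = gene_ids
    return out


def dmg_table(assigned_dmrs: pd.DataFrame) -> pd.DataFrame:
    """Genes containing >= 1 DMR, with per-direction DMR counts."""
    genic = assigned_dmrs[assigned_dmrs["gene"] != ""]
    if len(genic) == 0:
        return pd.DataFrame(columns=["gene", "n_dmrs", "direction"])
    rows = []
    for gene, grp in genic.groupby("gene"):
        counts = grp["direction"].value_counts()
        rows.append(
            {
                "gene": gene,
                "n_dmrs": len(grp),
                "direction": counts.idxmax(),
                **{f"n_{d}": int(c) for d, c in counts.items()},
            }
        )
    return pd.DataFrame(rows).fillna(0).sort_values("gene", ignore_index=True)


def merge_and_assign(
    results: pd.DataFrame, annotation, downstream_bp: int = 2000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DMR list plus DMG table from a window result table."""
    dmrs = assign_features(merge_dmrs(results), annotation, downstream_bp)
    return dmrs, dmg_table(dmrs)


def paired_intersection(dmg_a: pd.DataFrame, dmg_b: pd.DataFrame) -> pd.DataFrame:
    """Conservative DMG set: significant in both pairwise comparisons with
    a consistent direction."""
    if len(dmg_a) == 0 or len(dmg_b) == 0:
        return pd.DataFrame(columns=["gene", "direction"])
    merged = dmg_a[["gene", "direction"]].merge(
        dmg_b[["gene", "direction"]], on="gene", suffixes=("_1", "_2")
    )
    keep = merged["direction_1"] == merged["direction_2"]
    out = merged[keep].rename(columns={"direction_1": "direction"})
    return out[["gene", "direction"]].reset_index(drop=True)
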