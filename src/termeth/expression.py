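"""Expression summaries and their integration with methylation.

FPKM quantification, within-morph replicate CV, between-morph absolute
differences on log2(FPKM+1), the tau specificity index, the
antisense-transcription binomial procedure, rank-based
methylation-expression regressions, gene-family conservation/duplication
metrics, and DMG-vs-expression/splicing contrasts.  Differential
expression and differential exon usage are consumed as externally
computed call tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .calling import bh_fdr


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = count * 1e9 / (length_bp * library_total); library totals
    default to column sums of ``counts``.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every gene needs a positive transcript length")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    return counts * 1e9 / np.outer(lengths, library_sizes)


def tau(values: np.ndarray) -> float:
    """Tau specificity index over condition means (0 uniform, 1 exclusive)."""
    x = np.asarray(values, dtype=float)
    mx = x.max()
    if mx <= 0 or len(x) < 2:
        return float("nan")
    return float(np.sum(1 - x / mx) / (len(x) - 1))


def expression_summaries(fpkm_mat: pd.DataFrame, design) -> pd.DataFrame:
    """Per-gene expression level, CV, between-morph |delta| and tau.

    CV = sd/mean within each morph, averaged over morphs (missing when a
    morph mean is 0 or a morph has < 2 replicates); |delta| = max - min of
    morph means on the log2(FPKM+1) scale; tau on raw morph means.
    Expression level is reported as the mean of morph means.
    """
    morphs = design.morphs()
    morph_means = {}
    cvs = []
    for morph, libs in morphs.items():
        sub = fpkm_mat[libs]
        mean = sub.mean(axis=1)
        morph_means[morph] = mean
        if len(libs) >= 2:
            with np.errstate(invalid="ignore", divide="ignore"):
                cv = sub.std(axis=1, ddof=1) / mean
            cv[mean <= 0] = np.nan
        else:
            cv = pd.Series(np.nan, index=fpkm_mat.index)
        cvs.append(cv)
    mm = pd.DataFrame(morph_means)
    log_mm = np.log2(mm + 1)
    out = pd.DataFrame(index=fpkm_mat.index)
    out["level"] = mm.mean(axis=1)
    out["cv"] = pd.concat(cvs, axis=1).mean(axis=1)
    out["abs_diff"] = log_mm.max(axis=1) - log_mm.min(axis=1)
    out["tau"] = mm.apply(lambda r: tau(r.to_numpy()), axis=1)
    return out


def antisense_flags(
    sense: pd.DataFrame,
    antisense: pd.DataFrame,
    design,
    excluded_genes=(),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag genes significantly transcribed from the antisense strand.

    Per library, each gene's antisense count is tested against
    Binomial(total reads, library-wide antisense proportion) one-sided;
    BH-correction runs within the library.  A gene is flagged when more
    than 1/3 of libraries are individually significant.  Genes overlapping
    more than half of another gene are excluded beforehand (pass them via
    ``excluded_genes``); the library-wide proportion is computed over the
    included loci only.  The continuous metric is the mean antisense read
    proportion across the replicates of each sample type, averaged over
    sample types.
    """
    excluded = set(excluded_genes)
    keep = [g for g in sense.index if g not in excluded]
    s = sense.loc[keep]
    a = antisense.loc[keep]
    libs = [lib for lib in s.columns]
    sig = pd.DataFrame(False, index=keep, columns=libs)
    for lib in libs:
        tot = (s[lib] + a[lib]).to_numpy()
        anti = a[lib].to_numpy()
        global_rate = anti.sum() / max(tot.sum(), 1)
        testable = tot > 0
        p = np.ones(len(keep))
        p[testable] = stats.binom.sf(anti[testable] - 1, tot[testable], global_rate)
        q = np.ones(len(keep))
        q[testable] = bh_fdr(p[testable])
        sig[lib] = (q < alpha) & testable
    n_sig = sig.sum(axis=1)
    flag = n_sig > len(libs) / 3

    # continuous metric: mean antisense proportion per sample type
    props = {}
    for morph, mlibs in design.morphs().items():
        tot = s[mlibs].to_numpy() + a[mlibs].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            pr = np.where(tot > 0, a[mlibs].to_numpy() / np.maximum(tot, 1), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            props[morph] = np.nanmean(pr, axis=1)
    prop_df = pd.DataFrame(props, index=keep)
    out = pd.DataFrame(
        {
            "n_significant_libraries": n_sig,
            "antisense_flag": flag,
            "antisense_proportion": prop_df.mean(axis=1),
        },
        index=pd.Index(keep, name="gene"),
    )
    return out


def methylation_expression_model(
    table: pd.DataFrame, response: str = "methylation"
) -> dict[str, pd.DataFrame]:
    """Rank correlations and a joint rank-based linear model.

    ``table`` holds the response column and predictor columns.  Each
    predictor gets Spearman rho, R^2 (of the rank regression) and p; the
    joint model is OLS of the rank-transformed response on standardized
    rank-transformed predictors, giving comparable coefficients.
    Zero-variance (or duplicated) predictors are dropped with a warning.
    """
    df = table.dropna()
    y = df[response].to_numpy(dtype=float)
    predictors = [c for c in df.columns if c != response]
    kept = []
    ranks = {}
    for c in predictors:
        x = df[c].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"predictor {c!r} has zero variance; dropped", stacklevel=2)
            continue
        r = stats.rankdata(x)
        if any(np.allclose(r, ranks[k]) for k in kept):
            warnings.warn(f"predictor {c!r} collinear with an earlier one; dropped",
                          stacklevel=2)
            continue
        ranks[c] = r
        kept.append(c)
    rows = []
    for c in kept:
        rho, p = stats.spearmanr(df[c], y)
        rows.append({"predictor": c, "rho": rho, "r2": rho**2, "p": p})
    marginal = pd.DataFrame(rows)

    ry = stats.rankdata(y)
    ry = (ry - ry.mean()) / ry.std()
    X = np.column_stack([(ranks[c] - ranks[c].mean()) / ranks[c].std() for c in kept])
    fit = sm.OLS(ry, sm.add_constant(X)).fit()
    joint = pd.DataFrame(
        {
            "predictor": kept,
            "coef": fit.params[1:],
            "se": fit.bse[1:],
            "p": fit.pvalues[1:],
        }
    )
    joint["abs_rank"] = joint["coef"].abs().rank(ascending=False).astype(int)
    return {"marginal": marginal, "joint": joint, "r2_joint": float(fit.rsquared)}


def family_metrics(ortholog_table: pd.DataFrame, focal: str = "Znev") -> pd.DataFrame:
    """Conservation and duplication metrics per gene family.

    ``ortholog_table`` is long: columns family, species, copy_number.
    Emits the proportion of species with >= 1 member (large-scale
    conservation), the cross-species mean copy number (ancestral
    duplication rate) and the focal-species copy number over the
    cross-species mean (focal-normalized duplication).  Families without
    a focal-species member get a missing ratio.
    """
    rows = []
    for fam, grp in ortholog_table.groupby("family"):
        copies = grp.set_index("species")["copy_number"]
        present = (copies >= 1).mean()
        mean_copy = copies.mean()
        focal_copy = copies.get(focal, np.nan)
        others = copies.drop(focal, errors="ignore")
        ratio = (
            focal_copy / others.mean()
            if not np.isnan(focal_copy) and len(others) and others.mean() > 0
            else np.nan
        )
        rows.append(
            {
                "family": fam,
                "prop_species_present": present,
                "mean_copy_number": mean_copy,
                "focal_copy_number": focal_copy,
                "focal_ratio": ratio,
                "duplicated": bool(focal_copy > 1) if not np.isnan(focal_copy) else False,
            }
        )
    return pd.DataFrame(rows)


def duplicate_stratified_model(
    table: pd.DataFrame,
    duplicated: pd.Series,
    response: str = "methylation",
) -> dict:
    """Methylation-expression model per duplication stratum plus the
    slope contrast (duplicated minus single-copy) per predictor."""
    dup = duplicated.reindex(table.index).fillna(False).astype(bool)
    models = {
        "duplicated": methylation_expression_model(table[dup], response),
        "single": methylation_expression_model(table[~dup], response),
    }
    d = models["duplicated"]["marginal"].set_index("predictor")["rho"]
    s = models["single"]["marginal"].set_index("predictor")["rho"]
    contrast = (d - s).rename("rho_duplicated_minus_single").reset_index()
    return {"models": models, "contrast": contrast}


def dmg_expression_contrasts(
    dmg_genes,
    summaries: pd.DataFrame,
    splicing_calls: pd.DataFrame | None = None,
    dmr_midpoints: pd.Series | None = None,
    nondmr_midpoints: pd.Series | None = None,
    spliced_exon_positions: pd.Series | None = None,
) -> dict:
    """Contrast DMGs against non-DMGs on expression and splicing.

    Rank-sum tests of CV and |delta| between DMGs and other genes; Fisher
    exact test of the DMG x alternatively-spliced 2x2 table
    (``splicing_calls``: columns gene, spliced bool); and, when DMR/nonDMR
    midpoints plus differentially spliced exon positions are supplied,
    a rank-sum comparison of distances to the nearest spliced exon.
    Empty strata skip their test with a notice.
    """
    dmg_set = set(dmg_genes)
    is_dmg = summaries.index.isin(dmg_set)
    out: dict = {"n_dmg": int(is_dmg.sum()), "n_other": int((~is_dmg).sum())}
    for col in ("cv", "abs_diff"):
        a = summaries.loc[is_dmg, col].dropna()
        b = summaries.loc[~is_dmg, col].dropna()
        if len(a) < 2 or len(b) < 2:
            out[f"{col}_p"] = np.nan
            out[f"{col}_note"] = "stratum too small; test skipped"
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        out[f"{col}_p"] = float(res.pvalue)
        out[f"{col}_dmg_median"] = float(a.median())
        out[f"{col}_other_median"] = float(b.median())

    if splicing_calls is not None:
        sp = splicing_calls.set_index("gene")["spliced"].astype(bool)
        common = summaries.index.intersection(sp.index)
        dmg_mask = common.isin(dmg_set)
        spliced = sp.reindex(common).to_numpy()
        tab = np.array(
            [
                [int((dmg_mask & spliced).sum()), int((dmg_mask & ~spliced).sum())],
                [int((~dmg_mask & spliced).sum()), int((~dmg_mask & ~spliced).sum())],
            ]
        )
        odds, p = stats.fisher_exact(tab)
        out["splicing_table"] = tab
        out["splicing_odds_ratio"] = float(odds)
        out["splicing_p"] = float(p)

    if (
        dmr_midpoints is not None
        and nondmr_midpoints is not None
        and spliced_exon_positions is not None
    ):
        targets = np.sort(np.asarray(spliced_exon_positions, dtype=float))

        def dists(mids):
            mids = np.asarray(mids, dtype=float)
            idx = np.searchsorted(targets, mids)
            left = np.abs(mids - targets[np.clip(idx - 1, 0, len(targets) - 1)])
            right = np.abs(mids - targets[np.clip(idx, 0, len(targets) - 1)])
            return np.minimum(left, right)

        d_dmr = dists(dmr_midpoints)
        d_non = dists(nondmr_midpoints)
        if len(d_dmr) >= 2 and len(d_non) >= 2:
            res = stats.mannwhitneyu(d_dmr, d_non, alternative="two-sided")
            out["splice_distance_p"] = float(res.pvalue)
            out["splice_distance_dmr_median"] = float(np.median(d_dmr))
            out["splice_distance_nondmr_median"] = float(np.median(d_non))
    return out
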