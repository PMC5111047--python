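"""Descriptive methylome geography.

Metagene and exon-intron junction profiles, CpG observed/expected
depletion, methylation deciles, gene spacing, promoter-island tracks,
repeat-vs-context methylation and cross-species ortholog methylation
classes.  All profile operations orient genes 5' -> 3', so a minus-strand
gene mirrors its plus-strand twin.

Site tables are DataFrames with columns scaffold, pos, m, u (pooled
counts) and optionally status from the caller; fractions are m/(m+u).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .calling import METHYLATED


def _with_fraction(sites: pd.DataFrame) -> pd.DataFrame:
    if "fraction" in sites:
        return sites
    sites = sites.copy()
    cov = sites["m"] + sites["u"]
    sites = sites[cov > 0]
    sites["fraction"] = sites["m"] / (sites["m"] + sites["u"])
    return sites


def _profile_from_bins(per_gene: list[pd.Series]) -> pd.DataFrame:
    """Average per-gene bin means into a profile with a CI half-width."""
    mat = pd.concat(per_gene, axis=1)
    mean = mat.mean(axis=1)
    n = mat.notna().sum(axis=1)
    sd = mat.std(axis=1)
    ci = 1.96 * sd / np.sqrt(n.clip(lower=1))
    out = pd.DataFrame({"bin": mean.index, "mean_fraction": mean.values,
                        "n_genes": n.values, "ci_halfwidth": ci.values})
    return out.sort_values("bin", ignore_index=True)


def metagene_profile(
    sites: pd.DataFrame,
    genes,
    n_bins: int = 40,
    flank_bp: int = 2000,
    flank_bins: int = 20,
    multiexon_only: bool = False,
    mode: str = "proportional",
    span_bp: int = 4000,
) -> pd.DataFrame:
    """Mean methylation across length-normalised gene bodies plus flanks.

    ``proportional`` mode assigns gene-body CpGs to ``n_bins``
    equal-proportion bins (bins 0..n_bins-1) and flanking CpGs to
    fixed-width bp bins (negative upstream, >= n_bins downstream).
    ``absolute`` mode profiles the first and last ``span_bp`` of the gene
    body in bp bins instead (bin = bp offset bucket from each end).
    Strand is flipped so every profile reads 5' -> 3'.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sites = _with_fraction(sites)
    by_scaf = {k: v for k, v in sites.groupby("scaffold")}
    per_gene = []
    for g in genes:
        if multiexon_only and len(g.exons) < 2:
            continue
        sub = by_scaf.get(g.scaffold)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        frac = sub["fraction"].to_numpy()
        L = g.end - g.start
        if mode == "proportional":
            sel = (pos >= g.start - flank_bp) & (pos < g.end + flank_bp)
            if not sel.any():
                continue
            p, f = pos[sel], frac[sel]
            fb = max(flank_bp, 1)
            rel = np.where(
                p < g.start,
                # upstream flank (gene coords): negative bins
                -1 - ((g.start - 1 - p) * flank_bins) // fb,
                np.where(
                    p < g.end,
                    ((p - g.start) * n_bins) // L,
                    n_bins + ((p - g.end) * flank_bins) // fb,
                ),
            ).astype(int)
            if g.strand == "-":
                rel = (n_bins - 1) - rel  # mirrors body and swaps flanks
        elif mode == "absolute":
            half = min(span_bp, L)
            first = (pos >= g.start) & (pos < g.start + half)
            last = (pos >= g.end - half) & (pos < g.end)
            sel = first | last
            if not sel.any():
                continue
            p, f = pos[sel], frac[sel]
            if g.strand == "+":
                rel = np.where(p < g.start + half, p - g.start,
                               (p - g.end) + 2 * span_bp)
            else:
                rel = np.where(p >= g.end - half, g.end - 1 - p,
                               (g.start - 1 - p) + 2 * span_bp)
            rel = (rel // 100).astype(int)  # 100-bp bins within each 4-kb end
        else:
            raise ValueError(f"unknown mode {mode!r}")
        per_gene.append(pd.Series(f, index=rel).groupby(level=0).mean())
    if not per_gene:
        return pd.DataFrame(columns=["bin", "mean_fraction", "n_genes", "ci_halfwidth"])
    return _profile_from_bins(per_gene)


def junction_profile(
    sites: pd.DataFrame,
    genes,
    span_bp: int = 200,
    methylated_only: bool = False,
) -> pd.DataFrame:
    """Mean fraction per bp offset around internal exon-intron junctions.

    Offsets are negative on the exon side and non-negative on the intron
    side.  Only internal junctions contribute (a single-exon gene has
    none); offsets beyond the feature are truncated, not padded.  With
    ``methylated_only``, only exons containing a methylated CpG (pooled
    calls; requires a ``status`` column) contribute junctions.
    """
    sites = _with_fraction(sites)
    by_scaf = {k: v for k, v in sites.groupby("scaffold")}
    chunks = []
    for g in genes:
        if len(g.exons) < 2:
            continue
        sub = by_scaf.get(g.scaffold)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        frac = sub["fraction"].to_numpy()
        status = sub["status"].to_numpy() if "status" in sub else None
        for i, (es, ee) in enumerate(g.exons):
            if methylated_only:
                if status is None:
                    raise ValueError("methylated_only requires a status column")
                inside = (pos >= es) & (pos < ee)
                if not (status[inside] == METHYLATED).any():
                    continue
            # offsets: negative = exon side (bp into the exon),
            # non-negative = intron side (bp into the intron)
            if i < len(g.exons) - 1:  # junction at exon end; intron to the right
                jpos = ee
                exon_sel = (pos >= max(es, jpos - span_bp)) & (pos < jpos)
                exon_off = pos[exon_sel] - jpos
                ilim = min(g.exons[i + 1][0], jpos + span_bp)
                intr_sel = (pos >= jpos) & (pos < ilim)
                intr_off = pos[intr_sel] - jpos
                chunks.append(pd.DataFrame({
                    "offset": np.concatenate([exon_off, intr_off]),
                    "fraction": np.concatenate([frac[exon_sel], frac[intr_sel]]),
                }))
            if i > 0:  # junction at exon start; intron to the left
                jpos = es
                exon_sel = (pos >= jpos) & (pos < min(ee, jpos + span_bp))
                exon_off = -(pos[exon_sel] - jpos) - 1
                ilim = max(g.exons[i - 1][1], jpos - span_bp)
                intr_sel = (pos >= ilim) & (pos < jpos)
                intr_off = (jpos - 1) - pos[intr_sel]
                chunks.append(pd.DataFrame({
                    "offset": np.concatenate([exon_off, intr_off]),
                    "fraction": np.concatenate([frac[exon_sel], frac[intr_sel]]),
                }))
    if not chunks:
        return pd.DataFrame(columns=["offset", "mean_fraction", "n_sites"])
    allc = pd.concat(chunks, ignore_index=True)
    out = (
        allc.groupby("offset")["fraction"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_fraction", "count": "n_sites"})
    )
    return out


def cpg_oe(seq: str) -> float:
    """CpG observed/expected ratio (N_CG * L) / (N_C * N_G).

    Low values mark historical germline methylation (deamination-driven
    CpG loss).  Missing (nan) when the sequence has no C or no G.
    """
    seq = seq.upper()
    L = len(seq)
    n_c, n_g = seq.count("C"), seq.count("G")
    if n_c * n_g == 0:
        return float("nan")
    n_cg = seq.count("CG")
    return n_cg * L / (n_c * n_g)


def gc_content(seq: str) -> float:
    seq = seq.upper()
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


def methylation_deciles(gene_fractions: pd.Series) -> pd.Series:
    """Decile 1..10 of ascending methylation for methylated genes.

    Equal-size bins (sizes differ by at most 1); ties break by stable
    gene-id order.  Fewer than 10 genes is an error.
    """
    n = len(gene_fractions)
    if n < 10:
        raise ValueError("need at least 10 genes to form deciles")
    order = gene_fractions.sort_index(kind="mergesort").sort_values(kind="mergesort")
    ranks = np.arange(n)
    deciles = (ranks * 10) // n + 1
    return pd.Series(deciles, index=order.index, name="decile").reindex(
        gene_fractions.index
    )


def nearest_gene_distance(genes) -> pd.Series:
    """Gap in bp to the nearest other gene on the same scaffold.

    Overlapping genes get 0; a gene alone on its scaffold gets nan.
    """
    out = {}
    by_scaf: dict[str, list] = {}
    for g in genes:
        by_scaf.setdefault(g.scaffold, []).append(g)
    for scaf, gs in by_scaf.items():
        gs = sorted(gs, key=lambda g: (g.start, g.end))
        for i, g in enumerate(gs):
            dists = []
            if i > 0:
                dists.append(max(0, g.start - gs[i - 1].end))
            if i < len(gs) - 1:
                dists.append(max(0, gs[i + 1].start - g.end))
            out[g.id] = min(dists) if dists else float("nan")
    return pd.Series(out, name="nearest_gene_bp")


def promoter_island_profile(
    sites: pd.DataFrame,
    genes,
    genome,
    span_bp: int = 2000,
    n_bins: int = 40,
) -> pd.DataFrame:
    """Methylation, CpG o/e and GC tracks around unmethylated promoters of
    methylated genes.

    Qualifying promoters contain no methylated CpG while the gene body
    contains at least one (pooled calls; requires a ``status`` column).
    The window is 2*span_bp wide, centred on the promoter midpoint and
    oriented by gene strand.
    """
    if "status" not in sites:
        raise ValueError("promoter_island_profile requires called status")
    sites = _with_fraction(sites)
    by_scaf = {k: v for k, v in sites.groupby("scaffold")}
    width = 2 * span_bp
    bin_bp = width / n_bins
    meth_rows: list[pd.Series] = []
    oe_rows = []
    gc_rows = []
    n_used = 0
    for g in genes:
        if g.promoter is None:
            continue
        sub = by_scaf.get(g.scaffold)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        status = sub["status"].to_numpy()
        ps, pe = g.promoter
        in_prom = (pos >= ps) & (pos < pe)
        in_body = (pos >= g.start) & (pos < g.end)
        if (status[in_prom] == METHYLATED).any():
            continue
        if not (status[in_body] == METHYLATED).any():
            continue
        mid = (ps + pe) // 2
        lo, hi = mid - span_bp, mid + span_bp
        sel = (pos >= lo) & (pos < hi)
        rel = pos[sel] - lo
        if g.strand == "-":
            rel = width - 1 - rel
        bins = (rel / bin_bp).astype(int)
        meth_rows.append(
            pd.Series(sub["fraction"].to_numpy()[sel], index=bins)
            .groupby(level=0)
            .mean()
        )
        seq = genome.sequences[g.scaffold]
        oe, gc = np.full(n_bins, np.nan), np.full(n_bins, np.nan)
        for b in range(n_bins):
            s = seq[max(0, lo + int(b * bin_bp)) : max(0, lo + int((b + 1) * bin_bp))]
            bb = (n_bins - 1 - b) if g.strand == "-" else b
            if s:
                oe[bb] = cpg_oe(s)
                gc[bb] = gc_content(s)
        oe_rows.append(oe)
        gc_rows.append(gc)
        n_used += 1
    if n_used == 0:
        warnings.warn("no qualifying unmethylated promoters of methylated genes",
                      stacklevel=2)
        return pd.DataFrame(columns=["bin", "meth_fraction", "cpg_oe", "gc"])
    meth = _profile_from_bins(meth_rows).set_index("bin")["mean_fraction"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        oe = np.nanmean(np.vstack(oe_rows), axis=0)
        gc = np.nanmean(np.vstack(gc_rows), axis=0)
    out = pd.DataFrame({"bin": range(n_bins), "cpg_oe": oe, "gc": gc})
    out["meth_fraction"] = meth.reindex(out["bin"]).to_numpy()
    return out[["bin", "meth_fraction", "cpg_oe", "gc"]]


def repeat_context_methylation(
    sites: pd.DataFrame,
    repeats: list[tuple[str, int, int, str]],
    annotation,
    min_cpgs: int = 3,
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Repeat vs containing/surrounding methylation per repeat class.

    Repeats with >= ``min_cpgs`` covered CpGs are classed as
    exon-intersecting, intron-intersecting or non-genic.  The context is
    the intersected exon/intron (repeat CpGs excluded), or for non-genic
    repeats the +-``flank_bp`` flank excluding any repeat or gene bp.  A
    two-sided Wilcoxon rank-sum test compares repeat and context
    fractions per class (skipped below 2 repeats).
    """
    sites = _with_fraction(sites)
    by_scaf = {k: v for k, v in sites.groupby("scaffold")}
    rep_spans: dict[str, list[tuple[int, int]]] = {}
    for scaf, s, e, _ in repeats:
        rep_spans.setdefault(scaf, []).append((s, e))
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.genes:
        gene_spans.setdefault(g.scaffold, []).append((g.start, g.end))

    def frac_of(scaf, include, exclude=()):
        sub = by_scaf.get(scaf)
        if sub is None:
            return np.nan, 0
        pos = sub["pos"].to_numpy()
        mask = np.zeros(len(sub), dtype=bool)
        for s, e in include:
            mask |= (pos >= s) & (pos < e)
        for s, e in exclude:
            mask &= ~((pos >= s) & (pos < e))
        m = sub["m"].to_numpy()[mask]
        u = sub["u"].to_numpy()[mask]
        cov = m + u
        ok = cov > 0
        if not ok.any():
            return np.nan, 0
        return m[ok].sum() / cov[ok].sum(), int(ok.sum())

    rows = []
    for scaf, rs, re_, name in repeats:
        rfrac, n_cpg = frac_of(scaf, [(rs, re_)])
        if n_cpg < min_cpgs:
            continue
        klass = "nongenic"
        context = np.nan
        for g in annotation.genes_on(scaf):
            ex_hit = [(s, e) for s, e in g.exons if s < re_ and rs < e]
            if ex_hit:
                klass = "exonic"
                context, _ = frac_of(scaf, ex_hit, exclude=[(rs, re_)])
                break
            in_hit = [(s, e) for s, e in g.introns if s < re_ and rs < e]
            if in_hit:
                klass = "intronic"
                context, _ = frac_of(scaf, in_hit, exclude=[(rs, re_)])
                break
        if klass == "nongenic":
            flanks = [(max(0, rs - flank_bp), rs), (re_, re_ + flank_bp)]
            excl = list(rep_spans.get(scaf, [])) + list(gene_spans.get(scaf, []))
            context, _ = frac_of(scaf, flanks, exclude=excl)
        rows.append(
            {"repeat": name, "scaffold": scaf, "start": rs, "end": re_,
             "class": klass, "repeat_fraction": rfrac, "context_fraction": context}
        )
    per_repeat = pd.DataFrame(rows)
    summary = []
    for klass in ("exonic", "intronic", "nongenic"):
        grp = per_repeat[per_repeat["class"] == klass] if len(per_repeat) else per_repeat
        if len(grp) < 2:
            summary.append({"class": klass, "n_repeats": len(grp),
                            "repeat_mean": np.nan, "context_mean": np.nan, "p": np.nan})
            continue
        r = grp["repeat_fraction"].dropna()
        c = grp["context_fraction"].dropna()
        p = np.nan
        if len(r) >= 2 and len(c) >= 2:
            p = float(stats.mannwhitneyu(r, c, alternative="two-sided").pvalue)
        summary.append(
            {"class": klass, "n_repeats": len(grp), "repeat_mean": float(r.mean()),
             "context_mean": float(c.mean()) if len(c) else np.nan, "p": p}
        )
    out = pd.DataFrame(summary)
    out.attrs["per_repeat"] = per_repeat
    return out


def ortholog_methylation_classes(
    status: pd.DataFrame,
    species: list[str] | None = None,
    fractions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Venn-style methylation class per 1-to-1 ortholog.

    ``status`` has one row per ortholog (column ``ortholog``) and one
    column per species holding 'methylated'/'unmethylated' (missing rows
    are dropped and counted).  Returns (per-ortholog classes, per-class
    summary with counts and, when per-species ``fractions`` are given,
    mean methylation).
    """
    if status["ortholog"].duplicated().any():
        raise ValueError("duplicate ortholog rows")
    if species is None:
        species = [c for c in status.columns if c != "ortholog"]
    complete = status.dropna(subset=species).copy()
    n_dropped = len(status) - len(complete)

    def label(row):
        meth = [sp for sp in species if row[sp] == METHYLATED]
        if len(meth) == len(species):
            return "all"
        if not meth:
            return "none"
        if len(meth) == 1:
            return f"{meth[0]}-only"
        return "+".join(meth)

    complete["class"] = complete.apply(label, axis=1)
    summary = (
        complete.groupby("class")
        .size()
        .rename("n_orthologs")
        .reset_index()
        .sort_values("class", ignore_index=True)
    )
    if fractions is not None:
        merged = complete.merge(fractions, on="ortholog", how="left",
                                suffixes=("", "_frac"))
        for sp in species:
            col = f"{sp}_frac" if f"{sp}_frac" in merged else None
            if col:
                mean = merged.groupby("class")[col].mean()
                summary[f"mean_fraction_{sp}"] = summary["class"].map(mean)
    summary.attrs["n_dropped_incomplete"] = n_dropped
    return complete[["ortholog", "class"]], summary
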