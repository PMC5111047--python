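"""Motif enrichment around differentially methylated cytosines.

Test sequence sets are fixed-width windows centred on confident DMCs;
controls are windows centred on methylated-but-not-differential cytosines
within 1.5 kb of a tested DMC (and not overlapping any test window),
which controls for the CpG-composition biases of methylated regions.

Position weight matrices (TF binding profiles, or point-mass matrices
built from mature miRNA sequences) are scanned over both strands with a
log2 likelihood-ratio score against a background base composition.  Each
position's p-value comes from the exact distribution of the score under
the background model, computed by dynamic programming over motif columns;
hits are positions with BH q < 0.1 within a sequence set.  Enrichment per
motif is a one-sided Fisher exact test on sequences-with-a-hit
(test vs control), BH-corrected over motifs, and the size-normalised fold
enrichment (pos_hits/n_pos) / (max(neg_hits,1)/n_neg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import bh_fdr

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGT", "TGCA")
UNIFORM = np.full(4, 0.25)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class MotifModel:
    """A motif as per-position A/C/G/T probabilities."""

    id: str
    matrix: np.ndarray  # (length, 4), rows sum to 1
    kind: str = "pwm"
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must be length x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM rows of {self.id!r} must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """log2 likelihood-ratio score matrix against the background."""
        bg = np.asarray(background, dtype=float)
        with np.errstate(divide="ignore"):
            return np.log2(np.maximum(self.matrix, 1e-300)) - np.log2(bg)


def pwm_from_consensus(
    consensus: str, motif_id: str | None = None, pseudocount: float = 0.0
) -> MotifModel:
    """Point-mass PWM for a consensus, optionally pseudocounted."""
    consensus = consensus.upper()
    if set(consensus) - set("ACGT"):
        raise ValueError(f"non-ACGT letter in consensus {consensus!r}")
    L = len(consensus)
    mat = np.full((L, 4), pseudocount)
    for i, c in enumerate(consensus):
        mat[i, _IDX[c]] = 1.0 - 3 * pseudocount
    return MotifModel(motif_id or consensus, mat)


def mirna_to_motif(mature_seq: str, motif_id: str | None = None,
                   pseudocount: float = 0.01) -> MotifModel:
    """Point-mass PWM from a mature miRNA (RNA) sequence.

    U becomes T; each off-consensus letter gets the pseudocount.  Both the
    mature sequence and its reverse complement are matched when scanning
    (target-site convention), since scans cover both strands.
    """
    s = mature_seq.upper().replace("U", "T")
    if set(s) - set("ACGT"):
        raise ValueError(f"non-ACGU letter in miRNA {mature_seq!r}")
    m = pwm_from_consensus(s, motif_id or s, pseudocount=pseudocount)
    m.kind = "mirna"
    return m


def read_meme_motifs(path) -> list[MotifModel]:
    """Minimal MEME-text parser: MOTIF blocks with letter-probability rows."""
    motifs = []
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name and rows:
                    motifs.append(MotifModel(name, np.array(rows)))
                name = line.split()[1]
                rows = []
            elif name is not None:
                parts = line.split()
                if len(parts) == 4:
                    try:
                        rows.append([float(x) for x in parts])
                    except ValueError:
                        pass
    if name and rows:
        motifs.append(MotifModel(name, np.array(rows)))
    return motifs


def write_meme_motifs(motifs: list[MotifModel], path,
                      background: np.ndarray = UNIFORM) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(background))
        for m in motifs:
            fh.write(f"MOTIF {m.id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(m)}\n")
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def estimate_background(seqs) -> np.ndarray:
    """A/C/G/T frequencies pooled over a sequence collection."""
    counts = np.zeros(4)
    for s in seqs:
        s = s.upper()
        for b, i in _IDX.items():
            counts[i] += s.count(b)
    if counts.sum() == 0:
        return UNIFORM.copy()
    return counts / counts.sum()


@dataclass
class ScoreDistribution:
    """Exact null distribution of a PWM score under a background model.

    Built by dynamic programming over motif columns: the state is the set
    of attainable partial score sums with their probabilities.  Partial
    sums accumulate left to right exactly as sequence scoring does, so
    score values coincide bit-for-bit with scanned scores.  If the state
    space explodes (long dense matrices), partial sums are rounded to
    ``round_decimals`` to keep it bounded.
    """

    scores: np.ndarray  # descending
    tail_p: np.ndarray  # P(score >= scores[i])
    max_states: int = field(default=2_000_000, repr=False)

    @classmethod
    def build(
        cls,
        motif: MotifModel,
        background: np.ndarray = UNIFORM,
        max_states: int = 2_000_000,
        round_decimals: int = 9,
    ) -> "ScoreDistribution":
        lo = motif.log_odds(background)
        bg = np.asarray(background, dtype=float)
        state: dict[float, float] = {0.0: 1.0}
        for j in range(len(motif)):
            nxt: dict[float, float] = {}
            for s, p in state.items():
                for b in range(4):
                    ns = s + lo[j, b]
                    nxt[ns] = nxt.get(ns, 0.0) + p * bg[b]
            if len(nxt) > max_states:
                nxt2: dict[float, float] = {}
                for s, p in nxt.items():
                    rs = round(s, round_decimals)
                    nxt2[rs] = nxt2.get(rs, 0.0) + p
                nxt = nxt2
            state = nxt
        scores = np.array(sorted(state, reverse=True))
        probs = np.array([state[s] for s in scores])
        return cls(scores=scores, tail_p=np.cumsum(probs), max_states=max_states)

    def pvalue(self, score) -> np.ndarray:
        """P(score >= s) under the background, vectorized."""
        s = np.atleast_1d(np.asarray(score, dtype=float))
        # scores are descending; find last index with scores >= s
        idx = np.searchsorted(-self.scores, -s, side="right") - 1
        out = np.where(idx >= 0, self.tail_p[np.clip(idx, 0, None)], 0.0)
        return out if np.ndim(score) else float(out[0])


def _scan_one(seq: str, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores at every ungapped position of one strand; N voids a window."""
    L, w = len(seq), lo.shape[0]
    if L < w:
        return np.empty(0, dtype=int), np.empty(0)
    code = np.array([_IDX.get(c, -1) for c in seq.upper()], dtype=int)
    positions = []
    scores = []
    for i in range(L - w + 1):
        window = code[i : i + w]
        if (window < 0).any():
            continue
        s = 0.0
        for j in range(w):
            s += lo[j, window[j]]
        positions.append(i)
        scores.append(s)
    return np.array(positions, dtype=int), np.array(scores)


def pwm_scan(
    seqs: dict[str, str],
    motif: MotifModel,
    background: np.ndarray = UNIFORM,
    q_thresh: float = 0.1,
    both_strands: bool = True,
    dist: ScoreDistribution | None = None,
) -> pd.DataFrame:
    """Scan a sequence set with one motif.

    Every position on each strand is scored; p-values come from the exact
    background score distribution, and BH runs over all scanned positions
    of the set.  A hit is a position with q < ``q_thresh``.  Sequences
    shorter than the motif contribute no positions.
    """
    if dist is None:
        dist = ScoreDistribution.build(motif, background)
    lo = motif.log_odds(background)
    rows = []
    for sid, seq in seqs.items():
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", revcomp(seq)))
        for strand, s in strands:
            pos, sc = _scan_one(s, lo)
            if strand == "-" and len(pos):
                pos = len(seq) - lo.shape[0] - pos  # plus-strand coordinates
            for p_, s_ in zip(pos, sc):
                rows.append((sid, int(p_), strand, float(s_)))
    if not rows:
        return pd.DataFrame(columns=["seq", "pos", "strand", "score", "p", "q", "hit"])
    out = pd.DataFrame(rows, columns=["seq", "pos", "strand", "score"])
    out["p"] = dist.pvalue(out["score"].to_numpy())
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["hit"] = out["q"] < q_thresh
    return out


def build_sequence_sets(
    dmcs: pd.DataFrame,
    non_dmcs: pd.DataFrame,
    genome,
    width: int = 150,
    max_dist: int = 1500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DMC-centred test windows and distance-matched control windows.

    Test window = [anchor - ceil((w-1)/2), anchor + floor((w-1)/2) + 1).
    Controls keep only non-DMC anchors within ``max_dist`` of some DMC
    whose windows do not overlap any test window.  Anchors too close to a
    scaffold edge are dropped (counted in ``attrs['n_dropped']``).
    """
    left = (width - 1 + 1) // 2  # ceil((w-1)/2)
    right = (width - 1) // 2

    def windows(anchors: pd.DataFrame) -> tuple[pd.DataFrame, int]:
        rows = []
        dropped = 0
        for r in anchors.itertuples():
            start, end = r.pos - left, r.pos + right + 1
            slen = len(genome.sequences[r.scaffold])
            if start < 0 or end > slen:
                dropped += 1
                continue
            rows.append(
                {"scaffold": r.scaffold, "start": start, "end": end, "anchor": r.pos,
                 "seq": genome.fetch(r.scaffold, start, end)}
            )
        return pd.DataFrame(rows, columns=["scaffold", "start", "end", "anchor", "seq"]), dropped

    test, test_dropped = windows(dmcs)
    ctrl_all, ctrl_dropped = windows(non_dmcs)

    dmc_pos = {k: np.sort(v["anchor"].to_numpy()) for k, v in test.groupby("scaffold")}
    test_iv = {k: v[["start", "end"]].to_numpy() for k, v in test.groupby("scaffold")}
    keep = []
    for r in ctrl_all.itertuples():
        anchors = dmc_pos.get(r.scaffold)
        if anchors is None or len(anchors) == 0:
            keep.append(False)
            continue
        i = np.searchsorted(anchors, r.anchor)
        near = min(
            abs(r.anchor - anchors[max(i - 1, 0)]),
            abs(r.anchor - anchors[min(i, len(anchors) - 1)]),
        )
        if near > max_dist:
            keep.append(False)
            continue
        ivs = test_iv[r.scaffold]
        overlaps = bool(np.any((r.start < ivs[:, 1]) & (ivs[:, 0] < r.end)))
        keep.append(not overlaps)
    control = ctrl_all[np.array(keep, dtype=bool)] if len(ctrl_all) else ctrl_all
    control = control.reset_index(drop=True)
    test.attrs["n_dropped"] = test_dropped
    control.attrs["n_dropped"] = ctrl_dropped
    test.attrs["control_test_ratio"] = (
        len(control) / len(test) if len(test) else float("nan")
    )
    return test, control


def fold_enrichment(pos_hits: int, neg_hits: int, n_pos: int, n_neg: int) -> float:
    """Size-normalised fold enrichment of hit counts.

    fold = (pos_hits/n_pos) / (max(neg_hits,1)/n_neg): a zero-hit control
    set contributes a denominator count of one rather than dividing by
    zero.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("set sizes must be positive")
    return (pos_hits / n_pos) / (max(neg_hits, 1) / n_neg)


def fisher_enrichment(
    pos_with: int, n_pos: int, neg_with: int, n_neg: int
) -> tuple[float, float]:
    """One-sided Fisher exact test on sequences-with-a-hit counts.

    Returns (odds ratio, p).  Degenerate margins give p = 1.
    """
    table = [[pos_with, n_pos - pos_with], [neg_with, n_neg - neg_with]]
    if min(n_pos, n_neg) == 0 or (pos_with + neg_with) == 0:
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def enrich_motifs(
    test_seqs: dict[str, str],
    control_seqs: dict[str, str],
    motifs: list[MotifModel],
    background: np.ndarray | None = None,
    q_thresh: float = 0.1,
) -> pd.DataFrame:
    """Scan both sets with every motif and summarise enrichment.

    The background defaults to the base composition of the pooled control
    set.  Output columns mirror an enrichment table: significant hit
    counts, sequences-with-hit counts, Fisher p and BH q over motifs, and
    the size-normalised fold enrichment.
    """
    if background is None:
        background = estimate_background(control_seqs.values())
    rows = []
    n_pos, n_neg = len(test_seqs), len(control_seqs)
    for m in motifs:
        dist = ScoreDistribution.build(m, background)
        ht = pwm_scan(test_seqs, m, background, q_thresh=q_thresh, dist=dist)
        hc = pwm_scan(control_seqs, m, background, q_thresh=q_thresh, dist=dist)
        pos_hits = int(ht["hit"].sum())
        neg_hits = int(hc["hit"].sum())
        pos_with = int(ht.loc[ht["hit"], "seq"].nunique())
        neg_with = int(hc.loc[hc["hit"], "seq"].nunique())
        odds, p = fisher_enrichment(pos_with, n_pos, neg_with, n_neg)
        rows.append(
            {
                "motif": m.id,
                "pos_hits": pos_hits,
                "neg_hits": neg_hits,
                "pos_seqs_with_hit": pos_with,
                "neg_seqs_with_hit": neg_with,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "odds_ratio": odds,
                "p": p,
                "fold": fold_enrichment(pos_hits, neg_hits, n_pos, n_neg)
                if n_pos and n_neg
                else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def phenotype_specific_enrichment(
    caste_vs_control: pd.DataFrame,
    sex_vs_control: pd.DataFrame,
    caste_vs_sex: pd.DataFrame,
    sex_vs_caste: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Label each enriched motif caste / sex / ns.

    A motif enriched against its flank controls is labelled "caste"
    ("sex") when it is also enriched using the other phenotype's test set
    as control; enrichment against flank controls only yields "ns".
    Motifs enriched nowhere are absent from the table.
    """
    def sig(df):
        return set(df.loc[df["q"] < alpha, "motif"]) if len(df) else set()

    base_caste, base_sex = sig(caste_vs_control), sig(sex_vs_control)
    cross_caste, cross_sex = sig(caste_vs_sex), sig(sex_vs_caste)
    rows = []
    for motif in sorted(base_caste | base_sex):
        if motif in base_caste and motif in cross_caste:
            label = "caste"
        elif motif in base_sex and motif in cross_sex:
            label = "sex"
        else:
            label = "ns"
        rows.append(
            {
                "motif": motif,
                "enriched_caste": motif in base_caste,
                "enriched_sex": motif in base_sex,
                "comparison": label,
            }
        )
    return pd.DataFrame(rows, columns=["motif", "enriched_caste", "enriched_sex",
                                       "comparison"])
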