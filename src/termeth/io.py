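"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversion to and
from the 1-based closed convention happens only at the GFF3 boundary and
the cytosine-report boundary.  CpG dyads are strand-combined: the plus- and
minus-strand cytosines of one dyad are merged into a single site keyed by
the 0-based position of the plus-strand C (symmetric CpG methylation
assumption).

All result tables are TSV with a header line beginning ``#`` and a
deterministic row order, so byte-identical re-runs are possible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")


@dataclass
class GenomeAssembly:
    """A genome as a map scaffold-id -> uppercase A/C/G/T/N string."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, scaffold: str, start: int, end: int) -> str:
        """Subsequence in 0-based half-open coordinates."""
        return self.sequences[scaffold][start:end]

    def cpg_positions(self, scaffold: str) -> np.ndarray:
        """0-based positions of the plus-strand C of every CpG dyad."""
        seq = self.sequences[scaffold]
        return np.array([m.start() for m in re.finditer("CG", seq)], dtype=int)


@dataclass
class GeneModel:
    """A gene with ordered, disjoint exons; introns are the gaps between them."""

    id: str
    scaffold: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    promoter: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base on '+', rightmost on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]


@dataclass
class AnnotationSet:
    genes: list[GeneModel]
    repeats: list[tuple[str, int, int, str]] = field(default_factory=list)

    def by_id(self) -> dict[str, GeneModel]:
        return {g.id: g for g in self.genes}

    def genes_on(self, scaffold: str) -> list[GeneModel]:
        return [g for g in self.genes if g.scaffold == scaffold]


def read_genome(path) -> GenomeAssembly:
    """Load a FASTA; lowercase is upcased, non-ACGTN letters become N."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not set(seq) <= _VALID:
            seq = "".join(c if c in _VALID else "N" for c in seq)
        sequences[rec.id] = seq
    return GenomeAssembly(sequences)


def write_genome(genome: GenomeAssembly, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(genome.sequences.items())
    ]
    SeqIO.write(recs, str(path), "fasta")


def _derive_promoter(
    strand: str, start: int, end: int, promoter_len: int, scaffold_len: int | None
) -> tuple[int, int]:
    if strand == "+":
        p = (max(0, start - promoter_len), start)
    else:
        hi = end + promoter_len
        if scaffold_len is not None:
            hi = min(hi, scaffold_len)
        p = (end, hi)
    return p


def read_annotation(
    path,
    promoter_len: int = 1000,
    genome: GenomeAssembly | None = None,
    repeats_bed=None,
) -> AnnotationSet:
    """Parse a GFF3 with gene/mRNA/exon features into gene models.

    GFF3 1-based closed coordinates become 0-based half-open.  Exons of all
    isoforms of one gene are unioned (overlaps merged).  The promoter is
    ``promoter_len`` bp upstream of the TSS on the gene strand, clipped at
    scaffold bounds when the genome is supplied.
    """
    import gffutils

    lengths = genome.lengths if genome is not None else {}
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exon_ivs: list[tuple[int, int]] = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            start, end = exon.start - 1, exon.end
            slen = lengths.get(exon.seqid)
            if slen is not None and (start < 0 or end > slen):
                raise ValueError(
                    f"exon {start}-{end} of feature {gene.id!r} outside "
                    f"scaffold {exon.seqid}"
                )
            exon_ivs.append((start, end))
        exons = _merge_intervals(exon_ivs)
        if not exons:
            continue
        strand = gene.strand if gene.strand in "+-" else "+"
        prom = _derive_promoter(
            strand, exons[0][0], exons[-1][1], promoter_len,
            lengths.get(gene.seqid),
        )
        genes.append(GeneModel(gene.id, gene.seqid, strand, exons, promoter=prom))

    repeats: list[tuple[str, int, int, str]] = []
    if repeats_bed is not None:
        repeats = read_bed(repeats_bed)
    return AnnotationSet(genes, repeats)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def write_annotation(ann: AnnotationSet, path) -> None:
    """Write gene models as GFF3 (gene + mRNA + exon rows, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(ann.genes, key=lambda g: (g.scaffold, g.start, g.id)):
            fh.write(
                f"{g.scaffold}\ttermeth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )
            mid = f"{g.id}.t1"
            fh.write(
                f"{g.scaffold}\ttermeth\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mid};Parent={g.id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.scaffold}\ttermeth\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tParent={mid}\n"
                )


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """BED (0-based half-open) -> (scaffold, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            name = f[3].strip() if len(f) > 3 else "."
            out.append((f[0], int(f[1]), int(f[2]), name))
    return out


def write_bed(rows, path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a Bismark-style CpG cytosine report into strand-combined dyads.

    Expected columns: scaffold, 1-based position, strand, count-methylated,
    count-unmethylated, context.  Only CpG-context rows are kept; the two
    strands of a dyad are summed into one site keyed by the 0-based position
    of the plus-strand C.

    Returns a DataFrame with columns scaffold, pos, m, u sorted by
    (scaffold, pos).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["scaffold", "pos1", "strand", "m", "u", "context"],
        dtype={"scaffold": str, "pos1": int, "strand": str, "context": str},
    )
    if (df["m"] < 0).any() or (df["u"] < 0).any():
        raise ValueError(f"negative counts in cytosine report {path}")
    df = df[df["context"].isin(["CG", "CpG"])].copy()
    df["pos"] = np.where(df["strand"] == "+", df["pos1"] - 1, df["pos1"] - 2)
    out = (
        df.groupby(["scaffold", "pos"], as_index=False)[["m", "u"]]
        .sum()
        .sort_values(["scaffold", "pos"], kind="mergesort", ignore_index=True)
    )
    return out[["scaffold", "pos", "m", "u"]]


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    """Write strand-combined dyad counts back out in the report dialect.

    Each dyad is emitted as its two strand rows with the plus strand
    carrying all counts (the reader sums them again), keeping the file a
    valid instance of the dialect.
    """
    with open(path, "w") as fh:
        for row in df.sort_values(["scaffold", "pos"], kind="mergesort").itertuples():
            fh.write(f"{row.scaffold}\t{row.pos + 1}\t+\t{row.m}\t{row.u}\tCG\n")
            fh.write(f"{row.scaffold}\t{row.pos + 2}\t-\t0\t0\tCG\n")


def combine_sample_counts(per_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Outer-join per-sample dyad tables into one wide table.

    Columns: scaffold, pos, then m_<sample>, u_<sample> per sample, with 0
    where a sample did not cover a site.
    """
    wide = None
    for name in sorted(per_sample):
        df = per_sample[name].rename(columns={"m": f"m_{name}", "u": f"u_{name}"})
        wide = df if wide is None else wide.merge(df, on=["scaffold", "pos"], how="outer")
    if wide is None:
        raise ValueError("no samples supplied")
    wide = wide.fillna(0).sort_values(
        ["scaffold", "pos"], kind="mergesort", ignore_index=True
    )
    for c in wide.columns[2:]:
        wide[c] = wide[c].astype(int)
    return wide


def write_table(df: pd.DataFrame, path) -> None:
    """TSV with a '#'-prefixed header line; floats at full precision."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        return pd.read_csv(
            fh, sep="\t", header=None, names=header, float_precision="round_trip"
        )
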