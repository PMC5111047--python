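"""Synthetic genomes, methylomes, expression counts and motif plants.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* a bimodal gene-body methylation landscape — a configurable fraction of
  genes is highly methylated (true CpG methylation level
  ``high_meth_level``), the rest essentially unmethylated
  (``low_meth_level``) — with methylated genes spatially clustered and
  more closely spaced (``cluster_factor``);
* 4 phenotypes (alate/worker x male/female) with ``n_reps`` replicated
  methylomes each, caste- or sex-biased hypermethylated regions planted
  inside designated genes;
* bisulfite conversion error: unmethylated cytosines are read as
  methylated at rate ``conversion_error`` (default 0.5%), and a fully
  unmethylated lambda spike-in with the same error accompanies every
  library;
* stranded expression counts, negative-binomial across replicates, with a
  small baseline antisense read fraction and designated loci of elevated
  antisense transcription;
* TF/miRNA motif instances written into the sequence near designated
  differentially methylated cytosines.

Coverage is Poisson(``mean_coverage``) per dyad per library and the
methylated read count is Binomial(coverage, pi(1 - over_conversion) +
(1 - pi) * conversion_error).  Every output stream derives its RNG from
(master seed, output name), so adding samples never reshuffles existing
ones and a fixed seed reproduces every byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import ConversionControl
from .design import StudyDesign, default_methylome_design, default_transcriptome_design
from .io import AnnotationSet, GeneModel, GenomeAssembly

_BASES = np.array(list("ACGT"))


def _rng(seed: int, name: str) -> np.random.Generator:
    """One stream per output, keyed by (master seed, name)."""
    return np.random.default_rng([seed, zlib.crc32(name.encode()) & 0x7FFFFFFF])


@dataclass
class SimulationDesign:
    """Parameters of one synthetic study.

    ``caste_dmr_spec`` / ``sex_dmr_spec`` are lists of
    (gene_index, pi_side_a, pi_side_b) — side A is alate (resp. male).  A
    window-aligned region of ``dmr_len`` bp inside the gene body gets
    these phenotype-specific methylation levels instead of the gene's
    base level.
    """

    seed: int
    n_scaffolds: int = 2
    scaffold_len: int = 60_000
    n_genes: int = 30
    gene_len: int = 2_000
    n_exons_per_gene: int = 3
    promoter_len: int = 500
    fraction_methylated_genes: float = 0.7
    cluster_factor: float = 1.0
    high_meth_level: float = 0.8
    low_meth_level: float = 0.01
    promoters_unmethylated: bool = True
    conversion_error: float = 0.005
    over_conversion: float = 0.0
    mean_coverage: float = 20.0
    n_reps: int = 2
    control_cytosines: int = 20_000
    caste_dmr_spec: list[tuple[int, float, float]] = field(default_factory=list)
    sex_dmr_spec: list[tuple[int, float, float]] = field(default_factory=list)
    dmr_len: int = 200
    # expression
    n_expr_reps: int = 3
    expr_base_mean: float = 200.0
    nb_dispersion: float = 0.2
    antisense_base: float = 0.05
    antisense_signal_prop: float = 0.30
    n_antisense_loci: int = 0
    n_de_genes: int = 0
    de_log2fc: float = 1.0
    transcript_len: int = 1_500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in (
            "fraction_methylated_genes",
            "high_meth_level",
            "low_meth_level",
            "conversion_error",
            "over_conversion",
            "antisense_base",
            "antisense_signal_prop",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for spec in list(self.caste_dmr_spec) + list(self.sex_dmr_spec):
            _, pa, pb = spec
            if not (0 <= pa <= 1 and 0 <= pb <= 1):
                raise ValueError(f"DMR methylation levels {spec} outside [0, 1]")

    def methylome_design(self) -> StudyDesign:
        return default_methylome_design(self.n_reps)

    def transcriptome_design(self) -> StudyDesign:
        return default_transcriptome_design(self.n_expr_reps)


def simulate_genome(
    design: SimulationDesign,
) -> tuple[GenomeAssembly, AnnotationSet, dict[str, pd.DataFrame]]:
    """Random genome with clustered methylated genes and planted DMRs.

    Returns the assembly, the annotation and a truth bundle with
    ``genes`` (per-gene class and placement) and ``dmrs`` (planted
    phenotype-specific regions).
    """
    d = design
    rng = _rng(d.seed, "genome")
    per_scaf = -(-d.n_genes // d.n_scaffolds)
    footprint = d.gene_len + d.promoter_len
    if per_scaf * footprint > d.scaffold_len:
        raise ValueError(
            f"{per_scaf} genes x {footprint} bp exceed scaffold length "
            f"{d.scaffold_len}"
        )

    n_meth = round(d.n_genes * d.fraction_methylated_genes)
    labels = np.array([True] * n_meth + [False] * (d.n_genes - n_meth))
    if d.cluster_factor <= 0:
        rng.shuffle(labels)
    else:
        # start fully clustered, then swap pairs to dilute clustering
        n_swaps = int(round(d.n_genes * (1.0 - d.cluster_factor)))
        for _ in range(n_swaps):
            i, j = rng.integers(0, d.n_genes, size=2)
            labels[i], labels[j] = labels[j], labels[i]

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    rows = []
    gi = 0
    for si in range(d.n_scaffolds):
        scaf = f"scaffold_{si + 1}"
        seq = _BASES[rng.integers(0, 4, size=d.scaffold_len)]
        here = labels[si * per_scaf : (si + 1) * per_scaf]
        n_here = len(here)
        if n_here:
            slack = d.scaffold_len - n_here * footprint
            base_gap = slack / (n_here + 1)
            pos = 0.0
            for k, meth in enumerate(here):
                prev_meth = here[k - 1] if k > 0 else False
                # methylated neighbours sit closer together
                gap = base_gap * (0.3 if (meth and prev_meth and d.cluster_factor > 0) else 1.3)
                pos = min(pos + gap, d.scaffold_len - (n_here - k) * footprint)
                start = int(pos) + d.promoter_len
                exons = _split_exons(start, start + d.gene_len, d.n_exons_per_gene)
                gid = f"g{gi + 1:04d}"
                genes.append(
                    GeneModel(
                        gid,
                        scaf,
                        "+",
                        exons,
                        promoter=(start - d.promoter_len, start),
                    )
                )
                rows.append(
                    {
                        "gene": gid,
                        "scaffold": scaf,
                        "start": start,
                        "end": start + d.gene_len,
                        "strand": "+",
                        "methylated": bool(meth),
                    }
                )
                pos = start + d.gene_len
                gi += 1
        sequences[scaf] = "".join(seq)

    gene_truth = pd.DataFrame(rows)
    dmr_rows = []
    for kind, spec in (("caste", d.caste_dmr_spec), ("sex", d.sex_dmr_spec)):
        for idx, pa, pb in spec:
            g = gene_truth.iloc[idx]
            # window-aligned region inside the gene body
            start = ((int(g["start"]) // d.dmr_len) + 1) * d.dmr_len
            end = start + d.dmr_len
            if end > int(g["end"]):
                raise ValueError(f"gene {g['gene']} too short for a planted DMR")
            dmr_rows.append(
                {
                    "kind": kind,
                    "gene": g["gene"],
                    "scaffold": g["scaffold"],
                    "start": start,
                    "end": end,
                    "pi_a": pa,
                    "pi_b": pb,
                }
            )
    dmr_truth = pd.DataFrame(
        dmr_rows,
        columns=["kind", "gene", "scaffold", "start", "end", "pi_a", "pi_b"],
    )
    genome = GenomeAssembly(sequences)
    ann = AnnotationSet(genes)
    truth = {"genes": gene_truth, "dmrs": dmr_truth}
    return genome, ann, truth


def _split_exons(start: int, end: int, n: int) -> list[tuple[int, int]]:
    """Split a gene span into n exons separated by introns of equal size."""
    if n == 1:
        return [(start, end)]
    L = end - start
    exon_len = L // (2 * n - 1)
    exons = []
    p = start
    for i in range(n):
        e = end if i == n - 1 else p + exon_len
        exons.append((p, e))
        p = e + exon_len
    return exons


def true_pi(
    genome: GenomeAssembly,
    annotation: AnnotationSet,
    truth: dict[str, pd.DataFrame],
    design: SimulationDesign,
) -> pd.DataFrame:
    """Per-CpG true methylation level per morph.

    Columns: scaffold, pos, pi_<morph> for the four phenotypes.  Base
    level is ``high_meth_level`` within methylated gene bodies (promoters
    optionally reset to the low level), ``low_meth_level`` elsewhere;
    planted DMRs override phenotype-specifically.
    """
    d = design
    meth_genes = set(truth["genes"].loc[truth["genes"]["methylated"], "gene"])
    frames = []
    morphs = ["alate_male", "alate_female", "worker_male", "worker_female"]
    for scaf in sorted(genome.sequences):
        pos = genome.cpg_positions(scaf)
        base = np.full(len(pos), d.low_meth_level)
        for g in annotation.genes_on(scaf):
            if g.id in meth_genes:
                base[(pos >= g.start) & (pos < g.end)] = d.high_meth_level
        if d.promoters_unmethylated:
            for g in annotation.genes_on(scaf):
                if g.promoter is not None:
                    s, e = g.promoter
                    base[(pos >= s) & (pos < e)] = d.low_meth_level
        df = pd.DataFrame({"scaffold": scaf, "pos": pos})
        for m in morphs:
            df[f"pi_{m}"] = base
        for r in truth["dmrs"].itertuples():
            if r.scaffold != scaf:
                continue
            inside = (pos >= r.start) & (pos < r.end)
            if r.kind == "caste":
                for m in morphs:
                    df.loc[inside, f"pi_{m}"] = r.pi_a if m.startswith("alate") else r.pi_b
            else:
                for m in morphs:
                    df.loc[inside, f"pi_{m}"] = r.pi_a if m.endswith("male") else r.pi_b
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_methylomes(
    genome: GenomeAssembly,
    annotation: AnnotationSet,
    truth: dict[str, pd.DataFrame],
    design: SimulationDesign,
) -> tuple[dict[str, pd.DataFrame], dict[str, ConversionControl]]:
    """Per-library dyad count tables plus lambda spike-in controls."""
    d = design
    pi_table = true_pi(genome, annotation, truth, design)
    counts: dict[str, pd.DataFrame] = {}
    controls: dict[str, ConversionControl] = {}
    for s in design.methylome_design().samples:
        rng = _rng(d.seed, f"methylome:{s.name}")
        pi = pi_table[f"pi_{s.morph}"].to_numpy()
        cov = rng.poisson(d.mean_coverage, size=len(pi))
        p_obs = pi * (1 - d.over_conversion) + (1 - pi) * d.conversion_error
        m = rng.binomial(cov, p_obs)
        counts[s.name] = pd.DataFrame(
            {
                "scaffold": pi_table["scaffold"],
                "pos": pi_table["pos"],
                "m": m,
                "u": cov - m,
            }
        )
        ctrl_cov = rng.poisson(d.mean_coverage, size=d.control_cytosines)
        total = int(ctrl_cov.sum())
        unconv = int(rng.binomial(total, d.conversion_error))
        controls[s.name] = ConversionControl(unconv, max(total, 1))
    return counts, controls


def simulate_expression(
    truth: dict[str, pd.DataFrame], design: SimulationDesign
) -> dict[str, pd.DataFrame | pd.Series | list[str]]:
    """Stranded per-library gene counts with a small antisense fraction.

    Total locus reads are negative-binomial around morph-specific means;
    the antisense read count is Binomial(total, antisense proportion),
    with designated loci (the first ``n_antisense_loci`` genes) elevated
    to ``antisense_signal_prop``.  The first ``n_de_genes`` methylated
    genes are upregulated in alates by ``de_log2fc`` log2 units.
    """
    d = design
    genes = truth["genes"]["gene"].tolist()
    n = len(genes)
    tdesign = design.transcriptome_design()
    de_genes = set(genes[: d.n_de_genes])
    as_loci = set(genes[: d.n_antisense_loci])
    sense = {}
    anti = {}
    nb_n = 1.0 / d.nb_dispersion if d.nb_dispersion > 0 else None
    for s in tdesign.samples:
        rng = _rng(d.seed, f"expression:{s.name}")
        mean = np.full(n, d.expr_base_mean)
        if s.caste == "alate":
            mean[[g in de_genes for g in genes]] *= 2.0**d.de_log2fc
        if nb_n is None:
            total = rng.poisson(mean)
        else:
            p = nb_n / (nb_n + mean)
            total = rng.negative_binomial(nb_n, p)
        prop = np.where(
            [g in as_loci for g in genes], d.antisense_signal_prop, d.antisense_base
        )
        a = rng.binomial(total, prop)
        sense[s.name] = total - a
        anti[s.name] = a
    sense_df = pd.DataFrame(sense, index=genes)
    anti_df = pd.DataFrame(anti, index=genes)
    lengths = pd.Series(d.transcript_len, index=genes, name="length")
    return {
        "sense": sense_df,
        "antisense": anti_df,
        "lengths": lengths,
        "antisense_loci": sorted(as_loci),
        "de_genes": sorted(de_genes),
    }


def plant_motifs(
    genome: GenomeAssembly, plants: list[tuple[str, int, str]]
) -> tuple[GenomeAssembly, pd.DataFrame]:
    """Write motif instances into the sequence at recorded positions.

    ``plants`` is a list of (scaffold, 0-based position, sequence).
    Overlapping plants are an error; the returned truth table lists every
    planted instance.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for scaf, pos, seq in plants:
        if scaf not in genome.sequences:
            raise KeyError(f"unknown scaffold {scaf!r}")
        if pos < 0 or pos + len(seq) > len(genome.sequences[scaf]):
            raise ValueError(f"plant at {scaf}:{pos} outside scaffold")
        for s, e in spans.get(scaf, []):
            if pos < e and s < pos + len(seq):
                raise ValueError(f"overlapping plants at {scaf}:{pos}")
        spans.setdefault(scaf, []).append((pos, pos + len(seq)))
    sequences = dict(genome.sequences)
    rows = []
    for scaf, pos, seq in plants:
        s = sequences[scaf]
        sequences[scaf] = s[:pos] + seq.upper() + s[pos + len(seq) :]
        rows.append({"scaffold": scaf, "pos": pos, "sequence": seq.upper()})
    return GenomeAssembly(sequences), pd.DataFrame(
        rows, columns=["scaffold", "pos", "sequence"]
    )
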