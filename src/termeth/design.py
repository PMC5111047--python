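"""Study design: which library belongs to which caste, sex and replicate.

The design of the study is 4 phenotypes (alate/worker x male/female).
Methylomes carry 2 replicates per phenotype (8 libraries) and transcriptomes
3 (12 libraries).  Caste comparisons pool both sexes on each side (4 vs 4
methylome libraries); sex comparisons pool both castes.
"""

from __future__ import annotations

from dataclasses import dataclass

CASTES = ("alate", "worker")
SEXES = ("male", "female")


@dataclass(frozen=True)
class SampleInfo:
    name: str
    caste: str
    sex: str
    replicate: int

    def __post_init__(self) -> None:
        if self.caste not in CASTES:
            raise ValueError(f"unknown caste {self.caste!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def morph(self) -> str:
        return f"{self.caste}_{self.sex}"


@dataclass
class StudyDesign:
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample names in design")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.samples]

    def morphs(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(s.morph, []).append(s.name)
        return out

    def sides(self, comparison: str) -> tuple[list[str], list[str]]:
        """Sample names on each side of a comparison.

        ``caste``: alates (both sexes) vs workers; ``sex``: males (both
        castes) vs females.  Side A is alate / male respectively.
        """
        if comparison == "caste":
            a = [s.name for s in self.samples if s.caste == "alate"]
            b = [s.name for s in self.samples if s.caste == "worker"]
        elif comparison == "sex":
            a = [s.name for s in self.samples if s.sex == "male"]
            b = [s.name for s in self.samples if s.sex == "female"]
        else:
            raise ValueError(f"unknown comparison {comparison!r}")
        return a, b

    def pair_comparisons(self, comparison: str) -> list[tuple[list[str], list[str]]]:
        """The two constituent pairwise comparisons of a pooled contrast.

        For caste: (AF vs WF) and (AM vs WM); for sex: (AM vs AF) and
        (WM vs WF).  Used for the conservative paired-intersection list.
        """
        by = {(s.caste, s.sex): [] for s in self.samples}
        for s in self.samples:
            by[(s.caste, s.sex)].append(s.name)
        if comparison == "caste":
            return [
                (by[("alate", "female")], by[("worker", "female")]),
                (by[("alate", "male")], by[("worker", "male")]),
            ]
        if comparison == "sex":
            return [
                (by[("alate", "male")], by[("alate", "female")]),
                (by[("worker", "male")], by[("worker", "female")]),
            ]
        raise ValueError(f"unknown comparison {comparison!r}")


def default_methylome_design(n_reps: int = 2) -> StudyDesign:
    """The replicated 4-phenotype methylome design (2 reps -> 8 libraries)."""
    samples = [
        SampleInfo(f"{c[0].upper()}{x[0].upper()}{r}", c, x, r)
        for c in CASTES
        for x in SEXES
        for r in range(1, n_reps + 1)
    ]
    return StudyDesign(samples)


def default_transcriptome_design(n_reps: int = 3) -> StudyDesign:
    """The replicated transcriptome design (3 reps -> 12 libraries)."""
    return default_methylome_design(n_reps)
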