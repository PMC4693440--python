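"""Mendelian candidate-variant filtration for dominant pedigrees.

Implements the exome-narrowing funnel used to pin down a dominant
spinocerebellar-ataxia variant: sequential exclusion by public-database
membership (dbSNP / 1000 Genomes / ESP6500), genomic function class,
heterozygous zygosity, sharing across affected individuals, and an in-house
disease-cohort database; a 2-of-3 pathogenicity-prediction consensus rule
(PolyPhen-2 / SIFT / MutationTaster style calls); a pedigree segregation
check; and detection of the shared haplotype interval around an index marker
in two family haplotypes.

Annotation is assumed to have happened upstream (Annovar-style flags in the
input); no live database queries are made.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "PedigreeSample",
    "HaplotypeMatrix",
    "FunnelResult",
    "SegregationResult",
    "SharedInterval",
    "DEFAULT_STAGES",
    "RETAINED_FUNCTION_CLASSES",
    "funnel_filter",
    "prediction_consensus",
    "check_segregation",
    "shared_haplotype_interval",
    "read_ped",
    "write_ped",
    "read_variants_tsv",
    "write_variants_tsv",
]

GENOTYPES = ("ref", "het", "hom", "missing")
PREDICTION_CALLS = ("damaging", "benign", "unknown")

#: function classes retained by the "genomic position and function" stage:
#: protein-altering exonic classes plus splicing.
RETAINED_FUNCTION_CLASSES = frozenset(
    {
        "exonic-nonsynonymous",
        "exonic-stopgain",
        "exonic-stoploss",
        "exonic-frameshift",
        "exonic-nonframeshift",
        "splicing",
    }
)

DEFAULT_STAGES = ("database", "function", "zygosity", "shared", "inhouse")


@dataclass
class VariantRecord:
    """One annotated variant with per-sample genotypes and prediction calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    function_class: str
    in_dbsnp: bool = False
    in_1000g: bool = False
    in_esp: bool = False
    in_inhouse: bool = False
    genotypes: dict = field(default_factory=dict)  # sample id -> ref|het|hom|missing
    prediction_calls: tuple = ("unknown", "unknown", "unknown")

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"variant position must be positive, got {self.pos}")
        if len(self.prediction_calls) != 3:
            raise ValueError("exactly 3 prediction-call slots are required")
        for call in self.prediction_calls:
            if call not in PREDICTION_CALLS:
                raise ValueError(f"unknown prediction call {call!r}")
        for s, g in self.genotypes.items():
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype {g!r} for sample {s}")

    def carries_alt(self, sample_id: str) -> bool:
        return self.genotypes.get(sample_id) in ("het", "hom")


@dataclass(frozen=True)
class PedigreeSample:
    """One individual of a 6-column PED pedigree."""

    family_id: str
    sample_id: str
    father_id: str = "0"
    mother_id: str = "0"
    sex: int = 0  # 1 male, 2 female, 0 unknown
    status: str = "unknown"  # affected | unaffected | unknown

    def __post_init__(self) -> None:
        if self.status not in ("affected", "unaffected", "unknown"):
            raise ValueError(f"unknown affection status {self.status!r}")


@dataclass(frozen=True)
class HaplotypeMatrix:
    """Ordered marker positions with named per-haplotype allele vectors."""

    positions_bp: tuple
    haplotypes: dict  # name -> tuple of alleles

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_bp)
        if pos.size and not np.all(np.diff(pos) > 0):
            raise ValueError("marker positions must be strictly increasing")
        for name, alleles in self.haplotypes.items():
            if len(alleles) != len(self.positions_bp):
                raise ValueError(f"haplotype {name!r} length mismatch")


# ---------------------------------------------------------------------------
# funnel


@dataclass
class FunnelResult:
    survivors: list
    stage_counts: list  # [(stage name, count after stage)], first entry ("input", n)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_counts, columns=["stage", "n_variants"])


def _stage_database(v: VariantRecord, affected_ids) -> bool:
    return not (v.in_dbsnp or v.in_1000g or v.in_esp)


def _stage_function(v: VariantRecord, affected_ids) -> bool:
    return v.function_class in RETAINED_FUNCTION_CLASSES


def _stage_zygosity(v: VariantRecord, affected_ids) -> bool:
    # dominant model: any affected carrier must be heterozygous
    return all(v.genotypes.get(s) != "hom" for s in affected_ids)


def _stage_shared(v: VariantRecord, affected_ids) -> bool:
    return all(v.carries_alt(s) for s in affected_ids)


def _stage_inhouse(v: VariantRecord, affected_ids) -> bool:
    return not v.in_inhouse


_STAGE_PREDICATES = {
    "database": _stage_database,
    "function": _stage_function,
    "zygosity": _stage_zygosity,
    "shared": _stage_shared,
    "inhouse": _stage_inhouse,
}


def funnel_filter(variants, affected_ids, stages=DEFAULT_STAGES) -> FunnelResult:
    """Apply the candidate-variant funnel in the given stage order.

    Stages (default order): ``database`` drops variants present in any of
    dbSNP / 1000 Genomes / ESP; ``function`` retains protein-altering exonic
    classes and splicing; ``zygosity`` drops variants homozygous in any
    affected (dominant expectation); ``shared`` keeps variants carried by
    every affected individual; ``inhouse`` drops variants seen in the
    in-house database of other diseases.

    Returns the survivors plus the variant count after every stage.
    """
    affected_ids = list(affected_ids)
    for stage in stages:
        if stage not in _STAGE_PREDICATES:
            raise ValueError(f"unknown funnel stage {stage!r}; known: {sorted(_STAGE_PREDICATES)}")
    current = list(variants)
    counts = [("input", len(current))]
    for stage in stages:
        pred = _STAGE_PREDICATES[stage]
        current = [v for v in current if pred(v, affected_ids)]
        counts.append((stage, len(current)))
    return FunnelResult(survivors=current, stage_counts=counts)


def prediction_consensus(variant: VariantRecord, threshold: int = 2) -> bool:
    """True iff at least ``threshold`` of the 3 algorithm calls are damaging.

    ``unknown`` counts as not-damaging.
    """
    return sum(call == "damaging" for call in variant.prediction_calls) >= threshold


# ---------------------------------------------------------------------------
# segregation


@dataclass
class SegregationResult:
    segregates: bool
    discordant: list  # sample ids violating the dominant model


def check_segregation(variant: VariantRecord, pedigree) -> SegregationResult:
    """Dominant-model segregation: every affected carries the alternate
    allele, every unaffected carries none.

    Unknown-status individuals (e.g. possibly pre-symptomatic carriers) are
    skipped and can never be discordant.  A missing genotype on a scored
    sample counts as discordant — conservatively flagged rather than silently
    passed.
    """
    discordant = []
    n_scored = 0
    for person in pedigree:
        if person.status == "unknown":
            continue
        gt = variant.genotypes.get(person.sample_id, "missing")
        n_scored += 1
        if gt == "missing":
            discordant.append(person.sample_id)
        elif person.status == "affected" and gt == "ref":
            discordant.append(person.sample_id)
        elif person.status == "unaffected" and gt != "ref":
            discordant.append(person.sample_id)
    if n_scored == 0:
        raise ValueError("no scorable samples: every pedigree member has unknown status")
    return SegregationResult(segregates=not discordant, discordant=discordant)


# ---------------------------------------------------------------------------
# haplotype sharing


@dataclass
class SharedInterval:
    start_bp: int
    end_bp: int
    length_bp: int
    marker_indices: tuple  # contiguous run of marker indices, inclusive
    empty: bool = False


def shared_haplotype_interval(hap_a, hap_b, positions_bp, index_position) -> SharedInterval:
    """Maximal identical allele run containing the index marker.

    Expands bidirectionally from the index marker while alleles of the two
    haplotypes agree.  Interval length is measured marker-to-marker:
    position(last) - position(first).  If the haplotypes already differ at
    the index marker, an empty flagged interval is returned.
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    pos = np.asarray(positions_bp)
    if not (len(a) == len(b) == len(pos)):
        raise ValueError("haplotypes and positions must have equal length")
    if pos.size and not np.all(np.diff(pos) > 0):
        raise ValueError("marker positions must be strictly increasing")
    matches = np.flatnonzero(pos == index_position)
    if matches.size == 0:
        raise ValueError(f"index position {index_position} is not a marker")
    idx = int(matches[0])
    if a[idx] != b[idx]:
        return SharedInterval(0, 0, 0, (), empty=True)
    lo = idx
    while lo > 0 and a[lo - 1] == b[lo - 1]:
        lo -= 1
    hi = idx
    while hi < len(a) - 1 and a[hi + 1] == b[hi + 1]:
        hi += 1
    return SharedInterval(
        start_bp=int(pos[lo]),
        end_bp=int(pos[hi]),
        length_bp=int(pos[hi] - pos[lo]),
        marker_indices=tuple(range(lo, hi + 1)),
    )


# ---------------------------------------------------------------------------
# I/O — 6-column PED and Annovar-style TSV

_STATUS_TO_PED = {"unaffected": "1", "affected": "2", "unknown": "0"}
_PED_TO_STATUS = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}


def read_ped(path) -> list:
    pedigree = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fam, sid, father, mother, sex, pheno = line.split()[:6]
            pedigree.append(
                PedigreeSample(
                    family_id=fam,
                    sample_id=sid,
                    father_id=father,
                    mother_id=mother,
                    sex=int(sex),
                    status=_PED_TO_STATUS.get(pheno, "unknown"),
                )
            )
    ids = [p.sample_id for p in pedigree]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids in pedigree")
    return pedigree


def write_ped(pedigree, path) -> None:
    with open(path, "w") as fh:
        for p in pedigree:
            fh.write(
                f"{p.family_id}\t{p.sample_id}\t{p.father_id}\t{p.mother_id}"
                f"\t{p.sex}\t{_STATUS_TO_PED[p.status]}\n"
            )


_FIXED_COLS = [
    "Chr",
    "Start",
    "Ref",
    "Alt",
    "Gene",
    "Func",
    "dbSNP",
    "g1000",
    "esp6500",
    "inhouse",
    "PolyPhen2",
    "SIFT",
    "MutationTaster",
]


def write_variants_tsv(variants, path) -> None:
    """Annovar-style TSV: fixed annotation columns then one GT_<sample> column
    per genotyped sample (values ref/het/hom/missing)."""
    sample_ids = sorted({s for v in variants for s in v.genotypes})
    cols = _FIXED_COLS + [f"GT_{s}" for s in sample_ids]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(cols)
        for v in variants:
            row = [
                v.chrom,
                v.pos,
                v.ref,
                v.alt,
                v.gene,
                v.function_class,
                int(v.in_dbsnp),
                int(v.in_1000g),
                int(v.in_esp),
                int(v.in_inhouse),
                *v.prediction_calls,
            ]
            row += [v.genotypes.get(s, "missing") for s in sample_ids]
            w.writerow(row)


def read_variants_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str})
    gt_cols = [c for c in df.columns if c.startswith("GT_")]
    variants = []
    for _, row in df.iterrows():
        variants.append(
            VariantRecord(
                chrom=str(row["Chr"]),
                pos=int(row["Start"]),
                ref=str(row["Ref"]),
                alt=str(row["Alt"]),
                gene=str(row["Gene"]),
                function_class=str(row["Func"]),
                in_dbsnp=bool(row["dbSNP"]),
                in_1000g=bool(row["g1000"]),
                in_esp=bool(row["esp6500"]),
                in_inhouse=bool(row["inhouse"]),
                genotypes={c[3:]: str(row[c]) for c in gt_cols},
                prediction_calls=(
                    str(row["PolyPhen2"]),
                    str(row["SIFT"]),
                    str(row["MutationTaster"]),
                ),
            )
        )
    return variants
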