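"""Core domain types for pooled-array differential methylation analysis.

The analysis operates on Illumina 450K-style data: every CpG probe carries a
beta value (fraction methylated, in [0, 1]) per pooled sample, a detection
p-value per pooled sample, and manifest annotations mapping the probe to zero
or more (gene, region group) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np


class RegionGroup(str, Enum):
    """Gene-relative location of a probe, as annotated in array manifests."""

    TSS1500 = "TSS1500"
    TSS200 = "TSS200"
    UTR5 = "5'UTR"
    FIRST_EXON = "1stExon"
    BODY = "Body"
    UTR3 = "3'UTR"

    @classmethod
    def parse(cls, label: str) -> "RegionGroup":
        label = label.strip()
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(f"unknown region group {label!r}")


#: Canonical ordering used for reports (promoter-proximal to 3').
REGION_ORDER: tuple[RegionGroup, ...] = (
    RegionGroup.TSS1500,
    RegionGroup.TSS200,
    RegionGroup.UTR5,
    RegionGroup.FIRST_EXON,
    RegionGroup.BODY,
    RegionGroup.UTR3,
)

#: hg19 chromosome lengths (bp) for the chromosomes the 450K array covers.
HG19_CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMS: tuple[str, ...] = ("X", "Y")
CHROM_ORDER: tuple[str, ...] = AUTOSOMES + SEX_CHROMS


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix and surrounding whitespace."""
    label = label.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (CHROM_ORDER.index(chrom), "")
    except ValueError:
        return (len(CHROM_ORDER), chrom)


@dataclass(frozen=True)
class ProbeAnnotation:
    """One array probe: genomic location plus gene/region annotations.

    ``gene_entries`` holds the zipped (gene symbol, region group) pairs from
    the manifest, deduplicated but order-preserving; an empty list marks an
    intergenic probe or an isolated CpG island.
    """

    probe_id: str
    chrom: str
    pos: int
    gene_entries: tuple[tuple[str, RegionGroup], ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(
                f"probe {self.probe_id}: position must be >= 1, got {self.pos}"
            )
        seen = set()
        deduped = []
        for gene, group in self.gene_entries:
            if not isinstance(group, RegionGroup):
                group = RegionGroup.parse(str(group))
            key = (gene, group)
            if key not in seen:
                seen.add(key)
                deduped.append(key)
        object.__setattr__(self, "gene_entries", tuple(deduped))

    @property
    def genes(self) -> tuple[str, ...]:
        """Distinct gene symbols, order-preserving."""
        out: list[str] = []
        for gene, _ in self.gene_entries:
            if gene not in out:
                out.append(gene)
        return tuple(out)

    @property
    def region_groups(self) -> tuple[RegionGroup, ...]:
        """Distinct region groups, order-preserving."""
        out: list[RegionGroup] = []
        for _, group in self.gene_entries:
            if group not in out:
                out.append(group)
        return tuple(out)


@dataclass
class PooledBetaSet:
    """Aligned beta and detection-p vectors for two pools over shared probes.

    The two pools are conventionally labelled "male" (reference) and "female"
    (comparison); ΔMe is defined female − male throughout.
    """

    probe_ids: list[str]
    beta_male: np.ndarray
    beta_female: np.ndarray
    detp_male: np.ndarray
    detp_female: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        n = len(self.probe_ids)
        if len(set(self.probe_ids)) != n:
            raise ValueError("probe_ids must be unique")
        for name in ("beta_male", "beta_female", "detp_male", "detp_female"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (n,):
                raise ValueError(
                    f"{name}: expected length {n}, got shape {vec.shape}"
                )
            setattr(self, name, vec)
        for name in ("beta_male", "beta_female"):
            vec = getattr(self, name)
            if vec.size and (np.nanmin(vec) < 0 or np.nanmax(vec) > 1):
                bad = self.probe_ids[int(np.argmax((vec < 0) | (vec > 1)))]
                raise ValueError(
                    f"{name}: beta outside [0, 1] at probe {bad}"
                )

    def __len__(self) -> int:
        return len(self.probe_ids)

    def subset(self, mask: np.ndarray) -> "PooledBetaSet":
        """Row-subset by boolean mask, preserving order."""
        mask = np.asarray(mask, dtype=bool)
        ids = [p for p, keep in zip(self.probe_ids, mask) if keep]
        return PooledBetaSet(
            probe_ids=ids,
            beta_male=self.beta_male[mask],
            beta_female=self.beta_female[mask],
            detp_male=self.detp_male[mask],
            detp_female=self.detp_female[mask],
        )

    def index_of(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probe_ids)}


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths plus the window size used for density tables."""

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(HG19_CHROM_LENGTHS)
    )
    window_size: int = 10_000_000

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: length must be positive")

    def n_windows(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return -(-length // self.window_size)  # ceil division


class Direction(str, Enum):
    """Sign of a differential call, from the female pool's perspective."""

    HYPER = "hyper"
    HYPO = "hypo"


@dataclass(frozen=True)
class DmpCall:
    """A differentially methylated probe with its ΔMe and direction."""

    probe_id: str
    delta_me: float
    direction: Direction
    chrom: str
    pos: int
    gene_entries: tuple[tuple[str, RegionGroup], ...] = ()

    def __post_init__(self) -> None:
        expected = Direction.HYPER if self.delta_me > 0 else Direction.HYPO
        if self.direction is not expected:
            raise ValueError(
                f"probe {self.probe_id}: direction {self.direction.value} "
                f"inconsistent with delta_me {self.delta_me:+.4f}"
            )


class DmgStatus(str, Enum):
    """Gene-level methylation status from member-probe directions."""

    HYPER = "+"
    HYPO = "-"
    MIXED = "mixed"


@dataclass(frozen=True)
class DmgRecord:
    """A gene with its member DMPs and hyper/hypo/mixed status."""

    gene_symbol: str
    dmp_ids: tuple[str, ...]
    status: DmgStatus

    def __post_init__(self) -> None:
        if not self.dmp_ids:
            raise ValueError(f"gene {self.gene_symbol}: dmp_ids must be non-empty")


def annotations_by_probe(
    annotations: Iterable[ProbeAnnotation],
) -> dict[str, ProbeAnnotation]:
    out: dict[str, ProbeAnnotation] = {}
    for ann in annotations:
        if ann.probe_id in out:
            raise ValueError(f"duplicate probe_id {ann.probe_id}")
        out[ann.probe_id] = ann
    return out


def manifest_genes(annotations: Iterable[ProbeAnnotation]) -> list[str]:
    """Sorted distinct (case-folded) gene symbols in a manifest."""
    genes = {g.upper() for ann in annotations for g in ann.genes}
    return sorted(genes)
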