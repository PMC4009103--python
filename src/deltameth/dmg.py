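"""Gene-level aggregation of DMPs and overlaps with external gene lists.

A differentially methylated gene (DMG) is any gene holding at least one DMP.
Its status follows the member directions: hypermethylated ("+") when every
member DMP is hyper, hypomethylated ("−") when every member is hypo, and
"mixed" when both directions occur. Gene identity is the bare symbol,
case-folded; a symbol seen on more than one chromosome is merged with a
warning since the manifest dialect carries no stable gene identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .datatypes import Direction, DmgRecord, DmgStatus, DmpCall

logger = logging.getLogger(__name__)


def map_dmps_to_genes(dmps: Sequence[DmpCall]) -> list[DmgRecord]:
    """Aggregate DMPs into DMG records, sorted by gene symbol.

    A DMP contributes to every distinct gene symbol in its annotations;
    intergenic DMPs contribute to no gene. Each (DMP, gene) annotation pair
    lands in exactly one record's ``dmp_ids``.
    """
    members: dict[str, list[str]] = {}
    directions: dict[str, set[Direction]] = {}
    chrom_of: dict[str, set[str]] = {}
    for call in dmps:
        for gene in {g.upper() for g, _ in call.gene_entries}:
            members.setdefault(gene, []).append(call.probe_id)
            directions.setdefault(gene, set()).add(call.direction)
            chrom_of.setdefault(gene, set()).add(call.chrom)
    records = []
    for gene in sorted(members):
        if len(chrom_of[gene]) > 1:
            logger.warning(
                "gene symbol %s seen on chromosomes %s; merged",
                gene, sorted(chrom_of[gene]),
            )
        dirs = directions[gene]
        if dirs == {Direction.HYPER}:
            status = DmgStatus.HYPER
        elif dirs == {Direction.HYPO}:
            status = DmgStatus.HYPO
        else:
            status = DmgStatus.MIXED
        records.append(
            DmgRecord(
                gene_symbol=gene,
                dmp_ids=tuple(sorted(set(members[gene]))),
                status=status,
            )
        )
    return records


@dataclass(frozen=True)
class DmgStatusSummary:
    n_hyper: int
    n_hypo: int
    n_mixed: int

    @property
    def total(self) -> int:
        return self.n_hyper + self.n_hypo + self.n_mixed

    def fractions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {"hyper": float("nan"), "hypo": float("nan"), "mixed": float("nan")}
        return {
            "hyper": self.n_hyper / total,
            "hypo": self.n_hypo / total,
            "mixed": self.n_mixed / total,
        }


def dmg_status_summary(dmgs: Sequence[DmgRecord]) -> DmgStatusSummary:
    """Counts per status; the three counts always sum to the total."""
    return DmgStatusSummary(
        n_hyper=sum(1 for d in dmgs if d.status is DmgStatus.HYPER),
        n_hypo=sum(1 for d in dmgs if d.status is DmgStatus.HYPO),
        n_mixed=sum(1 for d in dmgs if d.status is DmgStatus.MIXED),
    )


@dataclass(frozen=True)
class OverlapResult:
    """Intersection of the DMG set with an external flat gene list.

    ``expected_overlap`` is the hypergeometric expectation n·K/N for a
    random list of the same size drawn from the declared universe — context
    for judging whether the observed overlap is small or large.
    """

    label: str
    overlap: pd.DataFrame  # gene, status
    n_dmgs: int
    n_list: int
    n_universe: int

    @property
    def n_overlap(self) -> int:
        return len(self.overlap)

    @property
    def expected_overlap(self) -> float:
        return self.n_dmgs * self.n_list / self.n_universe


def gene_list_overlap(
    dmgs: Sequence[DmgRecord],
    gene_list: Sequence[str],
    label: str,
    universe: Sequence[str],
) -> OverlapResult:
    """Case-insensitive intersection of DMG symbols with a flat gene list.

    ``universe`` is the sampling frame (normally every gene on the filtered
    manifest) used for the expected-overlap context figure. The external
    list is restricted to the universe before comparing.
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("gene universe is empty")
    listed = {g.upper() for g in gene_list} & universe_set
    by_symbol = {d.gene_symbol.upper(): d for d in dmgs}
    hits = sorted(set(by_symbol) & listed)
    table = pd.DataFrame(
        [{"gene": g, "status": by_symbol[g].status.value, "list": label} for g in hits],
        columns=["gene", "status", "list"],
    )
    return OverlapResult(
        label=label,
        overlap=table,
        n_dmgs=len(by_symbol),
        n_list=len(listed),
        n_universe=len(universe_set),
    )


def dmgs_to_frame(dmgs: Sequence[DmgRecord]) -> pd.DataFrame:
    """Flatten DMG records to the output TSV schema (gene, status, probes)."""
    return pd.DataFrame(
        [
            {
                "gene": d.gene_symbol,
                "status": d.status.value,
                "dmp_ids": ";".join(d.dmp_ids),
                "n_dmps": len(d.dmp_ids),
            }
            for d in dmgs
        ],
        columns=["gene", "status", "dmp_ids", "n_dmps"],
    )
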