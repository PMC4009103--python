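"""Readers and writers for the tab-separated formats the pipeline consumes.

Formats
-------
Manifest TSV
    Columns ``probe_id, chrom, pos, genes, groups``; ``genes``/``groups`` are
    semicolon-delimited parallel lists (the array-manifest dialect), either
    possibly empty for intergenic probes.
Beta TSV
    Columns ``probe_id, beta, detection_p`` — one file per pooled sample.
Gene-set file
    GMT dialect: tab-separated ``term_id, description, gene, gene, ...``.
Flat gene list
    One symbol per line.

All files are UTF-8; lines starting with ``#`` are comments and are skipped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    PooledBetaSet,
    ProbeAnnotation,
    RegionGroup,
    annotations_by_probe,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "genes", "groups"]
BETA_COLUMNS = ["probe_id", "beta", "detection_p"]


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_manifest(path: str | Path) -> list[ProbeAnnotation]:
    """Parse a manifest TSV into probe annotations.

    Parallel ``genes``/``groups`` lists are zipped positionally, then
    deduplicated on identical (gene, group) pairs. Raises on a length
    mismatch between the two lists, an unknown region group, or a duplicate
    probe id — each error names the offending probe.
    """
    df = _read_tsv(path, MANIFEST_COLUMNS)
    annotations: list[ProbeAnnotation] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        probe_id = row.probe_id.strip()
        if probe_id in seen:
            raise ValueError(f"duplicate probe_id {probe_id}")
        seen.add(probe_id)
        genes = [g for g in row.genes.split(";") if g.strip()] if row.genes.strip() else []
        groups = [g for g in row.groups.split(";") if g.strip()] if row.groups.strip() else []
        if len(genes) != len(groups):
            raise ValueError(
                f"probe {probe_id}: genes/groups list length mismatch "
                f"({len(genes)} vs {len(groups)})"
            )
        try:
            entries = tuple(
                (g.strip(), RegionGroup.parse(r)) for g, r in zip(genes, groups)
            )
        except ValueError as exc:
            raise ValueError(f"probe {probe_id}: {exc}") from exc
        annotations.append(
            ProbeAnnotation(
                probe_id=probe_id,
                chrom=normalize_chrom(row.chrom),
                pos=int(row.pos),
                gene_entries=entries,
            )
        )
    return annotations


def write_manifest(annotations: Iterable[ProbeAnnotation], path: str | Path) -> None:
    rows = []
    for ann in annotations:
        rows.append(
            {
                "probe_id": ann.probe_id,
                "chrom": ann.chrom,
                "pos": ann.pos,
                "genes": ";".join(g for g, _ in ann.gene_entries),
                "groups": ";".join(r.value for _, r in ann.gene_entries),
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_beta_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, BETA_COLUMNS)
    out = pd.DataFrame(
        {
            "probe_id": df["probe_id"].str.strip(),
            "beta": pd.to_numeric(df["beta"]),
            "detection_p": pd.to_numeric(df["detection_p"]),
        }
    )
    bad = out[(out["beta"] < 0) | (out["beta"] > 1)]
    if len(bad):
        raise ValueError(
            f"{path}: beta outside [0, 1] at probe {bad.iloc[0]['probe_id']}"
        )
    if out["probe_id"].duplicated().any():
        dup = out.loc[out["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"{path}: duplicate probe_id {dup}")
    return out


def read_beta_tables(path_male: str | Path, path_female: str | Path) -> PooledBetaSet:
    """Read two per-pool beta tables and inner-join them on probe id.

    Probes present in only one file are dropped (the count is logged); an
    empty intersection is an error. Probe order follows the male table.
    """
    male = _read_beta_table(path_male)
    female = _read_beta_table(path_female)
    merged = male.merge(female, on="probe_id", how="inner", suffixes=("_m", "_f"))
    n_dropped = len(male) + len(female) - 2 * len(merged)
    if n_dropped:
        logger.info("read_beta_tables: dropped %d unmatched probe rows", n_dropped)
    if merged.empty:
        raise ValueError("no probes shared between the two beta tables")
    return PooledBetaSet(
        probe_ids=merged["probe_id"].tolist(),
        beta_male=merged["beta_m"].to_numpy(),
        beta_female=merged["beta_f"].to_numpy(),
        detp_male=merged["detection_p_m"].to_numpy(),
        detp_female=merged["detection_p_f"].to_numpy(),
    )


def write_beta_table(
    path: str | Path,
    probe_ids: Sequence[str],
    beta: np.ndarray,
    detection_p: np.ndarray,
) -> None:
    pd.DataFrame(
        {
            "probe_id": list(probe_ids),
            "beta": np.asarray(beta, dtype=float),
            "detection_p": np.asarray(detection_p, dtype=float),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class RetentionReport:
    """Probe-QC accounting: how many probes each filter removed.

    A probe failing both filters is counted once, under the detection-p
    reason (applied first).
    """

    n_input: int = 0
    n_retained: int = 0
    removed_detection_p: int = 0
    removed_chromosome: int = 0

    @property
    def n_removed(self) -> int:
        return self.removed_detection_p + self.removed_chromosome

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_detection_p": self.removed_detection_p,
            "removed_chromosome": self.removed_chromosome,
        }


def filter_probes(
    data: PooledBetaSet,
    annotations: Iterable[ProbeAnnotation] | dict[str, ProbeAnnotation],
    detp_max: float = 0.05,
    exclude_chroms: frozenset[str] | set[str] = frozenset({"X", "Y"}),
) -> tuple[PooledBetaSet, RetentionReport]:
    """Apply probe QC: detection-p and chromosome-exclusion filters.

    A probe is retained when its detection p-value is ``<= detp_max`` in BOTH
    pools (a probe unreliable in either pool leaves ΔMe undefined) and its
    chromosome is not excluded. Every probe must be annotated.
    """
    if not (0 < detp_max <= 1):
        raise ValueError("detp_max must be in (0, 1]")
    if not isinstance(annotations, dict):
        annotations = annotations_by_probe(annotations)
    exclude = {normalize_chrom(c) for c in exclude_chroms}

    chroms = []
    for probe_id in data.probe_ids:
        ann = annotations.get(probe_id)
        if ann is None:
            raise ValueError(f"probe {probe_id} missing from annotations")
        chroms.append(ann.chrom)

    detp_ok = (data.detp_male <= detp_max) & (data.detp_female <= detp_max)
    chrom_ok = np.array([c not in exclude for c in chroms])
    keep = detp_ok & chrom_ok

    report = RetentionReport(
        n_input=len(data),
        n_retained=int(keep.sum()),
        removed_detection_p=int((~detp_ok).sum()),
        removed_chromosome=int((detp_ok & ~chrom_ok).sum()),
    )
    logger.info(
        "filter_probes: %d in, %d retained (%d detection-p, %d chromosome)",
        report.n_input, report.n_retained,
        report.removed_detection_p, report.removed_chromosome,
    )
    return data.subset(keep), report


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT-dialect gene-set file: term → (description, gene list).

    Gene symbols are upper-cased; duplicate genes within a term are dropped.
    """
    terms: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed GMT line {line!r}")
            term_id, description = fields[0], fields[1]
            if term_id in terms:
                raise ValueError(f"{path}: duplicate term {term_id}")
            genes: list[str] = []
            for g in fields[2:]:
                g = g.strip().upper()
                if g and g not in genes:
                    genes.append(g)
            terms[term_id] = (description, genes)
    return terms


def write_gmt(terms: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for term_id, (description, genes) in terms.items():
            handle.write("\t".join([term_id, description, *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a flat one-symbol-per-line gene list (upper-cased, deduplicated)."""
    genes: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbol = line.upper()
            if symbol not in genes:
                genes.append(symbol)
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gene in genes:
            handle.write(gene + "\n")
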