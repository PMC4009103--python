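"""Differential-methylation-probe calling and distribution summaries.

ΔMe is the per-probe pooled-beta difference, female − male. A probe is a DMP
when |ΔMe| strictly exceeds the threshold (default 0.20, the Monte Carlo
calibrated value): ΔMe > t is hypermethylated in the female pool, ΔMe < −t
hypomethylated. Exactly ±t is never called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    REGION_ORDER,
    Direction,
    DmpCall,
    GenomeLayout,
    PooledBetaSet,
    ProbeAnnotation,
    RegionGroup,
    annotations_by_probe,
    chrom_sort_key,
)

logger = logging.getLogger(__name__)

INTERGENIC = "intergenic"


def compute_delta(data: PooledBetaSet) -> np.ndarray:
    """Per-probe ΔMe = beta_female − beta_male, order preserved."""
    return data.beta_female - data.beta_male


def call_dmps(
    data: PooledBetaSet,
    annotations: Iterable[ProbeAnnotation] | Mapping[str, ProbeAnnotation],
    threshold: float = 0.20,
) -> list[DmpCall]:
    """Call DMPs at a strict |ΔMe| threshold, sorted by (chrom, pos)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not isinstance(annotations, Mapping):
        annotations = annotations_by_probe(annotations)
    delta = compute_delta(data)
    calls: list[DmpCall] = []
    for probe_id, d in zip(data.probe_ids, delta):
        if d > threshold:
            direction = Direction.HYPER
        elif d < -threshold:
            direction = Direction.HYPO
        else:
            continue
        ann = annotations.get(probe_id)
        if ann is None:
            raise ValueError(f"probe {probe_id} missing from annotations")
        calls.append(
            DmpCall(
                probe_id=probe_id,
                delta_me=float(d),
                direction=direction,
                chrom=ann.chrom,
                pos=ann.pos,
                gene_entries=ann.gene_entries,
            )
        )
    calls.sort(key=lambda c: (chrom_sort_key(c.chrom), c.pos))
    return calls


@dataclass(frozen=True)
class GlobalSummary:
    """Genome-wide pooled means and a Welch t comparison of the two pools."""

    mean_male: float
    mean_female: float
    t_statistic: float
    p_value: float
    n_probes: int


def global_summary(data: PooledBetaSet) -> GlobalSummary:
    """Compare whole-genome mean methylation between the pools.

    Two-sided Welch (unequal-variance) t-test with probes as observations.
    Identical zero-variance pools yield t = 0, p = 1 rather than an error.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 probes")
    m, f = data.beta_male, data.beta_female
    if np.var(m) == 0 and np.var(f) == 0:
        equal = float(m.mean()) == float(f.mean())
        t, p = (0.0, 1.0) if equal else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(f, m, equal_var=False)
    return GlobalSummary(
        mean_male=float(m.mean()),
        mean_female=float(f.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_probes=len(data),
    )


def region_distribution(dmps: Sequence[DmpCall]) -> pd.DataFrame:
    """Tally calls over gene region groups.

    Counting unit: unique (probe, region group) pairs — a probe annotated to
    the same group through two genes counts once for that group, while a
    probe spanning two groups contributes to both. Fractions are over the
    total genic pairs; probes with no gene entry are tallied under a
    seventh "intergenic" row that is excluded from the fractions.
    """
    counts = {group.value: 0 for group in REGION_ORDER}
    intergenic = 0
    for call in dmps:
        groups = {group for _, group in call.gene_entries}
        if not groups:
            intergenic += 1
            continue
        for group in groups:
            counts[group.value] += 1
    total_pairs = sum(counts.values())
    rows = [
        {
            "region_group": group.value,
            "count": counts[group.value],
            "fraction": counts[group.value] / total_pairs if total_pairs else np.nan,
        }
        for group in REGION_ORDER
    ]
    rows.append(
        {"region_group": INTERGENIC, "count": intergenic, "fraction": np.nan}
    )
    return pd.DataFrame(rows, columns=["region_group", "count", "fraction"])


def window_counts(
    probes: Sequence[DmpCall] | Sequence[ProbeAnnotation],
    layout: GenomeLayout,
    beta_by_probe: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Genome density table over fixed windows (Circos-ready).

    One row per window per chromosome present in the layout and the input,
    including empty windows (count 0, missing means). 1-based positions map
    to 0-based indices over half-open windows: index = (pos − 1) // size, so
    position 10,000,000 falls in window 0 and 10,000,001 in window 1 at the
    default 10 Mbp width. ``beta_by_probe`` optionally supplies per-probe
    (male, female) betas for per-window mean methylation tracks.
    """
    per_window: dict[tuple[str, int], list[str]] = {}
    chroms_seen: list[str] = []
    for probe in probes:
        if probe.chrom not in layout.chrom_lengths:
            raise ValueError(f"chromosome {probe.chrom} not in layout")
        if probe.pos > layout.chrom_lengths[probe.chrom]:
            raise ValueError(
                f"probe {probe.probe_id}: position {probe.pos} exceeds "
                f"chromosome {probe.chrom} length"
            )
        if probe.chrom not in chroms_seen:
            chroms_seen.append(probe.chrom)
        idx = (probe.pos - 1) // layout.window_size
        per_window.setdefault((probe.chrom, idx), []).append(probe.probe_id)

    chroms_seen.sort(key=chrom_sort_key)
    rows = []
    for chrom in chroms_seen:
        for idx in range(layout.n_windows(chrom)):
            members = per_window.get((chrom, idx), [])
            row = {"chrom": chrom, "window_index": idx, "count": len(members)}
            if beta_by_probe is not None:
                if members:
                    pairs = [beta_by_probe[p] for p in members]
                    row["mean_beta_male"] = float(np.mean([m for m, _ in pairs]))
                    row["mean_beta_female"] = float(np.mean([f for _, f in pairs]))
                else:
                    row["mean_beta_male"] = np.nan
                    row["mean_beta_female"] = np.nan
            rows.append(row)
    columns = ["chrom", "window_index", "count"]
    if beta_by_probe is not None:
        columns += ["mean_beta_male", "mean_beta_female"]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class DirectionSplit:
    """Hyper/hypo totals plus the per-region direction breakdown."""

    n_hyper: int
    n_hypo: int
    per_region: pd.DataFrame  # region_group, n_hyper, n_hypo

    @property
    def total(self) -> int:
        return self.n_hyper + self.n_hypo

    @property
    def hyper_fraction(self) -> float:
        return self.n_hyper / self.total if self.total else float("nan")

    @property
    def hypo_fraction(self) -> float:
        return self.n_hypo / self.total if self.total else float("nan")


def direction_split(dmps: Sequence[DmpCall]) -> DirectionSplit:
    """Split calls by direction, overall and per region group.

    Per-region counts use the same unique (probe, region group) pair unit as
    :func:`region_distribution`.
    """
    n_hyper = sum(1 for c in dmps if c.direction is Direction.HYPER)
    n_hypo = len(dmps) - n_hyper
    per_region = {group: [0, 0] for group in REGION_ORDER}
    for call in dmps:
        col = 0 if call.direction is Direction.HYPER else 1
        for group in {g for _, g in call.gene_entries}:
            per_region[group][col] += 1
    table = pd.DataFrame(
        [
            {
                "region_group": group.value,
                "n_hyper": per_region[group][0],
                "n_hypo": per_region[group][1],
            }
            for group in REGION_ORDER
        ]
    )
    return DirectionSplit(n_hyper=n_hyper, n_hypo=n_hypo, per_region=table)


def x_hypomethylation_analysis(
    data: PooledBetaSet,
    annotations: Iterable[ProbeAnnotation] | Mapping[str, ProbeAnnotation],
    threshold: float = 0.20,
    detp_max: float = 0.05,
) -> list[DmpCall]:
    """Hypomethylation-only DMP calling restricted to chrX.

    X inactivation methylates one female X, inflating female chrX betas, so
    hypermethylation calls there are biased and suppressed; only
    ΔMe < −threshold survives. Expects data that retained chrX (detection-p
    QC is applied here); returns an empty list with a warning if no chrX
    probe passes.
    """
    if not isinstance(annotations, Mapping):
        annotations = annotations_by_probe(annotations)
    mask = np.array(
        [
            annotations[p].chrom == "X" if p in annotations else False
            for p in data.probe_ids
        ]
    )
    mask &= (data.detp_male <= detp_max) & (data.detp_female <= detp_max)
    if not mask.any():
        logger.warning("x_hypomethylation_analysis: no usable chrX probes")
        return []
    x_data = data.subset(mask)
    calls = call_dmps(x_data, annotations, threshold)
    return [c for c in calls if c.direction is Direction.HYPO]


def percent_of_probes(n_calls: int, n_retained: int) -> str:
    """Call rate as a percentage string with 3 significant figures."""
    if n_retained <= 0:
        raise ValueError("n_retained must be positive")
    value = 100.0 * n_calls / n_retained
    return f"{value:.3g}"


def dmps_to_frame(dmps: Sequence[DmpCall]) -> pd.DataFrame:
    """Flatten calls to the output TSV schema."""
    return pd.DataFrame(
        [
            {
                "probe_id": c.probe_id,
                "chrom": c.chrom,
                "pos": c.pos,
                "delta_me": c.delta_me,
                "direction": c.direction.value,
                "genes": ";".join(g for g, _ in c.gene_entries),
                "groups": ";".join(r.value for _, r in c.gene_entries),
            }
            for c in dmps
        ],
        columns=["probe_id", "chrom", "pos", "delta_me", "direction", "genes", "groups"],
    )
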