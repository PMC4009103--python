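"""Synthetic 450K-style data with known ground truth.

The generator emulates the statistical structure of a pooled two-sample
methylation-array experiment: a manifest of CpG probes over the 22 autosomes
plus chrX/chrY with (gene, region group) annotations; a bimodal baseline beta
landscape (most CpGs are either nearly unmethylated or nearly fully
methylated); small per-pool technical noise on the beta scale; and a set of
planted group differences with known signed effect, recorded in a truth
table so that every downstream stage can be validated against ground truth.

Draw order is fixed and documented so a given seed reproduces byte-identical
outputs: manifest draws run per chromosome in karyotype order (positions,
then gene-entry counts, gene picks, region groups); pool draws then run in
the order baseline class, baseline beta, planted-probe selection, male
noise, female noise, male detection-p, female detection-p.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CHROM_ORDER,
    HG19_CHROM_LENGTHS,
    REGION_ORDER,
    PooledBetaSet,
    ProbeAnnotation,
    RegionGroup,
)

#: Desk-scale default probe budget (the real array has ~485K probes; the
#: generator keeps the same chromosomal proportions at a tractable size).
DEFAULT_TOTAL_PROBES = 20_000

_GENOME_BP = sum(HG19_CHROM_LENGTHS.values())


def _default_probes_per_chrom(total: int = DEFAULT_TOTAL_PROBES) -> dict[str, int]:
    return {
        chrom: max(20, round(total * length / _GENOME_BP))
        for chrom, length in HG19_CHROM_LENGTHS.items()
    }


@dataclass(frozen=True)
class PlantedEffect:
    """A planted group difference: ``delta`` added to the female pool.

    Either explicit ``probe_ids`` or a count ``n_probes`` of probes drawn at
    random from mid-range-baseline probes chosen so both the baseline and the
    shifted value stay well inside [0, 1] (the full effect survives clipping);
    ``chrom`` optionally restricts the draw to one chromosome.
    """

    delta: float
    n_probes: int = 0
    probe_ids: tuple[str, ...] = ()
    chrom: str | None = None

    def __post_init__(self) -> None:
        if abs(self.delta) > 1:
            raise ValueError("|delta| must be <= 1")
        if bool(self.n_probes) == bool(self.probe_ids):
            raise ValueError("specify exactly one of n_probes or probe_ids")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the standard study conditions."""

    n_probes_per_chrom: dict[str, int] = field(
        default_factory=_default_probes_per_chrom
    )
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(HG19_CHROM_LENGTHS)
    )
    genes_per_chrom: int = 40
    #: P(probe has 0, 1, 2 gene entries).
    gene_count_weights: tuple[float, float, float] = (0.25, 0.65, 0.10)
    #: Probability of each region group for a gene entry, in REGION_ORDER
    #: (body-heavy, as on the real array).
    regions_weights: tuple[float, ...] = (0.14, 0.10, 0.12, 0.07, 0.43, 0.14)
    #: Mixture weights of the unmethylated / intermediate / methylated
    #: baseline classes and their Beta-distribution shape parameters.
    baseline_weights: tuple[float, float, float] = (0.30, 0.40, 0.30)
    baseline_shapes: tuple[tuple[float, float], ...] = ((2, 18), (10, 10), (18, 2))
    #: Per-pool technical noise SD on the beta scale.
    noise_sd: float = 0.02
    #: Fraction of probes per pool with a failing detection p-value (> 0.05).
    detp_fail_frac: float = 0.005
    planted_dmps: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.detp_fail_frac < 1:
            raise ValueError("detp_fail_frac must be in [0, 1)")
        for name, weights in (
            ("regions_weights", self.regions_weights),
            ("baseline_weights", self.baseline_weights),
            ("gene_count_weights", self.gene_count_weights),
        ):
            if abs(sum(weights) - 1.0) > 1e-9 or min(weights) < 0:
                raise ValueError(f"{name} must be a probability vector")
        if len(self.regions_weights) != len(REGION_ORDER):
            raise ValueError("regions_weights must cover the six region groups")


def _manifest_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])


def _pools_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])


def generate_manifest(config: SimulationConfig) -> list[ProbeAnnotation]:
    """Generate a manifest with sorted unique positions per chromosome."""
    rng = _manifest_rng(config)
    annotations: list[ProbeAnnotation] = []
    counter = 0
    for chrom in CHROM_ORDER:
        n = config.n_probes_per_chrom.get(chrom, 0)
        if n == 0:
            continue
        length = config.chrom_lengths[chrom]
        if n > length:
            raise ValueError(
                f"chromosome {chrom}: {n} probes exceed length {length}"
            )
        positions = np.sort(
            rng.choice(length, size=n, replace=False).astype(np.int64) + 1
        )
        gene_pool = [f"G{chrom}_{i:03d}" for i in range(config.genes_per_chrom)]
        n_entries = rng.choice(3, size=n, p=config.gene_count_weights)
        for pos, k in zip(positions, n_entries):
            entries = []
            if k:
                genes = rng.choice(config.genes_per_chrom, size=k, replace=False)
                groups = rng.choice(len(REGION_ORDER), size=k, p=config.regions_weights)
                entries = [
                    (gene_pool[g], REGION_ORDER[r]) for g, r in zip(genes, groups)
                ]
            counter += 1
            annotations.append(
                ProbeAnnotation(
                    probe_id=f"cg{counter:08d}",
                    chrom=chrom,
                    pos=int(pos),
                    gene_entries=tuple(entries),
                )
            )
    return annotations


def generate_pools(
    manifest: Sequence[ProbeAnnotation], config: SimulationConfig
) -> tuple[PooledBetaSet, pd.DataFrame]:
    """Generate the two pooled beta vectors plus the planted-DMP truth table.

    beta_male = clip(baseline + noise); beta_female = clip(baseline + planted
    delta + noise). The truth table (columns ``probe_id``, ``delta``) lists
    every planted probe with its signed effect; with ``noise_sd = 0`` the
    observed ΔMe equals the planted delta exactly (clipping permitting).
    """
    rng = _pools_rng(config)
    n = len(manifest)
    probe_ids = [ann.probe_id for ann in manifest]
    chroms = np.array([ann.chrom for ann in manifest])

    classes = rng.choice(3, size=n, p=config.baseline_weights)
    baseline = np.empty(n)
    for idx, (a, b) in enumerate(config.baseline_shapes):
        mask = classes == idx
        baseline[mask] = rng.beta(a, b, size=int(mask.sum()))

    delta = np.zeros(n)
    index = {p: i for i, p in enumerate(probe_ids)}
    taken: set[int] = set()
    for effect in config.planted_dmps:
        if effect.probe_ids:
            chosen = [index[p] for p in effect.probe_ids]
        else:
            # mid-range baselines whose shifted value keeps >= 0.1 headroom,
            # so the planted effect survives clipping even with noise
            eligible = np.flatnonzero(
                (baseline >= 0.25)
                & (baseline <= 0.75)
                & (baseline + effect.delta >= 0.1)
                & (baseline + effect.delta <= 0.9)
                & ((chroms == effect.chrom) if effect.chrom else True)
            )
            eligible = np.array(
                [i for i in eligible if i not in taken], dtype=np.int64
            )
            if len(eligible) < effect.n_probes:
                raise ValueError(
                    f"planted effect {effect.delta:+.2f}: only {len(eligible)} "
                    f"eligible probes for {effect.n_probes} requested"
                )
            chosen = rng.choice(eligible, size=effect.n_probes, replace=False)
        for i in chosen:
            if i in taken:
                raise ValueError(f"probe {probe_ids[i]} planted twice")
            taken.add(int(i))
            delta[i] = effect.delta

    noise_m = rng.normal(0, config.noise_sd, size=n) if config.noise_sd else np.zeros(n)
    noise_f = rng.normal(0, config.noise_sd, size=n) if config.noise_sd else np.zeros(n)
    beta_male = np.clip(baseline + noise_m, 0, 1)
    beta_female = np.clip(baseline + delta + noise_f, 0, 1)

    detp_male = _detection_p(rng, n, config.detp_fail_frac)
    detp_female = _detection_p(rng, n, config.detp_fail_frac)

    truth_idx = sorted(taken)
    truth = pd.DataFrame(
        {
            "probe_id": [probe_ids[i] for i in truth_idx],
            "delta": delta[truth_idx],
        }
    )
    pools = PooledBetaSet(
        probe_ids=probe_ids,
        beta_male=beta_male,
        beta_female=beta_female,
        detp_male=detp_male,
        detp_female=detp_female,
    )
    return pools, truth


def _detection_p(rng: np.random.Generator, n: int, fail_frac: float) -> np.ndarray:
    """Mostly near-zero detection p-values with a planted failing fraction."""
    detp = rng.uniform(0, 0.01, size=n)
    if fail_frac:
        failing = rng.random(n) < fail_frac
        detp[failing] = rng.uniform(0.06, 0.5, size=int(failing.sum()))
    return detp


@dataclass(frozen=True)
class GeneSetConfig:
    """Shape of the synthetic term collection and flat gene lists."""

    n_terms: int = 50
    term_size_range: tuple[int, int] = (5, 40)
    #: When given, one extra term containing exactly these genes is added so
    #: enrichment recovery can be validated against ground truth.
    enriched_genes: tuple[str, ...] = ()
    enriched_term_id: str = "TERM_ENRICHED"
    aging_list_size: int = 30
    disease_list_size: int = 30
    seed: int = 0


def generate_gene_sets(
    manifest: Sequence[ProbeAnnotation], config: GeneSetConfig
) -> tuple[dict[str, tuple[str, list[str]]], list[str], list[str]]:
    """Generate a GMT term collection plus flat aging/disease gene lists.

    Terms are random draws from the manifest's gene universe; the optional
    enriched term is the ground-truth positive for enrichment tests.
    Returns ``(terms, aging_genes, disease_genes)``.
    """
    universe = sorted({g.upper() for ann in manifest for g in ann.genes})
    if not universe:
        raise ValueError("manifest contains no genes")
    lo, hi = config.term_size_range
    if hi > len(universe):
        raise ValueError(
            f"term size {hi} exceeds gene universe of {len(universe)}"
        )
    rng = np.random.default_rng(config.seed)
    terms: dict[str, tuple[str, list[str]]] = {}
    for i in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = sorted(rng.choice(universe, size=size, replace=False).tolist())
        terms[f"TERM_{i:04d}"] = (f"synthetic term {i}", genes)
    if config.enriched_genes:
        genes = sorted({g.upper() for g in config.enriched_genes})
        terms[config.enriched_term_id] = ("planted enriched term", genes)
    aging = sorted(
        rng.choice(universe, size=min(config.aging_list_size, len(universe)),
                   replace=False).tolist()
    )
    disease = sorted(
        rng.choice(universe, size=min(config.disease_list_size, len(universe)),
                   replace=False).tolist()
    )
    return terms, aging, disease


def default_planted_config(
    seed: int = 0,
    n_hyper: int = 30,
    n_hypo: int = 25,
    effect: float = 0.3,
    noise_sd: float = 0.02,
    n_x_hypo: int = 8,
) -> SimulationConfig:
    """Standard study conditions: autosomal effects both ways plus chrX
    hypomethylation, small technical noise, desk-scale probe count."""
    return SimulationConfig(
        noise_sd=noise_sd,
        planted_dmps=(
            PlantedEffect(delta=+effect, n_probes=n_hyper),
            PlantedEffect(delta=-effect, n_probes=n_hypo),
            PlantedEffect(delta=-effect, n_probes=n_x_hypo, chrom="X"),
        ),
        seed=seed,
    )
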