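"""Genome-wide pooled CRISPR resistance-screen analysis.

A resistance (suppressor) screen selects for sgRNAs whose loss-of-function
target confers survival under drug: after treatment those sgRNAs enrich in
the sequencing library relative to the vehicle arm.  The analysis here is
deliberately simple and self-contained:

1. counts are scaled to reads-per-million (RPM) within each sample;
2. per sgRNA, log2 fold change of treated vs control RPM (with pseudocount);
3. an empirical null over all sgRNAs in a condition (median/MAD robust
   z-score of the log2 fold changes) yields a per-sgRNA p-value — no
   replicates are required;
4. a gene is a hit in a condition when at least ``min_passing_sgrnas`` of
   its sgRNAs clear both the fold-change and p-value thresholds, and a
   final hit when it scores in every treated condition (intersection mode).

The per-sgRNA p-value is an interpretive choice: the screening convention
of "p < 0.05" thresholds does not pin down a test, and the empirical
median/MAD null assumes most sgRNAs are inert, which holds genome-wide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats_core import robust_z

__all__ = [
    "ScreenCountTable",
    "SgRNAStat",
    "HitCallConfig",
    "GeneHitRecord",
    "rpm_normalize",
    "sgrna_enrichment",
    "call_gene_hits",
    "call_hits_brute_force",
    "coverage_check",
]


@dataclass
class ScreenCountTable:
    """sgRNA x sample read counts with gene mapping and sample annotations.

    ``counts`` is indexed by sgRNA id with one integer column per sample;
    ``gene_map`` maps each sgRNA id to exactly one gene id;
    ``sample_conditions`` maps each sample (column) to a condition label.
    ``rpm`` is filled by :func:`rpm_normalize`.
    """

    counts: pd.DataFrame
    gene_map: pd.Series
    sample_conditions: dict
    rpm: pd.DataFrame | None = None

    def __post_init__(self):
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative read counts")
        missing = set(self.counts.index) - set(self.gene_map.index)
        if missing:
            raise ValueError(f"sgRNAs without gene mapping: {sorted(missing)[:5]}")
        unknown = set(self.counts.columns) - set(self.sample_conditions)
        if unknown:
            raise ValueError(f"samples without condition annotation: {sorted(unknown)}")

    def samples_for_condition(self, condition: str) -> list:
        return [s for s, c in self.sample_conditions.items() if c == condition]


def rpm_normalize(table: ScreenCountTable) -> ScreenCountTable:
    """Fill per-sample reads-per-million: rpm_ij = 1e6 * count_ij / total_j."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    table.rpm = table.counts * 1e6 / totals
    return table


@dataclass(frozen=True)
class SgRNAStat:
    sgrna_id: str
    condition: str
    log2fc: float
    z: float
    p_value: float


@dataclass(frozen=True)
class HitCallConfig:
    """Thresholds of the gene-level hit rule.

    Defaults implement the standard resistance-screen rule: genes carried
    by 3-10 sgRNAs are eligible, and a gene scores in a condition when at
    least 2 of its sgRNAs show >= 2-fold RPM enrichment at p < 0.05.
    """

    fold_threshold: float = 2.0
    p_threshold: float = 0.05
    min_sgrnas: int = 3
    max_sgrnas: int = 10
    min_passing_sgrnas: int = 2
    combine_mode: str = "intersection"
    pseudocount: float = 1.0
    one_sided: bool = False

    def __post_init__(self):
        if self.min_sgrnas > self.max_sgrnas:
            raise ValueError("min_sgrnas must be <= max_sgrnas")
        if self.fold_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.combine_mode not in ("intersection", "union"):
            raise ValueError("combine_mode must be 'intersection' or 'union'")


def sgrna_enrichment(
    table: ScreenCountTable,
    control_label: str,
    treated_label: str,
    config: HitCallConfig = HitCallConfig(),
) -> list[SgRNAStat]:
    """Per-sgRNA enrichment statistics for one treated condition vs control.

    log2fc = log2((rpm_treated + pc) / (rpm_control + pc)); multiple samples
    per condition are averaged on the RPM scale.  The z-score is the robust
    (median/MAD) z of log2fc across all sgRNAs in this condition, and the
    p-value is two-sided standard normal on z (one-sided for enrichment when
    ``config.one_sided``).
    """
    if table.rpm is None:
        raise ValueError("RPM not computed; call rpm_normalize first")
    ctrl = table.samples_for_condition(control_label)
    trt = table.samples_for_condition(treated_label)
    if not ctrl:
        raise ValueError(f"no samples with condition label {control_label!r}")
    if not trt:
        raise ValueError(f"no samples with condition label {treated_label!r}")
    pc = config.pseudocount
    rpm_c = table.rpm[ctrl].mean(axis=1)
    rpm_t = table.rpm[trt].mean(axis=1)
    log2fc = np.log2((rpm_t + pc) / (rpm_c + pc))
    z = robust_z(log2fc.to_numpy())
    if config.one_sided:
        p = _sps.norm.sf(z)
    else:
        p = 2.0 * _sps.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    return [
        SgRNAStat(sg, treated_label, float(l), float(zz), float(pp))
        for sg, l, zz, pp in zip(table.counts.index, log2fc, z, p)
    ]


@dataclass
class GeneHitRecord:
    gene_id: str
    n_sgrnas: int
    passing_per_condition: dict = field(default_factory=dict)
    hit_per_condition: dict = field(default_factory=dict)
    is_hit: bool = False

    @property
    def conditions_hit(self) -> list:
        return [c for c, h in self.hit_per_condition.items() if h]


def call_gene_hits(
    stats_by_condition: dict,
    gene_map: pd.Series,
    config: HitCallConfig = HitCallConfig(),
) -> list[GeneHitRecord]:
    """Gene-level hit calls from per-condition sgRNA statistics.

    Parameters
    ----------
    stats_by_condition
        Mapping of treated-condition label to its ``SgRNAStat`` sequence.
    gene_map
        sgRNA id -> gene id.

    Genes represented outside [min_sgrnas, max_sgrnas] are excluded.  An
    sgRNA passes in a condition iff log2fc >= log2(fold_threshold) and
    p < p_threshold; a gene scores in a condition iff its passing-sgRNA
    count >= min_passing_sgrnas; the final call intersects (or unions)
    the per-condition calls.
    """
    conditions = list(stats_by_condition)
    if not conditions:
        raise ValueError("no conditions supplied")
    for cond, stats in stats_by_condition.items():
        unmapped = [s.sgrna_id for s in stats if s.sgrna_id not in gene_map.index]
        if unmapped:
            raise ValueError(f"unmapped sgRNAs in {cond}: {unmapped[:5]}")

    lfc_min = math.log2(config.fold_threshold)
    sgrnas_per_gene = gene_map.groupby(gene_map).size()

    records = {}
    for gene, n_sg in sgrnas_per_gene.items():
        if config.min_sgrnas <= n_sg <= config.max_sgrnas:
            records[gene] = GeneHitRecord(gene_id=gene, n_sgrnas=int(n_sg))

    for cond, stats in stats_by_condition.items():
        passing = {}
        for s in stats:
            gene = gene_map[s.sgrna_id]
            if gene not in records:
                continue
            ok = s.log2fc >= lfc_min and s.p_value < config.p_threshold
            passing[gene] = passing.get(gene, 0) + int(ok)
        for gene, rec in records.items():
            n_pass = passing.get(gene, 0)
            rec.passing_per_condition[cond] = n_pass
            rec.hit_per_condition[cond] = n_pass >= config.min_passing_sgrnas

    for rec in records.values():
        flags = [rec.hit_per_condition.get(c, False) for c in conditions]
        rec.is_hit = all(flags) if config.combine_mode == "intersection" else any(flags)
    return sorted(records.values(), key=lambda r: r.gene_id)


def call_hits_brute_force(stats_by_condition, gene_map, config=HitCallConfig()):
    """Unvectorized reference hit caller (nested loops; for validation only).

    Returns the sorted list of final-hit gene ids.  Kept deliberately
    independent of :func:`call_gene_hits`.
    """
    genes = sorted(set(gene_map.values))
    hits = []
    for gene in genes:
        gene_sgrnas = [sg for sg in gene_map.index if gene_map[sg] == gene]
        if not (config.min_sgrnas <= len(gene_sgrnas) <= config.max_sgrnas):
            continue
        per_condition = []
        for cond in stats_by_condition:
            n_pass = 0
            for s in stats_by_condition[cond]:
                if s.sgrna_id in gene_sgrnas:
                    if (
                        s.log2fc >= math.log2(config.fold_threshold)
                        and s.p_value < config.p_threshold
                    ):
                        n_pass += 1
            per_condition.append(n_pass >= config.min_passing_sgrnas)
        if config.combine_mode == "intersection":
            final = all(per_condition)
        else:
            final = any(per_condition)
        if final:
            hits.append(gene)
    return hits


def coverage_check(n_cells: float, n_sgrnas: int, infection_rate: float = 1.0) -> float:
    """Mean cells per sgRNA for a planned screen: n_cells * infection_rate / n_sgrnas.

    Pooled screens aim to keep this representation above ~500 so that
    sampling noise does not swamp true enrichment; e.g. 40 million cells
    over a 77,441-sgRNA library gives ~516 cells per sgRNA.
    """
    if n_cells <= 0 or n_sgrnas <= 0:
        raise ValueError("cell and library sizes must be positive")
    if not (0 < infection_rate <= 1):
        raise ValueError("infection_rate must be in (0, 1]")
    return n_cells * infection_rate / n_sgrnas
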