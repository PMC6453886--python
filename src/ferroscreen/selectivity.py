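"""Lineage / histotype selectivity analysis of drug-sensitivity matrices.

Operates on a cell-line x compound matrix of normalized viability AUCs
(1 = fully insensitive; lower = more sensitive), such as a CTRP-style
compound panel.  After coverage filtering, each compound is tested for
differential sensitivity between a flagged cell-line group (e.g. the
clear-cell carcinoma histotype) and all other lines with a two-sided
Mann-Whitney test, BH-adjusted across compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import bh_adjust, mann_whitney_u

__all__ = [
    "SensitivityMatrix",
    "SelectivityConfig",
    "SelectivityResult",
    "FilterReport",
    "apply_inclusion_filters",
    "compound_selectivity",
    "lineage_ranking",
]


@dataclass
class SensitivityMatrix:
    """Cell line x compound AUC matrix with lineage labels.

    ``auc`` is a DataFrame (rows = cell lines, columns = compounds, NaN =
    not profiled); ``lineages`` maps cell line -> lineage label;
    ``group_flags`` maps cell line -> bool for the histotype group of
    interest (e.g. clear-cell carcinoma membership, which cuts across
    lineages).
    """

    auc: pd.DataFrame
    lineages: dict
    group_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = self.auc.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite AUC values present")
        missing = set(self.auc.index) - set(self.lineages)
        if missing:
            raise ValueError(f"cell lines without lineage label: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class SelectivityConfig:
    """Inclusion filters for the selectivity analysis.

    Compounds must be profiled in at least ``compound_coverage_min`` of the
    cell-line collection, lines in at least ``line_coverage_min`` of the
    retained compounds, and a lineage enters the ranking only with more
    than ``min_lineage_size - 1`` lines (default floor: > 5 lines).
    """

    compound_coverage_min: float = 2.0 / 3.0
    line_coverage_min: float = 0.5
    min_lineage_size: int = 6

    def __post_init__(self):
        for f in (self.compound_coverage_min, self.line_coverage_min):
            if not (0 < f <= 1):
                raise ValueError("coverage fractions must be in (0, 1]")


@dataclass
class FilterReport:
    excluded_compounds: dict
    excluded_lines: dict


def apply_inclusion_filters(
    matrix: SensitivityMatrix, config: SelectivityConfig = SelectivityConfig()
):
    """Drop sparsely profiled compounds, then sparsely profiled lines.

    Compound coverage is the fraction of cell lines with a measured AUC;
    line coverage is recomputed against the retained compounds.  One pass
    each, compounds first — the order matters for borderline cases and is
    fixed for determinism.  Returns (filtered matrix, FilterReport).
    """
    if matrix.auc.size == 0:
        raise ValueError("empty sensitivity matrix")
    observed = matrix.auc.notna()

    comp_cov = observed.mean(axis=0)
    keep_comp = comp_cov >= config.compound_coverage_min
    excluded_compounds = {
        c: float(comp_cov[c]) for c in matrix.auc.columns if not keep_comp[c]
    }

    retained = matrix.auc.loc[:, keep_comp]
    if retained.shape[1] == 0:
        raise ValueError("all compounds removed by coverage filter")
    line_cov = retained.notna().mean(axis=1)
    keep_line = line_cov >= config.line_coverage_min
    excluded_lines = {
        l: float(line_cov[l]) for l in matrix.auc.index if not keep_line[l]
    }
    filtered = retained.loc[keep_line]
    if filtered.shape[0] == 0:
        raise ValueError("all cell lines removed by coverage filter")

    out = SensitivityMatrix(
        auc=filtered,
        lineages={l: matrix.lineages[l] for l in filtered.index},
        group_flags={l: matrix.group_flags.get(l, False) for l in filtered.index},
    )
    return out, FilterReport(excluded_compounds, excluded_lines)


@dataclass(frozen=True)
class SelectivityResult:
    compound: str
    effect: float  # mean(group AUC) - mean(rest AUC); negative = group more sensitive
    u_statistic: float
    p_value: float
    adj_p: float
    n_group: int
    n_rest: int


def compound_selectivity(
    matrix: SensitivityMatrix,
    group_flags: dict | None = None,
    effect_stat: str = "mean",
) -> list[SelectivityResult]:
    """Per-compound differential sensitivity of a cell-line group vs the rest.

    Missing AUCs are dropped per compound; compounds with fewer than two
    measured lines on either side are skipped.  Effect is the difference of
    group means (or medians with ``effect_stat='median'``); p-values come
    from the two-sided Mann-Whitney test and are BH-adjusted across the
    tested compounds.  Results are sorted by adjusted p, ties broken by
    effect (most sensitizing first).
    """
    flags = group_flags if group_flags is not None else matrix.group_flags
    in_group = np.array([bool(flags.get(l, False)) for l in matrix.auc.index])
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("group and complement must each contain >= 2 cell lines")
    if effect_stat not in ("mean", "median"):
        raise ValueError("effect_stat must be 'mean' or 'median'")
    loc = np.mean if effect_stat == "mean" else np.median

    tested = []
    for compound in matrix.auc.columns:
        col = matrix.auc[compound].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        g = col[ok & in_group]
        r = col[ok & ~in_group]
        if g.size < 2 or r.size < 2:
            continue
        res = mann_whitney_u(g, r)
        tested.append(
            (compound, float(loc(g) - loc(r)), res.statistic, res.p_value,
             g.size, r.size)
        )
    if not tested:
        raise ValueError("no compound had enough measurements on both sides")
    adj = bh_adjust([t[3] for t in tested])
    results = [
        SelectivityResult(c, eff, u, p, float(q), ng, nr)
        for (c, eff, u, p, ng, nr), q in zip(tested, adj)
    ]
    results.sort(key=lambda r: (r.adj_p, r.effect))
    return results


@dataclass(frozen=True)
class LineageRank:
    lineage: str
    mean_auc: float
    n_lines: int
    p_value: float
    adj_p: float


def lineage_ranking(
    matrix: SensitivityMatrix,
    compound: str,
    config: SelectivityConfig = SelectivityConfig(),
) -> list[LineageRank]:
    """Rank lineages by mean AUC for one compound (most sensitive first).

    Only lineages with at least ``config.min_lineage_size`` measured lines
    are ranked; each is tested against all other measured lines with the
    two-sided Mann-Whitney test, BH-adjusted across lineages.
    """
    if compound not in matrix.auc.columns:
        raise ValueError(f"compound {compound!r} not in matrix")
    col = matrix.auc[compound]
    measured = col.dropna()
    lineage_of = {l: matrix.lineages[l] for l in measured.index}
    counts = pd.Series(lineage_of).value_counts()
    eligible = [lg for lg in counts.index if counts[lg] >= config.min_lineage_size]
    if not eligible:
        raise ValueError("no lineage meets the minimum size floor")

    rows = []
    for lg in eligible:
        mask = np.array([lineage_of[l] == lg for l in measured.index])
        g = measured.to_numpy()[mask]
        r = measured.to_numpy()[~mask]
        res = mann_whitney_u(g, r)
        rows.append((lg, float(g.mean()), int(g.size), res.p_value))
    adj = bh_adjust([r[3] for r in rows])
    ranks = [
        LineageRank(lg, m, n, p, float(q)) for (lg, m, n, p), q in zip(rows, adj)
    ]
    ranks.sort(key=lambda r: r.mean_auc)
    return ranks
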