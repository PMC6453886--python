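"""Lipidomics: summed-composition annotation parsing, PUFA classification,
median normalization, differential abundance and class ratios.

LC-MS lipidomics commonly reports species at "summed composition": the
lipid class plus the total acyl-chain carbons and total double bonds, e.g.
"PE C38:4" — the split of those 4 double bonds across the two acyl chains
is not resolved.  A species is called PUFA-containing here when its total
double-bond count *guarantees* at least one polyunsaturated (>= 2 double
bonds) chain under every possible split: by pigeonhole that is
DB >= n_chains + 1.  This is the weakest class-aware rule that cannot
over-call; stricter per-class conventions can be supplied as overrides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import bh_adjust, student_t_test

__all__ = [
    "CHAIN_COUNTS",
    "LipidSpecies",
    "LipidAbundanceTable",
    "LipidDiffRecord",
    "LipidClassConfig",
    "parse_annotation",
    "classify_pufa",
    "median_normalize",
    "differential_abundance",
    "class_pufa_ratio",
    "pca_scores",
]

#: Acyl/alkenyl chain count by lipid class.  Single-chain: cholesterol
#: esters, monoacylglycerols, lyso-phospholipids, free fatty acids.
#: Triple-chain: triacylglycerols.  Everything else carries two chains.
CHAIN_COUNTS = {
    "CE": 1, "MAG": 1, "LPC": 1, "LPE": 1, "FFA": 1,
    "Cer": 2, "DAG": 2, "PC": 2, "PE": 2, "ePC": 2, "ePE": 2,
    "PI": 2, "PS": 2, "SM": 2,
    "TAG": 3,
}

_CLASS_LOOKUP = {k.upper(): k for k in CHAIN_COUNTS}
_COMP_RE = re.compile(r"^C?(\d+):(\d+)$")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at summed-composition resolution."""

    lipid_class: str
    n_carbons: int
    n_double_bonds: int
    annotation: str = ""

    def __post_init__(self):
        if self.lipid_class not in CHAIN_COUNTS:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.n_carbons <= 0:
            raise ValueError("carbon count must be positive")
        if self.n_double_bonds < 0:
            raise ValueError("double-bond count must be non-negative")
        if not self.annotation:
            object.__setattr__(self, "annotation", self.canonical())

    @property
    def n_chains(self) -> int:
        return CHAIN_COUNTS[self.lipid_class]

    def canonical(self) -> str:
        return f"{self.lipid_class} C{self.n_carbons}:{self.n_double_bonds}"


def parse_annotation(text: str) -> LipidSpecies:
    """Parse "<CLASS> C<carbons>:<db>" (or composition-first) annotations.

    The "C" prefix is optional and the class is matched case-insensitively;
    "TAG C54:6", "C38:4 PE" and "tag 54:6" all parse.
    """
    tokens = text.strip().split()
    if len(tokens) != 2:
        raise ValueError(f"cannot parse lipid annotation {text!r}: "
                         "expected '<CLASS> <carbons>:<db>' in either order")
    for cls_tok, comp_tok in (tokens, tokens[::-1]):
        cls = _CLASS_LOOKUP.get(cls_tok.upper())
        m = _COMP_RE.match(comp_tok)
        if cls is not None and m:
            return LipidSpecies(cls, int(m.group(1)), int(m.group(2)), text.strip())
    # Produce a precise error: composition or class?
    if not any(_COMP_RE.match(t) for t in tokens):
        raise ValueError(f"malformed composition token in {text!r}")
    bad = [t for t in tokens if not _COMP_RE.match(t)]
    raise ValueError(f"unknown lipid class {bad[0]!r} in {text!r}")


@dataclass(frozen=True)
class LipidClassConfig:
    """PUFA-classification settings.

    ``pufa_min_db_override`` maps a lipid class to a minimum total
    double-bond count that replaces the default pigeonhole threshold
    (n_chains + 1) for that class.
    """

    chain_counts: dict = field(default_factory=lambda: dict(CHAIN_COUNTS))
    pufa_min_db_override: dict = field(default_factory=dict)


def classify_pufa(
    species: LipidSpecies, config: LipidClassConfig = LipidClassConfig()
) -> bool:
    """True when the species necessarily contains a polyunsaturated chain.

    Default rule: total double bonds >= n_chains + 1.  With n_chains chains
    each holding at most 1 double bond, the total can reach n_chains; one
    more forces some chain to >= 2 double bonds, i.e. a PUFA chain.
    """
    threshold = config.pufa_min_db_override.get(
        species.lipid_class, config.chain_counts[species.lipid_class] + 1
    )
    return species.n_double_bonds >= threshold


@dataclass
class LipidAbundanceTable:
    """Species x sample abundances with group labels.

    ``abundances`` is indexed by annotation string with one column per
    sample; ``sample_groups`` maps sample -> group label and
    ``reference_group`` names the baseline (e.g. wild-type) group.
    """

    species: list
    abundances: pd.DataFrame
    sample_groups: dict
    reference_group: str

    def __post_init__(self):
        if (np.asarray(self.abundances) < 0).any():
            raise ValueError("negative abundances")
        if self.reference_group not in self.sample_groups.values():
            raise ValueError(f"reference group {self.reference_group!r} has no samples")
        if len(self.species) != len(self.abundances):
            raise ValueError("species list does not match abundance rows")

    def samples_in_group(self, group: str) -> list:
        return [s for s, g in self.sample_groups.items() if g == group]

    @property
    def groups(self) -> list:
        seen = []
        for g in self.sample_groups.values():
            if g not in seen:
                seen.append(g)
        return seen


def median_normalize(table: LipidAbundanceTable) -> LipidAbundanceTable:
    """Equalize sample medians (corrects per-sample loading/injection).

    Each sample is scaled by (grand median of sample medians)/(own median),
    so after normalization every sample has the same median abundance.
    """
    medians = table.abundances.median(axis=0)
    bad = medians[medians <= 0]
    if len(bad):
        raise ValueError(f"non-positive sample median(s): {list(bad.index)}")
    grand = float(np.median(medians))
    scaled = table.abundances * (grand / medians)
    return LipidAbundanceTable(
        species=list(table.species),
        abundances=scaled,
        sample_groups=dict(table.sample_groups),
        reference_group=table.reference_group,
    )


@dataclass(frozen=True)
class LipidDiffRecord:
    species: LipidSpecies
    group: str
    log2fc: float
    p_value: float
    adj_p: float
    pufa_flag: bool
    not_detected: bool = False

    @property
    def neg_log10_adj_p(self) -> float:
        return float(-np.log10(self.adj_p)) if self.adj_p > 0 else np.inf


def differential_abundance(
    table: LipidAbundanceTable,
    reference_group: str | None = None,
    class_config: LipidClassConfig = LipidClassConfig(),
) -> list[LipidDiffRecord]:
    """Per-species differential abundance of each group vs the reference.

    For each species and non-reference group: log2fc of the group mean over
    the reference mean, a two-tailed Student t-test on per-sample log2
    abundances, and BH adjustment across species within each group
    comparison.  Species with zero mean in either side of a comparison are
    reported with ``not_detected=True`` and excluded from testing (the
    "nd" convention); they never enter the BH family.
    """
    ref = reference_group or table.reference_group
    if ref not in table.sample_groups.values():
        raise ValueError(f"reference group {ref!r} has no samples")
    ref_samples = table.samples_in_group(ref)
    if len(ref_samples) < 2:
        raise ValueError("need >= 2 reference samples")

    records: list[LipidDiffRecord] = []
    for group in table.groups:
        if group == ref:
            continue
        test_samples = table.samples_in_group(group)
        if len(test_samples) < 2:
            raise ValueError(f"need >= 2 samples in group {group!r}")
        tested, pvals = [], []
        for sp, (_, row) in zip(table.species, table.abundances.iterrows()):
            a_ref = row[ref_samples].to_numpy(dtype=float)
            a_tst = row[test_samples].to_numpy(dtype=float)
            pufa = classify_pufa(sp, class_config)
            if a_ref.mean() <= 0 or a_tst.mean() <= 0:
                records.append(
                    LipidDiffRecord(sp, group, np.nan, np.nan, np.nan, pufa, True)
                )
                continue
            lfc = float(np.log2(a_tst.mean() / a_ref.mean()))
            # test on log scale; a tiny floor guards exact zeros in replicates
            eps = 1e-12
            res = student_t_test(np.log2(a_tst + eps), np.log2(a_ref + eps))
            tested.append((sp, group, lfc, pufa))
            pvals.append(res.p_value)
        adj = bh_adjust(pvals) if pvals else []
        for (sp, grp, lfc, pufa), p, q in zip(tested, pvals, adj):
            records.append(LipidDiffRecord(sp, grp, lfc, float(p), float(q), pufa))
    return records


def class_pufa_ratio(
    table: LipidAbundanceTable,
    classes,
    class_config: LipidClassConfig = LipidClassConfig(),
) -> pd.Series:
    """Per-sample fraction of class abundance carried by PUFA species.

    E.g. classes={"PE", "ePE"} gives PUFA-PE/ePE over total PE/ePE per
    sample — the tissue-level readout of polyunsaturated phospholipid
    enrichment.  Invariant to per-sample rescaling (hence to median
    normalization).
    """
    classes = set(classes)
    if not classes:
        raise ValueError("empty class selection")
    unknown = classes - set(CHAIN_COUNTS)
    if unknown:
        raise ValueError(f"unknown lipid class(es): {sorted(unknown)}")
    in_set = np.array([sp.lipid_class in classes for sp in table.species])
    if not in_set.any():
        raise ValueError(f"no species from classes {sorted(classes)} in table")
    pufa = np.array([classify_pufa(sp, class_config) for sp in table.species])
    total = table.abundances.loc[in_set].sum(axis=0)
    pufa_sum = table.abundances.loc[in_set & pufa].sum(axis=0)
    return pufa_sum / total


def pca_scores(matrix: pd.DataFrame, center: str = "median"):
    """Principal-component scores of a samples x features matrix via SVD.

    Intended for log-ratio lipid matrices (samples as rows).  Features are
    centered (median by default, matching median-normalized log-ratios;
    "mean" optional), then scores are taken from the SVD of the centered
    matrix.  Returns (scores DataFrame with PC1.. columns, variance-fraction
    array summing to 1).
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 features")
    if center == "median":
        Xc = X - np.median(X, axis=0)
    elif center == "mean":
        Xc = X - X.mean(axis=0)
    else:
        raise ValueError("center must be 'median' or 'mean'")
    if np.allclose(Xc, 0):
        raise ValueError("degenerate matrix: all samples identical after centering")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    var_frac = s**2 / np.sum(s**2)
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    idx = matrix.index if isinstance(matrix, pd.DataFrame) else None
    return pd.DataFrame(scores, index=idx, columns=cols), var_frac
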