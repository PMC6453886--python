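"""Synthetic data generators with planted ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — negative-binomial sgRNA counts with planted resistance genes,
log-normal lipidomes with PUFA-selective depletion, 4PL viability curves
with replicate noise, and AUC matrices with one lineage-selective
compound — and returns the planted truth alongside the data so that
recovery and calibration can be tested end to end.

All randomness is confined to a per-config seed; identical configs produce
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crispr_screen import ScreenCountTable
from .dose_response import DoseSeries, ViabilityCurveData, four_param_logistic
from .lipidomics import CHAIN_COUNTS, LipidSpecies, LipidAbundanceTable, classify_pufa
from .selectivity import SensitivityMatrix

__all__ = [
    "ScreenSimConfig",
    "LipidomeSimConfig",
    "ViabilitySimConfig",
    "SensitivitySimConfig",
    "gen_screen_counts",
    "gen_lipidome",
    "gen_viability",
    "gen_sensitivity_matrix",
    "tumor_volume",
]


def _require(ok: bool, name: str, msg: str) -> None:
    if not ok:
        raise ValueError(f"invalid config field {name!r}: {msg}")


# ---------------------------------------------------------------------------
# CRISPR screen counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSimConfig:
    """Pooled resistance-screen simulation.

    The default geometry is a scaled-down genome-wide screen: ``n_genes``
    genes at 4 sgRNAs each (within the 3-10 window the hit caller accepts),
    sequencing depth of 500 expected reads per sgRNA (the representation
    floor a well-powered screen maintains), and negative-binomial counts
    with variance m + dispersion * m^2.  Planted resistance genes have a
    fraction of their sgRNAs enriched ``enrichment_fold``-times in every
    treated condition; the rest of their sgRNAs stay null, so the
    >= 2-passing-sgRNAs rule is genuinely exercised.
    """

    n_genes: int = 1000
    sgrnas_per_gene: int = 4
    n_planted_resistance_genes: int = 20
    enrichment_fold: float = 8.0
    fraction_sgrnas_active: float = 0.75
    sequencing_depth: float | None = None  # default: 500 reads per sgRNA
    dispersion: float = 0.05
    conditions: tuple = ("d4", "d6", "d8")
    control_label: str = "DMSO"
    library_lognorm_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        _require(self.n_genes >= 1, "n_genes", "must be >= 1")
        _require(3 <= self.sgrnas_per_gene <= 10, "sgrnas_per_gene",
                 "must lie in 3-10 (the eligible window)")
        _require(0 <= self.n_planted_resistance_genes <= self.n_genes,
                 "n_planted_resistance_genes", "must be <= n_genes")
        _require(self.enrichment_fold > 0, "enrichment_fold", "must be positive")
        _require(0 < self.fraction_sgrnas_active <= 1,
                 "fraction_sgrnas_active", "must be in (0, 1]")
        if self.sequencing_depth is not None:
            _require(self.sequencing_depth > 0, "sequencing_depth", "must be positive")
        _require(self.dispersion >= 0, "dispersion", "must be >= 0")
        _require(len(self.conditions) >= 1, "conditions",
                 "need at least one treated condition")

    @property
    def n_sgrnas(self) -> int:
        return self.n_genes * self.sgrnas_per_gene

    @property
    def depth(self) -> float:
        return (
            self.sequencing_depth
            if self.sequencing_depth is not None
            else 500.0 * self.n_sgrnas
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial with variance m + dispersion*m^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def gen_screen_counts(config: ScreenSimConfig):
    """Simulate a screen count table plus its planted-gene truth.

    Returns
    -------
    (ScreenCountTable, truth)
        ``truth`` is a dict with ``planted_genes`` (sorted ids) and
        ``active_sgrnas`` (the enriched guides of each planted gene).

    Baseline sgRNA abundances are log-normal (library skew); expected
    per-sample counts are rescaled so each sample's expected total equals
    the configured depth, so treated columns stay depth-comparable to the
    control even when enrichment adds mass.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    sgrnas, gene_of = [], []
    for g in genes:
        for k in range(config.sgrnas_per_gene):
            sgrnas.append(f"{g}_sg{k}")
            gene_of.append(g)
    gene_map = pd.Series(gene_of, index=sgrnas)

    planted_idx = rng.choice(
        config.n_genes, size=config.n_planted_resistance_genes, replace=False
    )
    planted = sorted(genes[i] for i in planted_idx)
    n_active = max(1, round(config.fraction_sgrnas_active * config.sgrnas_per_gene))
    active_sgrnas: dict[str, list] = {}
    active_mask = np.zeros(len(sgrnas), dtype=bool)
    sg_index = {sg: i for i, sg in enumerate(sgrnas)}
    for g in planted:
        guides = [f"{g}_sg{k}" for k in range(config.sgrnas_per_gene)]
        chosen = sorted(rng.choice(guides, size=n_active, replace=False))
        active_sgrnas[g] = chosen
        for sg in chosen:
            active_mask[sg_index[sg]] = True

    baseline = rng.lognormal(mean=0.0, sigma=config.library_lognorm_sd,
                             size=len(sgrnas))

    counts = {}
    samples = [config.control_label, *config.conditions]
    for sample in samples:
        w = baseline.copy()
        if sample != config.control_label:
            w[active_mask] *= config.enrichment_fold
        mean = config.depth * w / w.sum()
        counts[sample] = _nb_draw(rng, mean, config.dispersion)
    count_df = pd.DataFrame(counts, index=sgrnas)
    table = ScreenCountTable(
        counts=count_df,
        gene_map=gene_map,
        sample_conditions={s: s for s in samples},
    )
    truth = {"planted_genes": planted, "active_sgrnas": active_sgrnas}
    return table, truth


# ---------------------------------------------------------------------------
# Lipidome
# ---------------------------------------------------------------------------

#: default species counts per class, roughly mirroring the footprint of a
#: ~200-species summed-composition LC-MS panel
DEFAULT_LIPID_CLASSES = {
    "TAG": 40, "PC": 20, "PE": 15, "ePC": 10, "ePE": 10, "PI": 8, "PS": 6,
    "SM": 10, "LPC": 6, "LPE": 5, "DAG": 10, "MAG": 4, "CE": 8, "Cer": 8,
    "FFA": 10,
}

# per-chain carbon range used when sampling summed compositions
_CHAIN_CARBONS = (14, 22)
_MAX_DB_PER_CHAIN = 6


@dataclass(frozen=True)
class LipidomeSimConfig:
    """Lipid abundance tables with planted PUFA-selective depletion.

    Defaults mirror a two-group lipidomics comparison with triplicate
    samples: log-normal baselines, log2-scale Gaussian noise of 0.25, and
    a -2 log2 fold change planted on every PUFA-classified species in the
    non-reference group(s).
    """

    classes: dict = field(
        default_factory=lambda: dict(DEFAULT_LIPID_CLASSES)
    )
    n_samples_per_group: int = 3
    groups: tuple = ("WT", "KO")
    pufa_depletion_log2fc: float = -2.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.classes) - set(CHAIN_COUNTS)
        _require(not unknown, "classes", f"unknown lipid class(es) {sorted(unknown)}")
        _require(len(self.groups) >= 2, "groups", "need at least 2 groups")
        _require(self.n_samples_per_group >= 3, "n_samples_per_group",
                 "need >= 3 samples per group for testing")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


def _sample_species(rng: np.random.Generator, lipid_class: str, n: int):
    """Draw n distinct (carbons, double-bond) summed compositions.

    Double-bond counts are sampled with geometrically decaying weights so
    that saturated/monounsaturated species dominate and PUFA species are a
    minority, as in real membranes — this also keeps the sample median
    anchored on unchanged species when a PUFA-selective effect is planted.
    """
    nc = CHAIN_COUNTS[lipid_class]
    lo, hi = _CHAIN_CARBONS
    carbons = np.arange(nc * lo, nc * hi + 1, 2)
    dbs = np.arange(0, nc * _MAX_DB_PER_CHAIN + 1)
    grid = [(int(c), int(d)) for c in carbons for d in dbs]
    weights = np.array([np.exp(-0.6 * d) for _, d in grid])
    weights /= weights.sum()
    idx = rng.choice(len(grid), size=min(n, len(grid)), replace=False, p=weights)
    pairs = sorted(grid[i] for i in idx)
    return [LipidSpecies(lipid_class, c, d) for c, d in pairs]


def gen_lipidome(config: LipidomeSimConfig):
    """Simulate a lipid abundance table plus per-species planted log2fc.

    Reference-group abundances are log-normal around per-species baselines;
    PUFA-classified species (pigeonhole rule on the summed composition)
    carry ``pufa_depletion_log2fc`` in every non-reference group.  Returns
    (LipidAbundanceTable, truth DataFrame with columns ``annotation``,
    ``pufa``, ``planted_log2fc``).
    """
    rng = np.random.default_rng(config.seed)
    species: list[LipidSpecies] = []
    for cls, n in config.classes.items():
        species.extend(_sample_species(rng, cls, n))

    n_sp = len(species)
    baselines = rng.lognormal(mean=np.log(1e4), sigma=1.0, size=n_sp)
    pufa = np.array([classify_pufa(sp) for sp in species])

    samples, sample_groups = [], {}
    data = {}
    reference = config.groups[0]
    for group in config.groups:
        lfc = np.where(pufa & (group != reference),
                       config.pufa_depletion_log2fc, 0.0)
        for j in range(config.n_samples_per_group):
            name = f"{group}_{j+1}"
            noise = rng.normal(0.0, config.noise_sd, size=n_sp)
            data[name] = baselines * 2.0 ** (lfc + noise)
            samples.append(name)
            sample_groups[name] = group

    table = LipidAbundanceTable(
        species=species,
        abundances=pd.DataFrame(
            data, index=[sp.annotation for sp in species]
        ),
        sample_groups=sample_groups,
        reference_group=reference,
    )
    truth = pd.DataFrame(
        {
            "annotation": [sp.annotation for sp in species],
            "pufa": pufa,
            "planted_log2fc": np.where(pufa, config.pufa_depletion_log2fc, 0.0),
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# Viability curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViabilitySimConfig:
    """4PL viability curves with homoscedastic replicate noise.

    Defaults match the common assay layout: a 7-point, 2-fold series with
    four replicate wells per concentration, vehicle-normalized top near 1.
    """

    top: float = 1.0
    bottom: float = 0.0
    ec50: float = 0.5
    hill: float = 1.0
    series: DoseSeries = field(
        default_factory=lambda: DoseSeries(5.0, 7, 2.0)
    )
    n_replicates: int = 4
    noise_sd: float = 0.02
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        _require(0 <= self.bottom <= self.top <= 1.5, "top/bottom",
                 "need 0 <= bottom <= top <= 1.5")
        _require(self.ec50 > 0, "ec50", "must be positive")
        _require(self.hill > 0, "hill", "must be positive")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


def gen_viability(config: ViabilitySimConfig) -> ViabilityCurveData:
    """Simulate replicate viabilities: 4PL signal + Gaussian noise, floored at 0."""
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(config.series.concentrations)
    signal = four_param_logistic(
        conc, config.top, config.bottom, config.ec50, config.hill
    )
    noise = rng.normal(0.0, config.noise_sd, size=(conc.size, config.n_replicates))
    v = np.clip(signal[:, None] + noise, 0.0, None)
    return ViabilityCurveData(
        series=config.series,
        replicate_viabilities=v,
        normalized=True,
        label=config.label,
    )


# ---------------------------------------------------------------------------
# Sensitivity matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivitySimConfig:
    """AUC matrices with one planted lineage-selective compound.

    ``lineage_sizes`` gives cell lines per lineage; exactly one lineage
    (``target_lineage``) is sensitive to the planted compound, whose mean
    AUC there is shifted by ``planted_effect`` (negative = sensitizing).
    Baseline AUCs are Gaussian around ``baseline_mean`` and clipped to
    [0, 1].
    """

    lineage_sizes: dict = field(
        default_factory=lambda: {"target": 10, "other_a": 50, "other_b": 50}
    )
    target_lineage: str = "target"
    n_compounds: int = 50
    planted_effect: float = -0.4
    missing_fraction: float = 0.0
    baseline_mean: float = 0.85
    baseline_sd: float = 0.08
    seed: int = 0

    def __post_init__(self):
        _require(self.target_lineage in self.lineage_sizes, "target_lineage",
                 "must name a lineage in lineage_sizes")
        _require(self.n_compounds >= 1, "n_compounds", "must be >= 1")
        _require(self.planted_effect <= 0, "planted_effect",
                 "must be <= 0 (the sensitive lineage has lower AUC)")
        _require(0 <= self.missing_fraction < 1, "missing_fraction",
                 "must be in [0, 1)")


def gen_sensitivity_matrix(config: SensitivitySimConfig):
    """Simulate an AUC matrix plus truth (the planted compound id).

    Returns (SensitivityMatrix, truth dict with ``selective_compound`` and
    ``target_lineage``).  The target-lineage lines carry the histotype
    group flag.
    """
    rng = np.random.default_rng(config.seed)
    lines, lineages = [], {}
    for lg, n in config.lineage_sizes.items():
        for j in range(n):
            name = f"{lg}_line_{j+1:03d}"
            lines.append(name)
            lineages[name] = lg
    compounds = [f"cpd_{i+1:03d}" for i in range(config.n_compounds)]
    planted = compounds[int(rng.integers(config.n_compounds))]

    target = np.array([lineages[l] == config.target_lineage for l in lines])
    auc = rng.normal(config.baseline_mean, config.baseline_sd,
                     size=(len(lines), len(compounds)))
    j = compounds.index(planted)
    auc[target, j] += config.planted_effect
    auc = np.clip(auc, 0.0, 1.0)
    if config.missing_fraction > 0:
        mask = rng.random(auc.shape) < config.missing_fraction
        auc = np.where(mask, np.nan, auc)

    matrix = SensitivityMatrix(
        auc=pd.DataFrame(auc, index=lines, columns=compounds),
        lineages=lineages,
        group_flags={l: bool(t) for l, t in zip(lines, target)},
    )
    truth = {"selective_compound": planted, "target_lineage": config.target_lineage}
    return matrix, truth


# ---------------------------------------------------------------------------
# Xenograft volume
# ---------------------------------------------------------------------------

def tumor_volume(length_l: float, width_w: float) -> float:
    """Caliper tumor volume in mm^3: V = L * W * W / 2, with L >= W > 0."""
    if width_w <= 0 or length_l <= 0:
        raise ValueError("length and width must be positive")
    if length_l < width_w:
        raise ValueError("length must be >= width (L is the long axis)")
    return length_l * width_w * width_w / 2.0
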