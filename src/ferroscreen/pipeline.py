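"""Pipeline orchestration: validated run configs, stage execution, manifest.

A run config selects stages and their parameters; ``run_pipeline`` executes
them in dependency order, writes each stage's TSV outputs under the output
directory, and records a manifest (config hash, seed, per-stage output row
counts) so that identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import crispr_screen as cs
from . import io as fio
from . import lipidomics as lp
from . import selectivity as sel
from . import synthetic_data as syn

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "STAGES"]

log = logging.getLogger("ferroscreen")

STAGES = (
    "simulate_screen",
    "screen",
    "simulate_lipidome",
    "lipids",
    "simulate_sensitivity",
    "select",
)

_KNOWN_KEYS = {"stages", "seed", "out_dir", "log_level", "params", "inputs"}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages``: ordered subset of :data:`STAGES`; ``params``: per-stage
    keyword blocks; ``inputs``: per-stage input paths (analysis stages fall
    back to the outputs of their simulate counterpart in ``out_dir``).
    """

    stages: list
    out_dir: Path
    seed: int = 0
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.stages:
            raise ValueError("config selects no stages")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; known: {list(STAGES)}")
        bad = set(self.params) - set(STAGES)
        if bad:
            raise ValueError(f"params for unknown stage(s): {sorted(bad)}")
        self.out_dir = Path(self.out_dir)
        for stage, paths in self.inputs.items():
            for key, p in paths.items():
                if not Path(p).exists():
                    raise ValueError(f"input path for {stage}.{key} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(
            stages=raw.get("stages", []),
            out_dir=raw.get("out_dir", "."),
            seed=int(raw.get("seed", 0)),
            params=raw.get("params", {}) or {},
            inputs=raw.get("inputs", {}) or {},
            log_level=raw.get("log_level", "INFO"),
        )

    def canonical_hash(self) -> str:
        blob = yaml.safe_dump(
            {
                "stages": list(self.stages),
                "seed": self.seed,
                "params": self.params,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _rows(path: Path) -> int:
    return sum(1 for _ in open(path)) - 1  # minus header


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and return the manifest dict."""
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.canonical_hash(),
        "seed": config.seed,
        "stages": {},
    }
    for stage in config.stages:
        params = dict(config.params.get(stage, {}))
        try:
            outputs = _STAGE_RUNNERS[stage](config, params, out)
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
            raise PipelineError(stage, exc) from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {name: {"path": str(p), "rows": _rows(p)}
                        for name, p in outputs.items()},
        }
        log.info("stage %s: wrote %s", stage, {k: str(v) for k, v in outputs.items()})
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest


# ---------------------------------------------------------------------------
# Stage runners: each returns {output name: written path}
# ---------------------------------------------------------------------------

def _run_simulate_screen(config, params, out):
    sim = syn.ScreenSimConfig(seed=config.seed, **params)
    table, truth = syn.gen_screen_counts(sim)
    counts, meta = out / "screen_counts.tsv", out / "screen_meta.tsv"
    fio.write_screen_counts(table, counts, meta)
    truth_path = out / "screen_truth.tsv"
    fio.write_table(
        pd.DataFrame({"planted_gene": truth["planted_genes"]}), truth_path
    )
    return {"counts": counts, "meta": meta, "truth": truth_path}


def _run_screen(config, params, out):
    inputs = config.inputs.get("screen", {})
    counts = inputs.get("counts", out / "screen_counts.tsv")
    meta = inputs.get("meta", out / "screen_meta.tsv")
    control = params.pop("control", "DMSO")
    hc = cs.HitCallConfig(**params)
    table = cs.rpm_normalize(fio.load_screen_counts(counts, meta))
    treated = sorted(
        {c for c in table.sample_conditions.values() if c != control}
    )
    stats = {
        cond: cs.sgrna_enrichment(table, control, cond, hc) for cond in treated
    }
    hits = cs.call_gene_hits(stats, table.gene_map, hc)

    stat_rows = [
        {"sgrna_id": s.sgrna_id, "condition": s.condition,
         "log2fc": s.log2fc, "z": s.z, "p_value": s.p_value}
        for cond in treated for s in stats[cond]
    ]
    stats_path = out / "sgrna_stats.tsv"
    fio.write_table(pd.DataFrame(stat_rows), stats_path)

    hit_rows = [
        {
            "gene_id": r.gene_id,
            "n_sgrnas": r.n_sgrnas,
            **{f"passing_{c}": r.passing_per_condition[c] for c in treated},
            "is_hit": r.is_hit,
        }
        for r in hits
    ]
    hits_path = out / "gene_hits.tsv"
    fio.write_table(pd.DataFrame(hit_rows), hits_path)
    return {"sgrna_stats": stats_path, "gene_hits": hits_path}


def _run_simulate_lipidome(config, params, out):
    sim = syn.LipidomeSimConfig(seed=config.seed, **params)
    table, truth = syn.gen_lipidome(sim)
    tbl, meta = out / "lipidome.tsv", out / "lipidome_meta.tsv"
    fio.write_lipid_table(table, tbl, meta)
    truth_path = out / "lipidome_truth.tsv"
    fio.write_table(truth, truth_path)
    return {"table": tbl, "meta": meta, "truth": truth_path}


def _run_lipids(config, params, out):
    inputs = config.inputs.get("lipids", {})
    tbl = inputs.get("table", out / "lipidome.tsv")
    meta = inputs.get("meta", out / "lipidome_meta.tsv")
    reference = params.get("reference", "WT")
    ratio_classes = params.get("classes", ["PE", "ePE"])
    table = fio.load_lipid_table(tbl, meta, reference)
    normalized = lp.median_normalize(table)
    records = lp.differential_abundance(normalized)

    diff_rows = [
        {
            "annotation": r.species.annotation,
            "group": r.group,
            "log2fc": r.log2fc,
            "p_value": r.p_value,
            "adj_p": r.adj_p,
            "neg_log10_adj_p": (r.neg_log10_adj_p if not r.not_detected else ""),
            "pufa": r.pufa_flag,
            "not_detected": r.not_detected,
        }
        for r in records
    ]
    diff_path = out / "lipid_differential.tsv"
    fio.write_table(pd.DataFrame(diff_rows), diff_path)

    ratios = lp.class_pufa_ratio(normalized, ratio_classes)
    ratio_path = out / "lipid_class_ratio.tsv"
    fio.write_table(
        pd.DataFrame({"sample": ratios.index, "pufa_ratio": ratios.values}),
        ratio_path,
    )
    norm_path = out / "lipidome_normalized.tsv"
    fio.write_lipid_table(normalized, norm_path, out / "lipidome_meta_out.tsv")
    return {"differential": diff_path, "class_ratio": ratio_path,
            "normalized": norm_path}


def _run_simulate_sensitivity(config, params, out):
    sim = syn.SensitivitySimConfig(seed=config.seed, **params)
    matrix, truth = syn.gen_sensitivity_matrix(sim)
    path = out / "sensitivity.tsv"
    fio.write_sensitivity_matrix(matrix, path)
    truth_path = out / "sensitivity_truth.tsv"
    fio.write_table(pd.DataFrame([truth]), truth_path)
    return {"matrix": path, "truth": truth_path}


def _run_select(config, params, out):
    inputs = config.inputs.get("select", {})
    path = inputs.get("matrix", out / "sensitivity.tsv")
    sc = sel.SelectivityConfig(**params)
    matrix = fio.load_sensitivity_matrix(path)
    filtered, report = sel.apply_inclusion_filters(matrix, sc)
    results = sel.compound_selectivity(filtered)
    res_path = out / "selectivity.tsv"
    fio.write_table(
        pd.DataFrame(
            [
                {"compound": r.compound, "effect": r.effect,
                 "u_statistic": r.u_statistic, "p_value": r.p_value,
                 "adj_p": r.adj_p, "n_group": r.n_group, "n_rest": r.n_rest}
                for r in results
            ]
        ),
        res_path,
    )
    excl_path = out / "selectivity_exclusions.tsv"
    rows = [
        {"kind": "compound", "id": k, "coverage": v}
        for k, v in report.excluded_compounds.items()
    ] + [
        {"kind": "cell_line", "id": k, "coverage": v}
        for k, v in report.excluded_lines.items()
    ]
    fio.write_table(
        pd.DataFrame(rows, columns=["kind", "id", "coverage"]), excl_path
    )
    return {"selectivity": res_path, "exclusions": excl_path}


_STAGE_RUNNERS = {
    "simulate_screen": _run_simulate_screen,
    "screen": _run_screen,
    "simulate_lipidome": _run_simulate_lipidome,
    "lipids": _run_lipids,
    "simulate_sensitivity": _run_simulate_sensitivity,
    "select": _run_select,
}
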