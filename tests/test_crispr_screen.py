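"""RPM normalization, sgRNA enrichment, gene hit calling, coverage checks."""

import numpy as np
import pandas as pd
import pytest

from ferroscreen.crispr_screen import (
    HitCallConfig,
    ScreenCountTable,
    SgRNAStat,
    call_gene_hits,
    call_hits_brute_force,
    coverage_check,
    rpm_normalize,
    sgrna_enrichment,
)
from ferroscreen.synthetic_data import ScreenSimConfig, gen_screen_counts


class TestRPMNormalize:
    def test_direct_arithmetic(self):
        t = ScreenCountTable(
            counts=pd.DataFrame({"s": [1, 3]}, index=["a_sg0", "a_sg1"]),
            gene_map=pd.Series(["a", "a"], index=["a_sg0", "a_sg1"]),
            sample_conditions={"s": "DMSO"},
        )
        rpm_normalize(t)
        assert t.rpm["s"].tolist() == pytest.approx([250000.0, 750000.0])

    def test_columns_sum_to_million(self, small_screen_table):
        sums = small_screen_table.rpm.sum(axis=0)
        assert np.allclose(sums, 1e6)

    def test_zero_total_sample_named(self):
        t = ScreenCountTable(
            counts=pd.DataFrame({"ok": [1, 2], "empty": [0, 0]},
                                index=["a_sg0", "a_sg1"]),
            gene_map=pd.Series(["a", "a"], index=["a_sg0", "a_sg1"]),
            sample_conditions={"ok": "DMSO", "empty": "d4"},
        )
        with pytest.raises(ValueError, match="empty"):
            rpm_normalize(t)


class TestSgRNAEnrichment:
    def test_equal_rpm_gives_zero_log2fc(self, small_screen_table):
        stats = sgrna_enrichment(small_screen_table, "DMSO", "d4")
        by_id = {s.sgrna_id: s for s in stats}
        # g2 sgRNAs have identical counts in both samples but totals differ;
        # build an exactly-matched pair instead
        t = small_screen_table
        equal = t.rpm["d4"] == t.rpm["DMSO"]
        for sg in t.counts.index[equal]:
            assert by_id[sg].log2fc == 0.0

    def test_exact_fourfold_ratio_without_pseudocount(self):
        counts = pd.DataFrame(
            {"DMSO": [2, 8], "d4": [8, 2]}, index=["a_sg0", "b_sg0"]
        )
        t = rpm_normalize(ScreenCountTable(
            counts=counts,
            gene_map=pd.Series(["a", "b"], index=counts.index),
            sample_conditions={"DMSO": "DMSO", "d4": "d4"},
        ))
        cfg = HitCallConfig(pseudocount=0.0)
        with pytest.raises(ValueError):
            # robust z needs >= 3 sgRNAs; check the log2fc path separately
            sgrna_enrichment(t, "DMSO", "d4", cfg)
        rpm_c, rpm_t = t.rpm["DMSO"], t.rpm["d4"]
        assert np.log2(rpm_t / rpm_c).tolist() == pytest.approx([2.0, -2.0])

    def test_missing_condition_label(self, small_screen_table):
        with pytest.raises(ValueError, match="d9"):
            sgrna_enrichment(small_screen_table, "DMSO", "d9")

    def test_null_simulation_p_value_calibration(self):
        """Without planted genes, ~5% of sgRNAs fall below p=0.05."""
        fracs = []
        for seed in (0, 1, 2):
            table, _ = gen_screen_counts(ScreenSimConfig(
                n_genes=1000, n_planted_resistance_genes=0, seed=seed))
            rpm_normalize(table)
            stats = sgrna_enrichment(table, "DMSO", "d4")
            p = np.array([s.p_value for s in stats])
            fracs.append((p < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.01)


def _random_stats(rng, gene_sizes, conditions):
    """Random per-condition sgRNA statistics over genes of varied size."""
    gene_map = {}
    for g, size in enumerate(gene_sizes):
        for k in range(size):
            gene_map[f"g{g}_sg{k}"] = f"g{g}"
    gene_map = pd.Series(gene_map)
    stats = {}
    for cond in conditions:
        stats[cond] = [
            SgRNAStat(sg, cond,
                      log2fc=float(rng.uniform(-2, 4)),
                      z=0.0,
                      p_value=float(rng.random()))
            for sg in gene_map.index
        ]
    return stats, gene_map


class TestCallGeneHits:
    def _stats(self, per_gene_lfc_p, conditions=("d4", "d6", "d8")):
        """per_gene_lfc_p: {gene: [(log2fc, p), ...]} replicated per condition."""
        gene_map = {}
        stats = {c: [] for c in conditions}
        for gene, guides in per_gene_lfc_p.items():
            for k, (lfc, p) in enumerate(guides):
                sg = f"{gene}_sg{k}"
                gene_map[sg] = gene
                for c in conditions:
                    stats[c].append(SgRNAStat(sg, c, lfc, 0.0, p))
        return stats, pd.Series(gene_map)

    def test_two_sgrna_gene_excluded(self):
        stats, gm = self._stats({"tiny": [(5.0, 1e-9), (5.0, 1e-9)]})
        records = call_gene_hits(stats, gm)
        assert records == []  # outside the 3-10 sgRNA window

    def test_three_passing_of_four_is_hit(self):
        guides = [(3.5, 0.001), (3.0, 0.001), (2.8, 0.001), (0.1, 0.9)]
        stats, gm = self._stats({"hit": guides})
        (rec,) = call_gene_hits(stats, gm)
        assert rec.is_hit
        assert rec.passing_per_condition == {"d4": 3, "d6": 3, "d8": 3}
        assert rec.conditions_hit == ["d4", "d6", "d8"]

    def test_single_passing_sgrna_not_a_hit(self):
        guides = [(4.0, 1e-6), (0.0, 0.9), (0.0, 0.9), (0.0, 0.9)]
        stats, gm = self._stats({"weak": guides})
        (rec,) = call_gene_hits(stats, gm)
        assert not rec.is_hit

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(200):
            n_genes = int(rng.integers(3, 10))
            sizes = rng.integers(1, 13, size=n_genes)
            conditions = ["d4", "d6", "d8"][: int(rng.integers(1, 4))]
            stats, gm = _random_stats(rng, sizes, conditions)
            mode = "intersection" if rng.random() < 0.5 else "union"
            cfg = HitCallConfig(combine_mode=mode)
            fast = sorted(r.gene_id for r in call_gene_hits(stats, gm, cfg)
                          if r.is_hit)
            slow = call_hits_brute_force(stats, gm, cfg)
            assert fast == slow

    def test_intersection_subset_of_union(self, rng):
        for _ in range(20):
            stats, gm = _random_stats(rng, rng.integers(3, 8, size=8),
                                      ["d4", "d6", "d8"])
            inter = {r.gene_id for r in call_gene_hits(
                stats, gm, HitCallConfig(combine_mode="intersection"))
                if r.is_hit}
            union = {r.gene_id for r in call_gene_hits(
                stats, gm, HitCallConfig(combine_mode="union")) if r.is_hit}
            assert inter <= union

    def test_tightening_thresholds_never_adds_hits(self, rng):
        stats, gm = _random_stats(rng, rng.integers(3, 8, size=10),
                                  ["d4", "d6"])
        base = {r.gene_id for r in call_gene_hits(
            stats, gm, HitCallConfig()) if r.is_hit}
        higher_fold = {r.gene_id for r in call_gene_hits(
            stats, gm, HitCallConfig(fold_threshold=4.0)) if r.is_hit}
        lower_p = {r.gene_id for r in call_gene_hits(
            stats, gm, HitCallConfig(p_threshold=0.01)) if r.is_hit}
        assert higher_fold <= base
        assert lower_p <= base

    def test_unmapped_sgrna_listed(self):
        stats = {"d4": [SgRNAStat("orphan_sg0", "d4", 1.0, 0.0, 0.5)]}
        with pytest.raises(ValueError, match="orphan_sg0"):
            call_gene_hits(stats, pd.Series(dtype=object))


class TestCoverageCheck:
    def test_screen_design_values(self):
        # 40e6 cells over the 77,441-guide library
        assert coverage_check(40e6, 77441) == pytest.approx(516.5, abs=0.05)
        assert coverage_check(40e6, 77441) >= 500
        # 150e6 cells at 30% infection
        assert coverage_check(150e6, 77441, 0.30) == pytest.approx(581.1, abs=0.05)
        assert coverage_check(150e6, 77441, 0.30) >= 500

    def test_unit_representation(self):
        assert coverage_check(77441, 77441) == 1.0

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            coverage_check(1e6, 0)


class TestPlantedRecovery:
    def test_recovers_planted_genes_with_few_false_positives(self):
        cfg = ScreenSimConfig(seed=1)  # 1000 genes, 20 planted @ 8-fold
        table, truth = gen_screen_counts(cfg)
        rpm_normalize(table)
        hc = HitCallConfig()
        stats = {c: sgrna_enrichment(table, "DMSO", c, hc)
                 for c in cfg.conditions}
        hits = {r.gene_id for r in call_gene_hits(stats, table.gene_map, hc)
                if r.is_hit}
        planted = set(truth["planted_genes"])
        assert len(hits & planted) >= 18
        assert len(hits - planted) <= 2
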