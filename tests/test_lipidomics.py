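"""Annotation parsing, PUFA classification, normalization, differential
abundance and class ratios."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ferroscreen.lipidomics import (
    CHAIN_COUNTS,
    LipidAbundanceTable,
    LipidClassConfig,
    LipidSpecies,
    class_pufa_ratio,
    classify_pufa,
    differential_abundance,
    median_normalize,
    parse_annotation,
    pca_scores,
)
from ferroscreen.synthetic_data import LipidomeSimConfig, gen_lipidome


class TestParseAnnotation:
    def test_class_first(self):
        sp = parse_annotation("TAG C54:6")
        assert (sp.lipid_class, sp.n_carbons, sp.n_double_bonds,
                sp.n_chains) == ("TAG", 54, 6, 3)

    def test_composition_first(self):
        sp = parse_annotation("C38:4 PE")
        assert (sp.lipid_class, sp.n_carbons, sp.n_double_bonds,
                sp.n_chains) == ("PE", 38, 4, 2)

    def test_optional_c_prefix_and_case(self):
        assert parse_annotation("tag 54:6").canonical() == "TAG C54:6"

    def test_unknown_class_named_in_error(self):
        with pytest.raises(ValueError, match="XYZ"):
            parse_annotation("XYZ C10:0")

    def test_malformed_composition(self):
        with pytest.raises(ValueError):
            parse_annotation("PE C38.4")

    def test_round_trip_canonical(self):
        for text in ["TAG C54:6", "C38:4 PE", "ffa 20:4", "ePE C40:7"]:
            sp = parse_annotation(text)
            again = parse_annotation(sp.canonical())
            assert (again.lipid_class, again.n_carbons,
                    again.n_double_bonds) == (sp.lipid_class, sp.n_carbons,
                                              sp.n_double_bonds)


def _pufa_oracle(db: int, n_chains: int) -> bool:
    """Does every composition of db double bonds into n_chains chains
    force some chain to carry >= 2?"""
    compositions = [
        c for c in itertools.product(range(db + 1), repeat=n_chains)
        if sum(c) == db
    ]
    return all(max(c) >= 2 for c in compositions)


class TestClassifyPUFA:
    def test_named_examples(self):
        assert not classify_pufa(parse_annotation("TAG C50:1"))
        assert classify_pufa(parse_annotation("PE C38:4"))
        assert classify_pufa(parse_annotation("FFA C20:4"))  # arachidonic

    def test_matches_exhaustive_composition_oracle(self):
        for cls, n_chains in CHAIN_COUNTS.items():
            for db in range(13):
                sp = LipidSpecies(cls, 18 * n_chains, db)
                assert classify_pufa(sp) == _pufa_oracle(db, n_chains), \
                    f"{cls} DB={db}"

    def test_per_class_override(self):
        cfg = LipidClassConfig(pufa_min_db_override={"TAG": 6})
        assert not classify_pufa(LipidSpecies("TAG", 54, 5), cfg)
        assert classify_pufa(LipidSpecies("TAG", 54, 6), cfg)


def _table(values: dict, groups: dict, reference="WT"):
    species = [parse_annotation(a) for a in values]
    return LipidAbundanceTable(
        species=species,
        abundances=pd.DataFrame.from_dict(values, orient="index",
                                          columns=list(groups)),
        sample_groups=groups,
        reference_group=reference,
    )


class TestMedianNormalize:
    def test_direct_computation(self):
        values = {
            "PE C38:4": [1.0, 2.0],
            "PE C36:2": [2.0, 4.0],
            "PC C34:1": [3.0, 6.0],
        }
        groups = {"a": "WT", "b": "KO"}
        out = median_normalize(_table(values, groups))
        # medians 2 and 4, grand median 3 -> scales 1.5 and 0.75
        assert out.abundances["a"].tolist() == pytest.approx([1.5, 3.0, 4.5])
        assert out.abundances["b"].tolist() == pytest.approx([1.5, 3.0, 4.5])
        assert out.abundances.median(axis=0).tolist() == pytest.approx([3, 3])

    def test_equal_medians_identity(self):
        values = {"PE C38:4": [1.0, 1.0], "PC C34:1": [3.0, 3.0],
                  "SM C34:1": [5.0, 5.0]}
        t = _table(values, {"a": "WT", "b": "KO"})
        out = median_normalize(t)
        assert np.allclose(out.abundances, t.abundances)

    def test_per_sample_scale_invariance(self):
        values = {"PE C38:4": [1.0, 2.0], "PC C34:1": [3.0, 5.0],
                  "SM C34:1": [7.0, 11.0]}
        t = _table(values, {"a": "WT", "b": "KO"})
        scaled = _table(
            {k: [v[0] * 13.0, v[1]] for k, v in values.items()},
            {"a": "WT", "b": "KO"},
        )
        base = median_normalize(t).abundances.to_numpy()
        resc = median_normalize(scaled).abundances.to_numpy()
        # scaling a sample may move the grand-median target, so invariance
        # holds up to one global factor
        ratio = resc / base
        assert np.allclose(ratio, ratio.flat[0])

    def test_zero_median_sample_named(self):
        values = {"PE C38:4": [1.0, 0.0], "PC C34:1": [3.0, 0.0],
                  "SM C34:1": [5.0, 0.0]}
        with pytest.raises(ValueError, match="b"):
            median_normalize(_table(values, {"a": "WT", "b": "KO"}))


class TestDifferentialAbundance:
    def _two_group_table(self, wt, ko, annotations):
        samples = {f"WT_{i}": "WT" for i in range(len(wt[0]))}
        samples.update({f"KO_{i}": "KO" for i in range(len(ko[0]))})
        data = np.hstack([np.asarray(wt, float), np.asarray(ko, float)])
        return LipidAbundanceTable(
            species=[parse_annotation(a) for a in annotations],
            abundances=pd.DataFrame(data, index=annotations,
                                    columns=list(samples)),
            sample_groups=samples,
            reference_group="WT",
        )

    def test_identical_groups_null(self):
        wt = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        t = self._two_group_table(wt, wt, ["PE C38:4", "PC C34:1"])
        for rec in differential_abundance(t):
            assert rec.log2fc == 0.0
            assert rec.p_value == 1.0

    def test_noiseless_planted_depletion_exact(self):
        table, truth = gen_lipidome(LipidomeSimConfig(
            pufa_depletion_log2fc=-1.0, noise_sd=0.0, seed=0))
        recs = differential_abundance(table)
        planted = set(truth[truth.pufa].annotation)
        for rec in recs:
            expected = -1.0 if rec.species.annotation in planted else 0.0
            assert rec.log2fc == pytest.approx(expected, abs=1e-9)

    def test_antisymmetric_under_group_swap(self):
        wt = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        ko = [[2.0, 3.0, 5.0], [1.0, 2.0, 2.0]]
        ann = ["PE C38:4", "PC C34:1"]
        fwd = differential_abundance(self._two_group_table(wt, ko, ann))
        swapped = self._two_group_table(ko, wt, ann)
        rev = differential_abundance(swapped)
        for f, r in zip(fwd, rev):
            assert f.log2fc == pytest.approx(-r.log2fc)

    def test_adj_p_never_below_p(self):
        table, _ = gen_lipidome(LipidomeSimConfig(seed=3))
        for rec in differential_abundance(table):
            if not rec.not_detected:
                assert rec.adj_p >= rec.p_value - 1e-15

    def test_undetected_species_flagged_not_tested(self):
        wt = [[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]]
        ko = [[1.0, 2.0, 3.0], [1.0, 1.0, 1.0]]
        t = self._two_group_table(wt, ko, ["PE C38:4", "PC C34:1"])
        recs = differential_abundance(t)
        nd = [r for r in recs if r.not_detected]
        assert [r.species.annotation for r in nd] == ["PC C34:1"]
        assert np.isnan(nd[0].p_value)

    def test_planted_depletion_recovery(self):
        """Default two-group lipidome: >90% of planted PUFA species at
        BH-adjusted p < 0.05 with the correct sign."""
        table, truth = gen_lipidome(LipidomeSimConfig(seed=7))
        recs = differential_abundance(median_normalize(table))
        planted = set(truth[truth.pufa].annotation)
        detected = [r for r in recs
                    if r.species.annotation in planted and r.adj_p < 0.05]
        assert len(detected) / len(planted) > 0.90
        assert all(r.log2fc < 0 for r in detected)


class TestClassPufaRatio:
    def test_direct_ratio(self):
        values = {
            "PE C38:4": [30.0, 10.0],   # PUFA (DB 4 >= 3)
            "PE C36:2": [90.0, 90.0],   # not PUFA
        }
        t = _table(values, {"a": "WT", "b": "KO"})
        ratios = class_pufa_ratio(t, {"PE"})
        assert ratios["a"] == pytest.approx(0.25)
        assert ratios["b"] == pytest.approx(0.10)

    def test_zero_pufa_species(self):
        values = {"PE C36:2": [5.0, 5.0], "PE C34:1": [5.0, 5.0],
                  "PC C34:1": [5.0, 5.0]}
        t = _table(values, {"a": "WT", "b": "KO"})
        assert class_pufa_ratio(t, {"PE"}).tolist() == [0.0, 0.0]

    def test_invariant_under_median_normalize(self):
        table, _ = gen_lipidome(LipidomeSimConfig(seed=11))
        before = class_pufa_ratio(table, {"PE", "ePE"})
        after = class_pufa_ratio(median_normalize(table), {"PE", "ePE"})
        assert np.allclose(before, after)

    def test_empty_selection_rejected(self):
        table, _ = gen_lipidome(LipidomeSimConfig(seed=0))
        with pytest.raises(ValueError):
            class_pufa_ratio(table, set())


class TestPCAScores:
    def test_single_varying_feature_dominates(self):
        X = pd.DataFrame({"f1": [0.0, 1.0, 2.0, 3.0], "f2": [1.0] * 4})
        scores, var = pca_scores(X, center="mean")
        assert var[0] == pytest.approx(1.0)

    def test_svd_reconstruction_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 8)))
        Xc = X - X.median(axis=0)
        scores, var = pca_scores(X)
        U, s, Vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
        recon = (U * s) @ Vt
        assert np.allclose(recon, Xc.to_numpy(), atol=1e-8)
        assert var.sum() == pytest.approx(1.0)

    def test_duplicated_samples_coincide(self, rng):
        row = rng.normal(size=6)
        X = pd.DataFrame(np.vstack([row, row, rng.normal(size=6)]))
        scores, _ = pca_scores(X)
        assert np.allclose(scores.iloc[0], scores.iloc[1])

    def test_degenerate_matrix_rejected(self):
        X = pd.DataFrame(np.ones((3, 3)))
        with pytest.raises(ValueError):
            pca_scores(X)
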