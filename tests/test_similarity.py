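"""Similarity-score core: z-normalization, references, gene/composite scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnamonitor import (
    ExpressionMatrix,
    SimilarityScorer,
    composite_scores,
    compute_cpm,
    filter_genes,
    gene_scores,
    interpret_score,
    reference_profiles,
    zscore_normalize,
)
from rnamonitor.similarity import ReferenceProfiles, ZScoreMatrix
from tests.conftest import make_meta


def cpm_matrix(values: pd.DataFrame, groups) -> ExpressionMatrix:
    return ExpressionMatrix(values, "cpm",
                            sample_meta=make_meta(list(values.columns), groups))


class TestZScore:
    def test_closed_form_three_samples(self):
        vals = pd.DataFrame({"s1": [10.0], "s2": [20.0], "s3": [30.0]}, index=["g"])
        z = zscore_normalize(cpm_matrix(vals, ["baseline", "control", "treated"]))
        # sample sd (n-1) of (10,20,30) is 10
        assert z.z.loc["g"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert z.norm_stats.loc["g", "mu"] == pytest.approx(20.0)
        assert z.norm_stats.loc["g", "sigma"] == pytest.approx(10.0)

    def test_constant_gene_dropped(self):
        vals = pd.DataFrame({"s1": [5.0, 1.0], "s2": [5.0, 2.0], "s3": [5.0, 3.0]},
                            index=["flat", "varies"])
        z = zscore_normalize(cpm_matrix(vals, ["baseline", "control", "treated"]))
        assert list(z.z.index) == ["varies"]

    def test_per_gene_mean_zero_sd_one(self, small_cohort):
        cm, _ = small_cohort
        cpm = compute_cpm(filter_genes(cm))
        z = zscore_normalize(cpm)
        assert np.abs(z.z.mean(axis=1)).max() < 1e-10
        assert np.abs(z.z.std(axis=1, ddof=1) - 1).max() < 1e-10

    def test_population_sd_option(self):
        vals = pd.DataFrame({"s1": [10.0], "s2": [20.0], "s3": [30.0]}, index=["g"])
        z = zscore_normalize(cpm_matrix(vals, ["baseline"] * 3), ddof=0)
        sd_pop = np.sqrt(200.0 / 3)
        assert z.z.loc["g", "s1"] == pytest.approx(-10.0 / sd_pop)

    def test_single_sample_rejected(self):
        vals = pd.DataFrame({"s1": [10.0]}, index=["g"])
        with pytest.raises(ValueError, match="2 samples"):
            zscore_normalize(cpm_matrix(vals, ["baseline"]))


class TestReferenceProfiles:
    def _z(self, data, groups):
        vals = pd.DataFrame(data)
        stats = pd.DataFrame({"mu": 0.0, "sigma": 1.0}, index=vals.index)
        return (ZScoreMatrix(vals, stats),
                make_meta(list(vals.columns), groups))

    def test_single_baseline_sample_is_its_own_mean(self):
        z, meta = self._z({"b1": [0.5, -1.0], "c1": [1.0, 1.0], "c2": [0.0, 0.0]},
                          ["baseline", "control", "control"])
        refs = reference_profiles(z, meta)
        assert refs.z_baseline.tolist() == [0.5, -1.0]
        assert refs.z_control.tolist() == [0.5, 0.5]

    def test_swapping_labels_swaps_profiles(self):
        z, meta = self._z({"x": [1.0], "y": [-1.0]}, ["baseline", "control"])
        swapped = meta.copy()
        swapped["group"] = ["control", "baseline"]
        a = reference_profiles(z, meta)
        b = reference_profiles(z, swapped)
        assert a.z_baseline.tolist() == b.z_control.tolist()
        assert a.z_control.tolist() == b.z_baseline.tolist()

    def test_zero_separation_when_means_coincide(self):
        z, meta = self._z({"b1": [2.0], "c1": [2.0]}, ["baseline", "control"])
        refs = reference_profiles(z, meta)
        assert refs.separation.iloc[0] == 0.0

    def test_empty_reference_group_rejected(self):
        z, meta = self._z({"b1": [1.0], "b2": [2.0]}, ["baseline", "baseline"])
        with pytest.raises(ValueError, match="control"):
            reference_profiles(z, meta)


def refs_from_series(z_baseline, z_control) -> ReferenceProfiles:
    return ReferenceProfiles(z_baseline=pd.Series(z_baseline),
                             z_control=pd.Series(z_control),
                             baseline_ids=["b"], control_ids=["c"])


class TestGeneScores:
    def _score_single(self, z_s, z_b, z_c):
        vals = pd.DataFrame({"s": [z_s]})
        stats = pd.DataFrame({"mu": [0.0], "sigma": [1.0]})
        refs = refs_from_series([z_b], [z_c])
        return gene_scores(ZScoreMatrix(vals, stats), refs, ["s"]).iloc[0, 0]

    def test_sample_at_control_profile(self):
        assert self._score_single(1.0, -1.0, 1.0) == pytest.approx(2.0)

    def test_equidistant_midpoint(self):
        assert self._score_single(0.0, -1.0, 1.0) == pytest.approx(0.0)

    def test_sample_at_baseline_profile(self):
        assert self._score_single(-1.0, -1.0, 1.0) == pytest.approx(-2.0)

    def test_unknown_sample_rejected(self):
        vals = pd.DataFrame({"s": [0.0]})
        stats = pd.DataFrame({"mu": [0.0], "sigma": [1.0]})
        refs = refs_from_series([0.0], [1.0])
        with pytest.raises(KeyError, match="nope"):
            gene_scores(ZScoreMatrix(vals, stats), refs, ["nope"])


class TestCompositeAndInterpretation:
    def test_arithmetic_mean_of_gene_scores(self):
        scores = pd.DataFrame({"s": [2.0, 0.0]}, index=["g1", "g2"])
        assert composite_scores(scores)["s"] == pytest.approx(1.0)

    def test_endpoint_composites_equal_mean_separation(self):
        rng = np.random.default_rng(3)
        zb = rng.normal(-1, 0.3, 5)
        zc = rng.normal(1, 0.3, 5)
        refs = refs_from_series(zb, zc)
        vals = pd.DataFrame({"at_control": zc, "at_baseline": zb})
        stats = pd.DataFrame({"mu": 0.0, "sigma": 1.0}, index=vals.index)
        gs = gene_scores(ZScoreMatrix(vals, stats), refs,
                         ["at_control", "at_baseline"])
        comp = composite_scores(gs)
        dbar = refs.mean_separation
        assert comp["at_control"] == pytest.approx(dbar)
        assert comp["at_baseline"] == pytest.approx(-dbar)

    def test_empty_gene_set_rejected(self):
        scores = pd.DataFrame({"s": [1.0]}, index=["g"])
        with pytest.raises((ValueError, KeyError)):
            composite_scores(scores, gene_set=[])

    def test_interpretation_bands(self):
        refs = refs_from_series([-1.0, -1.0], [1.0, 1.0])  # Dbar = 2
        assert interpret_score(2.0, refs) == "control_like"
        assert interpret_score(0.0, refs) == "intermediate"
        assert interpret_score(-2.0, refs) == "baseline_like"
        assert interpret_score(0.19, refs) == "intermediate"  # eps = 0.2
        assert interpret_score(0.21, refs) == "control_like"

    def test_degenerate_references_rejected(self):
        refs = refs_from_series([0.5], [0.5])
        with pytest.raises(ValueError, match="degenerate"):
            interpret_score(0.0, refs)


class TestPipelineOracle:
    def test_hand_computed_three_gene_table(self):
        """Composite for 3 genes x 4 samples checked against plain loops."""
        cpm = pd.DataFrame(
            {
                "b1": [100.0, 10.0, 50.0],
                "b2": [120.0, 14.0, 55.0],
                "c1": [40.0, 30.0, 52.0],
                "t1": [60.0, 25.0, 53.0],
            },
            index=["g1", "g2", "g3"],
        )
        groups = ["baseline", "baseline", "control", "treated"]
        em = cpm_matrix(cpm, groups)
        z = zscore_normalize(em)
        refs = reference_profiles(z, em.sample_meta)
        comp = composite_scores(gene_scores(z, refs, list(cpm.columns)))

        # independent brute-force path
        for g in cpm.index:
            row = cpm.loc[g]
            mu, sd = row.mean(), row.std(ddof=1)
            zrow = (row - mu) / sd
            zb = (zrow["b1"] + zrow["b2"]) / 2
            zc = zrow["c1"]
            for s in cpm.columns:
                expected = abs(zrow[s] - zb) - abs(zrow[s] - zc)
                got = gene_scores(z, refs, [s]).loc[g, s]
                assert got == pytest.approx(expected, abs=1e-12)
        brute_comp = {
            s: np.mean([
                abs(((cpm.loc[g, s] - cpm.loc[g].mean()) / cpm.loc[g].std(ddof=1))
                    - np.mean([(cpm.loc[g, b] - cpm.loc[g].mean()) / cpm.loc[g].std(ddof=1)
                               for b in ["b1", "b2"]]))
                - abs(((cpm.loc[g, s] - cpm.loc[g].mean()) / cpm.loc[g].std(ddof=1))
                      - ((cpm.loc[g, "c1"] - cpm.loc[g].mean()) / cpm.loc[g].std(ddof=1)))
                for g in cpm.index
            ])
            for s in cpm.columns
        }
        for s in cpm.columns:
            assert comp[s] == pytest.approx(brute_comp[s], abs=1e-12)


class TestScorerProperties:
    def test_boundedness_on_synthetic_cohort(self, small_cohort):
        cm, truth = small_cohort
        cpm = compute_cpm(filter_genes(cm))
        genes = [g for g in truth.signature_genes() if g in cpm.values.index]
        scorer = SimilarityScorer(gene_set=genes).fit(
            cpm.values.T, cm.sample_meta.loc[list(cpm.values.columns), "group"])
        res = scorer.score_samples()
        dbar = res.mean_separation
        assert (res.composite.abs() <= dbar + 1e-10).all()

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
    def test_affine_invariance_of_scores(self, scale, shift):
        """A per-gene positive affine transform of CPM leaves scores unchanged
        because z-scores are affine-invariant."""
        rng = np.random.default_rng(17)
        cpm = pd.DataFrame(rng.uniform(5, 500, size=(6, 5)),
                           index=[f"g{i}" for i in range(6)],
                           columns=["b1", "b2", "c1", "c2", "t1"])
        groups = ["baseline", "baseline", "control", "control", "treated"]

        def run(values):
            em = cpm_matrix(values, groups)
            z = zscore_normalize(em)
            refs = reference_profiles(z, em.sample_meta)
            return gene_scores(z, refs, ["t1"])

        a = run(cpm)
        b = run(cpm * scale + shift * scale + 1.0)  # positive affine map
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_noiseless_linear_interpolation_identity(self):
        """Profiles interpolated linearly between the references score exactly
        (2*alpha - 1) * D_g per gene."""
        rng = np.random.default_rng(23)
        n_genes = 8
        base = rng.uniform(50, 150, n_genes)
        ctrl = rng.uniform(200, 400, n_genes)
        alphas = {"a00": 0.0, "a25": 0.25, "a50": 0.5, "a75": 0.75, "a100": 1.0}
        cols = {}
        for i in range(2):
            cols[f"b{i}"] = base
        for i in range(2):
            cols[f"c{i}"] = ctrl
        for name, a in alphas.items():
            cols[name] = (1 - a) * base + a * ctrl
        cpm = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
        groups = (["baseline"] * 2 + ["control"] * 2 + ["treated"] * len(alphas))
        em = cpm_matrix(cpm, groups)
        z = zscore_normalize(em)
        refs = reference_profiles(z, em.sample_meta)
        gs = gene_scores(z, refs, list(alphas))
        for name, a in alphas.items():
            expected = (2 * a - 1) * refs.separation
            assert np.allclose(gs[name], expected, atol=1e-10)
        comp = composite_scores(gs)
        assert (comp[list(alphas)].diff().dropna() > 0).all()
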