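import numpy as np
import pandas as pd
import pytest

from respnet.errors import ValidationError
from respnet.expression import (CountMatrix, CpmMatrix, build_tissue_interactome,
                                call_expressed, prefilter_counts, tmm_normalize)
from respnet.interactome import EdgeType, Interaction, Kind, Molecule
from respnet.synth import make_counts

from conftest import G, M, P, build_net, ppi, tfdna
from oracles import tmm_factors_oracle


def counts_of(matrix, samples=None, tissue="t"):
    matrix = np.asarray(matrix)
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, index=[f"g{i}" for i in range(matrix.shape[0])],
                      columns=samples)
    return CountMatrix(counts=df, tissue_of={s: tissue for s in samples})


def cpm_of(matrix, tissue="t"):
    matrix = np.asarray(matrix, dtype=float)
    samples = [f"s{j}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, index=[f"g{i}" for i in range(matrix.shape[0])],
                      columns=samples)
    return CpmMatrix(cpm=df, norm_factors=pd.Series(1.0, index=samples),
                     tissue_of={s: tissue for s in samples})


class TestCountMatrix:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            counts_of([[-1, 2]])

    def test_unlabeled_sample_rejected(self):
        df = pd.DataFrame([[1, 2]], index=["g0"], columns=["s0", "s1"])
        with pytest.raises(ValidationError):
            CountMatrix(counts=df, tissue_of={"s0": "t"})


class TestPrefilter:
    def test_count_six_in_ten_of_twelve_kept(self):
        row = [6] * 10 + [0, 0]
        cm = prefilter_counts(counts_of([row]))
        assert cm.genes == ["g0"]

    def test_count_five_everywhere_dropped(self):
        # 5 is not "more than five"
        cm = prefilter_counts(counts_of([[5] * 12]))
        assert cm.genes == []

    def test_all_zero_matrix(self):
        cm = prefilter_counts(counts_of(np.zeros((4, 12), dtype=int)))
        assert cm.genes == []

    def test_min_samples_above_sample_count_warns_empty(self, caplog):
        cm = prefilter_counts(counts_of([[100, 100]]), min_samples=10)
        assert cm.genes == []


class TestTMM:
    def test_identical_samples_all_factors_one(self, rng):
        col = rng.integers(1, 500, size=40)
        cm = counts_of(np.column_stack([col] * 4))
        res = tmm_normalize(cm)
        assert np.allclose(res.norm_factors, 1.0)
        for j in range(1, 4):
            assert np.allclose(res.cpm.iloc[:, 0], res.cpm.iloc[:, j])

    def test_doubled_library_absorbed(self, rng):
        # doubling is pure library size: factors 1, cpm identical
        col = rng.integers(1, 500, size=20)
        cm = counts_of(np.column_stack([col, col * 2]))
        res = tmm_normalize(cm)
        assert np.allclose(res.norm_factors, 1.0, atol=1e-12)
        assert np.allclose(res.cpm.iloc[:, 0], res.cpm.iloc[:, 1])

    def test_spiked_sample_factor_below_one_matches_oracle(self, rng):
        # one 10-fold spiked gene inflates sample 3's library; the trimmed,
        # weighted mean of M-values yields a factor < 1 for that sample
        # (standard TMM composition correction), matching the independent
        # oracle exactly.
        mu = rng.integers(50, 500, size=50).astype(float)
        X = rng.poisson(mu[:, None], size=(50, 3)).astype(int)
        X[0, 2] *= 10
        res = tmm_normalize(counts_of(X))
        expected = tmm_factors_oracle(X.astype(float))
        assert np.allclose(res.norm_factors.to_numpy(), expected, atol=1e-9)
        assert res.norm_factors.iloc[2] < 1.0

    def test_oracle_agreement_random(self, rng):
        for _ in range(5):
            X = rng.integers(0, 400, size=(50, 4))
            res = tmm_normalize(counts_of(X))
            assert np.allclose(res.norm_factors.to_numpy(),
                               tmm_factors_oracle(X.astype(float)), atol=1e-9)

    def test_scale_invariance_exact_on_identical_composition(self, rng):
        # pure depth change of a sample with the same composition: every
        # M-value is constant, so the weighted trimmed mean is weight-free
        # and the factor (hence cpm) is exactly invariant
        col = rng.integers(1, 500, size=60)
        X = np.column_stack([col, col, col * 3])
        base = tmm_normalize(counts_of(X)).cpm.to_numpy()
        Y = X.copy()
        Y[:, 2] *= 7
        scaled = tmm_normalize(counts_of(Y)).cpm.to_numpy()
        assert np.allclose(base, scaled, rtol=1e-12)

    def test_scale_invariance_approximate_in_general(self, rng):
        # with heterogeneous composition the inverse-variance weights depend
        # on sequencing depth, so invariance is only approximate (edgeR
        # behaves identically: ~1e-4..1e-3 relative on realistic data)
        mu = rng.integers(20, 500, size=60).astype(float)
        X = rng.poisson(mu[:, None] * np.array([1.0, 1.3, 0.8, 1.1]),
                        size=(60, 4)).astype(int)
        base = tmm_normalize(counts_of(X)).cpm.to_numpy()
        Y = X.copy()
        Y[:, 2] *= 7
        scaled = tmm_normalize(counts_of(Y)).cpm.to_numpy()
        assert np.allclose(base, scaled, rtol=5e-3)

    def test_cpm_invariant_and_geometric_mean(self, rng):
        X = rng.integers(0, 300, size=(50, 6))
        cm = counts_of(X)
        res = tmm_normalize(cm)
        assert abs(np.exp(np.mean(np.log(res.norm_factors))) - 1.0) < 1e-9
        lib = X.sum(axis=0)
        manual = X / (lib * res.norm_factors.to_numpy())[None, :] * 1e6
        assert np.allclose(res.cpm.to_numpy(), manual)

    def test_needs_two_samples(self):
        with pytest.raises(ValidationError):
            tmm_normalize(counts_of([[5], [3]]))

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            tmm_normalize(counts_of([[5, 0], [3, 0]]))


class TestCallExpressed:
    def test_boundary_exactly_at_thresholds(self):
        # cpm 8.0 in exactly 10 of 12 samples, median exactly 8 -> expressed
        row = [8.0] * 10 + [0.0, 0.0]
        row2 = [8.0] * 10 + [8.0, 8.0]
        call = call_expressed(cpm_of([row2, row]), "t")
        assert "g0" in call.expressed  # 12 passing samples, median 8
        # g1: 10 passing samples >= 10, median of sorted row = 8 -> expressed
        assert "g1" in call.expressed

    def test_fails_stage1_count(self):
        row = [100.0] * 9 + [0.0, 0.0, 0.0]
        call = call_expressed(cpm_of([row]), "t")
        assert "g0" not in call.expressed

    def test_eleven_samples_nine_passing_fails_stage1(self):
        # 9 samples at cpm 10 and 2 at 0: median 10 >= 8 but only 9 samples
        # pass stage 1, short of min_samples=10 -> not expressed
        row = [10.0] * 9 + [0.0, 0.0]
        call = call_expressed(cpm_of([row]), "t")
        assert "g0" not in call.expressed
        # relaxing min_samples to 9 flips the call (median oracle: 10 >= 8)
        call9 = call_expressed(cpm_of([row]), "t", min_samples=9)
        assert "g0" in call9.expressed

    def test_ten_passing_of_eleven_expressed(self):
        row = [10.0] * 10 + [0.0]
        call = call_expressed(cpm_of([row]), "t")
        assert "g0" in call.expressed
        assert call.threshold_config["cpm_threshold"] == 8.0

    def test_median_failure_blocks(self):
        # passes stage 1 but median below threshold
        row = [8.0] * 10 + [0.0] * 12
        call = call_expressed(cpm_of([row]), "t")
        assert "g0" not in call.expressed

    def test_log2_scale_mode(self):
        row = [300.0] * 12
        call = call_expressed(cpm_of([row]), "t", median_scale="log2cpm")
        assert "g0" in call.expressed  # log2(300) ~ 8.2 >= 8
        call2 = call_expressed(cpm_of([[200.0] * 12]), "t", median_scale="log2cpm")
        assert "g0" not in call2.expressed  # log2(200) ~ 7.6 < 8

    def test_unknown_tissue(self):
        with pytest.raises(KeyError):
            call_expressed(cpm_of([[8.0] * 12]), "nosuch")

    def test_monotonicity_in_thresholds(self, rng):
        X = rng.uniform(0, 30, size=(40, 15))
        cpmM = cpm_of(X)
        base = call_expressed(cpmM, "t").expressed
        assert call_expressed(cpmM, "t", cpm_threshold=12).expressed <= base
        assert call_expressed(cpmM, "t", min_samples=12).expressed <= base
        assert call_expressed(cpmM, "t", median_threshold=12).expressed <= base

    def test_stage1_scope_all_vs_tissue(self):
        # gene passes stage 1 only when counting the other tissue's samples
        df = pd.DataFrame([[10.0] * 6 + [10.0] * 6], index=["g0"],
                          columns=[f"s{j}" for j in range(12)])
        tissue_of = {f"s{j}": ("t1" if j < 6 else "t2") for j in range(12)}
        cpmM = CpmMatrix(cpm=df, norm_factors=pd.Series(1.0, index=df.columns),
                         tissue_of=tissue_of)
        assert "g0" not in call_expressed(cpmM, "t1").expressed
        assert "g0" in call_expressed(cpmM, "t1", stage1_scope="all").expressed


class TestBuildTissueInteractome:
    def _net(self):
        return build_net(
            ppi("P1", "P2", 0.5), ppi("P2", "P3", 0.6), tfdna("P2", "G1"),
            Interaction(P("P3"), M("miR-1"), EdgeType.TF_MIRNA, 1.0),
            Interaction(M("miR-1"), G("G2"), EdgeType.MIRNA_RNA, 1.0))

    def _call(self, expressed):
        from respnet.expression import ExpressionCall
        return ExpressionCall(tissue="t", expressed=frozenset(expressed))

    def test_all_expressed_is_identity(self):
        net = self._net()
        tnet = build_tissue_interactome(net, self._call(
            ["P1", "P2", "P3", "G1", "G2", "miR-1"]))
        assert {e.key for e in tnet.edges} == {e.key for e in net.edges}

    def test_ppi_with_unexpressed_mate_removed(self):
        tnet = build_tissue_interactome(self._net(), self._call(["P1", "P2", "P3"]))
        keys = {e.key for e in tnet.edges}
        assert (("P1", "PROTEIN"), ("P2", "PROTEIN"), "PPI") in keys
        tnet2 = build_tissue_interactome(self._net(), self._call(["P1", "P3"]))
        assert (("P1", "PROTEIN"), ("P2", "PROTEIN"), "PPI") not in \
            {e.key for e in tnet2.edges}

    def test_mirna_edges_never_filtered(self):
        tnet = build_tissue_interactome(self._net(), self._call(["P1"]))
        etypes = {e.etype for e in tnet.edges}
        assert EdgeType.TF_MIRNA in etypes and EdgeType.MIRNA_RNA in etypes

    def test_tf_dna_kept_by_default_dropped_with_filter_tf(self):
        call = self._call(["P1"])
        assert any(e.etype is EdgeType.TF_DNA
                   for e in build_tissue_interactome(self._net(), call).edges)
        strict = build_tissue_interactome(self._net(), call, filter_tf=True)
        assert not any(e.etype is EdgeType.TF_DNA for e in strict.edges)

    def test_edges_subset_and_endpoints_expressed(self, rng):
        cm, truth = make_counts(genes=80, tissues=["t1"], seed=5)
        cpmM = tmm_normalize(prefilter_counts(cm))
        call = call_expressed(cpmM, "t1")
        ids = sorted(truth.expressed_truth["t1"])[:20] + ["PX1", "PX2"]
        net = build_net(*[ppi(a, b, 0.5) for a, b in zip(ids[:-1], ids[1:])])
        tnet = build_tissue_interactome(net, call)
        assert {e.key for e in tnet.edges} <= {e.key for e in net.edges}
        for e in tnet.edges:  # exhaustive endpoint scan
            if e.etype is EdgeType.PPI:
                assert e.a.id in call.expressed and e.b.id in call.expressed

    def test_empty_expressed_leaves_regulatory_only(self, caplog):
        tnet = build_tissue_interactome(self._net(), self._call([]))
        assert all(e.etype is not EdgeType.PPI for e in tnet.edges)

    def test_orphan_nodes_dropped(self):
        tnet = build_tissue_interactome(self._net(), self._call(["P1", "P2"]))
        used = {e.a.key for e in tnet.edges} | {e.b.key for e in tnet.edges}
        assert {m.key for m in tnet.nodes} == used


def test_planted_recovery_exact():
    # high-abundance planted set vs near-zero complement: exact recovery
    cm, truth = make_counts(genes=150, tissues=["t1"], samples_per_tissue=12,
                            mean_expressed_cpm=80.0, mean_silent_cpm=0.05,
                            dispersion=0.05, seed=11)
    cpmM = tmm_normalize(cm)
    call = call_expressed(cpmM, "t1")
    assert call.expressed == truth.expressed_truth["t1"]
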