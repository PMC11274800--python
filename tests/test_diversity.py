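"""Fingerprint, scaffold and property diversity statistics."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

import libprof as lp
from libprof.diversity import (
    FingerprintKind,
    Representation,
    Scaling,
    fingerprint_matrix,
    property_matrix,
)


class TestFingerprint:
    def test_maccs_is_166_bits(self):
        assert lp.fingerprint("CCO", "MACCS166").shape == (166,)

    @pytest.mark.parametrize("kind,nbits", [("ECFP4_1024", 1024), ("ECFP4_2048", 2048)])
    def test_ecfp_width(self, kind, nbits):
        assert lp.fingerprint("CCO", kind).shape == (nbits,)

    def test_atom_order_invariance(self):
        mol = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
        renum = Chem.RenumberAtoms(mol, list(reversed(range(mol.GetNumAtoms()))))
        a = lp.fingerprint(mol, "ECFP4_1024")
        b = lp.fingerprint(Chem.MolToSmiles(renum, canonical=False), "ECFP4_1024")
        assert np.array_equal(a, b)

    def test_different_molecules_differ(self):
        assert not np.array_equal(
            lp.fingerprint("C", "ECFP4_1024"), lp.fingerprint("CC", "ECFP4_1024")
        )

    def test_unknown_kind_is_error(self):
        with pytest.raises(ValueError):
            lp.fingerprint("CCO", "FP3")


class TestTanimoto:
    def test_identical_nonzero(self):
        a = np.array([1, 0, 1, 1], dtype=bool)
        assert lp.tanimoto(a, a) == 1.0

    def test_disjoint(self):
        a = np.array([1, 1, 0, 0], dtype=bool)
        b = np.array([0, 0, 1, 1], dtype=bool)
        assert lp.tanimoto(a, b) == 0.0

    def test_brute_force_bit_counting(self):
        # set bits {1,2,3} vs {2,3,4}: |intersection|=2, |union|=4
        a = np.zeros(8, dtype=bool); a[[1, 2, 3]] = True
        b = np.zeros(8, dtype=bool); b[[2, 3, 4]] = True
        assert lp.tanimoto(a, b) == 0.5

    def test_all_zero_defined_as_identical(self):
        z = np.zeros(16, dtype=bool)
        assert lp.tanimoto(z, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            lp.tanimoto(np.zeros(4, dtype=bool), np.zeros(5, dtype=bool))


class TestPairwiseStats:
    def test_three_copies_of_one_molecule(self):
        stats = lp.pairwise_similarity_stats(["CCO", "OCC", "CCO"])
        assert stats.median == stats.mean == 1.0

    def test_fewer_than_two_is_error(self):
        with pytest.raises(ValueError):
            lp.pairwise_similarity_stats(["CCO"])

    def test_cdf_monotone_ends_at_one(self, synthetic_library_50):
        records, _ = synthetic_library_50
        stats = lp.pairwise_similarity_stats(
            [r.canonical_smiles for r in records][:30], "MACCS166"
        )
        fracs = [f for _, f in stats.cdf]
        assert fracs == sorted(fracs)
        assert fracs[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["MACCS166", "ECFP4_1024"])
    def test_streaming_equals_dense_matrix_oracle(self, kind, synthetic_library_50):
        records, _ = synthetic_library_50
        smiles = [r.canonical_smiles for r in records]
        stats = lp.pairwise_similarity_stats(smiles, kind)
        # dense oracle: full similarity matrix, off-diagonal upper triangle
        fps = fingerprint_matrix(smiles, FingerprintKind(kind))
        n = len(smiles)
        dense = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                dense[i, j] = lp.tanimoto(fps[i], fps[j])
        tri = dense[np.triu_indices(n, k=1)]
        assert stats.median == pytest.approx(np.median(tri), abs=1e-12)
        assert stats.mean == pytest.approx(tri.mean(), abs=1e-12)
        assert stats.n == n

    def test_row_order_invariance(self, synthetic_library_50):
        records, _ = synthetic_library_50
        smiles = [r.canonical_smiles for r in records][:25]
        rng = np.random.default_rng(4)
        shuffled = [smiles[i] for i in rng.permutation(len(smiles))]
        assert lp.pairwise_similarity_stats(smiles).median == pytest.approx(
            lp.pairwise_similarity_stats(shuffled).median
        )


class TestScaffold:
    def test_toluene_reduces_to_benzene(self):
        assert lp.bm_scaffold("Cc1ccccc1") == "c1ccccc1"

    def test_hexane_is_acyclic(self):
        assert lp.bm_scaffold("CCCCCC") == lp.ACYCLIC

    def test_anilide_homologs_share_scaffold(self):
        # manual Bemis-Murcko pruning: both reduce to N-phenyl amide core
        assert lp.bm_scaffold("CC(=O)Nc1ccccc1") == lp.bm_scaffold(
            "CCC(=O)Nc1ccccc1"
        )


class TestScaffoldProfile:
    def test_hand_computed_oracle(self):
        # counts [4,2,2,1,1] over 10 molecules:
        # CSR (0,0),(.2,.4),(.4,.6),(.6,.8),(.8,.9),(1,1)
        # trapezoid AUC = .04+.10+.14+.17+.19 = 0.64; F50 = 2/5
        # SSE_5 = -(.4ln.4+.2ln.2*2+.1ln.1*2)/ln5 = 0.913864688...
        profile = lp.profile_from_counts(
            Counter({"a": 4, "b": 2, "c": 2, "d": 1, "e": 1}), sse_top_n=5
        )
        assert profile.auc == pytest.approx(0.64, abs=1e-12)
        assert profile.f50 == pytest.approx(0.4, abs=1e-12)
        assert profile.sse_n == pytest.approx(0.9138646883853216, abs=1e-12)
        assert profile.M == 10 and profile.N == 5
        assert profile.nm_ratio == pytest.approx(0.5)

    def test_all_unique_is_maximum_diversity(self):
        profile = lp.profile_from_counts(Counter({c: 1 for c in "abcdefghij"}))
        assert profile.auc == pytest.approx(0.5, abs=1e-12)
        assert profile.f50 == pytest.approx(0.5, abs=1e-12)
        assert profile.nm_ratio == 1.0

    def test_sse_limits(self):
        assert lp.scaled_shannon_entropy([3, 3, 3, 3], 4) == 1.0
        assert lp.scaled_shannon_entropy([10], 10) == 0.0
        # log-base invariance: value unchanged if computed in base 10
        counts = [5, 3, 2]
        h10 = -sum(
            p * np.log10(p) for p in np.array(counts) / sum(counts)
        ) / np.log10(3)
        assert lp.scaled_shannon_entropy(counts, 3) == pytest.approx(h10)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=20))
    def test_invariants_on_random_counts(self, counts):
        profile = lp.profile_from_counts(
            Counter({f"s{i}": c for i, c in enumerate(counts)})
        )
        assert 0.5 <= profile.auc <= 1.0
        assert 0.0 < profile.f50 <= 1.0
        assert 0.0 <= profile.sse_n <= 1.0
        assert profile.csr[0] == (0.0, 0.0)
        assert profile.csr[-1] == (1.0, 1.0)
        assert profile.f50 >= 1.0 / profile.N

    def test_concentrating_counts_raises_auc(self):
        # moving a molecule from a minor to the dominant chemotype at
        # fixed N concentrates the distribution and raises the AUC
        before = lp.profile_from_counts(Counter({"a": 4, "b": 3, "c": 3}))
        after = lp.profile_from_counts(Counter({"a": 6, "b": 3, "c": 1}))
        assert after.auc > before.auc

    def test_acyclic_pooled_as_chemotype_and_reported(self):
        mols = ["Cc1ccccc1", "CCc1ccccc1", "CCCCCC", "CCCCC"]
        with_acyclic = lp.scaffold_profile(mols)
        assert with_acyclic.N == 2
        assert with_acyclic.acyclic_fraction == 0.5
        without = lp.scaffold_profile(mols, include_acyclic=False)
        assert without.N == 1 and without.M == 2
        assert without.acyclic_fraction == 0.5

    def test_generated_library_counts_recovered(self, synthetic_library_50):
        records, truth = synthetic_library_50
        profile = lp.scaffold_profile([r.canonical_smiles for r in records])
        expected = Counter(truth["chemotype"])
        assert profile.counts == dict(expected)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            lp.scaffold_profile([])


class TestScaffoldOverlap:
    def test_identical_datasets(self):
        p = lp.scaffold_profile(["Cc1ccccc1", "Cc1ccncc1"])
        shared, ua, ub = lp.scaffold_overlap(p, p)
        assert ua == ub == set()
        assert shared == set(p.counts)

    def test_partition_identity_excludes_acyclic(self):
        a = lp.scaffold_profile(["Cc1ccccc1", "Cc1ccncc1", "CCCC"])
        b = lp.scaffold_profile(["Cc1ccccc1", "C1CCCCC1"])
        shared, ua, ub = lp.scaffold_overlap(a, b)
        assert len(shared) + len(ua) == a.N - 1  # ACYCLIC not a scaffold
        assert shared == {"c1ccccc1"}


class TestPropertyDistance:
    def test_duplicates_have_zero_distance(self):
        assert lp.property_distance(["CCO", "CCO", "OCC"]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_single_axis_case(self):
        # two molecules differing in several properties; with MINMAX each
        # differing column spans exactly 1 scaled unit
        d = lp.property_distance(["CCO", "CCCO"], scaling="MINMAX")
        x = property_matrix(["CCO", "CCCO"])
        differing = (x[0] != x[1]).sum()
        assert d == pytest.approx(np.sqrt(differing))

    def test_matches_dense_oracle(self, synthetic_library_50):
        records, _ = synthetic_library_50
        smiles = [r.canonical_smiles for r in records][:20]
        d = lp.property_distance(smiles, "ZSCORE")
        x = property_matrix(smiles)
        mu, sd = x.mean(axis=0), x.std(axis=0)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
        dists = [
            np.linalg.norm(z[i] - z[j])
            for i in range(len(z)) for j in range(i + 1, len(z))
        ]
        assert d == pytest.approx(np.median(dists), abs=1e-12)

    def test_too_few_is_error(self):
        with pytest.raises(ValueError):
            lp.property_distance(["CCO"])


class TestCDPlot:
    def test_single_dataset_assembly(self, synthetic_library_50, tmp_path):
        records, _ = synthetic_library_50
        smiles = [r.canonical_smiles for r in records]
        points = lp.cdplot_data(
            [("A", smiles)], plot_path=str(tmp_path / "cdp.png")
        )
        assert len(points) == 1
        point = points[0]
        assert point.x == pytest.approx(
            lp.pairwise_similarity_stats(smiles, "MACCS166").median
        )
        assert point.y == pytest.approx(lp.scaffold_profile(smiles).auc)
        assert point.size_value == len(smiles)
        assert (tmp_path / "cdp.png").exists()

    def test_duplicate_dataset_gives_identical_points(self, synthetic_library_50):
        records, _ = synthetic_library_50
        smiles = [r.canonical_smiles for r in records][:20]
        a, b = lp.cdplot_data([("A", smiles), ("B", smiles)])
        assert (a.x, a.y, a.color_value, a.size_value) == (
            b.x, b.y, b.color_value, b.size_value
        )

    def test_planted_redundancy_orders_median_similarity(self):
        # increasing planted redundancy: 12 distinct scaffolds -> 2
        # scaffolds -> 1 scaffold with homogeneous (alkyl-only) decoration
        alkyl = ["C", "CC", "CCC", "CCCC", "C(C)C", "CC(C)C", "CCCCC",
                 "CC(C)(C)C", "CCC(C)C", "CCCCCC", "CCCCCCC"]
        specs = [
            lp.SyntheticLibrarySpec(frequency=[1] * 12, seed=9),
            lp.SyntheticLibrarySpec(frequency=[6, 6], seed=9),
            lp.SyntheticLibrarySpec(
                scaffold_pool=["c1ccccc1"], frequency=[12],
                substituent_pool=alkyl, seed=9,
            ),
        ]
        sims = []
        for spec in specs:
            records, _ = lp.gen_scaffold_library(spec)
            stats = lp.pairwise_similarity_stats(
                [r.canonical_smiles for r in records], "MACCS166"
            )
            sims.append(stats.median)
        assert sims[0] < sims[1] < sims[2]


class TestEmbedChemspace:
    def _datasets(self, smiles):
        return [("A", [(f"m{i}", s) for i, s in enumerate(smiles)])]

    def test_pca_duplicates_coincide(self, synthetic_library_50):
        records, _ = synthetic_library_50
        smiles = [r.canonical_smiles for r in records][:10] + [
            records[0].canonical_smiles
        ]
        df = lp.embed_chemspace(self._datasets(smiles), "PROPERTIES6", "PCA")
        first, dup = df.iloc[0], df.iloc[-1]
        assert first.dim1 == pytest.approx(dup.dim1)
        assert first.dim2 == pytest.approx(dup.dim2)
        assert "explained_variance_ratio" in df.attrs

    def test_pca_perfectly_correlated_columns(self):
        # alkane homologs: every varying property is collinear with size
        smiles = ["CCCC", "CCCCC", "CCCCCC", "CCCCCCC"]
        df = lp.embed_chemspace(self._datasets(smiles), "PROPERTIES6", "PCA")
        assert df.attrs["explained_variance_ratio"][0] == pytest.approx(1.0)

    def test_tsne_deterministic_given_seed(self, synthetic_library_50):
        records, _ = synthetic_library_50
        smiles = [r.canonical_smiles for r in records][:15]
        a = lp.embed_chemspace(self._datasets(smiles), "MACCS166", "TSNE", seed=5)
        b = lp.embed_chemspace(self._datasets(smiles), "MACCS166", "TSNE", seed=5)
        assert np.allclose(a[["dim1", "dim2"]], b[["dim1", "dim2"]])

    def test_zero_variance_pca_is_error(self):
        with pytest.raises(ValueError):
            lp.embed_chemspace(
                self._datasets(["CCO", "CCO", "CCO"]), "PROPERTIES6", "PCA"
            )
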