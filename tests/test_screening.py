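import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cdscreen import synthetic
from cdscreen.io_formats import SignatureLibrary
from cdscreen.screening import borda_merge, cosine_distance, score_library
from cdscreen.signature import SignatureVector


def unit_sig(values, genes=None):
    v = np.asarray(values, dtype=float)
    genes = genes if genes is not None else [f"g{i}" for i in range(v.size)]
    return SignatureVector(
        coefficients=pd.Series(v / np.linalg.norm(v), index=genes), gamma=0.0
    )


def series(values, genes=None):
    v = np.asarray(values, dtype=float)
    genes = genes if genes is not None else [f"g{i}" for i in range(v.size)]
    return pd.Series(v, index=genes)


class TestCosineDistance:
    def test_identities(self, rng):
        for _ in range(50):
            u = series(rng.normal(size=20))
            assert cosine_distance(u, u) == pytest.approx(0.0, abs=1e-12)
            assert cosine_distance(u, -u) == pytest.approx(2.0, abs=1e-12)

    def test_orthogonal_is_one(self):
        assert cosine_distance(series([1, 0]), series([0, 1])) == pytest.approx(1.0)

    def test_computed_on_shared_genes_only(self):
        u = series([1.0, 2.0], ["a", "b"])
        v = series([3.0, -1.0], ["b", "c"])
        # shared = {b}: cos = sign agreement = +1 -> distance 0
        assert cosine_distance(u, v) == pytest.approx(0.0)

    def test_nan_entries_are_undefined(self):
        u = series([1.0, 1.0], ["a", "b"])
        v = series([np.nan, 2.0], ["a", "b"])
        assert cosine_distance(u, v) == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="no shared"):
            cosine_distance(series([1.0], ["a"]), series([1.0], ["b"]))
        with pytest.raises(ValueError, match="zero vector"):
            cosine_distance(series([0.0, 1.0], ["a", "b"]),
                            series([1.0, np.nan], ["a", "b"]))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 10**6))
    def test_bounded_in_zero_two(self, seed):
        rng = np.random.default_rng(seed)
        u, v = series(rng.normal(size=8)), series(rng.normal(size=8))
        assert 0.0 <= cosine_distance(u, v) <= 2.0


class TestScoreLibrary:
    def library_from_rows(self, rows, genes):
        drugs = [f"d{i}" for i in range(len(rows))]
        return SignatureLibrary(
            values=pd.DataFrame(np.asarray(rows, dtype=float),
                                index=drugs, columns=genes)
        )

    def test_exact_antipode_is_perfect_reverser(self, rng):
        sig = unit_sig(rng.normal(size=10))
        lib = self.library_from_rows(
            [-sig.coefficients.to_numpy(), rng.normal(size=10)], sig.gene_ids
        )
        ranked = score_library(sig, lib, mode="reverse", top_n=10, min_overlap=5)
        assert ranked["drug_id"].iloc[0] == "d0"
        assert ranked["score"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_exact_copy_is_perfect_mimic_and_worst_reverser(self, rng):
        sig = unit_sig(rng.normal(size=10))
        lib = self.library_from_rows(
            [sig.coefficients.to_numpy(), rng.normal(size=10)], sig.gene_ids
        )
        mimic = score_library(sig, lib, mode="mimic", top_n=10, min_overlap=5)
        assert mimic["drug_id"].iloc[0] == "d0"
        assert mimic["score"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        reverse = score_library(sig, lib, mode="reverse", top_n=10, min_overlap=5)
        assert reverse["drug_id"].iloc[-1] == "d0"
        assert reverse.loc[reverse["drug_id"] == "d0", "score"].iloc[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_reverse_and_mimic_scores_sum_to_one(self, rng):
        sig = unit_sig(rng.normal(size=30))
        lib = self.library_from_rows(rng.normal(size=(8, 30)), sig.gene_ids)
        rev = score_library(sig, lib, "reverse", top_n=30, min_overlap=5)
        mim = score_library(sig, lib, "mimic", top_n=30, min_overlap=5)
        total = (
            rev.set_index("drug_id")["score"] + mim.set_index("drug_id")["score"]
        )
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_min_overlap_skips_sparse_drugs(self, rng):
        sig = unit_sig(rng.normal(size=10))
        sparse = np.full(10, np.nan)
        sparse[:3] = 1.0
        lib = self.library_from_rows(
            [rng.normal(size=10), sparse], sig.gene_ids
        )
        ranked = score_library(sig, lib, "reverse", top_n=10, min_overlap=5)
        assert list(ranked["drug_id"]) == ["d0"]
        assert ranked.attrs["skipped"] == 1

    def test_no_drug_passing_overlap_is_error(self, rng):
        sig = unit_sig(rng.normal(size=4))
        lib = self.library_from_rows([np.ones(4)], sig.gene_ids)
        with pytest.raises(ValueError, match="min_overlap"):
            score_library(sig, lib, "reverse", top_n=4, min_overlap=5)

    def test_invalid_mode_rejected(self, rng):
        sig = unit_sig(rng.normal(size=4))
        lib = self.library_from_rows([np.ones(4)], sig.gene_ids)
        with pytest.raises(ValueError, match="mode"):
            score_library(sig, lib, "backward")

    def test_planted_reverser_ranked_first(self):
        """A fidelity-0.8 reverser among 199 nulls wins nearly every seed."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sig = unit_sig(rng.normal(size=500),
                           genes=[f"G{i:05d}" for i in range(500)])
            spec = synthetic.LibrarySpec(
                n_drugs=200, n_reversers=1, reverser_fidelity=0.8, seed=seed
            )
            lib, truth = synthetic.simulate_library(spec, sig)
            ranked = score_library(sig, lib, "reverse", top_n=500, min_overlap=5)
            if ranked["drug_id"].iloc[0] == truth.reversers[0]:
                wins += 1
        assert wins >= 95


def ranked(drugs):
    return pd.DataFrame(
        {"rank": np.arange(1, len(drugs) + 1), "drug_id": drugs,
         "score": np.linspace(1, 0.5, len(drugs))}
    )


class TestBordaMerge:
    def test_rank_one_in_two_lists_earns_double_base(self):
        lists = [ranked(["a", "b"]), ranked(["a", "c"])]
        out = borda_merge(lists, base_score=50)
        row = out[out["drug_id"] == "a"].iloc[0]
        assert row["points"] == 100 and row["rank"] == 1

    def test_single_list_preserves_order(self):
        lst = ranked(["x", "y", "z"])
        out = borda_merge([lst], base_score=50)
        assert list(out["drug_id"]) == ["x", "y", "z"]

    def test_rank_beyond_base_score_earns_nothing(self):
        drugs = [f"d{i:03d}" for i in range(60)]
        out = borda_merge([ranked(drugs)], base_score=50)
        pts = out.set_index("drug_id")["points"]
        assert pts["d049"] == 1
        assert pts["d050"] == 0 and pts["d059"] == 0

    def test_zero_point_ties_break_by_appearances_then_id(self):
        l1 = ranked([f"d{i:03d}" for i in range(52)])
        l2 = ranked([f"d{i:03d}" for i in range(50)] + ["d051"])
        out = borda_merge([l1, l2], base_score=50).set_index("drug_id")
        # d050 (1 list), d051 (2 lists) both at 0 points
        assert out.loc["d051", "rank"] < out.loc["d050", "rank"]

    def test_input_list_order_invariance(self, rng):
        lists = [
            ranked(list(rng.permutation([f"d{i}" for i in range(20)])))
            for _ in range(4)
        ]
        out1 = borda_merge(lists, base_score=10)
        out2 = borda_merge(lists[::-1], base_score=10)
        pd.testing.assert_frame_equal(out1, out2)

    def test_dominance(self):
        """A drug ranking at least as well everywhere and better once wins."""
        l1 = ranked(["a", "b", "c"])
        l2 = ranked(["b", "a", "c"])
        l3 = ranked(["a", "b", "c"])
        out = borda_merge([l1, l2, l3], base_score=50).set_index("drug_id")
        assert out.loc["a", "points"] > out.loc["b", "points"]
        assert out.loc["b", "points"] > out.loc["c", "points"]

    def test_duplicate_drug_in_one_list_rejected(self):
        bad = pd.DataFrame({"rank": [1, 2], "drug_id": ["a", "a"],
                            "score": [1.0, 0.9]})
        with pytest.raises(ValueError, match="duplicate"):
            borda_merge([bad], base_score=50)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            borda_merge([], base_score=50)
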