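import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spikeflow import GeneSetCollection, ValidationError, enrichment_score, preranked_gsea
from spikeflow.detest import DEResult
from spikeflow.gsea import pc_gsea


def brute_force_es(scores: np.ndarray, hit: np.ndarray, p: float) -> float:
    """Independent oracle: walk the list position by position."""
    n = len(scores)
    m = int(hit.sum())
    w = np.abs(scores) ** p
    denom = w[hit].sum()
    if denom == 0:
        w = np.ones(n)
        denom = float(m)
    running = 0.0
    best_pos, best_neg = -np.inf, np.inf
    for i in range(n):
        running += w[i] / denom if hit[i] else -1.0 / (n - m)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    # tie rule: positive deviation wins at equal magnitude
    return best_pos if abs(best_pos) >= abs(best_neg) else best_neg


def _ranked(scores, prefix="g"):
    return pd.Series(scores, index=[f"{prefix}{i}" for i in range(len(scores))])


class TestEnrichmentScore:
    def test_top_gene_unweighted_hits_one(self):
        ranked = _ranked(np.linspace(10, 1, 10))
        es, running = enrichment_score(ranked, {"g0"}, weight=0.0)
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_bottom_gene_unweighted_hits_minus_one(self):
        ranked = _ranked(np.linspace(10, 1, 10))
        es, running = enrichment_score(ranked, {"g9"}, weight=0.0)
        assert es == pytest.approx(-1.0)
        assert running[-2] == pytest.approx(-1.0)  # just before the final hit

    def test_five_gene_hand_example(self):
        ranked = _ranked(np.array([5.0, 4.0, 3.0, 2.0, 1.0]))
        es, _ = enrichment_score(ranked, {"g0", "g2"}, weight=1.0)
        hit = np.array([True, False, True, False, False])
        assert es == pytest.approx(brute_force_es(ranked.to_numpy(), hit, 1.0), abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, 2.0])
    def test_matches_brute_force_on_random_instances(self, rng, p):
        for _ in range(30):
            n = int(rng.integers(5, 51))
            scores = np.sort(rng.normal(size=n))[::-1]
            m = int(rng.integers(1, n))
            hit_idx = rng.choice(n, size=m, replace=False)
            hit = np.zeros(n, dtype=bool)
            hit[hit_idx] = True
            ranked = _ranked(scores)
            members = set(ranked.index[hit])
            es, _ = enrichment_score(ranked, members, weight=p)
            assert es == pytest.approx(brute_force_es(scores, hit, p), abs=1e-12)

    @given(
        n=st.integers(5, 40),
        m=st.integers(1, 10),
        seed=st.integers(0, 10_000),
        p=st.sampled_from([0.0, 1.0, 2.0]),
    )
    @settings(max_examples=50, deadline=None)
    def test_es_bounded_in_unit_interval(self, n, m, seed, p):
        r = np.random.default_rng(seed)
        scores = np.sort(r.normal(size=n))[::-1]
        ranked = _ranked(scores)
        members = set(ranked.index[r.choice(n, size=min(m, n - 1), replace=False)])
        es, running = enrichment_score(ranked, members, weight=p)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        assert np.all(running <= 1.0 + 1e-12) and np.all(running >= -1.0 - 1e-12)

    def test_reversal_symmetry_unweighted(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            scores = np.sort(rng.normal(size=n))[::-1]
            hit = np.zeros(n, dtype=bool)
            hit[rng.choice(n, size=int(rng.integers(1, n // 2)), replace=False)] = True
            ranked = _ranked(scores)
            ours, running = enrichment_score(ranked, set(ranked.index[hit]), weight=0.0)
            rev = _ranked(-scores[::-1])
            rev_members = set(rev.index[hit[::-1]])
            ours_rev, _ = enrichment_score(rev, rev_members, weight=0.0)
            # when positive and negative extrema tie exactly, the tie rule
            # picks the positive one on both orientations; otherwise mirroring
            # the list negates the enrichment score
            if abs(abs(running.max()) - abs(running[:-1].min())) > 1e-9:
                assert ours_rev == pytest.approx(-ours, abs=1e-12)
            else:
                assert abs(ours_rev) == pytest.approx(abs(ours), abs=1e-12)

    def test_disjoint_and_full_cover_rejected(self):
        ranked = _ranked(np.linspace(5, 1, 5))
        with pytest.raises(ValidationError, match="disjoint"):
            enrichment_score(ranked, {"zz"})
        with pytest.raises(ValidationError, match="entire"):
            enrichment_score(ranked, set(ranked.index))

    def test_unsorted_list_rejected(self):
        with pytest.raises(ValidationError, match="descending"):
            enrichment_score(_ranked(np.array([1.0, 2.0])), {"g0"})


def _random_collection(rng, n_sets, size, n_genes, prefix="g"):
    return GeneSetCollection(
        {
            f"S{j}": [f"{prefix}{i}" for i in rng.choice(n_genes, size, replace=False)]
            for j in range(n_sets)
        }
    )


class TestPrerankedGsea:
    def test_planted_top_set_is_significant(self, rng):
        scores = np.sort(rng.normal(size=1000))[::-1]
        ranked = _ranked(scores)
        coll_sets = {"PLANT": [f"g{i}" for i in range(20)]}
        coll_sets.update(_random_collection(rng, 30, 20, 1000).sets)
        result = preranked_gsea(ranked, GeneSetCollection(coll_sets), n_perm=500, seed=1)
        row = result.table.loc["PLANT"]
        assert row["nes"] > 2.0
        assert row["fdr_q"] < 0.01

    def test_null_sets_calibrated(self):
        fracs = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            ranked = _ranked(np.sort(r.normal(size=800))[::-1])
            coll = _random_collection(r, 60, 20, 800)
            result = preranked_gsea(ranked, coll, n_perm=300, seed=seed)
            fracs.append((result.table["fdr_q"] < 0.01).mean())
        assert np.mean(fracs) <= 0.02

    def test_size_filter_and_empty_result_error(self, rng):
        ranked = _ranked(np.sort(rng.normal(size=100))[::-1])
        coll = _random_collection(rng, 5, 5, 100)
        with pytest.raises(ValidationError, match="between 15 and 500"):
            preranked_gsea(ranked, coll, min_size=15)
        result = preranked_gsea(ranked, coll, n_perm=100, min_size=2, seed=0)
        assert (result.table["size"] == 5).all()

    def test_nes_sign_matches_es_sign(self, rng):
        ranked = _ranked(np.sort(rng.normal(size=500))[::-1])
        coll = _random_collection(rng, 25, 25, 500)
        result = preranked_gsea(ranked, coll, n_perm=200, min_size=10, seed=3)
        t = result.table
        assert (np.sign(t["nes"]) == np.sign(t["es"])).all()
        assert t["fdr_q"].between(0, 1).all()

    def test_fdr_monotone_within_sign(self, rng):
        ranked = _ranked(np.sort(rng.normal(size=500))[::-1])
        coll = _random_collection(rng, 40, 20, 500)
        t = preranked_gsea(ranked, coll, n_perm=200, min_size=10, seed=4).table
        for side in (t[t["nes"] >= 0], t[t["nes"] < 0]):
            s = side.sort_values("nes", key=np.abs, ascending=False)
            assert (np.diff(s["fdr_q"]) >= -1e-12).all()

    def test_deterministic_under_seed(self, rng):
        ranked = _ranked(np.sort(rng.normal(size=300))[::-1])
        coll = _random_collection(rng, 10, 20, 300)
        t1 = preranked_gsea(ranked, coll, n_perm=100, seed=7).table
        t2 = preranked_gsea(ranked, coll, n_perm=100, seed=7).table
        assert t1.to_csv() == t2.to_csv()


def test_es_agrees_with_independent_reference_implementation(rng):
    """Cross-check the weighted-KS enrichment score against gseapy."""
    gseapy = pytest.importorskip("gseapy")
    scores = np.sort(rng.normal(size=200))[::-1]
    genes = [f"g{i}" for i in range(200)]
    sets = {f"S{j}": [f"g{i}" for i in rng.choice(200, 25, replace=False)] for j in range(4)}
    ref = gseapy.prerank(
        rnk=pd.DataFrame({"gene_name": genes, "score": scores}),
        gene_sets=sets,
        permutation_num=10,
        min_size=5,
        max_size=500,
        seed=1,
        threads=1,
        no_plot=True,
        outdir=None,
    ).res2d.set_index("Term")
    ranked = _ranked(scores)
    for name, members in sets.items():
        es, _ = enrichment_score(ranked, set(members), weight=1.0)
        assert es == pytest.approx(float(ref.loc[name, "ES"]), abs=1e-9)


class TestPcGsea:
    def _de_result(self, scores, genes):
        table = pd.DataFrame(
            {"score": scores, "local_fdr": 0.5, "direction": np.sign(scores)},
            index=pd.Index(genes, name="gene_id"),
        )
        return DEResult(table=table, response_kind="quantitative")

    def test_ranks_by_descending_score(self, rng):
        genes = [f"g{i}" for i in range(200)]
        scores = rng.normal(size=200)
        de = self._de_result(scores, genes)
        coll = _random_collection(rng, 5, 20, 200)
        result = pc_gsea(de, coll, n_perm=100, seed=0)
        assert len(result.table) == 5

    def test_equal_scores_keep_input_order(self):
        genes = [f"g{i}" for i in range(10)]
        de = self._de_result(np.zeros(10), genes)
        ranked = de.table["score"].sort_values(ascending=False, kind="mergesort")
        assert ranked.index.tolist() == genes
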