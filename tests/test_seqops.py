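import itertools
import math

import dendropy
import numpy as np
import pytest

from epidiatom.seqops import (
    assign_taxonomy,
    greedy_cluster,
    mcl_distance,
    nj_tree,
    p_distance,
    pairwise_identity,
    rank_summary,
)
from epidiatom.tables import DistanceMatrix, SequenceCollection, ValidationError


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_single_mismatch(self):
        assert p_distance("ACGT", "ACGA") == 0.25

    def test_pairwise_deletion(self):
        # gap column excluded: 0 mismatches over 3 effective sites
        assert p_distance("AC-T", "ACGT") == 0.0

    def test_n_excluded(self):
        assert p_distance("ACNT", "ACGA") == pytest.approx(1 / 3)

    def test_no_effective_sites_nan(self):
        assert math.isnan(p_distance("--NN", "AC-T"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            p_distance("ACG", "AC")


class TestPairwiseIdentity:
    def test_equal_length(self):
        assert pairwise_identity("ACGT", "ACGA") == 0.75

    def test_unequal_length_aligned_globally(self):
        # one extra base: alignment introduces a gap, identity stays high
        ident = pairwise_identity("ACGTACGTACGT", "ACGTACGTACGTA")
        assert ident == pytest.approx(1.0)


def _jc_pair() -> tuple[str, str]:
    """Pair with equal pooled base frequencies and JC-proportioned mismatches.

    36 identical sites (9 per base) + one of each of the 12 ordered mismatch
    pairs: p = 0.25, P1 = P2 = p/6, Q = 2p/3, all pooled frequencies 1/4.
    """
    ident = "ACGT" * 9
    mm = [
        ("A", "C"), ("A", "G"), ("A", "T"), ("C", "A"), ("C", "G"), ("C", "T"),
        ("G", "A"), ("G", "C"), ("G", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
    ]
    s1 = ident + "".join(a for a, _ in mm)
    s2 = ident + "".join(b for _, b in mm)
    return s1, s2


def _tn93_oracle(a: str, b: str, freqs: dict[str, float]) -> float:
    """Step-by-step independent evaluation of the published formula."""
    eff = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(eff)
    p1 = sum(1 for x, y in eff if {x, y} == {"A", "G"}) / n
    p2 = sum(1 for x, y in eff if {x, y} == {"C", "T"}) / n
    q = sum(1 for x, y in eff if x != y and {x, y} not in ({"A", "G"}, {"C", "T"})) / n
    pa, pc, pg, pt = freqs["A"], freqs["C"], freqs["G"], freqs["T"]
    pr, py = pa + pg, pc + pt
    return (
        -(2 * pa * pg / pr) * math.log(1 - pr * p1 / (2 * pa * pg) - q / (2 * pr))
        - (2 * pc * pt / py) * math.log(1 - py * p2 / (2 * pc * pt) - q / (2 * py))
        - 2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
        * math.log(1 - q / (2 * pr * py))
    )


class TestMclDistance:
    def test_identical_sequences_zero(self):
        seqs = SequenceCollection([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert mcl_distance(seqs).data[0, 1] == 0.0

    def test_jukes_cantor_closed_form_limit(self):
        s1, s2 = _jc_pair()
        seqs = SequenceCollection([("a", s1), ("b", s2)])
        d = mcl_distance(seqs).data[0, 1]
        p = 0.25
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert d == pytest.approx(jc, abs=1e-9)

    def test_four_sequence_toy_matches_formula_oracle(self):
        rng = np.random.default_rng(17)
        base = rng.choice(list("ACGT"), size=120)
        seqs = {}
        for i in range(4):
            s = base.copy()
            pos = rng.choice(120, size=6 + 3 * i, replace=False)
            for p in pos:
                s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
            seqs[f"s{i}"] = "".join(s)
        coll = SequenceCollection(seqs)
        result = mcl_distance(coll)
        # pooled frequency oracle computed independently
        allbases = "".join(coll.values())
        freqs = {b: allbases.count(b) / len(allbases) for b in "ACGT"}
        for i, j in itertools.combinations(range(4), 2):
            expected = _tn93_oracle(seqs[f"s{i}"], seqs[f"s{j}"], freqs)
            assert result.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_saturated_pair_marked_nan(self):
        seqs = SequenceCollection(
            [("a", "ACGT" * 10), ("b", "CATG" * 10), ("c", "ACGT" * 10)]
        )
        d = mcl_distance(seqs)
        assert math.isnan(d.data[0, 1])

    def test_correction_never_shrinks(self):
        rng = np.random.default_rng(23)
        base = rng.choice(list("ACGT"), size=300)
        variants = {}
        for i in range(5):
            s = base.copy()
            pos = rng.choice(300, size=rng.integers(5, 40), replace=False)
            for p in pos:
                s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
            variants[f"v{i}"] = "".join(s)
        coll = SequenceCollection(variants)
        d = mcl_distance(coll)
        ids = list(variants)
        for i, j in itertools.combinations(range(5), 2):
            if math.isnan(d.data[i, j]):
                continue
            assert d.data[i, j] >= p_distance(variants[ids[i]], variants[ids[j]]) - 1e-12

    def test_needs_two_sequences(self):
        with pytest.raises(ValidationError):
            mcl_distance(SequenceCollection([("a", "ACGT")]))


class TestGreedyCluster:
    def test_all_identical_one_otu(self):
        seqs = SequenceCollection([(f"s{i}", "ACGT" * 20) for i in range(5)])
        assert len(greedy_cluster(seqs)) == 1

    def test_two_divergent_families(self):
        rng = np.random.default_rng(2)
        fam_a = rng.choice(list("ACGT"), size=200)
        fam_b = fam_a.copy()
        pos = rng.choice(200, size=40, replace=False)  # 20% divergence
        for p in pos:
            fam_b[p] = rng.choice([b for b in "ACGT" if b != fam_b[p]])
        seqs = {}
        for fam, proto in (("a", fam_a), ("b", fam_b)):
            for i in range(3):
                s = proto.copy()
                mpos = rng.choice(200, size=2, replace=False)  # <=2% within
                for p in mpos:
                    s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
                seqs[f"{fam}{i}"] = "".join(s)
        clusters = greedy_cluster(SequenceCollection(seqs), similarity=0.95)
        assert len(clusters) == 2
        members = sorted(frozenset(m) for m in clusters.values())
        assert {frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"})} == set(
            members
        )

    def test_single_sequence(self):
        clusters = greedy_cluster(SequenceCollection([("only", "ACGT")]))
        assert clusters == {"only": ["only"]}

    def test_abundance_order_picks_centroid(self):
        seqs = SequenceCollection([("low", "ACGTACGTAA"), ("high", "ACGTACGTAC")])
        clusters = greedy_cluster(seqs, similarity=0.8, abundances={"high": 10, "low": 1})
        assert list(clusters) == ["high"]

    def test_similarity_one_is_dereplication(self):
        seqs = SequenceCollection(
            [("a", "ACGT" * 10), ("b", "ACGT" * 10), ("c", "ACGA" + "ACGT" * 9)]
        )
        clusters = greedy_cluster(seqs, similarity=1.0)
        assert len(clusters) == 2

    def test_otu_count_monotone_in_similarity(self):
        rng = np.random.default_rng(6)
        base = rng.choice(list("ACGT"), size=150)
        seqs = {}
        for i in range(12):
            s = base.copy()
            pos = rng.choice(150, size=rng.integers(0, 30), replace=False)
            for p in pos:
                s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
            seqs[f"s{i:02d}"] = "".join(s)
        coll = SequenceCollection(seqs)
        counts = [
            len(greedy_cluster(coll, similarity=s)) for s in (1.0, 0.97, 0.9, 0.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            greedy_cluster(SequenceCollection())


def _ref_setup():
    base = "ACGT" * 25  # length 100
    refs = SequenceCollection([("ref1", base)])
    taxonomy = {
        "ref1": {
            "species": "Nitzschia inconspicua",
            "genus": "Nitzschia",
            "family": "Bacillariaceae",
            "class": "Bacillariophyceae",
        }
    }
    return base, refs, taxonomy


def _mutated(base: str, k: int) -> str:
    out = list(base)
    for p in range(k):
        out[p] = "A" if out[p] != "A" else "C"
    return "".join(out)


class TestAssignTaxonomy:
    def test_exact_match_species(self):
        base, refs, tax = _ref_setup()
        (a,) = assign_taxonomy(SequenceCollection([("otu", base)]), refs, tax)
        assert a.rank == "species" and a.identity == 1.0
        assert a.name == "Nitzschia inconspicua"

    @pytest.mark.parametrize(
        "k,rank",
        [(2, "species"), (4, "genus"), (7, "family"), (15, "class"), (50, "unassigned")],
    )
    def test_threshold_table(self, k, rank):
        base, refs, tax = _ref_setup()
        otu = SequenceCollection([("otu", _mutated(base, k))])
        (a,) = assign_taxonomy(otu, refs, tax)
        assert a.rank == rank

    def test_rank_monotone_in_identity(self):
        base, refs, tax = _ref_setup()
        order = {"species": 4, "genus": 3, "family": 2, "class": 1, "unassigned": 0}
        last = 5
        for k in (0, 3, 6, 12, 25, 60):
            (a,) = assign_taxonomy(
                SequenceCollection([("otu", _mutated(base, k))]), refs, tax
            )
            assert order[a.rank] <= last
            last = order[a.rank]

    def test_rank_summary_percentages(self):
        base, refs, tax = _ref_setup()
        otus = SequenceCollection(
            [("o1", base), ("o2", _mutated(base, 4)), ("o3", _mutated(base, 50)),
             ("o4", _mutated(base, 50))]
        )
        summary = rank_summary(assign_taxonomy(otus, refs, tax))
        assert summary["species"] == 25.0
        assert summary["genus"] == 25.0
        assert summary["unassigned"] == 50.0
        assert sum(summary.values()) == pytest.approx(100.0)

    def test_empty_refs_rejected(self):
        with pytest.raises(ValidationError):
            assign_taxonomy(
                SequenceCollection([("o", "ACGT")]), SequenceCollection(), {}
            )


def _newick_path_distances(newick: str, labels: list[str]) -> np.ndarray:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return out


def _random_additive_tree(n_leaves: int, rng) -> tuple[dict, list[str]]:
    """Random unrooted binary tree as an adjacency {node: {nbr: length}}."""
    adj: dict = {}

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def lengths():
        return float(rng.uniform(0.2, 2.0))

    labels = [f"L{i}" for i in range(n_leaves)]
    connect(labels[0], "I0", lengths())
    connect(labels[1], "I0", lengths())
    connect(labels[2], "I0", lengths())
    internal = 1
    for leaf in labels[3:]:
        # split a random existing edge with a new internal node
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        node = f"I{internal}"
        internal += 1
        split = float(rng.uniform(0.2, 0.8))
        connect(a, node, w * split)
        connect(b, node, w * (1 - split))
        connect(leaf, node, lengths())
    return adj, labels


def _path_distances(adj: dict, labels: list[str]) -> np.ndarray:
    import heapq

    n = len(labels)
    out = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, math.inf):
                continue
            for v, w in adj[u].items():
                nd = d + w
                if nd < dist.get(v, math.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        for j, dst in enumerate(labels):
            out[i, j] = dist[dst]
    return out


class TestNjTree:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["a", "b", "c"], [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        newick = nj_tree(d)
        paths = _newick_path_distances(newick, ["a", "b", "c"])
        np.testing.assert_allclose(paths, d.data, atol=1e-9)

    def test_additive_four_taxon_recovery(self):
        # distances built from a known tree: ((a:1,b:2):1.5,(c:0.5,d:3))
        d = np.array(
            [
                [0.0, 3.0, 3.0, 5.5],
                [3.0, 0.0, 4.0, 6.5],
                [3.0, 4.0, 0.0, 3.5],
                [5.5, 6.5, 3.5, 0.0],
            ]
        )
        dm = DistanceMatrix(["a", "b", "c", "d"], d)
        paths = _newick_path_distances(nj_tree(dm), ["a", "b", "c", "d"])
        np.testing.assert_allclose(paths, d, atol=1e-9)

    def test_star_distances_zero_internal(self):
        n = 5
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0)
        labels = [f"t{i}" for i in range(n)]
        paths = _newick_path_distances(nj_tree(DistanceMatrix(labels, d)), labels)
        np.testing.assert_allclose(paths, d, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_additive_tree_recovered(self, seed):
        rng = np.random.default_rng(seed)
        adj, labels = _random_additive_tree(6, rng)
        d = _path_distances(adj, labels)
        newick = nj_tree(DistanceMatrix(labels, d))
        paths = _newick_path_distances(newick, labels)
        # exact reproduction of an additive metric pins topology and lengths
        np.testing.assert_allclose(paths, d, atol=1e-8)

    def test_undefined_distances_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(["a", "b", "c"], d))

    def test_too_few_taxa(self):
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(["a", "b"], [[0, 1], [1, 0]]))
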