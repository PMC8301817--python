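"""Identity pruning, medoid selection vs brute force, reduction bookkeeping."""

import itertools
import statistics

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lhr.records import PF_RECA1, PF_RECA2, ProfileHit
from lhr.reduce import (ReductionParams, RepresentativeSet, compute_medoid,
                        discard_missing_core, dissimilarity_from_hits,
                        prune_graph_by_identity, reduce_dataset)


def brute_force_medoid(group, lengths, mat, tol_frac):
    """Exhaustive re-derivation of the medoid rule."""
    if len(group) == 1:
        return group[0]
    med = statistics.median(lengths[g] for g in group)
    cands = [g for g in group if abs(lengths[g] - med) <= tol_frac * med]
    if not cands:
        closest = min(abs(lengths[g] - med) for g in group)
        cands = [g for g in group if abs(lengths[g] - med) == closest]
    scored = sorted(
        (sum(mat.loc[g, h] for h in group if h != g) / (len(group) - 1), g)
        for g in cands)
    return scored[0][1]


def random_symmetric_matrix(ids, rng):
    n = len(ids)
    raw = rng.uniform(0, 100, size=(n, n))
    sym = (raw + raw.T) / 2
    np.fill_diagonal(sym, 0.0)
    return pd.DataFrame(sym, index=ids, columns=ids)


class TestPrune:
    def _graph(self, identities):
        g = nx.Graph()
        for k, ident in enumerate(identities):
            g.add_edge(f"a{k}", f"b{k}", weight=10.0, identity_pct=ident)
        return g

    def test_all_above_threshold_is_identity_transform(self):
        g = self._graph([95, 80, 71])
        assert prune_graph_by_identity(g, 70).number_of_edges() == 3

    def test_all_below_threshold_keeps_nodes(self):
        g = self._graph([50, 60])
        pruned = prune_graph_by_identity(g, 70)
        assert pruned.number_of_edges() == 0
        assert pruned.number_of_nodes() == g.number_of_nodes()

    def test_mixed_edge_count_matches_direct_count(self):
        rng = np.random.default_rng(4)
        idents = rng.uniform(0, 100, 30)
        g = self._graph(list(idents))
        pruned = prune_graph_by_identity(g, 70)
        assert pruned.number_of_edges() == int((idents >= 70).sum())


class TestComputeMedoid:
    def test_singleton_returns_itself(self):
        mat = pd.DataFrame([[0.0]], index=["x"], columns=["x"])
        assert compute_medoid(["x"], {"x": 100}, mat) == "x"

    def test_equidistant_equal_lengths_lexicographic_tie_break(self):
        ids = ["c", "a", "b"]
        mat = pd.DataFrame(30.0, index=ids, columns=ids)
        np.fill_diagonal(mat.values, 0.0)
        assert compute_medoid(ids, {i: 200 for i in ids}, mat) == "a"

    def test_asymmetric_matrix_rejected(self):
        ids = ["a", "b"]
        mat = pd.DataFrame([[0.0, 10.0], [20.0, 0.0]],
                           index=ids, columns=ids)
        with pytest.raises(ValueError):
            compute_medoid(ids, {"a": 10, "b": 10}, mat)

    def test_matches_brute_force_with_length_window(self):
        rng = np.random.default_rng(9)
        for trial in range(25):
            size = int(rng.integers(1, 16))
            ids = [f"g{trial}_{i}" for i in range(size)]
            lengths = {i: int(rng.integers(200, 400)) for i in ids}
            mat = random_symmetric_matrix(ids, rng)
            assert compute_medoid(ids, lengths, mat) == \
                brute_force_medoid(ids, lengths, mat, 0.10)

    def test_length_window_excludes_off_length_member(self):
        # "short" is nearest to everyone but far from the median length
        ids = ["long1", "long2", "long3", "short"]
        mat = pd.DataFrame(50.0, index=ids, columns=ids)
        np.fill_diagonal(mat.values, 0.0)
        mat.loc["short", ["long1", "long2", "long3"]] = 1.0
        mat.loc[["long1", "long2", "long3"], "short"] = 1.0
        lengths = {"long1": 300, "long2": 300, "long3": 302, "short": 80}
        assert compute_medoid(ids, lengths, mat) in ("long1", "long2",
                                                     "long3")


def _chain_graph(groups):
    """Graph whose >=70% components are the given groups."""
    g = nx.Graph()
    for group in groups:
        g.add_nodes_from(group)
        for a, b in zip(group, group[1:]):
            g.add_edge(a, b, weight=50.0, identity_pct=90.0)
    return g


class TestReduceDataset:
    def _inputs(self, groups):
        ids = [m for grp in groups for m in grp]
        rng = np.random.default_rng(1)
        mat = random_symmetric_matrix(ids, rng)
        lengths = {i: 300 for i in ids}
        return _chain_graph(groups), mat, lengths

    def test_bookkeeping_counts(self):
        groups = [["a1", "a2", "a3"], ["b1"], ["c1", "c2"], ["d1"]]
        g, mat, lengths = self._inputs(groups)
        reps = reduce_dataset(g, mat, lengths)
        assert len(reps.representatives) == \
            reps.n_singletons + reps.n_medoid_groups
        assert reps.n_singletons == 2
        assert reps.n_medoid_groups == 2
        assert set(reps.member_of) == set(lengths)

    def test_member_of_is_a_projection(self):
        groups = [["a1", "a2", "a3"], ["b1", "b2"]]
        g, mat, lengths = self._inputs(groups)
        reps = reduce_dataset(g, mat, lengths)
        for member, rep in reps.member_of.items():
            assert reps.member_of[rep] == rep

    def test_keep_list_already_selected_is_idempotent(self):
        groups = [["a1", "a2", "a3"], ["b1"]]
        g, mat, lengths = self._inputs(groups)
        base = reduce_dataset(g, mat, lengths)
        some_rep = sorted(base.representatives)[0]
        again = reduce_dataset(g, mat, lengths,
                               ReductionParams(keep_list=(some_rep,)))
        assert again.representatives == base.representatives

    def test_keep_list_readds_nonrepresentative(self):
        groups = [["a1", "a2", "a3"]]
        g, mat, lengths = self._inputs(groups)
        base = reduce_dataset(g, mat, lengths)
        dropped = sorted(set(lengths) - base.representatives)[0]
        again = reduce_dataset(g, mat, lengths,
                               ReductionParams(keep_list=(dropped,)))
        assert dropped in again.representatives
        assert again.member_of[dropped] == dropped

    def test_unknown_keep_list_id_rejected(self):
        g, mat, lengths = self._inputs([["a1", "a2"]])
        with pytest.raises(ValueError):
            reduce_dataset(g, mat, lengths,
                           ReductionParams(keep_list=("ghost",)))

    def test_raising_threshold_never_merges_groups(self, two_family_dataset):
        from lhr import graph as graph_mod
        from lhr import pairwise
        prots = two_family_dataset.proteins
        hits = pairwise.all_vs_all(prots)
        bbh = graph_mod.build_bbh_graph(
            graph_mod.best_hits_per_species(hits, prots), prots)
        comp_sets = []
        for thr in (50.0, 70.0, 90.0):
            pruned = prune_graph_by_identity(bbh, thr)
            comp_sets.append(
                {frozenset(c) for c in nx.connected_components(pruned)})
        # each component at a higher threshold is inside one at a lower one
        for lower, higher in zip(comp_sets, comp_sets[1:]):
            for comp in higher:
                assert any(comp <= big for big in lower)


class TestDiscardMissingCore:
    def _reps(self, ids):
        return RepresentativeSet(set(ids), {i: i for i in ids},
                                 n_singletons=len(ids), n_medoid_groups=0)

    def _core_hits(self, pid):
        return [ProfileHit(pid, PF_RECA1, 1e-50, 200, 1, 140, 140, 1.0),
                ProfileHit(pid, PF_RECA2, 1e-50, 200, 150, 290, 140, 1.0)]

    def test_removes_exactly_the_incomplete(self):
        hits = self._core_hits("good") + \
            [ProfileHit("half", PF_RECA1, 1e-50, 200, 1, 140, 140, 1.0)]
        out = discard_missing_core(self._reps(["good", "half"]), hits)
        assert out.representatives == {"good"}

    def test_all_complete_is_identity(self):
        hits = self._core_hits("a") + self._core_hits("b")
        out = discard_missing_core(self._reps(["a", "b"]), hits)
        assert out.representatives == {"a", "b"}

    def test_exempt_id_survives(self):
        hits = self._core_hits("good")
        out = discard_missing_core(self._reps(["good", "bare"]), hits,
                                   exempt=("bare",))
        assert out.representatives == {"good", "bare"}
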