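import json
import math

import numpy as np
import pytest

from oracles import naive_best_placement, naive_placement_loglik
from sqamp.models import ModelConfig, lg_model, poisson_model
from sqamp.place import (AlignedQuery, OptimizerConfig, PlacementEngine,
                         UnplaceableQueryError, align_query,
                         edge_log_likelihood, place_query, write_jplace)
from sqamp.resources import ReferenceEntry, ReferenceResource, RefTree
from sqamp.synth import SynthConfig, simulate_reference


def _single_site_resource():
    tree = RefTree("(A:1,B:2,C:3);")
    seqs = {"A": "A", "B": "A", "C": "R"}
    entries = [ReferenceEntry(id=i, protein_seq=s, label="target")
               for i, s in seqs.items()]
    return ReferenceResource(entries=entries, alignment=seqs, tree=tree,
                             target_leaves=set(seqs))


class TestModels:
    def test_transition_matrix_rows_sum_to_one(self):
        for model in (lg_model(), poisson_model()):
            for t in (0.0, 0.1, 2.5):
                P = model.transition_matrix(t)
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
                assert (P >= 0).all()

    def test_unit_expected_substitution_rate(self):
        for model in (lg_model(), poisson_model()):
            mu = -np.dot(model.frequencies, np.diag(model.rate_matrix))
            assert mu == pytest.approx(1.0)

    def test_stationarity(self):
        model = lg_model()
        pi = model.frequencies
        assert np.allclose(pi @ model.transition_matrix(0.7), pi, atol=1e-12)


class TestEdgeLogLikelihood:
    def test_poisson_closed_form_three_leaves(self):
        """Single-site 3-leaf likelihood matches the analytic equal-rates
        transition probability P_same(t) = 1/20 + (19/20) e^(-20t/19)."""
        res = _single_site_resource()
        eng = PlacementEngine(res, ModelConfig("poisson"))

        def p_same(t):
            return 1 / 20 + (19 / 20) * math.exp(-20 * t / 19)

        def p_diff(t):
            return 1 / 20 - (1 / 20) * math.exp(-20 * t / 19)

        L = sum(
            (1 / 20)
            * (p_same(1) if x == 0 else p_diff(1))    # state A at leaf A
            * (p_same(2) if x == 0 else p_diff(2))    # state A at leaf B
            * (p_same(3) if x == 1 else p_diff(3))    # state R at leaf C
            for x in range(20))
        assert eng.reference_log_likelihood() == pytest.approx(math.log(L),
                                                               abs=1e-9)

    def test_gap_query_adds_nothing(self):
        """A query that is all missing data leaves the likelihood unchanged
        wherever and however it is attached."""
        res = _single_site_resource()
        eng = PlacementEngine(res, ModelConfig("poisson"))
        ref_ll = eng.reference_log_likelihood()
        q = AlignedQuery(asv_id="q", row="-")
        for e in range(res.tree.n_edges):
            for pendant in (1e-8, 0.3, 2.0):
                assert edge_log_likelihood(res, q, e, pendant,
                                           ModelConfig("poisson")) == \
                    pytest.approx(ref_ll, abs=1e-9)

    def test_matches_naive_rebuild(self, small_reference):
        """Two-pass engine equals naive full-tree pruning (pulley check)."""
        model = lg_model()
        eng = PlacementEngine(small_reference)
        row = small_reference.alignment["T003"]
        q = AlignedQuery(asv_id="q", row=row)
        qtip = eng._query_tip(q)
        rng = np.random.default_rng(0)
        for e in rng.choice(small_reference.tree.n_edges, 4, replace=False):
            for pendant in (1e-6, 0.05, 0.7):
                fast = eng.edge_log_likelihood_partials(qtip, int(e), pendant)
                slow = naive_placement_loglik(small_reference, model, row,
                                              int(e), pendant)
                assert fast == pytest.approx(slow, abs=1e-6)


class TestAlignQuery:
    def test_identical_to_reference_row(self, small_reference):
        row = small_reference.alignment["T001"]
        assert align_query(row.replace("-", ""), small_reference).row == row

    def test_truncated_query_gets_leading_gaps(self, small_reference):
        row = small_reference.alignment["T001"]
        got = align_query(row.replace("-", "")[5:], small_reference).row
        assert got == "-" * 5 + row[5:]

    def test_insertion_discarded(self, small_reference):
        row = small_reference.alignment["T001"]
        pep = row.replace("-", "")
        got = align_query(pep[:70] + "QQQ" + pep[70:], small_reference).row
        assert got == row

    def test_query_exceeding_reference_coverage_raises(self, small_reference):
        # more than twice as many residues as reference columns: fewer than
        # half can land in columns, so the query is flagged unplaceable
        ncol = small_reference.n_columns
        with pytest.raises(UnplaceableQueryError):
            align_query("W" * (2 * ncol + 20), small_reference)


class TestPlaceQuery:
    def test_self_placement_target(self, small_reference):
        row = small_reference.alignment["T004"]
        pl = place_query(small_reference, AlignedQuery(asv_id="q", row=row))
        tree = small_reference.tree
        assert pl.best_edge == tree.edge_above[tree.name_to_node["T004"]]
        assert pl.verified
        assert pl.pendant_length <= 1e-4
        assert sum(pl.lwr.values()) == pytest.approx(1.0, abs=1e-9)
        assert max(pl.lwr.values()) == pl.lwr[pl.best_edge]

    def test_decoy_not_verified(self, small_reference):
        row = small_reference.alignment["D002"]
        pl = place_query(small_reference, AlignedQuery(asv_id="q", row=row))
        assert not pl.verified

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_oracle(self, seed):
        """Best edge and log-likelihood match an oracle that rebuilds the
        full tree per (edge x pendant grid) on random 8-leaf bundles."""
        cfg = SynthConfig(seed=100 + seed, n_target_leaves=5,
                          n_decoy_leaves=3, protein_length=120,
                          amplicon_start=1, amplicon_length=300)
        res, _ = simulate_reference(cfg)
        model = lg_model()
        eng = PlacementEngine(res)
        rng = np.random.default_rng(seed)
        # query: mutated copy of a random leaf
        leaf = rng.choice(sorted(res.alignment))
        row = list(res.alignment[leaf])
        aas = list("ARNDCQEGHILKMFPSTWYV")
        for pos in rng.choice(len(row), size=12, replace=False):
            row[pos] = rng.choice(aas)
        row = "".join(row)
        pl = eng.place(AlignedQuery(asv_id="q", row=row))
        oe, oll, _ = naive_best_placement(res, model, row, grid_size=60)
        assert pl.best_edge == oe
        assert pl.log_likelihood == pytest.approx(oll, abs=1e-3)

    def test_leaf_relabeling_invariance(self, small_reference):
        """Consistently renaming leaves does not change the chosen branch."""
        res = small_reference
        mapping = {n: f"x_{n}" for n in res.tree.leaf_names}
        newick = res.tree.newick()
        for old, new in mapping.items():
            newick = newick.replace(old + ":", new + ":")
        entries = [ReferenceEntry(id=mapping[e.id], protein_seq=e.protein_seq,
                                  label=e.label) for e in res.entries]
        res2 = ReferenceResource(
            entries=entries,
            alignment={mapping[k]: v for k, v in res.alignment.items()},
            tree=RefTree(newick),
            target_leaves={mapping[t] for t in res.target_leaves})
        row = res.alignment["T002"]
        p1 = place_query(res, AlignedQuery(asv_id="q", row=row))
        p2 = place_query(res2, AlignedQuery(asv_id="q", row=row))
        assert p1.best_edge == p2.best_edge
        assert p1.log_likelihood == pytest.approx(p2.log_likelihood, abs=1e-9)


class TestJplace:
    def test_roundtrip_and_consistency(self, small_reference, tmp_path):
        row = small_reference.alignment["T000"]
        pl = place_query(small_reference, AlignedQuery(asv_id="q1", row=row))
        path = tmp_path / "out.jplace"
        write_jplace([pl], small_reference, path, {"q1": 9})
        doc = json.loads(path.read_text())
        assert doc["version"] == 3
        assert doc["fields"][0] == "edge_num"
        rows = doc["placements"][0]["p"]
        assert rows[0][0] == pl.best_edge
        # self-placement: best edge carries most of the weight
        assert rows[0][2] > 0.5
        # distal length is half the attachment edge (midpoint convention)
        assert rows[0][3] == pytest.approx(
            0.5 * small_reference.tree.edge_length(pl.best_edge))
        assert doc["placements"][0]["nm"] == [["q1", 9]]
        # every edge number in the tree string round-trips
        import re
        nums = sorted(int(m) for m in re.findall(r"\{(\d+)\}", doc["tree"]))
        assert nums == list(range(small_reference.tree.n_edges))

    def test_empty_placements_rejected(self, small_reference, tmp_path):
        with pytest.raises(ValueError):
            write_jplace([], small_reference, tmp_path / "x.jplace")
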