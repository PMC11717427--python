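import json

import networkx as nx
import numpy as np
import pytest

from metascreen.synth import DimerFixtureSpec, _build_dimer, gen_dimer_fixture
from metascreen.triage import (
    InteractionCall,
    ModelScore,
    call_interaction,
    concordance,
    constrained_pairs,
    constrained_profile,
    export_network,
    load_model,
    ranking_score,
)
from metascreen.triage.models import ContactPair


def brute_force_pairs(model, pae_max=5.0, dist_max=6.0):
    """Naive O(L_A * L_B) double loop over all inter-chain residue pairs."""
    found = set()
    pae = model.pae.values
    la = len(model.chain_a)
    for i in range(la):
        for j in range(len(model.chain_b)):
            d = float(np.linalg.norm(
                model.chain_a.ca_coords[i] - model.chain_b.ca_coords[j]
            ))
            p = max(pae[i, la + j], pae[la + j, i])
            if d < dist_max and p < pae_max:
                found.add((i + 1, j + 1))
    return found


@pytest.fixture
def fixture_model(tmp_path):
    truth = gen_dimer_fixture(DimerFixtureSpec(n_pairs=7, seed=11), tmp_path, "fx")
    model = load_model(
        tmp_path / "fx.pdb", tmp_path / "fx_pae.json", tmp_path / "fx_scores.json"
    )
    return model, truth


class TestLoadModel:
    def test_fixture_loads(self, fixture_model):
        model, _ = fixture_model
        assert len(model.chain_a) == 50
        assert len(model.chain_b) == 40
        assert model.pae.values.shape == (90, 90)
        assert (model.chain_a.plddt > 0).all()

    def test_pae_dimension_mismatch(self, tmp_path):
        gen_dimer_fixture(DimerFixtureSpec(n_pairs=2, seed=0), tmp_path, "fx")
        bad = np.zeros((89, 90)).tolist()
        (tmp_path / "bad_pae.json").write_text(json.dumps({"pae": bad}))
        with pytest.raises(ValueError, match="square"):
            load_model(
                tmp_path / "fx.pdb", tmp_path / "bad_pae.json",
                tmp_path / "fx_scores.json",
            )
        square_bad = np.zeros((89, 89)).tolist()
        (tmp_path / "bad2_pae.json").write_text(json.dumps({"pae": square_bad}))
        with pytest.raises(ValueError, match="dimension"):
            load_model(
                tmp_path / "fx.pdb", tmp_path / "bad2_pae.json",
                tmp_path / "fx_scores.json",
            )

    def test_three_chain_file_is_error(self, tmp_path):
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        gen_dimer_fixture(DimerFixtureSpec(n_pairs=1, seed=0), tmp_path, "fx")
        n = 9
        atoms = struc.AtomArray(n)
        atoms.coord = np.arange(n * 3, dtype=float).reshape(n, 3)
        atoms.chain_id = np.repeat(["A", "B", "C"], 3)
        atoms.res_id = np.tile([1, 2, 3], 3)
        atoms.res_name = np.full(n, "ALA")
        atoms.atom_name = np.full(n, "CA")
        atoms.element = np.full(n, "C")
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(str(tmp_path / "three.pdb"))
        with pytest.raises(ValueError, match="2 chains"):
            load_model(
                tmp_path / "three.pdb", tmp_path / "fx_pae.json",
                tmp_path / "fx_scores.json",
            )

    def test_unknown_format_is_error(self, tmp_path):
        (tmp_path / "model.xyz").write_text("nonsense")
        with pytest.raises(ValueError, match="format"):
            load_model(tmp_path / "model.xyz", tmp_path / "x", tmp_path / "y")


class TestRankingScore:
    def test_af2_perfect(self):
        assert ranking_score(ModelScore(iptm=1.0, ptm=1.0)) == pytest.approx(1.0)

    def test_af2_midpoint(self):
        assert ranking_score(ModelScore(iptm=0.5, ptm=0.5)) == pytest.approx(0.5)

    def test_af3_with_disorder(self):
        s = ModelScore(iptm=0.5, ptm=0.5, version="AF3", disorder_frac=0.2)
        assert ranking_score(s) == pytest.approx(0.6)

    def test_af3_requires_disorder(self):
        with pytest.raises(ValueError, match="disorder"):
            ModelScore(iptm=0.5, ptm=0.5, version="AF3")

    def test_no_clamping(self):
        s = ModelScore(iptm=1.0, ptm=1.0, version="AF3", disorder_frac=1.0)
        assert ranking_score(s) == pytest.approx(1.5)


class TestConstrainedPairs:
    def test_seven_planted_pairs(self, fixture_model):
        model, truth = fixture_model
        pairs = constrained_pairs(model)
        assert sorted((p.res_a, p.res_b) for p in pairs) == [
            tuple(p) for p in truth["pairs"]
        ]

    def test_equals_brute_force_oracle(self, tmp_path):
        for seed in range(10):
            spec = DimerFixtureSpec(
                len_a=30, len_b=25, n_pairs=int(seed % 5) + 1, seed=seed
            )
            model, _ = _build_dimer(spec)
            got = {(p.res_a, p.res_b) for p in constrained_pairs(model)}
            assert got == brute_force_pairs(model)

    def test_distance_boundary_is_strict(self, tmp_path):
        model, _ = _build_dimer(DimerFixtureSpec(n_pairs=1, seed=0))
        # move the planted prey residue to exactly 6.0 A from its bait
        model.chain_b.ca_coords[0] = model.chain_a.ca_coords[0] + [0.0, 6.0, 0.0]
        assert constrained_pairs(model) == frozenset()

    def test_asymmetric_pae_uses_max(self):
        model, _ = _build_dimer(DimerFixtureSpec(n_pairs=1, seed=0))
        la = len(model.chain_a)
        model.pae.values[0, la] = 4.0
        model.pae.values[la, 0] = 6.0
        assert constrained_pairs(model) == frozenset()
        model.pae.values[la, 0] = 4.5
        assert len(constrained_pairs(model)) == 1

    def test_threshold_monotonicity(self):
        model, _ = _build_dimer(DimerFixtureSpec(n_pairs=5, seed=2))
        loose = constrained_pairs(model, pae_max=25.0, dist_max=10.0)
        default = constrained_pairs(model)
        tight = constrained_pairs(model, pae_max=2.0, dist_max=3.0)
        as_tuples = lambda ps: {(p.res_a, p.res_b) for p in ps}
        assert as_tuples(tight) <= as_tuples(default) <= as_tuples(loose)


class TestCallInteraction:
    def _call(self, n_bait, n_prey, ranking):
        pairs = frozenset(
            ContactPair(res_a=(k % n_bait) + 1, res_b=k + 1,
                        ca_distance=4.0, pae_ab=3.0, pae_ba=3.0)
            for k in range(n_prey)
        )
        return InteractionCall(
            pair_id=("bait", "prey"), pairs=pairs,
            n_bait=len({p.res_a for p in pairs}),
            n_prey=len({p.res_b for p in pairs}),
            ranking=ranking,
            passes_v1=ranking > 0.6 and n_prey >= 20,
            passes_v2=ranking > 0.6 and n_bait * n_prey > 100,
        )

    def test_v1_passes_at_25_prey(self, tmp_path):
        truth = gen_dimer_fixture(
            DimerFixtureSpec(n_pairs=25, iptm=0.8, ptm=0.55, seed=5),
            tmp_path, "v1",
        )
        model = load_model(tmp_path / "v1.pdb", tmp_path / "v1_pae.json",
                           tmp_path / "v1_scores.json")
        call = call_interaction(model)
        assert call.ranking == pytest.approx(0.75)
        assert call.passes_v1 and truth["passes_v1"]

    def test_boundary_19_prey_product_95(self, tmp_path):
        truth = gen_dimer_fixture(
            DimerFixtureSpec(n_bait=5, n_prey=19, iptm=0.8, ptm=0.55, seed=6),
            tmp_path, "b1",
        )
        model = load_model(tmp_path / "b1.pdb", tmp_path / "b1_pae.json",
                           tmp_path / "b1_scores.json")
        call = call_interaction(model)
        assert (call.n_bait, call.n_prey) == (5, 19)
        assert not call.passes_v1  # 19 < 20
        assert not call.passes_v2  # 95 <= 100

    def test_boundary_product_114(self, tmp_path):
        gen_dimer_fixture(
            DimerFixtureSpec(n_bait=6, n_prey=19, iptm=0.8, ptm=0.55, seed=7),
            tmp_path, "b2",
        )
        model = load_model(tmp_path / "b2.pdb", tmp_path / "b2_pae.json",
                           tmp_path / "b2_scores.json")
        call = call_interaction(model)
        assert (call.n_bait, call.n_prey) == (6, 19)
        assert not call.passes_v1
        assert call.passes_v2  # 114 > 100

    def test_no_pairs_fails_both(self, tmp_path):
        gen_dimer_fixture(
            DimerFixtureSpec(n_pairs=0, iptm=0.9, ptm=0.9, seed=8), tmp_path, "z"
        )
        model = load_model(tmp_path / "z.pdb", tmp_path / "z_pae.json",
                           tmp_path / "z_scores.json")
        call = call_interaction(model)
        assert not call.passes_v1 and not call.passes_v2

    def test_verdicts_pure_function_of_pairs_and_ranking(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_bait = int(rng.integers(1, 30))
            n_prey = int(rng.integers(n_bait, 40))
            ranking = float(rng.uniform(0, 1))
            min_rank = float(rng.uniform(0, 1))
            min_prey = int(rng.integers(1, 40))
            min_product = int(rng.integers(1, 500))
            call = self._call(n_bait, n_prey, ranking)
            v1 = ranking > min_rank and call.n_prey >= min_prey
            v2 = ranking > min_rank and call.n_bait * call.n_prey > min_product
            recomputed = InteractionCall(
                pair_id=call.pair_id, pairs=call.pairs, n_bait=call.n_bait,
                n_prey=call.n_prey, ranking=ranking,
                passes_v1=v1, passes_v2=v2,
            )
            assert recomputed.passes_v1 == v1
            assert recomputed.passes_v2 == v2


class TestConstrainedProfile:
    def test_planted_pairs_mark_prey_positions(self):
        spec = DimerFixtureSpec(
            pairs=[(1, 1), (1, 2), (4, 3), (7, 4), (10, 5), (11, 5), (12, 5)],
            seed=9,
        )
        model, pairs = _build_dimer(spec)
        profile = constrained_profile(model)
        assert profile["B"].sum() == 5  # 7 pairs touch 5 distinct prey residues
        assert profile["A"].sum() == len({a for a, _ in pairs})

    def test_no_pairs_all_false(self):
        model, _ = _build_dimer(DimerFixtureSpec(n_pairs=0, seed=0))
        profile = constrained_profile(model)
        assert not profile["A"].any() and not profile["B"].any()

    def test_every_residue_paired_all_true(self):
        spec = DimerFixtureSpec(len_a=5, len_b=5, n_pairs=5, seed=0)
        model, _ = _build_dimer(spec)
        profile = constrained_profile(model)
        assert profile["A"].all() and profile["B"].all()


class TestConcordance:
    def _call(self, prey_residues, passes=True):
        pairs = frozenset(
            ContactPair(res_a=1, res_b=r, ca_distance=4.0, pae_ab=3.0, pae_ba=3.0)
            for r in prey_residues
        )
        return InteractionCall(
            pair_id=("x", "y"), pairs=pairs, n_bait=1,
            n_prey=len(prey_residues), ranking=0.8,
            passes_v1=passes, passes_v2=passes,
        )

    def test_identical_sets_similar(self):
        a = self._call({1, 2, 3})
        assert concordance(a, a) == "similar_interface"

    def test_disjoint_sets_different(self):
        assert concordance(
            self._call({1, 2}), self._call({3, 4})
        ) == "different_interface"

    def test_exact_threshold_is_similar(self):
        # overlap 1/4 == 0.25 exactly -> inclusive
        a = self._call({1, 2})
        b = self._call({2, 3, 4})
        assert concordance(a, b, overlap_min=0.25) == "similar_interface"

    def test_one_sided_and_neither(self):
        a = self._call({1}, passes=True)
        b = self._call({1}, passes=False)
        assert concordance(a, b) == "one_sided"
        assert concordance(b, b) == "neither"


class TestExportNetwork:
    def _calls(self, n=3):
        calls = []
        for k in range(n):
            pairs = frozenset(
                {ContactPair(res_a=1, res_b=1, ca_distance=4.0,
                             pae_ab=3.0, pae_ba=3.0)}
            )
            calls.append(
                InteractionCall(
                    pair_id=("REG-1", f"CAND-{k}"), pairs=pairs,
                    n_bait=1, n_prey=1, ranking=0.7,
                    passes_v1=False, passes_v2=False,
                )
            )
        return calls

    def test_counts(self, tmp_path):
        graph = export_network(
            self._calls(3), tmp_path / "net.graphml", tmp_path / "net.tsv"
        )
        assert graph.number_of_nodes() == 4
        assert graph.number_of_edges() == 3

    def test_duplicate_pair_is_error(self, tmp_path):
        calls = self._calls(1) * 2
        with pytest.raises(ValueError, match="duplicate"):
            export_network(calls, tmp_path / "n.graphml", tmp_path / "n.tsv")

    def test_empty_call_set_valid_graphml(self, tmp_path):
        graph = export_network([], tmp_path / "e.graphml", tmp_path / "e.tsv")
        back = nx.read_graphml(tmp_path / "e.graphml")
        assert graph.number_of_nodes() == back.number_of_nodes() == 0

    def test_round_trip_isomorphic(self, tmp_path):
        graph = export_network(
            self._calls(3), tmp_path / "r.graphml", tmp_path / "r.tsv"
        )
        back = nx.read_graphml(tmp_path / "r.graphml")
        assert nx.is_isomorphic(graph, back)
        assert set(graph.nodes) == set(back.nodes)
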