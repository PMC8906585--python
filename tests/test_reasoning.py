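import itertools

import numpy as np
import pytest

from causalpath import (
    CausalKG,
    CausalPath,
    KGError,
    NodeKind,
    ReasoningConfig,
    Signature,
    SyntheticSpec,
    enumerate_causal_paths,
    enumerate_paths_to_disease,
    extract_mechanism_subgraph,
    generate_benchmark,
    infer_regulation,
    is_anti_correlated,
    is_concordant,
    is_drug_prioritized,
    prioritize_pairs,
    prioritize_targets,
)
from causalpath.reasoning import PrioritizationResult, PathVerdict

from conftest import random_typed_kg


def make_path(signs, n_proteins=None, source_kind=NodeKind.CHEMICAL):
    """A linear path S -> p1 -> ... -> pk -> X with the given edge signs."""
    k = len(signs) - 1 if n_proteins is None else n_proteins
    nodes = ("S",) + tuple(f"p{i}" for i in range(1, k + 1)) + ("X",)
    kinds = (source_kind,) + (NodeKind.PROTEIN,) * k + (NodeKind.DISEASE,)
    return CausalPath(nodes, tuple(signs), kinds)


def brute_force_paths(kg, source, target, lmax):
    """Independent oracle: every permutation of interior proteins checked
    against edge existence, expanded over parallel signed edges."""
    adj = {}
    for e in kg.edges():
        adj.setdefault(e.source, {}).setdefault(e.target, []).append(e.sign)
    proteins = [p for p in kg.nodes(NodeKind.PROTEIN) if p not in (source, target)]
    found = []
    for k in range(1, lmax):
        for interior in itertools.permutations(proteins, k):
            nodes = (source,) + interior + (target,)
            options = []
            for u, v in zip(nodes, nodes[1:]):
                signs = adj.get(u, {}).get(v)
                if not signs:
                    options = None
                    break
                options.append(sorted(signs))
            if options is None:
                continue
            for combo in itertools.product(*options):
                found.append((nodes, combo))
    return sorted(found)


class TestEnumeration:
    def test_fixture_has_two_paths(self, g1):
        paths = enumerate_causal_paths(g1, "D", "X", 7)
        assert [(p.nodes, p.edge_signs) for p in paths] == [
            (("D", "P1", "P2", "P3", "X"), (-1, 1, -1, 1)),
            (("D", "P2", "P3", "X"), (1, -1, 1)),
        ]

    def test_length_bound_filters(self, g1):
        paths = enumerate_causal_paths(g1, "D", "X", 3)
        assert [p.nodes for p in paths] == [("D", "P2", "P3", "X")]

    def test_cycle_does_not_add_paths(self, g1):
        with_cycle = g1.copy()
        with_cycle.add_edge("P3", "P1", 1)  # closes P1->P2->P3->P1
        before = [(p.nodes, p.edge_signs) for p in enumerate_causal_paths(g1, "D", "X", 7)]
        after = [(p.nodes, p.edge_signs) for p in enumerate_causal_paths(with_cycle, "D", "X", 7)]
        assert after == before == sorted(brute_force_paths(with_cycle, "D", "X", 7))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        kg = random_typed_kg(rng)
        for source in kg.nodes(NodeKind.CHEMICAL):
            for target in kg.nodes(NodeKind.DISEASE):
                for lmax in (2, 4, 7):
                    got = [
                        (p.nodes, p.edge_signs)
                        for p in enumerate_causal_paths(kg, source, target, lmax)
                    ]
                    assert got == brute_force_paths(kg, source, target, lmax)

    def test_matches_networkx_simple_paths(self, seed=7):
        # cross-check node sequences against the networkx enumeration
        import networkx as nx

        kg = random_typed_kg(np.random.default_rng(seed))
        for source in kg.nodes(NodeKind.CHEMICAL):
            for target in kg.nodes(NodeKind.DISEASE):
                ours = {p.nodes for p in enumerate_causal_paths(kg, source, target, 7)}
                nxs = {
                    tuple(p)
                    for p in nx.all_simple_paths(kg.graph, source, target, cutoff=7)
                    if len(p) >= 3
                }
                assert ours == nxs

    def test_wrong_kind_or_missing_node_rejected(self, g1):
        with pytest.raises(KGError):
            enumerate_causal_paths(g1, "P1", "X", 7)  # protein source in drug mode
        with pytest.raises(KGError):
            enumerate_causal_paths(g1, "D", "P1", 7)  # protein target
        with pytest.raises(KGError):
            enumerate_causal_paths(g1, "ghost", "X", 7)


class TestInferRegulation:
    def test_alternating_signs(self):
        path = make_path([-1, 1, -1, 1])
        assert infer_regulation(path) == {"p1": -1, "p2": -1, "p3": 1}
        assert path.cumulative_effect == 1

    @pytest.mark.parametrize("length", [2, 4, 7])
    def test_all_activation_is_identity(self, length):
        path = make_path([1] * length)
        assert set(infer_regulation(path).values()) == {1}
        assert path.cumulative_effect == 1

    def test_matches_second_pass_products(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            signs = [int(s) for s in rng.choice([1, -1], size=rng.integers(2, 8))]
            path = make_path(signs)
            regs = infer_regulation(path)
            running = 1
            for i, s in enumerate(signs[:-1]):
                running *= s
                assert regs[f"p{i + 1}"] == running
            assert path.cumulative_effect == running * signs[-1]

    def test_flipping_one_edge_flips_downstream_only(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            signs = [int(s) for s in rng.choice([1, -1], size=6)]
            flip_at = int(rng.integers(0, 6))
            flipped = list(signs)
            flipped[flip_at] *= -1
            regs, regs_f = (
                infer_regulation(make_path(s)) for s in (signs, flipped)
            )
            for i in range(1, 6):
                if i <= flip_at:
                    assert regs_f[f"p{i}"] == regs[f"p{i}"]
                else:
                    assert regs_f[f"p{i}"] == -regs[f"p{i}"]
            assert make_path(flipped).cumulative_effect == -make_path(signs).cumulative_effect


def sig(values, context="drug", cid="S"):
    return Signature(values, context, cid)


class TestChecks:
    # the alternating fixture path: inferred {p1:-1, p2:-1, p3:+1}
    PATH = None

    def setup_method(self):
        self.path = make_path([-1, 1, -1, 1])

    def test_exact_match_is_concordant_at_zero_budget(self):
        ok, errors = is_concordant(
            self.path, sig({"p1": -1, "p2": -1, "p3": 1}), ReasoningConfig(max_errors=0)
        )
        assert (ok, errors) == (True, 0)

    def test_single_disagreement_within_unit_budget(self):
        ok, errors = is_concordant(
            self.path, sig({"p1": -1, "p2": 1, "p3": 1}), ReasoningConfig(max_errors=1)
        )
        assert (ok, errors) == (True, 1)

    def test_unmeasured_proteins_count_as_errors(self):
        ok, errors = is_concordant(
            self.path, sig({"p1": -1}), ReasoningConfig(max_errors=1)
        )
        assert (ok, errors) == (False, 2)

    def test_exact_negation_is_anti_correlated(self):
        ok, errors = is_anti_correlated(
            self.path,
            sig({"p1": 1, "p2": 1, "p3": -1}, context="disease", cid="X"),
            ReasoningConfig(max_errors=0),
        )
        assert (ok, errors) == (True, 0)

    def test_identical_signature_fails_anti_correlation(self):
        ok, errors = is_anti_correlated(
            self.path,
            sig({"p1": -1, "p2": -1, "p3": 1}, context="disease", cid="X"),
            ReasoningConfig(max_errors=1),
        )
        assert (ok, errors) == (False, 3)

    def test_zero_calls_configurable(self):
        s = sig({"p1": 0, "p2": -1, "p3": 1})
        assert is_concordant(self.path, s, ReasoningConfig(max_errors=0))[1] == 1
        assert (
            is_concordant(
                self.path, s, ReasoningConfig(max_errors=0, treat_zero_as_error=False)
            )[1]
            == 0
        )

    def test_anti_correlation_equals_concordance_on_negated_path(self):
        # negating every inferred regulation (flip the first edge sign) turns
        # the anti-correlation check into the concordance check
        rng = np.random.default_rng(4)
        states = [-1, 0, 1, None]
        for _ in range(200):
            signs = [int(x) for x in rng.choice([1, -1], size=4)]
            path = make_path(signs)
            negated = make_path([-signs[0]] + signs[1:])
            values = {}
            for i in range(1, 4):
                v = states[int(rng.integers(0, 4))]
                if v is not None:
                    values[f"p{i}"] = v
            s = sig(values, context="disease", cid="X")
            assert (
                is_anti_correlated(path, s)[1] == is_concordant(negated, s)[1]
            )


class TestDrugPrioritization:
    def test_fixture_pair_prioritized(self, g1, g1_signatures):
        drug_sig, disease_sig = g1_signatures
        res = is_drug_prioritized(g1, "D", "X", drug_sig, disease_sig)
        assert res.prioritized
        assert res.n_surviving >= 1
        assert res.n_surviving <= res.n_concordant <= res.n_paths_total

    def test_disease_signature_equal_to_drug_fails(self, g1, g1_signatures):
        drug_sig, _ = g1_signatures
        mirrored = Signature(dict(drug_sig.values), "disease", "X")
        res = is_drug_prioritized(g1, "D", "X", drug_sig, mirrored)
        assert not res.prioritized

    def test_inhibition_filter_discards_activating_paths(self, g1):
        # signatures match the activating path D->P1->P2->P3->X exactly
        drug_sig = Signature({"P1": -1, "P2": -1, "P3": 1}, "drug", "D")
        disease_sig = Signature({"P1": 1, "P2": 1, "P3": -1}, "disease", "X")
        strict = is_drug_prioritized(g1, "D", "X", drug_sig, disease_sig)
        assert not strict.prioritized
        relaxed = is_drug_prioritized(
            g1, "D", "X", drug_sig, disease_sig,
            ReasoningConfig(require_disease_inhibition=False),
        )
        assert relaxed.prioritized

    def test_planted_pairs_recovered_and_decoys_rejected(self):
        for seed in range(8):
            bench = generate_benchmark(
                SyntheticSpec(n_chemicals=4, n_proteins=30, n_diseases=3,
                              n_planted_pairs=2, seed=seed)
            )
            config = ReasoningConfig(max_errors=0)
            for chem, dis in sorted(bench.truth.planted_positive_pairs):
                res = is_drug_prioritized(
                    bench.kg, chem, dis,
                    bench.drug_signatures[chem], bench.disease_signatures[dis], config,
                )
                assert res.prioritized, (seed, chem, dis)


class TestPrioritizePairs:
    def test_single_planted_pair_found_exactly(self):
        bench = generate_benchmark(
            SyntheticSpec(n_chemicals=2, n_proteins=25, n_diseases=2,
                          n_planted_pairs=1, p_chem_prot=0.02, p_prot_prot=0.02,
                          p_prot_dis=0.02, seed=1)
        )
        report = prioritize_pairs(
            bench.kg, bench.drug_signatures, bench.disease_signatures,
            ReasoningConfig(max_errors=0),
        )
        assert report.prioritized_pairs == bench.truth.planted_positive_pairs

    def test_missing_drug_skipped_and_reported(self, g1, g1_signatures):
        drug_sig, disease_sig = g1_signatures
        ghost = Signature({"P1": 1}, "drug", "ghost")
        report = prioritize_pairs(
            g1, {"D": drug_sig, "ghost": ghost}, {"X": disease_sig}
        )
        assert report.skipped_drugs == ["ghost"]
        assert {r.source_id for r in report.results} == {"D"}

    def test_funnel_is_non_increasing(self):
        bench = generate_benchmark(SyntheticSpec(seed=2))
        funnel = prioritize_pairs(
            bench.kg, bench.drug_signatures, bench.disease_signatures
        ).funnel
        assert (
            funnel["pairs_evaluated"]
            >= funnel["pairs_with_path"]
            >= funnel["pairs_concordant"]
            >= funnel["pairs_prioritized"]
        )

    def test_error_budget_and_lmax_monotonicity(self):
        bench = generate_benchmark(SyntheticSpec(seed=4))
        args = (bench.kg, bench.drug_signatures, bench.disease_signatures)
        by_budget = [
            prioritize_pairs(*args, ReasoningConfig(max_errors=k)).prioritized_pairs
            for k in (0, 1, 2)
        ]
        assert by_budget[0] <= by_budget[1] <= by_budget[2]
        by_lmax = [
            prioritize_pairs(*args, ReasoningConfig(lmax=L)).prioritized_pairs
            for L in (3, 5, 7)
        ]
        assert by_lmax[0] <= by_lmax[1] <= by_lmax[2]

    def test_deterministic_ranked_output(self):
        bench = generate_benchmark(SyntheticSpec(seed=5))
        runs = [
            [
                (r.source_id, r.target_id, r.n_paths_total, r.n_concordant, r.n_surviving)
                for r in prioritize_pairs(
                    bench.kg, bench.drug_signatures, bench.disease_signatures
                ).results
            ]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


class TestTargets:
    @staticmethod
    def planted_regulator_kg():
        """One regulator protein feeding 5 concordant 2-edge paths into X."""
        kg = CausalKG()
        kg.add_node("X", NodeKind.DISEASE)
        kg.add_node("R", NodeKind.PROTEIN)
        for i in range(5):
            mid = f"m{i}"
            kg.add_node(mid, NodeKind.PROTEIN)
            kg.add_edge("R", mid, 1)
            kg.add_edge(mid, "X", 1)
        sig = Signature({f"m{i}": 1 for i in range(5)}, "disease", "X")
        return kg, sig

    def test_planted_regulator_ranked_first(self):
        kg, disease_sig = self.planted_regulator_kg()
        rankings = prioritize_targets(kg, "X", disease_sig, ReasoningConfig(max_errors=0))
        assert rankings[0].protein_id == "R"
        assert rankings[0].n_concordant_paths == 5
        # R, the 5 intermediates, and X all appear in the concordant paths
        assert rankings[0].n_nodes_in_concordant_paths == 7

    def test_disease_without_incoming_paths(self):
        kg = CausalKG()
        kg.add_node("X", NodeKind.DISEASE)
        kg.add_node("p", NodeKind.PROTEIN)
        assert prioritize_targets(kg, "X", Signature({}, "disease", "X")) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_counts_match_per_protein_forward_enumeration(self, seed):
        kg = random_typed_kg(np.random.default_rng(seed), max_nodes=10)
        diseases = kg.nodes(NodeKind.DISEASE)
        rng = np.random.default_rng(seed + 100)
        values = {
            p: int(v)
            for p, v in zip(kg.nodes(NodeKind.PROTEIN), rng.choice([-1, 0, 1], size=50))
        }
        for disease in diseases:
            disease_sig = Signature(values, "disease", disease)
            config = ReasoningConfig(max_errors=1)
            rankings = {
                r.protein_id: r.n_concordant_paths
                for r in prioritize_targets(kg, disease, disease_sig, config)
            }
            expected = {}
            for protein in kg.nodes(NodeKind.PROTEIN):
                paths = enumerate_causal_paths(kg, protein, disease, config.lmax, mode="target")
                n = sum(1 for p in paths if is_concordant(p, disease_sig, config)[0])
                if n:
                    expected[protein] = n
            assert rankings == expected


class TestMechanismSubgraph:
    def test_single_path_subgraph(self):
        path = make_path([1, -1, 1, -1])
        res = PrioritizationResult("S", "X", 1, 1, 1, 1, [PathVerdict(path, 0, True, 0, True)])
        sub = extract_mechanism_subgraph(res)
        assert sub.n_nodes == 5 and sub.n_edges == 4
        assert all(
            d["traversal_count"] == 1 for _, _, d in sub.graph.edges(data=True)
        )

    def test_shared_edge_counted_twice(self, g1, g1_signatures):
        relaxed = ReasoningConfig(require_disease_inhibition=False, max_errors=3)
        drug_sig, disease_sig = g1_signatures
        res = is_drug_prioritized(g1, "D", "X", drug_sig, disease_sig, relaxed)
        assert res.n_surviving == 2  # both fixture paths survive a loose budget
        sub = extract_mechanism_subgraph(res)
        assert sub.graph.edges["P3", "X", 1]["traversal_count"] == 2

    def test_node_set_is_union_of_path_nodes(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n_paths = int(rng.integers(1, 4))
            verdicts = []
            for _ in range(n_paths):
                signs = [int(s) for s in rng.choice([1, -1], size=rng.integers(2, 6))]
                verdicts.append(PathVerdict(make_path(signs), 0, True, 0, True))
            res = PrioritizationResult("S", "X", n_paths, n_paths, n_paths, n_paths, verdicts)
            sub = extract_mechanism_subgraph(res)
            assert set(sub.nodes()) == set().union(*(set(v.path.nodes) for v in verdicts))

    def test_rejects_non_prioritized_result(self):
        res = PrioritizationResult("S", "X", 3, 3, 0, 0, [])
        with pytest.raises(ValueError):
            extract_mechanism_subgraph(res)
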