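import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpsignal import (
    SimulationConfig,
    TipCharacter,
    UninformativeCharacterError,
    fitch_steps,
    hamming_distances,
    neighbor_joining,
    parse_newick,
    randomization_test,
    results_table,
    retention_index,
    run_signal_suite,
    simulate,
    step_bounds,
)

from conftest import make_metadata
from oracles import brute_force_steps, exact_permutation_p, random_character, random_tree


def char(name="trait", **tip_states):
    return TipCharacter(name, dict(tip_states))


def int_char(states: dict) -> TipCharacter:
    return TipCharacter("trait", {
        t: (None if s is None else f"state{s}") for t, s in states.items()
    })


class TestFitchSteps:
    def test_perfect_split_one_step(self):
        tree = parse_newick("((A,B),(C,D));")
        assert fitch_steps(tree, char(A="x", B="x", C="y", D="y")) == 1

    def test_invariant_character_zero_steps(self):
        tree = parse_newick("((A,B),(C,D));")
        assert fitch_steps(tree, char(A="x", B="x", C="x", D="x")) == 0

    def test_missing_tips_force_no_steps(self):
        tree = parse_newick("((A,B),(C,D));")
        c = char(A="x", B=None, C=None, D="y")
        assert fitch_steps(tree, c) == 1

    def test_no_scored_tips_errors(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="no scored tips"):
            fitch_steps(tree, char(A=None, B=None, C=None, D=None))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_trees(self, seed):
        """Exhaustive-assignment oracle, including polytomies and missing."""
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(4, 8))
        names = [f"t{i}" for i in range(n_tips)]
        tree = random_tree(rng, names, allow_polytomies=True)
        k = int(rng.integers(2, 5))
        states = random_character(rng, names, k, missing_prob=0.25)
        expected = brute_force_steps(tree, states, k)
        assert fitch_steps(tree, int_char(states)) == expected


class TestStepBounds:
    def test_modal_state_example(self):
        # 6 scored tips, states x:4 y:2 -> M=1, G=2
        tree = parse_newick("((A,B,C),(D,(E,F)));")
        c = char(A="x", B="x", C="x", D="x", E="y", F="y")
        assert step_bounds(tree, c) == (1, 2)

    def test_invariant_character(self):
        tree = parse_newick("((A,B),C);")
        assert step_bounds(tree, char(A="x", B="x", C="x")) == (0, 0)

    def test_all_distinct_states(self):
        tree = parse_newick("((A,B),(C,(D,E)));")
        c = char(A="a", B="b", C="c", D="d", E="e")
        assert step_bounds(tree, c) == (4, 4)

    @pytest.mark.parametrize("seed", range(10))
    def test_G_equals_star_tree_steps(self, seed):
        rng = np.random.default_rng(100 + seed)
        names = [f"t{i}" for i in range(6)]
        tree = random_tree(rng, names)
        k = int(rng.integers(2, 4))
        states = random_character(rng, names, k, missing_prob=0.2)
        _, G = step_bounds(tree, int_char(states))
        star = parse_newick("(" + ",".join(names) + ");")
        assert G == brute_force_steps(star, states, k)


class TestRetentionIndex:
    def test_perfect_congruence_is_one(self):
        tree = parse_newick("((A,B),(C,D));")
        assert retention_index(tree, char(A="x", B="x", C="y", D="y")) == 1.0

    def test_maximal_homoplasy_is_zero(self):
        # S = G: states alternate across the perfect-split tree
        tree = parse_newick("((A,C),(B,D));")
        c = char(A="x", B="x", C="y", D="y")
        assert retention_index(tree, c) == 0.0

    def test_five_tip_example_against_oracle(self):
        tree = parse_newick("((A,B),(C,(D,E)));")
        states = {"A": 0, "B": 1, "C": 0, "D": 1, "E": 1}
        S = brute_force_steps(tree, states, 2)
        c = int_char(states)
        assert fitch_steps(tree, c) == S
        assert step_bounds(tree, c) == (1, 2)
        assert retention_index(tree, c) == (2 - S) / (2 - 1)

    def test_uninformative_flagged_not_nan(self):
        tree = parse_newick("((A,B),C);")
        with pytest.raises(UninformativeCharacterError):
            retention_index(tree, char(A="x", B="x", C="x"))

    @pytest.mark.parametrize("seed", range(40))
    def test_bounds_and_extremes_property(self, seed):
        """M <= S <= G; RI in [0,1]; RI=1 iff S=M; RI=0 iff S=G."""
        rng = np.random.default_rng(1000 + seed)
        n_tips = int(rng.integers(4, 9))
        names = [f"t{i}" for i in range(n_tips)]
        tree = random_tree(rng, names)
        states = random_character(rng, names, int(rng.integers(2, 4)), 0.2)
        c = int_char(states)
        S = fitch_steps(tree, c)
        M, G = step_bounds(tree, c)
        assert M <= S <= G
        if G > M:
            ri = retention_index(tree, c)
            assert 0.0 <= ri <= 1.0
            assert (ri == 1.0) == (S == M)
            assert (ri == 0.0) == (S == G)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    n_tips=st.integers(4, 10),
    k=st.integers(2, 5),
    missing=st.floats(0.0, 0.4),
)
def test_step_count_sandwiched_between_bounds(seed, n_tips, k, missing):
    """Property: M <= S <= G for any tree and scorable character."""
    rng = np.random.default_rng(seed)
    names = [f"t{i}" for i in range(n_tips)]
    tree = random_tree(rng, names)
    c = int_char(random_character(rng, names, k, missing))
    S = fitch_steps(tree, c)
    M, G = step_bounds(tree, c)
    assert M <= S <= G


class TestRootAndOrderInvariance:
    @pytest.mark.parametrize("seed", range(10))
    def test_reroot_leaves_statistics_unchanged(self, seed):
        rng = np.random.default_rng(2000 + seed)
        names = [f"t{i}" for i in range(7)]
        tree = random_tree(rng, names, with_lengths=True)
        states = random_character(rng, names, 3, missing_prob=0.15)
        c = int_char(states)
        S = fitch_steps(tree, c)
        bounds = step_bounds(tree, c)
        internal = [
            n for n in tree.non_tips(include_self=False) if n.parent is not None
        ]
        target = internal[int(rng.integers(len(internal)))] if internal else None
        if target is None:
            pytest.skip("no internal edge to reroot on")
        rerooted = tree.root_at(target)
        assert fitch_steps(rerooted, c) == S
        assert step_bounds(rerooted, c) == bounds
        if bounds[1] > bounds[0]:
            r1 = randomization_test(tree, c, n_reps=200, seed=5)
            r2 = randomization_test(rerooted, c, n_reps=200, seed=5)
            assert r1.p_value == r2.p_value

    def test_tip_storage_order_irrelevant(self):
        t1 = parse_newick("((A,B),(C,(D,E)));")
        t2 = parse_newick("(((E,D),C),(B,A));")
        c = char(A="x", B="y", C="x", D="y", E="y")
        assert fitch_steps(t1, c) == fitch_steps(t2, c)
        r1 = randomization_test(t1, c, n_reps=300, seed=8)
        r2 = randomization_test(t2, c, n_reps=300, seed=8)
        assert r1.S == r2.S and r1.RI == r2.RI


class TestRandomizationTest:
    def test_deterministic_given_seed(self):
        tree = parse_newick("((A,B),(C,(D,E)));")
        c = char(A="x", B="x", C="y", D="y", E="x")
        r1 = randomization_test(tree, c, n_reps=500, seed=99)
        r2 = randomization_test(tree, c, n_reps=500, seed=99)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_RIs, r2.null_RIs)

    def test_p_lower_bound_when_no_null_reaches_observed(self):
        # perfectly congruent character on a tree where most permutations break it
        tree = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        c = char(A="x", B="x", C="x", D="x", E="y", F="y", G="y", H="y")
        res = randomization_test(tree, c, n_reps=999, seed=1)
        assert res.RI == 1.0
        n_hits = int((res.null_RIs >= 1.0).sum())
        assert res.p_value == (1 + n_hits) / 1000

    def test_add_one_correction_keeps_p_positive(self):
        tree = parse_newick("((A,B),(C,D));")
        c = char(A="x", B="y", C="x", D="y")
        res = randomization_test(tree, c, n_reps=50, seed=2)
        assert 0 < res.p_value <= 1

    def test_monte_carlo_close_to_exact_enumeration(self):
        """5-tip tree, binary 3+2 character: exhaustive null vs Monte Carlo."""
        tree = parse_newick("((A,B),(C,(D,E)));")
        names = ["A", "B", "C", "D", "E"]
        states = [0, 0, 0, 1, 1]
        p_exact, n_assign = exact_permutation_p(tree, names, states, 2)
        assert n_assign == 10
        res = randomization_test(tree, int_char(dict(zip(names, states))),
                                 n_reps=9999, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / res.n_reps)
        assert abs(res.p_value - p_exact) <= 3 * se

    def test_uninformative_character_rejected(self):
        tree = parse_newick("((A,B),C);")
        with pytest.raises(UninformativeCharacterError):
            randomization_test(tree, char(A="x", B="x", C="x"), n_reps=9, seed=1)

    def test_seed_required(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="seed"):
            randomization_test(tree, char(A="x", B="y", C="x", D="y"), n_reps=9)


class TestSignalSuite:
    @pytest.fixture
    def trees_and_meta(self):
        ids = list("ABCDEFGH")
        meta = make_metadata(
            ids,
            borough=["BK"] * 4 + ["MN"] * 4,
            object=["bench", "rail"] * 4,
            constant=["same"] * 8,
        )
        t1 = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        t2 = parse_newick("(((A,E),(B,F)),((C,G),(D,H)));")
        return {"global": t1, "alt": t2}, meta

    def test_cardinality_all_informative(self, trees_and_meta):
        trees, meta = trees_and_meta
        results = run_signal_suite(trees, meta, ["borough", "object"],
                                   n_reps=99, seed=4)
        assert len(results) == 4
        assert {(r.tree_id, r.variable) for r in results} == {
            (t, v) for t in ("global", "alt") for v in ("borough", "object")
        }

    def test_constant_variable_skipped(self, trees_and_meta):
        trees, meta = trees_and_meta
        results = run_signal_suite(trees, meta, ["borough", "constant"],
                                   n_reps=99, seed=4)
        assert {(r.tree_id, r.variable) for r in results} == {
            ("global", "borough"), ("alt", "borough")
        }

    def test_unknown_variable_errors(self, trees_and_meta):
        trees, meta = trees_and_meta
        with pytest.raises(KeyError):
            run_signal_suite(trees, meta, ["nope"], n_reps=9, seed=4)

    def test_per_pair_seeds_stable_and_table_has_bh(self, trees_and_meta):
        trees, meta = trees_and_meta
        r1 = run_signal_suite(trees, meta, ["borough", "object"], n_reps=99, seed=4)
        r2 = run_signal_suite(trees, meta, ["borough", "object"], n_reps=99, seed=4)
        assert [r.seed for r in r1] == [r.seed for r in r2]
        assert [r.p_value for r in r1] == [r.p_value for r in r2]
        table = results_table(r1)
        assert {"variable", "tree_id", "S", "M", "G", "RI", "p_value",
                "p_bh"} <= set(table.columns)
        assert (table["p_bh"] >= table["p_value"] - 1e-12).all()

    def test_simulated_signal_detected_and_null_flat(self):
        strong = SimulationConfig(
            n_demes=4, samples_per_deme=12, n_variants=250,
            differentiation=0.35, missing_rate=0.1, seed=77,
        )
        m, meta = simulate(strong)
        tree = neighbor_joining(hamming_distances(m))
        res = randomization_test(
            tree, TipCharacter.from_metadata(meta, "deme"), n_reps=499, seed=6
        )
        assert res.p_value < 0.05
        null_cfg = strong.model_copy(update={"label_mode": "shuffled", "seed": 78})
        m2, meta2 = simulate(null_cfg)
        tree2 = neighbor_joining(hamming_distances(m2))
        res2 = randomization_test(
            tree2, TipCharacter.from_metadata(meta2, "deme"), n_reps=499, seed=6
        )
        assert res2.p_value > 0.05
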