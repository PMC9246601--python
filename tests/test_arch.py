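"""Architecture notation, constraints, and the cardinality calculus."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmnas import TDCN_PSO_NOTATION
from swarmnas.arch import (
    Architecture,
    ArchitectureParseError,
    ConstraintSet,
    LayerKind,
    LayerSpec,
    aco_default_space,
    count_models_aco,
    count_models_pso,
    count_parameterized_space,
    count_search_space,
    desk_space,
    format_architecture,
    parse_architecture,
    pso_default_space,
    random_architecture,
    repair_architecture,
    validate_architecture,
)


class TestNotation:
    def test_printed_pso_architecture_parses_to_17_layers(self):
        arch = parse_architecture(TDCN_PSO_NOTATION)
        assert len(arch) == 17
        expected = [
            "C2D", "C2D", "BN", "DO", "C2D", "BN", "MP", "AP", "MP", "MP",
            "DO", "C2D", "BN", "F", "DO", "DE", "BN",
        ]
        assert [k.value for k in arch.kinds] == expected

    def test_single_token(self):
        arch = parse_architecture("DE")
        assert len(arch) == 1 and arch.layers[0].kind is LayerKind.DE

    def test_unknown_token_names_token_and_position(self):
        with pytest.raises(ArchitectureParseError, match="'XX'.*position 2"):
            parse_architecture("C2D | XX")

    def test_case_and_whitespace_insensitive(self):
        assert parse_architecture("c2d|bn | mp").kinds == parse_architecture(
            "C2D | BN | MP"
        ).kinds

    def test_format_reproduces_printed_string(self):
        assert format_architecture(parse_architecture(TDCN_PSO_NOTATION)) == (
            TDCN_PSO_NOTATION
        )

    @given(
        st.lists(
            st.sampled_from(["C2D", "BN", "DO", "MP", "AP", "DE"]),
            min_size=1,
            max_size=12,
        )
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_parse_format_round_trip(self, kinds):
        text = " | ".join(kinds)
        assert format_architecture(parse_architecture(text)) == text

    def test_json_round_trip_preserves_params(self):
        arch = parse_architecture(TDCN_PSO_NOTATION, input_shape=(128, 128, 3))
        again = Architecture.from_json(arch.to_json())
        assert again == arch

    def test_at_most_one_flatten(self):
        with pytest.raises(ValueError, match="at most one flatten"):
            parse_architecture("F | DE | F")


class TestLayerSpec:
    def test_dropout_rate_bounds(self):
        with pytest.raises(ValueError):
            LayerSpec.make("DO", rate=1.0)
        with pytest.raises(ValueError):
            LayerSpec.make("DO", rate=0.0)

    def test_counts_must_be_positive_integers(self):
        with pytest.raises(ValueError):
            LayerSpec.make("C2D", filter_count=0)
        with pytest.raises(ValueError):
            LayerSpec.make("DE", unit_count=-3)


class TestConstraints:
    def test_printed_pso_architecture_is_valid(self):
        assert validate_architecture(parse_architecture(TDCN_PSO_NOTATION)) == []

    def test_conv_after_flatten_flagged_with_index(self):
        v = validate_architecture(parse_architecture("C2D | F | DE | C2D"))
        assert [(x.rule, x.index) for x in v] == [("no_conv_after_flatten", 3)]

    def test_missing_dense_and_flatten_both_flagged(self):
        rules = {x.rule for x in validate_architecture(parse_architecture("C2D | MP"))}
        assert rules == {"min_dense", "flatten_before_dense"}

    def test_dense_before_flatten_flagged(self):
        v = validate_architecture(parse_architecture("C2D | DE | F"))
        assert ("flatten_before_dense", 1) in [(x.rule, x.index) for x in v]

    @pytest.mark.parametrize(
        "text",
        ["C2D | MP", "DE", "C2D | F | DE | C2D", "C2D | DE | F | DE", "MP | AP"],
    )
    def test_repair_fixes_any_input_and_is_idempotent(self, text):
        arch = repair_architecture(parse_architecture(text))
        assert validate_architecture(arch) == []
        assert repair_architecture(arch) == arch

    def test_repair_leaves_valid_architectures_untouched(self):
        arch = parse_architecture(TDCN_PSO_NOTATION)
        assert repair_architecture(arch) == arch


class TestCardinality:
    def test_four_symbol_space_bounds_3_20(self):
        assert count_search_space(4, 3, 20) == 1_466_015_503_680

    def test_single_symbol_vocabulary_counts_lengths(self):
        assert count_search_space(1, 2, 7) == 6

    @pytest.mark.parametrize(
        "t_l,B_l,B_u",
        [(t, bl, bu) for t in (1, 2, 3) for bl in (1, 2, 3) for bu in range(3, 7) if bl <= bu],
    )
    def test_matches_brute_force_enumeration(self, t_l, B_l, B_u):
        brute = sum(
            1
            for b in range(B_l, B_u + 1)
            for _ in itertools.product(range(t_l), repeat=b)
        )
        assert count_search_space(t_l, B_l, B_u) == brute

    def test_strictly_increasing_in_bounds_and_vocabulary(self):
        assert count_search_space(4, 3, 21) > count_search_space(4, 3, 20)
        assert count_search_space(5, 3, 20) > count_search_space(4, 3, 20)

    def test_bound_violations_raise(self):
        with pytest.raises(ValueError):
            count_search_space(4, 5, 3)
        with pytest.raises(ValueError):
            count_search_space(0, 1, 2)

    def test_result_is_exact_python_int(self):
        out = count_search_space(7, 50, 60)
        assert isinstance(out, int) and out == sum(7**b for b in range(50, 61))


class TestParameterizedSpace:
    def test_sum_of_powers_for_published_layer_counts(self):
        # 9^12 + 2^1 + 1^15 + 4^3; differs from the article's printed total
        assert count_parameterized_space(
            [9, 2, 1, 4], [12, 1, 15, 3], mode="as_printed"
        ) == 282_429_536_548

    def test_combinatorial_mode_matches_enumeration(self):
        combos = list(itertools.product(range(2), range(3)))
        assert count_parameterized_space([2, 3], [1, 1], "combinatorial") == len(combos)

    def test_all_ones(self):
        assert count_parameterized_space([1, 1, 1], [5, 5, 5], "as_printed") == 3
        assert count_parameterized_space([1, 1, 1], [5, 5, 5], "combinatorial") == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            count_parameterized_space([1, 2], [1])


class TestBudgets:
    @pytest.mark.parametrize("ants,depth,expected", [(16, 32, 512), (1, 1, 1), (8, 32, 256)])
    def test_aco_budget(self, ants, depth, expected):
        assert count_models_aco(ants, depth) == expected

    @pytest.mark.parametrize("r,i,p,expected", [(5, 12, 20, 1200), (1, 1, 1, 1), (2, 3, 4, 24)])
    def test_pso_budget(self, r, i, p, expected):
        assert count_models_pso(r, i, p) == expected

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            count_models_aco(0, 5)
        with pytest.raises(ValueError):
            count_models_pso(1, 0, 1)


class TestSearchSpaceSpec:
    def test_aco_default_permutation_counts(self):
        space = aco_default_space()
        assert space.perm_counts == (9, 2, 1, 4)
        assert space.t_l == 4

    def test_pso_default_ranges(self):
        space = pso_default_space()
        convs = space.param_grids[LayerKind.C2D]
        filters = {p["filter_count"] for p in convs}
        assert min(filters) == 3 and max(filters) == 256
        units = {p["unit_count"] for p in space.param_grids[LayerKind.DE]}
        assert min(units) == 1 and max(units) == 300


class TestRandomArchitecture:
    def test_deterministic_given_seed(self):
        space = desk_space()
        a = random_architecture(space, rng=42)
        b = random_architecture(space, rng=42)
        assert a == b

    def test_always_valid_and_length_bounded(self):
        space = desk_space(B_l=3, B_u=20)
        for seed in range(200):
            arch = random_architecture(space, rng=seed)
            assert validate_architecture(arch) == []
            # repair may add up to a flatten + dense beyond the upper bound
            assert 3 <= len(arch) <= 22

    def test_trunk_kind_frequencies_match_probabilities(self):
        space = desk_space(B_l=3, B_u=20)
        rng = np.random.default_rng(0)
        counts = {"conv": 0, "pool": 0, "dense": 0}
        for _ in range(3000):
            arch = random_architecture(space, rng=rng)
            for l in arch.layers:
                if l.kind is LayerKind.C2D:
                    counts["conv"] += 1
                elif l.kind in (LayerKind.MP, LayerKind.AP):
                    counts["pool"] += 1
                elif l.kind is LayerKind.DE:
                    counts["dense"] += 1
        total = sum(counts.values())
        assert counts["conv"] / total == pytest.approx(0.70, abs=0.02)
        assert counts["pool"] / total == pytest.approx(0.15, abs=0.02)
        assert counts["dense"] / total == pytest.approx(0.15, abs=0.02)

    def test_infeasible_bounds_raise(self):
        with pytest.raises(ValueError):
            random_architecture(desk_space(B_l=1, B_u=1), rng=0)

    def test_custom_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            random_architecture(
                desk_space(), layer_probs={"conv": 0.5, "pool": 0.1, "dense": 0.1}, rng=0
            )
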