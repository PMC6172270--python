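"""Window extraction, pair alignment and feature-vector assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p2k.alphabet import ALPHABET, PAD
from p2k.features import (
    assemble_feature_vector,
    enumerate_candidates,
    extract_context,
    feature_length,
    featurize_candidates,
)


def test_full_window_extraction():
    ctx = extract_context("PVKAAFV", 3, "EIVFALT", 3, k=3)
    assert ctx.window_a == "PVKAAFV"
    assert ctx.center_a == "A"


def test_terminus_positions_are_padded():
    ctx = extract_context("ACD", 0, "WYV", 2, k=3)
    assert ctx.window_a == f"{PAD}{PAD}{PAD}ACD{PAD}"
    assert ctx.window_b == f"{PAD}WYV{PAD}{PAD}{PAD}"


def test_unknown_letters_become_pad():
    ctx = extract_context("AXC", 0, "DEF", 1, k=1)
    assert ctx.window_a == f"{PAD}A{PAD}"


def test_zero_neighbors_keeps_centers_only():
    ctx = extract_context("ACD", 1, "WY", 0, k=0)
    assert (ctx.window_a, ctx.window_b) == ("C", "W")


def test_center_bounds_are_validated():
    with pytest.raises(IndexError):
        extract_context("ACD", 3, "WY", 0, k=1)
    with pytest.raises(IndexError):
        extract_context("ACD", 0, "WY", -1, k=1)


def test_antiparallel_alignment_reproduces_reference_pairs():
    """Windows PVKAAFV / ITLVAFE pair up as P-E, V-F, K-A, A-V, A-L, F-T, V-I."""
    ctx = extract_context("PVKAAFV", 3, "ITLVAFE", 3, k=3)
    assert ctx.aligned_pairs() == [
        ("P", "E"), ("V", "F"), ("K", "A"), ("A", "V"),
        ("A", "L"), ("F", "T"), ("V", "I"),
    ]


@pytest.mark.parametrize("k,expected", [(0, 18), (1, 54), (2, 90), (3, 126)])
def test_feature_dimension_ladder(k, expected, knowledge):
    assert feature_length(k) == expected
    ctx = extract_context("PVKAAFVW", 3, "EIVFALTY", 3, k=k)
    vec = assemble_feature_vector(ctx, knowledge.projections, knowledge.rsrvs)
    assert vec.shape == (expected,)


def test_block_layout_with_synthetic_tables(identity_knowledge):
    projections, rsrvs = identity_knowledge
    ctx = extract_context("A", 0, "C", 0, k=0)
    vec = assemble_feature_vector(ctx, projections, rsrvs)
    # block 1: PC1..PC6 of A (index 0), then of C (index 1)
    np.testing.assert_array_equal(vec[:6], [100, 200, 300, 400, 500, 600])
    np.testing.assert_array_equal(vec[6:12], [101, 201, 301, 401, 501, 601])
    # block 2: constant matrices give their constants per component
    np.testing.assert_array_equal(vec[12:], [1, 2, 3, 4, 5, 6])


def test_pad_positions_contribute_zero(knowledge):
    ctx = extract_context("A", 0, "C", 0, k=2)
    vec = assemble_feature_vector(ctx, knowledge.projections, knowledge.rsrvs)
    n_pcs = 6
    block1 = vec[: 2 * 5 * n_pcs].reshape(10, n_pcs)
    # window slots 0,1,3,4 of both windows are pads
    for slot in (0, 1, 3, 4, 5, 6, 8, 9):
        np.testing.assert_array_equal(block1[slot], 0.0)
    assert np.any(block1[2] != 0) and np.any(block1[7] != 0)
    block2 = vec[2 * 5 * n_pcs :].reshape(5, n_pcs)
    for p in (0, 1, 3, 4):  # only the center pair is real
        np.testing.assert_array_equal(block2[p], 0.0)
    assert np.any(block2[2] != 0)


def test_symmetric_average_matches_direct_lookup(knowledge):
    ctx = extract_context("RNDCQ", 2, "WYVHK", 2, k=2)
    vec = assemble_feature_vector(ctx, knowledge.projections, knowledge.rsrvs)
    n_pcs = 6
    block2 = vec[2 * 5 * n_pcs :].reshape(5, n_pcs)
    letters = list(ALPHABET)
    for p, (a, b) in enumerate(ctx.aligned_pairs()):
        ia, ib = letters.index(a), letters.index(b)
        for m in range(n_pcs):
            mat = knowledge.rsrvs[m].rsrv
            assert block2[p, m] == pytest.approx(0.5 * (mat[ia, ib] + mat[ib, ia]))


def test_ordered_lookup_variant(knowledge):
    ctx = extract_context("RN", 0, "WY", 1, k=0)
    vec = assemble_feature_vector(
        ctx, knowledge.projections, knowledge.rsrvs, symmetric_average=False
    )
    letters = list(ALPHABET)
    ia, ib = letters.index("R"), letters.index("Y")
    for m in range(6):
        assert vec[12 + m] == pytest.approx(knowledge.rsrvs[m].rsrv[ia, ib])


def test_component_permutation_permutes_blocks(knowledge):
    perm = [3, 1, 5, 2, 0, 4]
    projections = knowledge.projections.iloc[:, perm]
    rsrvs = [knowledge.rsrvs[m] for m in perm]
    ctx = extract_context("RNDCQ", 2, "WYVHK", 2, k=1)
    base = assemble_feature_vector(ctx, knowledge.projections, knowledge.rsrvs)
    permuted = assemble_feature_vector(ctx, projections, rsrvs)
    n_pcs = 6
    for block_start, n_slots in ((0, 6), (6 * n_pcs, 3)):
        for slot in range(n_slots):
            lo = block_start + slot * n_pcs
            np.testing.assert_allclose(
                permuted[lo : lo + n_pcs], base[lo : lo + n_pcs][perm]
            )


def test_insufficient_component_coverage_is_an_error(knowledge):
    ctx = extract_context("RN", 0, "WY", 1, k=0)
    with pytest.raises(ValueError):
        assemble_feature_vector(ctx, knowledge.projections, knowledge.rsrvs[:4])


def test_candidate_enumeration_counts_and_order():
    contexts = list(enumerate_candidates("ACD", "WYVH", k=1))
    assert len(contexts) == 12
    assert [(c.pos_a, c.pos_b) for c in contexts[:5]] == [
        (0, 0), (0, 1), (0, 2), (0, 3), (1, 0)
    ]
    assert len(list(enumerate_candidates("A", "C", k=0))) == 1
    with pytest.raises(ValueError):
        list(enumerate_candidates("", "ACD", k=1))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    n_a=st.integers(1, 12),
    n_b=st.integers(1, 12),
    k=st.integers(0, 3),
)
def test_enumeration_is_cartesian_and_lengths_hold(n_a, n_b, k):
    rng = np.random.default_rng(n_a * 100 + n_b * 10 + k)
    letters = np.array(list(ALPHABET))
    seq_a = "".join(rng.choice(letters, n_a))
    seq_b = "".join(rng.choice(letters, n_b))
    contexts = list(enumerate_candidates(seq_a, seq_b, k))
    assert len(contexts) == n_a * n_b
    width = 2 * k + 1
    assert all(
        len(c.window_a) == width and len(c.window_b) == width for c in contexts
    )


def test_featurize_candidates_stacks_rows(knowledge):
    contexts = list(enumerate_candidates("ACD", "WY", k=1))
    X = featurize_candidates(contexts, knowledge)
    assert X.shape == (6, feature_length(1))
    single = assemble_feature_vector(
        contexts[2], knowledge.projections, knowledge.rsrvs
    )
    np.testing.assert_array_equal(X[2], single)
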