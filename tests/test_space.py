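"""Odor-response-space algebra: scaling, composition, embedding, bases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odormix import (
    Basis,
    DomainError,
    HullRegion,
    MixtureSpec,
    NotRepresentableError,
    ResponseTriple,
    ValidationError,
    canonical_bases,
    compose,
    decompose,
    embed,
    hull_coverage,
    is_valid_basis,
    mixture_response,
    recompose,
    scale,
    single_response,
    synthesize_target,
    unembed,
)

triple_st = st.builds(
    ResponseTriple,
    n=st.floats(0.1, 10.0),
    eta=st.floats(0.1, 10.0),
    s=st.floats(0.1, 10.0),
)


def test_scale_identity_and_composition_of_scalings():
    t = ResponseTriple(2.0, 1.5, 4.0)
    assert scale(t, 1.0) == t
    assert scale(scale(t, 2.0), 3.0) == scale(t, 6.0)
    with pytest.raises(DomainError):
        scale(t, 0.0)


def test_scaled_triple_shifts_the_curve():
    t = ResponseTriple(2.3, 1.4, 100.0)
    grid = np.logspace(-5, 1, 50)
    np.testing.assert_allclose(
        single_response(scale(t, 2.0).to_params(), grid),
        single_response(t.to_params(), 2.0 * grid),
        rtol=1e-14,
    )


@given(triple_st, triple_st)
@settings(deadline=None, max_examples=100)
def test_compose_commutative_and_embeds_additively(t1, t2):
    c12, c21 = compose(t1, t2), compose(t2, t1)
    assert c12.n == pytest.approx(c21.n, rel=1e-12)
    assert c12.eta == pytest.approx(c21.eta, rel=1e-12)
    assert c12.s == pytest.approx(c21.s, rel=1e-12)
    np.testing.assert_allclose(
        embed(c12).as_array(),
        embed(t1).as_array() + embed(t2).as_array(),
        rtol=1e-12,
    )


def test_self_composition_is_doubling():
    t = ResponseTriple(3.0, 0.7, 5.0)
    assert compose(t, t) == scale(t, 2.0)


def test_compose_associative_and_scale_distributes():
    rng = np.random.default_rng(0)
    for _ in range(100):
        a, b, c = (ResponseTriple(*rng.uniform(0.1, 10, 3)) for _ in range(3))
        lhs, rhs = compose(compose(a, b), c), compose(a, compose(b, c))
        np.testing.assert_allclose(embed(lhs).as_array(), embed(rhs).as_array(), rtol=1e-12)
        al = rng.uniform(0.1, 10)
        np.testing.assert_allclose(
            embed(scale(compose(a, b), al)).as_array(),
            embed(compose(scale(a, al), scale(b, al))).as_array(),
            rtol=1e-12,
        )


def test_composition_matches_equal_concentration_mixture():
    """The algebraic composition reproduces the mixture model at shared X."""
    rng = np.random.default_rng(4)
    for _ in range(30):
        t1, t2 = (ResponseTriple(*rng.uniform(0.2, 8, 3)) for _ in range(2))
        grid = np.logspace(-3, 2, 30)
        spec = MixtureSpec.of(t1.to_params(), t2.to_params())
        np.testing.assert_allclose(
            single_response(compose(t1, t2).to_params(), grid),
            mixture_response(spec, [grid, grid]),
            rtol=1e-11,
        )


def test_embed_unit_triple():
    v = embed(ResponseTriple(1.0, 1.0, 1.0))
    assert (v.x1, v.x2, v.x3) == (1.0, 1.0, 1.0)


@given(triple_st)
@settings(deadline=None, max_examples=200)
def test_embed_round_trip(t):
    back = unembed(embed(t))
    assert back.n == pytest.approx(t.n, rel=1e-12)
    assert back.eta == pytest.approx(t.eta, rel=1e-12)
    assert back.s == pytest.approx(t.s, rel=1e-12)


def test_embedded_images_span_rank_three():
    rng = np.random.default_rng(123)
    triples = [ResponseTriple(*rng.uniform(0.1, 10, 3)) for _ in range(20)]
    vecs = [embed(t).as_array() for t in triples]
    for _ in range(10):
        i, j = rng.integers(0, len(triples), 2)
        vecs.append(embed(compose(triples[i], triples[j])).as_array())
    assert np.linalg.matrix_rank(np.vstack(vecs)) == 3


def test_basis_validity_matches_determinant_oracle():
    rng = np.random.default_rng(2)
    e = embed(ResponseTriple(1.0, 2.0, 3.0))
    assert not is_valid_basis(e, e, e)
    for _ in range(100):
        vs = [embed(ResponseTriple(*rng.uniform(0.1, 10, 3))) for _ in range(3)]
        m = np.column_stack([v.as_array() for v in vs])
        det_scale = np.prod(np.abs(m).max(axis=0))
        expected = abs(np.linalg.det(m)) > 1e-12 * det_scale
        assert is_valid_basis(*vs) == expected


@pytest.fixture(scope="module")
def region():
    return HullRegion(n_min=0.5, n_max=20.0, eta_min=0.1, eta_max=16.0)


@pytest.fixture(scope="module")
def bases(region):
    return canonical_bases(region)


def test_canonical_bases_are_valid(bases):
    b1, b2 = bases
    assert b1.valid and b2.valid


def test_decompose_basis_element_gives_unit_coefficient(bases):
    b1, _ = bases
    dec = decompose(unembed(b1.e1), b1)
    np.testing.assert_allclose(dec.as_array(), [1.0, 0.0, 0.0], atol=1e-12)


def test_decompose_recompose_round_trip(bases):
    b1, _ = bases
    rng = np.random.default_rng(77)
    for _ in range(200):
        alpha = rng.uniform(0.05, 3.0, 3)
        target = unembed(
            type(b1.e1)(*(b1.matrix @ alpha))
        )
        dec = decompose(target, b1)
        np.testing.assert_allclose(dec.as_array(), alpha, rtol=1e-9)
        back = recompose(b1, dec)
        assert back.n == pytest.approx(target.n, rel=1e-9)
        assert back.eta == pytest.approx(target.eta, rel=1e-9)
        assert back.s == pytest.approx(target.s, rel=1e-9)


def test_decompose_rejects_out_of_hull_target(bases, region):
    b1, b2 = bases
    # below the eta floor of the rectangle: outside both coverage regions
    target = ResponseTriple(n=1.0, eta=region.eta_min / 10.0, s=1e6)
    with pytest.raises(NotRepresentableError) as exc:
        decompose(target, b1)
    assert exc.value.coefficients is not None
    with pytest.raises(ValidationError):
        e = b1.e1
        decompose(target, Basis(e, e, e))


def test_coverage_matches_decomposition_positivity(bases):
    b1, _ = bases
    rng = np.random.default_rng(31)
    queries = [(rng.uniform(0.1, 25.0), rng.uniform(0.05, 20.0)) for _ in range(300)]
    # add guaranteed-inside queries built as positive combinations
    for _ in range(50):
        t = unembed(type(b1.e1)(*(b1.matrix @ rng.uniform(0.05, 2.0, 3))))
        queries.append((t.n, t.eta))
    checked_in = checked_out = 0
    for n, eta in queries:
        covered = hull_coverage(b1, n, eta)
        try:
            decompose(ResponseTriple(n, eta, 1e6), b1)
            ok = True
        except NotRepresentableError:
            ok = False
        assert covered == ok
        checked_in += ok
        checked_out += not ok
    assert checked_in > 10 and checked_out > 10


def test_vertices_and_centroid_are_covered(bases, region):
    b1, _ = bases
    for e in (b1.e1, b1.e2, b1.e3):
        t = unembed(e)
        assert hull_coverage(b1, t.n, t.eta)
    ts = [unembed(e) for e in (b1.e1, b1.e2, b1.e3)]
    centroid = compose(compose(ts[0], ts[1]), ts[2])
    assert hull_coverage(b1, centroid.n, centroid.eta)


def test_union_of_canonical_bases_covers_the_rectangle(bases, region):
    b1, b2 = bases
    ns = np.linspace(region.n_min, region.n_max, 50)
    es = np.linspace(region.eta_min, region.eta_max, 50)
    miss1 = miss2 = 0
    for n in ns:
        for eta in es:
            c1 = hull_coverage(b1, n, eta)
            c2 = hull_coverage(b2, n, eta)
            assert c1 or c2
            miss1 += not c1
            miss2 += not c2
    # neither basis suffices alone
    assert miss1 > 0 and miss2 > 0


def test_four_vertex_hull_covers_what_either_basis_covers(bases, region):
    b1, b2 = bases
    corners = [unembed(e) for e in (b1.e1, b1.e2, b1.e3, b2.e3)]
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = rng.uniform(region.n_min, region.n_max)
        eta = rng.uniform(region.eta_min, region.eta_max)
        assert hull_coverage(corners, n, eta)


def test_synthesize_single_target_unit_coefficient():
    t = ResponseTriple(2.0, 1.5, 3.0)
    other = ResponseTriple(5.0, 0.5, 1.0)
    coeffs = synthesize_target([t], [[t, other]])
    np.testing.assert_allclose(coeffs, [1.0, 0.0], atol=1e-9)


def test_synthesize_recovers_constructed_coefficients():
    rng = np.random.default_rng(9)
    odors = [[ResponseTriple(*rng.uniform(0.3, 6, 3)) for _ in range(2)] for _ in range(2)]
    true = np.array([0.7, 1.8])
    targets = [
        unembed(type(embed(a[0]))(*(true[0] * embed(a[0]).as_array()
                                    + true[1] * embed(a[1]).as_array())))
        for a in odors
    ]
    coeffs = synthesize_target(targets, odors)
    np.testing.assert_allclose(coeffs, true, rtol=1e-9)


def test_synthesize_four_osn_two_odor_configuration():
    """Two odors activating four OSN types admit a shared positive mixture."""
    rng = np.random.default_rng(10)
    odors = [[ResponseTriple(*rng.uniform(0.3, 6, 3)) for _ in range(2)] for _ in range(4)]
    true = np.array([1.3, 0.4])
    targets = [
        unembed(type(embed(a[0]))(*(true[0] * embed(a[0]).as_array()
                                    + true[1] * embed(a[1]).as_array())))
        for a in odors
    ]
    coeffs = synthesize_target(targets, odors)
    np.testing.assert_allclose(coeffs, true, rtol=1e-8)


def test_synthesize_infeasible_identifies_osn():
    a = ResponseTriple(1.0, 1.0, 1.0)
    b = ResponseTriple(2.0, 2.0, 1.0)
    good = unembed(type(embed(a))(*(embed(a).as_array() + embed(b).as_array())))
    bad = ResponseTriple(9.0, 0.05, 4.0)
    with pytest.raises(NotRepresentableError) as exc:
        synthesize_target([good, bad], [[a, b], [a, b]])
    assert exc.value.osn == 1


def test_unembed_domain_error():
    from odormix import EmbeddedVector

    with pytest.raises(DomainError):
        unembed(EmbeddedVector(-1.0, 1.0, 1.0))


def test_hull_region_validation():
    with pytest.raises(ValidationError):
        HullRegion(n_min=2.0, n_max=1.0, eta_min=0.1, eta_max=1.0)
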