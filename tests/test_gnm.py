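import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gnmhot.gnm import (
    GNMParameters,
    build_kirchhoff,
    correlation_matrix,
    decompose,
    msdf_matrix,
    msf_weighted,
)

from conftest import make_chain


def brute_force_kirchhoff(coords, cutoff):
    n = len(coords)
    gamma = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                gamma[i, j] = -1
    for i in range(n):
        gamma[i, i] = -gamma[i].sum() - gamma[i, i]
    return gamma


def test_two_residue_contact():
    chain = make_chain([[0, 0, 0], [5.0, 0, 0]])
    k = build_kirchhoff(chain, GNMParameters(cutoff=6.5))
    np.testing.assert_array_equal(k.matrix, [[1, -1], [-1, 1]])


def test_three_collinear_residues_cutoff_excludes_far_pair():
    chain = make_chain([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
    k = build_kirchhoff(chain, GNMParameters(cutoff=7.1))
    np.testing.assert_array_equal(np.diag(k.matrix), [1, 2, 1])
    assert k.matrix[0, 2] == 0


def test_boundary_distance_counts_as_contact():
    chain = make_chain([[0, 0, 0], [7.0, 0, 0]])
    k = build_kirchhoff(chain, GNMParameters(cutoff=7.0))
    assert k.matrix[0, 1] == -1


def test_kirchhoff_matches_brute_force_double_loop(synth_chains):
    chain = synth_chains[0]
    coords = chain.coords[:10]
    small = make_chain(coords)
    k = build_kirchhoff(small, GNMParameters(cutoff=7.0))
    np.testing.assert_array_equal(k.matrix, brute_force_kirchhoff(coords, 7.0))


def test_decompose_two_node_closed_form():
    chain = make_chain([[0, 0, 0], [5.0, 0, 0]])
    params = GNMParameters(cutoff=6.5)
    spec = decompose(build_kirchhoff(chain, params), params)
    np.testing.assert_allclose(spec.eigenvalues, [0.0, 2.0], atol=1e-12)
    np.testing.assert_allclose(np.abs(spec.eigenvectors[:, 0]), [2**-0.5] * 2, atol=1e-12)
    assert spec.n_zero == 1


def test_decompose_path_graph_eigenvalues():
    """Three-node path Laplacian has the spectrum {0, 1, 3}."""
    chain = make_chain([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
    params = GNMParameters(cutoff=4.0)
    spec = decompose(build_kirchhoff(chain, params), params)
    np.testing.assert_allclose(spec.eigenvalues, [0.0, 1.0, 3.0], atol=1e-12)


def test_sign_convention_is_deterministic(spectrum_10):
    spec, _ = spectrum_10
    for col in range(spec.n):
        v = spec.eigenvectors[:, col]
        assert v[np.argmax(np.abs(v))] > 0


@pytest.mark.parametrize("chain_index", range(6))
def test_n_zero_equals_connected_components(synth_chains, chain_index):
    """Null-space dimension equals the BFS component count of the contact graph."""
    params = GNMParameters(cutoff=6.0)
    chain = synth_chains[chain_index]
    k = build_kirchhoff(chain, params)
    spec = decompose(k, params)
    graph = nx.from_numpy_array(-(k.matrix - np.diag(np.diag(k.matrix))))
    assert spec.n_zero == nx.number_connected_components(graph)


def test_disconnected_chain_has_two_null_modes():
    coords = [[0, 0, 0], [3.8, 0, 0], [100, 0, 0], [103.8, 0, 0]]
    params = GNMParameters(cutoff=7.0)
    spec = decompose(build_kirchhoff(make_chain(coords), params), params)
    assert spec.n_zero == 2


def test_spectrum_invariant_under_rigid_motion(synth_chains):
    chain = synth_chains[1]
    rot = Rotation.from_euler("xyz", [0.3, -1.2, 2.1]).as_matrix()
    moved = make_chain(chain.coords @ rot.T + np.array([10.0, -5.0, 3.0]))
    params = GNMParameters(cutoff=7.0)
    s1 = decompose(build_kirchhoff(chain, params), params)
    s2 = decompose(build_kirchhoff(moved, params), params)
    np.testing.assert_allclose(s1.eigenvalues, s2.eigenvalues, atol=1e-9)


def test_contact_degree_monotone_in_cutoff(synth_chains):
    chain = synth_chains[2]
    degrees = [
        np.diag(build_kirchhoff(chain, GNMParameters(cutoff=c)).matrix)
        for c in (6.0, 7.0, 8.0)
    ]
    assert np.all(degrees[1] >= degrees[0]) and np.all(degrees[2] >= degrees[1])


def test_orthonormality_and_reconstruction(synth_chains):
    params = GNMParameters(cutoff=7.0)
    k = build_kirchhoff(synth_chains[0], params)
    spec = decompose(k, params)
    u = spec.eigenvectors
    np.testing.assert_allclose(u.T @ u, np.eye(spec.n), atol=1e-8)
    rebuilt = u @ np.diag(spec.eigenvalues) @ u.T
    resid = np.abs(rebuilt - k.matrix).max() / max(spec.eigenvalues[-1], 1.0)
    assert resid < 1e-8


def test_single_mode_msf_is_squared_eigenvector(spectrum_10):
    spec, params = spectrum_10
    msf = msf_weighted(spec, [1], params, normalized=True)
    np.testing.assert_allclose(msf, spec.fast_mode(1) ** 2, atol=1e-12)
    assert msf.sum() == pytest.approx(1.0)


def test_msf_weighted_matches_direct_sum(spectrum_10):
    """Fast-mode MSF equals the term-by-term λ⁻¹-weighted average."""
    spec, params = spectrum_10
    ranks = [1, 2, 3]
    num = np.zeros(spec.n)
    den = 0.0
    for r in ranks:
        lam = spec.fast_eigenvalue(r)
        num += spec.fast_mode(r) ** 2 / lam
        den += 1.0 / lam
    np.testing.assert_allclose(msf_weighted(spec, ranks, params), params.scale * num / den, atol=1e-12)


def test_msf_equal_eigenvalues_average_evenly():
    lam = np.array([0.0, 2.0, 2.0])
    u, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(3, 3)))
    from gnmhot.gnm import ModeSpectrum

    spec = ModeSpectrum(eigenvalues=lam, eigenvectors=u, n_zero=1)
    msf = msf_weighted(spec, [1, 2], normalized=True)
    np.testing.assert_allclose(msf, 0.5 * (u[:, 1] ** 2 + u[:, 2] ** 2), atol=1e-12)


def test_msf_rejects_null_mode():
    chain = make_chain([[0, 0, 0], [5.0, 0, 0]])
    params = GNMParameters(cutoff=6.5)
    spec = decompose(build_kirchhoff(chain, params), params)
    with pytest.raises(ValueError, match="zero eigenvalue"):
        msf_weighted(spec, [1, 2], params)


def test_full_correlation_is_pseudo_inverse(spectrum_10):
    spec, params = spectrum_10
    c = correlation_matrix(spec, range(1, spec.n_nonnull + 1), params)
    k = spec.eigenvectors @ np.diag(spec.eigenvalues) @ spec.eigenvectors.T
    np.testing.assert_allclose(c / params.scale, np.linalg.pinv(k), atol=1e-8)
    np.testing.assert_allclose(k @ (c / params.scale) @ k, k, atol=1e-7)


def test_correlation_diagonal_is_unnormalized_msf(spectrum_10):
    spec, params = spectrum_10
    ranks = [1, 2, 3, 4]
    c = correlation_matrix(spec, ranks, params)
    direct = np.zeros(spec.n)
    for r in ranks:
        direct += spec.fast_mode(r) ** 2 / spec.fast_eigenvalue(r)
    np.testing.assert_allclose(np.diag(c), params.scale * direct, atol=1e-12)


def test_correlation_subset_is_outer_product_sum(synth_chains):
    chain = make_chain(synth_chains[0].coords[:8])
    params = GNMParameters(cutoff=7.5)
    spec = decompose(build_kirchhoff(chain, params), params)
    c = correlation_matrix(spec, [1, 2], params)
    expected = sum(
        np.outer(spec.fast_mode(r), spec.fast_mode(r)) / spec.fast_eigenvalue(r)
        for r in (1, 2)
    )
    np.testing.assert_allclose(c, params.scale * expected, atol=1e-12)


def test_msdf_structure_and_single_mode_closed_form(synth_chains):
    chain = make_chain(synth_chains[0].coords[:6])
    params = GNMParameters(cutoff=7.5)
    spec = decompose(build_kirchhoff(chain, params), params)
    d = msdf_matrix(spec, [1, 2], params)
    np.testing.assert_array_equal(np.diag(d), np.zeros(6))
    np.testing.assert_allclose(d, d.T, atol=1e-12)
    assert (d >= 0).all()

    d1 = msdf_matrix(spec, [1], params)
    u = spec.fast_mode(1)
    lam = spec.fast_eigenvalue(1)
    expected = params.scale * (u[:, None] - u[None, :]) ** 2 / lam
    np.testing.assert_allclose(d1, expected, atol=1e-12)


def test_row_sums_zero_and_psd(synth_chains):
    params = GNMParameters(cutoff=7.0)
    for chain in synth_chains[:5]:
        k = build_kirchhoff(chain, params)
        assert (k.matrix.sum(axis=1) == 0).all()
        eigvals = np.linalg.eigvalsh(k.matrix.astype(float))
        assert eigvals.min() >= -1e-10 * max(eigvals.max(), 1.0)
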