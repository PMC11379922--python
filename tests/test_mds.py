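import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import wdsqi as w
from wdsqi.errors import DegenerateInputError, ValidationError


def random_correlation(rng, p):
    """Correlation matrix of a random full-rank data sample (always PSD)."""
    x = rng.normal(size=(6 * p, p)) @ rng.normal(size=(p, p))
    return np.corrcoef(x, rowvar=False)


def test_standardize_definition_and_idempotence(synth_study):
    z = w.standardize(synth_study)
    assert np.allclose(z.mean(), 0, atol=1e-12)
    assert np.allclose(z.var(ddof=1), 1, atol=1e-12)
    # idempotence: standardizing a standardized matrix changes nothing
    zz = (z - z.mean()) / z.std(ddof=1)
    assert np.allclose(z.to_numpy(), zz.to_numpy(), atol=1e-12)


def test_standardize_degenerate_input(synth_study):
    df = synth_study.data.copy()
    df["SOM"] = 5.0
    with pytest.raises(DegenerateInputError, match="SOM"):
        w.standardize(w.SampleTable(df))


def test_pca_identity_matrix_closed_form():
    pca = w.pca_correlation(pd.DataFrame(np.eye(9), index=list(w.INDICATORS), columns=list(w.INDICATORS)))
    assert np.allclose(pca.eigenvalues, 1.0)
    assert np.allclose(pca.variance_pct, 100 / 9)


def test_pca_2x2_closed_form():
    r = 0.6
    mat = pd.DataFrame([[1, r], [r, 1]], index=["a", "b"], columns=["a", "b"])
    pca = w.pca_correlation(mat)
    assert pca.eigenvalues == pytest.approx([1 + r, 1 - r])


def test_pca_rejects_bad_input():
    with pytest.raises(ValidationError):
        w.pca_correlation(np.array([[1.0, 0.5], [0.1, 1.0]]))
    with pytest.raises(ValidationError):
        w.pca_correlation(np.full((2, 2), np.nan))


@pytest.mark.parametrize("p", [4, 5])
def test_trace_conservation_and_full_reconstruction(p):
    rng = np.random.default_rng(42 + p)
    for _ in range(5):
        corr = random_correlation(rng, p)
        pca = w.pca_correlation(pd.DataFrame(corr))
        assert pca.eigenvalues.sum() == pytest.approx(p, abs=1e-8)
        U = pca.loadings.to_numpy()
        assert np.allclose(U @ U.T, corr, atol=1e-8)


def test_pca_matches_sklearn_on_random_data():
    """Cross-check against an independent PCA implementation."""
    sklearn = pytest.importorskip("sklearn.decomposition")
    rng = np.random.default_rng(7)
    x = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6))
    z = (x - x.mean(0)) / x.std(0, ddof=1)
    pca = w.pca_correlation(pd.DataFrame(z, columns=list("abcdef")))
    ref = sklearn.PCA().fit(z)
    assert np.allclose(pca.eigenvalues, ref.explained_variance_, atol=1e-8)
    # loadings agree up to component sign
    ref_load = ref.components_.T * np.sqrt(ref.explained_variance_)
    assert np.allclose(np.abs(pca.loadings.to_numpy()), np.abs(ref_load), atol=1e-8)


@pytest.mark.parametrize(
    "eigenvalues, expected",
    [
        ((5.435, 1.204, 0.8, 0.5, 0.4, 0.3, 0.2, 0.1, 0.061), [1, 2]),
        (tuple([1.0] * 9), list(range(1, 10))),
        ((8.9, 0.05, 0.01, 0.01, 0.01, 0.01, 0.005, 0.005, 0.01), [1]),
    ],
)
def test_retain_components(eigenvalues, expected):
    p = len(eigenvalues)
    loadings = pd.DataFrame(
        np.zeros((p, p)), index=[f"i{k}" for k in range(p)],
        columns=[f"PC{k + 1}" for k in range(p)],
    )
    pca = w.PCAResult(eigenvalues=np.array(eigenvalues), loadings=loadings)
    assert w.retain_components(pca, 1.0, 5.0) == expected


def test_norm_scores_published_values(printed_pca):
    norms = w.norm_scores(printed_pca, [1, 2])
    assert norms.comprehensive_load["SOM"] == pytest.approx(4.520, abs=1.5e-3)
    assert norms.comprehensive_load["AN"] == pytest.approx(3.691, abs=1.5e-3)
    assert np.allclose(norms.norm**2, norms.comprehensive_load)


def test_norm_scores_single_unit_component():
    pca = w.PCAResult(
        eigenvalues=np.array([1.0]),
        loadings=pd.DataFrame({"PC1": [1.0]}, index=["x"]),
    )
    norms = w.norm_scores(pca, [1])
    assert norms.comprehensive_load["x"] == 1.0 and norms.norm["x"] == 1.0


def test_group_indicators_published_structure(printed_pca, correlations):
    groups = w.group_indicators(printed_pca, [1, 2], correlations, 0.6)
    assert groups["pH"] == 1  # cross-loader, less correlated with the PC1 block
    assert groups["BD"] == 2
    for ind in ("SOM", "AN", "AP", "AK", "TP", "TN", "SMC"):
        assert groups[ind] == 1


def test_group_indicators_edge_rules(correlations):
    # single retained component: everyone lands in group 1
    loadings = pd.DataFrame({"PC1": [0.9, 0.2], "PC2": [0.1, 0.95]}, index=["SOM", "BD"])
    pca = w.PCAResult(eigenvalues=np.array([1.5, 0.5]), loadings=loadings)
    groups = w.group_indicators(pca, [1], correlations, 0.6)
    assert set(groups.values()) == {1}
    # sub-cutoff loadings go to the largest-|loading| component
    loadings2 = pd.DataFrame({"PC1": [0.3, 0.9], "PC2": [0.5, 0.1]}, index=["SMC", "SOM"])
    pca2 = w.PCAResult(eigenvalues=np.array([1.2, 1.1]), loadings=loadings2)
    groups2 = w.group_indicators(pca2, [1, 2], correlations, 0.6)
    assert groups2["SMC"] == 2


def test_select_mds_reproduces_published_subset(printed_pca, correlations):
    norms = w.norm_scores(printed_pca, [1, 2])
    groups = w.group_indicators(printed_pca, [1, 2], correlations, 0.6)
    sel = w.select_mds(printed_pca, correlations, norms, groups)
    assert sel.selected == ["pH", "SOM", "BD"]
    assert len(sel.selected) == 3


def test_select_mds_one_indicator_per_group(correlations):
    loadings = pd.DataFrame({"PC1": [0.9, 0.1], "PC2": [0.1, 0.9]}, index=["SOM", "BD"])
    pca = w.PCAResult(eigenvalues=np.array([1.1, 1.0]), loadings=loadings)
    norms = w.norm_scores(pca, [1, 2])
    groups = {"SOM": 1, "BD": 2}
    sel = w.select_mds(pca, correlations, norms, groups)
    assert sel.selected == ["SOM", "BD"]


def test_selection_invariant_to_norm_monotone_transform(printed_pca, correlations):
    """Ranking by Norm or by comprehensive load selects the same MDS."""
    norms = w.norm_scores(printed_pca, [1, 2])
    groups = w.group_indicators(printed_pca, [1, 2], correlations, 0.6)
    base = w.select_mds(printed_pca, correlations, norms, groups)
    transformed = w.NormScores(
        pd.DataFrame(
            {"comprehensive_load": norms.norm, "norm": np.sqrt(norms.norm)}
        )
    )
    alt = w.select_mds(printed_pca, correlations, transformed, groups)
    assert alt.selected == base.selected


def test_selection_invariant_to_sign_flip(synth_study):
    base, *_ = w.select_mds_from_samples(synth_study)
    flipped_df = synth_study.data.copy()
    flipped_df["SMC"] = flipped_df["SMC"].max() + 1 - flipped_df["SMC"]
    flipped, *_ = w.select_mds_from_samples(w.SampleTable(flipped_df))
    assert flipped.selected == base.selected


def test_selection_deterministic(synth_study):
    a, *_ = w.select_mds_from_samples(synth_study)
    b, *_ = w.select_mds_from_samples(synth_study)
    assert a.selected == b.selected and a.audit == b.audit and a.groups == b.groups


def test_redundancy_rule_drops_high_correlation():
    """Two shortlisted indicators with |r| > 0.5 collapse to the higher load."""
    loadings = pd.DataFrame({"PC1": [0.9, 0.88]}, index=["SOM", "AP"])
    pca = w.PCAResult(eigenvalues=np.array([1.5]), loadings=loadings)
    corr = pd.DataFrame(
        [[1, 0.841], [0.841, 1]], index=["SOM", "AP"], columns=["SOM", "AP"]
    )
    norms = w.norm_scores(pca, [1])
    sel = w.select_mds(pca, corr, norms, {"SOM": 1, "AP": 1})
    assert sel.selected == ["SOM"]
    assert any("drop redundant" in line for line in sel.audit)
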