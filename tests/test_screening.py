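"""Univariate regression screening of sensitive/tolerant taxa."""
import numpy as np
import pandas as pd
import pytest

from ednarisk import SoilSample, fit_simple_regression, identify_key_stressors, screen_species
from ednarisk.datatypes import AlignmentError, CommunityProfile
from ednarisk.screening import DegenerateDesignError, InsufficientDataError
from ednarisk.teq import TeqResult


def profile_from(mat, samples=None):
    mat = np.asarray(mat, dtype=float)
    mat = mat / mat.sum(axis=0, keepdims=True)
    cols = samples or [f"S{j}" for j in range(mat.shape[1])]
    return CommunityProfile(
        pd.DataFrame(mat, index=[f"t{i}" for i in range(mat.shape[0])], columns=cols)
    )


def test_perfect_linear_response():
    x = np.arange(1.0, 6.0)
    res = fit_simple_regression(x, 2 * x)
    assert res.slope == pytest.approx(2.0)
    assert res.r == pytest.approx(1.0)
    assert res.p_value < 1e-6


def test_flat_response_convention():
    res = fit_simple_regression([1, 2, 3, 4], [5, 5, 5, 5])
    assert (res.slope, res.r, res.p_value) == (0.0, 0.0, 1.0)


def test_hand_computed_ols_example():
    # Sxy = 3, Sxx = Syy = 5 -> slope = r = 0.6 (closed-form hand oracle)
    res = fit_simple_regression([1, 2, 3, 4], [2, 1, 4, 3])
    assert res.slope == pytest.approx(0.6)
    assert res.r == pytest.approx(0.6)
    assert res.n == 4


def test_degenerate_designs_raise():
    with pytest.raises(DegenerateDesignError):
        fit_simple_regression([2, 2, 2, 2], [1, 2, 3, 4])
    with pytest.raises(InsufficientDataError):
        fit_simple_regression([1, 2], [1, 2])


def test_monotone_taxa_are_called(rng):
    stressor = np.linspace(1.0, 10.0, 10)
    up = 0.1 + 0.05 * stressor
    down = 1.0 - 0.05 * stressor
    flat = np.full(10, 0.5)
    profile = profile_from(np.vstack([up, down, flat]))
    calls = {c.taxon: c.call for c in screen_species(profile, stressor, alpha=0.1)}
    # renormalisation keeps monotone direction here (flat taxon absorbs it)
    assert calls["t0"] == "tolerant"
    assert calls["t1"] == "sensitive"


def test_null_taxa_classified_at_alpha_rate():
    """Under the null, p-values are uniform: ~10% of taxa classified at alpha=0.1."""
    rng = np.random.default_rng(7)
    stressor = rng.uniform(0, 1, 32)
    mat = rng.lognormal(0, 0.3, size=(100, 32))
    calls = screen_species(profile_from(mat), stressor, alpha=0.1)
    n_classified = sum(c.call != "unclassified" for c in calls)
    assert 3 <= n_classified <= 19  # binomial(100, 0.1) central 95% interval


def test_rare_taxa_are_unclassified():
    mat = np.array([[1, 1, 1, 1, 1], [0.5, 0, 0, 0, 0.2]])
    calls = screen_species(profile_from(mat), np.arange(5.0), min_present=3)
    assert calls[1].call == "unclassified"
    assert calls[1].regression is None


def test_alignment_mismatch_lists_missing_samples():
    profile = profile_from(np.ones((2, 3)), samples=["A", "B", "C"])
    with pytest.raises(AlignmentError, match="C"):
        screen_species(profile, {"A": 1.0, "B": 2.0})


def test_classification_invariant_to_affine_stressor_rescale(rng):
    mat = rng.lognormal(0, 0.5, size=(30, 20))
    stressor = rng.uniform(0, 5, 20)
    base = screen_species(profile_from(mat), stressor, alpha=0.2)
    scaled = screen_species(profile_from(mat), 3.7 * stressor + 11.0, alpha=0.2)
    for a, b in zip(base, scaled):
        assert a.call == b.call
        assert b.regression.p_value == pytest.approx(a.regression.p_value, rel=1e-9)
        assert np.sign(b.regression.slope) == np.sign(a.regression.slope)


def test_planted_responders_recovered(community42, teq42):
    """Sensitivity >= 0.9 and false-positive rate <= 2*alpha on the stated world."""
    profile, truth = community42
    calls = {c.taxon: c.call for c in screen_species(profile, teq42, alpha=0.1)}
    responders = truth[truth.responder]
    nulls = truth[~truth.responder]
    sensitivity = np.mean([calls[t] != "unclassified" for t in responders.taxon])
    fpr = np.mean([calls[t] != "unclassified" for t in nulls.taxon])
    assert sensitivity >= 0.9
    assert fpr <= 0.2


def _mk_samples(ec):
    return [
        SoilSample(sample_id=f"S{i}", ph=8.0, ec=float(e), som=5.0, tph=50.0)
        for i, e in enumerate(ec)
    ]


def _mk_teq(values):
    return [TeqResult(f"S{i}", float(v)) for i, v in enumerate(values)]


def test_key_stressor_with_constructed_effect():
    rng = np.random.default_rng(3)
    ec = rng.uniform(700, 4800, 32)
    richness = 1000 - 3 * ec / 10 + rng.normal(0, 5, 32)
    hits = identify_key_stressors(
        _mk_samples(ec), _mk_teq(rng.uniform(0.01, 1, 32)), richness, alpha=0.05
    )
    assert "EC" in [name for name, _ in hits]
    assert hits[0][0] == "EC"  # strongest (constructed) effect sorts first


def test_key_stressors_null_behaviour():
    rng = np.random.default_rng(5)
    ec = rng.uniform(700, 4800, 32)
    richness = rng.normal(1000, 30, 32)
    hits = identify_key_stressors(
        _mk_samples(ec), _mk_teq(rng.uniform(0.01, 1, 32)), richness, alpha=0.05
    )
    assert len(hits) <= 2  # each candidate significant only with probability alpha


def test_two_constructed_stressors_sort_before_null():
    rng = np.random.default_rng(13)
    ec = rng.uniform(700, 4800, 32)
    teq_vals = rng.uniform(0.01, 1.0, 32)
    richness = 1500 - 0.2 * ec - 1000 * teq_vals + rng.normal(0, 3, 32)
    hits = identify_key_stressors(_mk_samples(ec), _mk_teq(teq_vals), richness, alpha=0.05)
    assert {hits[0][0], hits[1][0]} == {"EC", "TEQ"}
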