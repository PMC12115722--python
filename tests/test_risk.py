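"""Risk quotients, the two-condition decision table and pollution indices."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ednarisk import (
    RiskStandards,
    assess_samples,
    classify_risk,
    igeo,
    nipi,
    pollution_index,
    risk_quotients,
)
from ednarisk.teq import TeqResult


def test_risk_quotients_are_ratios():
    rq_n, rq_m = risk_quotients(0.0028, 0.0028, 0.1956)
    assert rq_n == pytest.approx(1.0)
    rq_n, rq_m = risk_quotients(0.1956, 0.0028, 0.1956)
    assert rq_m == pytest.approx(1.0)
    rq_n, _ = risk_quotients(0.28, 0.0028, 0.1956)
    assert rq_n == pytest.approx(100.0)
    with pytest.raises(ValueError):
        risk_quotients(1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        risk_quotients(1.0, 2.0, 1.0)  # NCs must lie below MPCs


@pytest.mark.parametrize(
    "rq_ncs,rq_mpcs,level",
    [
        (900, 0.5, 2),
        (500, 0.5, 1),
        (900, 1.2, 4),
        (500, 1.2, 3),
        (0.5, 0.2, 0),
        (1.0, 0.0, 1),   # boundary: >= 1 row
        (800.0, 0.0, 2),  # boundary: >= 800 row
        (700, 1.0, 3),   # boundary: RQ_MPCs exactly 1 classifies as >= 1
        (800, 1.0, 4),
        (0.0, 0.0, 0),
    ],
)
def test_decision_table(rq_ncs, rq_mpcs, level):
    assert classify_risk(rq_ncs, rq_mpcs) == level


@settings(deadline=None, max_examples=200)
@given(
    rq_ncs=st.floats(0, 1e6, allow_nan=False),
    rq_mpcs=st.floats(0, 1e4, allow_nan=False),
)
def test_classification_is_total_and_single_valued(rq_ncs, rq_mpcs):
    level = classify_risk(rq_ncs, rq_mpcs)
    assert level in {0, 1, 2, 3, 4}
    assert classify_risk(rq_ncs, rq_mpcs) == level


@settings(deadline=None, max_examples=100)
@given(ci=st.floats(1e-6, 1e3, allow_nan=False))
def test_indices_scale_consistently(ci):
    std, bg = 0.5, 0.2
    pi, g1 = pollution_index(ci, std)
    pi2, g2 = pollution_index(2 * ci, std)
    assert pi2 == pytest.approx(2 * pi, rel=1e-12)
    assert g2 >= g1
    ig, ig_grade = igeo(ci, bg)
    ig2, ig2_grade = igeo(2 * ci, bg)
    assert ig2 == pytest.approx(ig + 1, abs=1e-9)
    assert ig2_grade >= ig_grade
    rq_n, _ = risk_quotients(ci, 0.0028, 0.1956)
    rq_n2, _ = risk_quotients(2 * ci, 0.0028, 0.1956)
    assert rq_n2 == pytest.approx(2 * rq_n, rel=1e-12)


def test_pollution_index_grading():
    assert pollution_index(1.0, 1.0) == (1.0, 2)
    assert pollution_index(3.5, 1.0)[1] == 5  # heavy
    assert pollution_index(0.0, 1.0) == (0.0, 2)


def test_igeo_examples():
    assert igeo(1.5, 1.0)[0] == pytest.approx(0.0)
    assert igeo(3.0, 1.0)[0] == pytest.approx(1.0)
    ig, grade = igeo(12.0, 1.0)
    assert ig == pytest.approx(3.0)
    assert grade == 3
    with pytest.raises(ValueError):
        igeo(0.0, 1.0)


def test_nipi_examples_and_bounds():
    assert nipi([2.0, 2.0, 2.0])[0] == pytest.approx(2.0)
    assert nipi([1.0, 2.0, 3.0])[0] == pytest.approx(np.sqrt(6.5))
    assert nipi([0.9])[0] == pytest.approx(0.9)
    with pytest.raises(ValueError):
        nipi([])


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=20))
def test_nipi_between_mean_and_max(pis):
    value, _ = nipi(pis)
    arr = np.asarray(pis)
    assert value >= arr.mean() - 1e-9
    assert value <= arr.max() + 1e-9


def test_assess_reproduces_reference_summary_statistics(table9):
    standards = RiskStandards(cqv_ncs=0.0028, cqv_mpcs=0.1956)
    teq_results = [
        TeqResult(row.sample_id, row.teq_sum_mg_kg, as_reported=True)
        for row in table9.itertuples()
    ]
    results = assess_samples(teq_results, standards)
    assert len(results) == 32
    teqs = np.array([r.teq for r in results])
    assert teqs.mean() == pytest.approx(0.3611, rel=0.005)
    assert teqs.max() == pytest.approx(1.3034, abs=0.005)
    zero = [r for r in results if r.teq == 0]
    assert all(r.level == 0 and r.warnings for r in zero)


def test_printed_levels_conflict_with_decision_table_and_are_reported(table9):
    """The reference table's own RQ pairs contradict some of its printed levels.

    The package recomputes levels from the printed quotients and reports
    the conflicts instead of reproducing them (e.g. GD3: RQ_MPCs 0.71 < 1
    printed as level 4; GD13: RQ_NCs 706.76 < 800 printed as level 3).
    """
    recomputed = np.array(
        [classify_risk(r, m) for r, m in zip(table9.rq_ncs, table9.rq_mpcs)]
    )
    conflicts = table9.loc[recomputed != table9.rq_level, "sample_id"].tolist()
    assert "GD3" in conflicts
    assert "GD13" in conflicts
    assert len(conflicts) > 0


def test_standards_validation():
    with pytest.raises(ValueError):
        RiskStandards(cqv_ncs=0.2, cqv_mpcs=0.1)
    with pytest.raises(ValueError):
        RiskStandards(cqv_ncs=-1.0, cqv_mpcs=0.1)
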