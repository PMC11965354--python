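"""AHI estimation, severity grading, boundary calibration and agreement
statistics, including the published worked examples."""
import numpy as np
import pytest

import bcgapnea as bg
from bcgapnea.assess import (accuracy_kappa, aggregate_boundaries,
                             confusion_matrix, default_boundary_grid)
from bcgapnea.types import ApneaEvent

# Published 4-class severity confusion matrices (rows = reference class,
# columns = predicted class), before and after boundary adjustment.
CONFUSION_BEFORE = np.array([[8, 0, 0, 0],
                             [3, 2, 1, 1],
                             [1, 6, 2, 0],
                             [1, 2, 2, 3]])
CONFUSION_AFTER = np.array([[8, 0, 0, 0],
                            [1, 2, 2, 2],
                            [0, 0, 8, 1],
                            [0, 0, 3, 5]])


def assessments_from_confusion(cm):
    """Per-subject assessments whose class pairs reproduce ``cm``; AHI
    values are placed inside the nominal band of each class."""
    mid = {0: 2.0, 1: 10.0, 2: 20.0, 3: 40.0}
    out = []
    k = 0
    for i in range(4):
        for j in range(4):
            for _ in range(int(cm[i, j])):
                out.append(bg.SubjectAssessment(
                    f"x{k}", estimated_ahi=mid[j], actual_ahi=mid[i],
                    predicted_class=bg.SEVERITY_CLASSES[j],
                    true_class=bg.SEVERITY_CLASSES[i]))
                k += 1
    return out


def test_estimate_ahi():
    assert bg.estimate_ahi(40, 8.0) == 5.0
    assert bg.estimate_ahi(0, 8.0) == 0.0
    assert bg.estimate_ahi(17, 8.5) == 2.0
    eps = [bg.Episode("s", 0, 30, prediction=1),
           bg.Episode("s", 40, 70, prediction=0)]
    assert bg.estimate_ahi(eps, 1.0) == 1.0
    with pytest.raises(bg.ValidationError):
        bg.estimate_ahi(3, 0.0)


def test_classify_severity_bands():
    assert bg.classify_severity(10.0) == "mild"
    assert bg.classify_severity(10.0, bg.SeverityBoundaries(2, 4, 18)) == \
        "moderate"
    # lower band edges are inclusive
    assert bg.classify_severity(5.0) == "mild"
    assert bg.classify_severity(15.0) == "moderate"
    assert bg.classify_severity(30.0) == "severe"
    assert bg.classify_severity(0.0) == "normal"


def test_adjust_boundaries_perfect_estimates_pick_nominal():
    pairs = [(2.0, "normal"), (3.0, "normal"), (10.0, "mild"),
             (12.0, "mild"), (20.0, "moderate"), (25.0, "moderate"),
             (40.0, "severe"), (50.0, "severe")]
    b = bg.adjust_boundaries(pairs)
    # accuracy 1 everywhere in the separating region; tie-break lands on
    # the triple nearest (5, 15, 30)
    assert b.as_tuple() == (5.0, 15.0, 30.0)


def test_adjust_boundaries_halved_estimates():
    pairs = [(1.0, "normal"), (2.0, "normal"), (5.0, "mild"),
             (6.5, "mild"), (10.0, "moderate"), (13.0, "moderate"),
             (20.0, "severe"), (25.0, "severe")]
    b = bg.adjust_boundaries(pairs)
    ahi = np.array([p[0] for p in pairs])
    cls = np.array([bg.classify_severity(a, b) for a in ahi])
    assert (cls == [p[1] for p in pairs]).all()  # accuracy 1.0
    # boundaries shrink towards the halved scale: each at most half its
    # nominal value (up to the tie-break pull towards nominal)
    assert 2.0 < b.b1 <= 5.0
    assert 6.5 < b.b2 <= 10.0
    assert 13.0 < b.b3 <= 20.0


def test_adjust_boundaries_hand_enumeration():
    pairs = [(1.0, "normal"), (3.0, "mild"), (10.0, "moderate"),
             (25.0, "severe")]
    b = bg.adjust_boundaries(pairs)
    assert 1.0 < b.b1 <= 3.0
    assert 3.0 < b.b2 <= 10.0
    assert 10.0 < b.b3 <= 25.0
    # tie-break: grid triple nearest (5, 15, 30) inside the feasible box
    assert b.as_tuple() == (3.0, 10.0, 25.0)


def test_adjust_boundaries_missing_class_and_empty_grid():
    with pytest.raises(bg.ValidationError, match="severe"):
        bg.adjust_boundaries([(1.0, "normal"), (10.0, "mild"),
                              (20.0, "moderate")])
    with pytest.raises(bg.ValidationError, match="empty"):
        bg.adjust_boundaries([(1.0, "normal"), (3.0, "mild"),
                              (10.0, "moderate"), (25.0, "severe")],
                             grid=np.empty((0, 3)))


def test_boundary_grid_contains_published_values():
    grid = default_boundary_grid()
    assert any(np.allclose(row, (2.0, 4.0, 18.0)) for row in grid)
    assert any(np.allclose(row, (5.0, 15.0, 30.0)) for row in grid)


def test_aggregate_boundaries_median():
    b = bg.SeverityBoundaries
    assert aggregate_boundaries([b(2, 4, 18)] * 31).as_tuple() == (2, 4, 18)
    assert aggregate_boundaries(
        [b(2, 4, 18), b(2, 4, 18), b(3, 5, 20)]).as_tuple() == (2, 4, 18)
    # even fold count: lower median keeps values on the search grid
    assert aggregate_boundaries(
        [b(2, 4, 18), b(3, 5, 20)]).as_tuple() == (2, 4, 18)
    with pytest.raises(bg.ValidationError, match="No folds|no folds"):
        aggregate_boundaries([])


def test_agreement_stats_perfect():
    a = [bg.SubjectAssessment(f"s{i}", ahi, ahi,
                              bg.classify_severity(ahi),
                              bg.classify_severity(ahi))
         for i, ahi in enumerate([2.0, 10.0, 20.0, 40.0])]
    st = bg.agreement_stats(a)
    assert st.spearman_r == pytest.approx(1.0)
    assert st.bland_altman_mean_diff == 0.0
    assert st.kappa_4 == pytest.approx(1.0)
    with pytest.raises(bg.ValidationError):
        bg.agreement_stats(a[:1])


def test_agreement_reproduces_published_matrices():
    st_after = bg.agreement_stats(assessments_from_confusion(CONFUSION_AFTER))
    assert np.array_equal(st_after.confusion_4, CONFUSION_AFTER)
    assert 100 * st_after.accuracy_4 == pytest.approx(71.9, abs=0.05)
    assert st_after.kappa_4 == pytest.approx(0.62, abs=0.005)
    # two-class collapse (normal+mild vs moderate+severe)
    assert 100 * st_after.accuracy_2 == pytest.approx(87.5, abs=0.05)
    assert st_after.kappa_2 == pytest.approx(0.75, abs=0.005)

    st_before = bg.agreement_stats(
        assessments_from_confusion(CONFUSION_BEFORE))
    assert 100 * st_before.accuracy_4 == pytest.approx(46.9, abs=0.05)
    assert st_before.kappa_4 == pytest.approx(0.30, abs=0.005)


def test_kappa_degenerate_cases():
    diag = np.diag([3, 4, 5, 6])
    acc, kap = accuracy_kappa(diag)
    assert acc == 1.0 and kap == 1.0
    # constant prediction: observed agreement equals chance agreement
    cm = np.zeros((4, 4), dtype=int)
    cm[:, 0] = [2, 2, 2, 2]
    acc, kap = accuracy_kappa(cm)
    assert kap == pytest.approx(0.0)


def test_underestimation_vs_hypopnea_construction():
    # hypopnea capture suppressed to 0, obstructive capture 1: the AHI
    # underestimation equals the hypopnea index exactly, rho = 1
    anns, assess = {}, []
    hours = {}
    for i, n_hyp in enumerate([1, 3, 5, 8]):
        sid = f"s{i}"
        events = [ApneaEvent(100.0 + 80 * k, 20, "obstructive")
                  for k in range(4)]
        events += [ApneaEvent(1000.0 + 80 * k, 20, "hypopnea")
                   for k in range(n_hyp)]
        ann = bg.ApneaAnnotation(sid, events, total_sleep_time_s=3600.0)
        anns[sid] = ann
        hours[sid] = 1.0
        actual = ann.actual_ahi(3600.0)
        estimated = 4.0  # only the obstructive events detected
        assess.append(bg.SubjectAssessment(
            sid, estimated, actual, bg.classify_severity(estimated),
            bg.classify_severity(actual)))
    rho, pairs = bg.underestimation_vs_hypopnea(assess, anns, hours)
    assert rho == pytest.approx(1.0)
    np.testing.assert_allclose(pairs["underestimation"],
                               pairs["hypopnea_index"])
    # monotone: more hypopneas never decreases underestimation
    assert pairs["underestimation"].is_monotonic_increasing


def test_underestimation_degenerate_flagged():
    anns = {f"s{i}": bg.ApneaAnnotation(
        f"s{i}", [ApneaEvent(10.0, 20, "obstructive")],
        total_sleep_time_s=3600.0) for i in range(3)}
    assess = [bg.SubjectAssessment(f"s{i}", 1.0, 1.0, "normal", "normal")
              for i in range(3)]
    rho, pairs = bg.underestimation_vs_hypopnea(
        assess, anns, {f"s{i}": 1.0 for i in range(3)})
    assert np.isnan(rho)
    assert len(pairs) == 3


def test_confusion_matrix_helper():
    cm = confusion_matrix(np.array([0, 1, 1]), np.array([0, 1, 0]), 2)
    assert cm.tolist() == [[1, 0], [1, 1]]
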