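"""IDR/IOR calling: run detection, classification, summaries, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optosite import (
    SegmentationParams,
    assign_ss,
    build_chain,
    classify_segments,
    get_plddt_profile,
    low_confidence_runs,
    segment_chain,
    segment_summary,
)
from optosite.secondary_structure import SSAnnotation
from optosite.segmentation import ConfidenceSegment
from optosite.synthetic import SegmentBlueprint, random_blueprint_chain


def _profile(values, start=1):
    return [(start + i, v) for i, v in enumerate(values)]


def _brute_force_runs(values, threshold=85.0, min_length=4):
    """Oracle: test every (start, end) pair for maximal low-confidence runs."""
    n = len(values)
    runs = []
    for i in range(n):
        for j in range(i, n):
            if all(v < threshold for v in values[i : j + 1]):
                left_ok = i == 0 or values[i - 1] >= threshold
                right_ok = j == n - 1 or values[j + 1] >= threshold
                if left_ok and right_ok and j - i + 1 >= min_length:
                    runs.append((i + 1, j + 1))
    return runs


@pytest.mark.parametrize(
    "values, expected",
    [
        ([95.0] * 10, []),                                   # nothing low
        ([95, 95, 80, 80, 80, 95, 95], []),                  # 3 < min_length
        ([95, 95, 80, 80, 80, 80, 95], [(3, 6)]),            # exactly 4
        ([84.9] * 4, [(1, 4)]),                              # strictly below threshold
        ([85.0] * 6, []),                                    # at threshold = confident
    ],
)
def test_run_detection_boundaries(values, expected):
    assert low_confidence_runs(_profile([float(v) for v in values])) == expected


def test_run_detection_two_runs_matches_brute_force():
    values = [95.0] * 4 + [84.9] * 4 + [95.0] * 3 + [60.0] * 7 + [95.0] * 2
    assert low_confidence_runs(_profile(values)) == _brute_force_runs(values)
    assert low_confidence_runs(_profile(values)) == [(5, 8), (12, 18)]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=100, allow_nan=False), min_size=1, max_size=60))
def test_run_detection_equals_brute_force(values):
    assert low_confidence_runs(_profile(values)) == _brute_force_runs(values)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=100, allow_nan=False), min_size=1, max_size=40),
    st.floats(min_value=10, max_value=90),
    st.floats(min_value=0, max_value=9.9),
)
def test_raising_threshold_never_removes_low_residues(values, threshold, bump):
    """Monotonicity: residues low at one threshold stay low at a higher one."""
    lo = low_confidence_runs(_profile(values), SegmentationParams(threshold, 1))
    hi = low_confidence_runs(_profile(values), SegmentationParams(threshold + bump, 1))
    lo_set = {s for a, b in lo for s in range(a, b + 1)}
    hi_set = {s for a, b in hi for s in range(a, b + 1)}
    assert lo_set <= hi_set


def test_classification_by_structured_fraction():
    values = [95.0] * 11 + [70.0] * 7 + [95.0] * 2
    profile = _profile(values)
    all_coil = SSAnnotation("A", [(i, "C") for i in range(1, 21)])
    runs = low_confidence_runs(profile)
    assert runs == [(12, 18)]
    seg = classify_segments(runs, all_coil, profile)[0]
    assert (seg.type, seg.structured_fraction) == ("IDR", 0.0)
    assert seg.mean_plddt == pytest.approx(70.0)
    # 6 of 7 residues helical -> IOR (fraction 6/7 > 0.5 by direct count)
    labels = [(i, "H" if 12 <= i <= 17 else "C") for i in range(1, 21)]
    seg = classify_segments(runs, SSAnnotation("A", labels), profile)[0]
    assert seg.type == "IOR"
    assert seg.structured_fraction == pytest.approx(6 / 7)


def test_labels_numbered_in_sequence_order():
    values = [70.0] * 4 + [95.0] * 2 + [70.0] * 4 + [95.0] * 2 + [70.0] * 4
    profile = _profile(values)
    labels = [(i, "H" if i >= 11 else "C") for i in range(1, 17)]
    segs = classify_segments(low_confidence_runs(profile), SSAnnotation("A", labels), profile)
    assert [s.label for s in segs] == ["IDR1", "IDR2", "IOR1"]


def test_run_outside_annotation_errors():
    profile = _profile([70.0] * 6)
    ss = SSAnnotation("A", [(i, "C") for i in range(1, 5)])
    with pytest.raises(ValueError):
        classify_segments([(1, 6)], ss, profile)


def test_summary_fractions():
    assert segment_summary([], 100).idr_fraction == 0.0
    seg = ConfidenceSegment("IDR", "A", 1, 10, 70.0, 0.0, "IDR1")
    summary = segment_summary([seg], 100)
    assert summary.idr_fraction == pytest.approx(0.10)
    assert summary.segment_shares == {"IDR1": 1.0}
    ior = ConfidenceSegment("IOR", "A", 20, 25, 70.0, 1.0, "IOR1")
    assert segment_summary([seg, ior], 100).n_ior == 1
    with pytest.raises(ValueError):
        segment_summary([seg], 5)


def test_planted_segment_recovery_over_random_blueprints(rng):
    """Generated chains with >=5 pLDDT margin yield exactly the planted spans/types."""
    for i in range(40):
        bps, expected = random_blueprint_chain(rng)
        model = build_chain(bps, seed=5000 + i)
        segs = segment_chain(get_plddt_profile(model, "A"), assign_ss(model, "A"))
        got = [{"start": s.start, "end": s.end, "type": s.type} for s in segs]
        assert got == expected


def test_segments_partition_and_do_not_overlap(rng):
    bps, _ = random_blueprint_chain(rng, n_low_segments=(2, 3))
    model = build_chain(bps, seed=77)
    profile = get_plddt_profile(model, "A")
    segs = segment_chain(profile, assign_ss(model, "A"))
    covered = []
    for s in segs:
        assert s.type in ("IDR", "IOR")
        covered.extend(range(s.start, s.end + 1))
    assert len(covered) == len(set(covered))  # no overlap
    run_residues = {
        sid for a, b in low_confidence_runs(profile) for sid in range(a, b + 1)
    }
    assert set(covered) == run_residues


def test_param_validation():
    with pytest.raises(ValueError):
        SegmentationParams(plddt_threshold=0.0)
    with pytest.raises(ValueError):
        SegmentationParams(min_length=0)
    with pytest.raises(ValueError):
        low_confidence_runs([])
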