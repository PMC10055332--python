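"""Gait classification, mirroring, transitions and prevalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitspace.cycles import cycles_to_frame, extract_step_cycles
from gaitspace.gaits import (
    CATEGORIES,
    TEMPLATES,
    circular_gait_distance,
    classify_phases,
    classify_step,
    gait_prevalence,
    label_cycles,
    mirror_point,
    transition_graph,
    transition_stats,
    write_dot,
)
from gaitspace.io import Limb
from gaitspace.simulate import simulate_bout

from conftest import make_fixed_gait_config

phase_triples = st.tuples(
    st.floats(0, 1, exclude_max=True),
    st.floats(0, 1, exclude_max=True),
    st.floats(0, 1, exclude_max=True),
)


def brute_force_nearest(phi):
    """Independent exhaustive search over the template dictionary."""
    best, best_d = None, np.inf
    for i, t in enumerate(TEMPLATES):
        d = 0.0
        for a, b in zip(phi, t.phases):
            delta = 2 * np.pi * (a - b)
            delta = delta - 2 * np.pi * np.floor(delta / (2 * np.pi) + 0.5)
            d += delta**2
        d = np.sqrt(d)
        if d < best_d - 1e-15:
            best, best_d = i, d
    return best, best_d


class TestDistance:
    def test_identity_and_symmetry(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0, 1, 3), rng.uniform(0, 1, 3)
            assert circular_gait_distance(a, a) == 0.0
            assert circular_gait_distance(a, b) == pytest.approx(
                circular_gait_distance(b, a)
            )

    def test_trot_pace_antiphase_components(self):
        d = circular_gait_distance((0.5, 0.5, 0.0), (0.5, 0.0, 0.5))
        assert d == pytest.approx(np.pi * np.sqrt(2))

    def test_wrapped_difference(self):
        d = circular_gait_distance((0.9, 0, 0), (0.1, 0, 0))
        assert d == pytest.approx(0.4 * np.pi)

    def test_zero_iff_equal_mod_one(self):
        assert circular_gait_distance((0.0, 0.25, 0.5), (1.0 - 1e-15, 0.25, 0.5)) < 1e-9


class TestClassification:
    @pytest.mark.parametrize(
        "phi, duty, expected",
        [
            ((0.5, 0.5, 0.0), 0.43, "trot"),
            ((0.94, 0.60, 0.36), 0.38, "half-bound gallop"),  # average half-bound
            ((0.5, 0.25, 0.75), 0.52, "lateral-sequence walk"),
            ((0.5, 0.25, 0.75), 0.48, "lateral-sequence amble"),
            ((0.0, 0.0, 0.0), 0.3, "pronk"),
        ],
    )
    def test_examples(self, phi, duty, expected):
        assert classify_phases(phi, duty)[1] == expected

    def test_duty_exactly_half_takes_walking_branch(self):
        assert classify_phases((0.5, 0.25, 0.75), 0.5)[1] == "lateral-sequence walk"

    def test_matches_independent_exhaustive_search(self, rng):
        for _ in range(2000):
            phi = rng.uniform(0, 1, 3)
            template, _, d, _ = classify_phases(phi, 0.4)
            idx, d_ref = brute_force_nearest(phi)
            assert TEMPLATES.index(template) == idx
            assert d == pytest.approx(d_ref, abs=1e-9)

    def test_every_category_is_canonical(self):
        for t in TEMPLATES:
            assert t.name_walking in CATEGORIES
            assert t.name_running in CATEGORIES

    def test_tie_is_flagged_and_first_row_wins(self):
        # (1/2, 1/2, 1/2) is equidistant to every three-beat template whose
        # components are all 1/3 or 2/3; the first such table row wins
        template, category, _, tie = classify_phases((0.5, 0.5, 0.5), 0.4)
        assert tie
        assert category == "canter"
        assert np.allclose(template.phases, (1 / 3, 1 / 3, 2 / 3))


class TestMirror:
    @settings(max_examples=200, derandomize=True)
    @given(phase_triples)
    def test_involution(self, phi):
        back = mirror_point(mirror_point(phi))
        for a, b in zip(back, phi):
            assert min(abs(a - b), 1 - abs(a - b)) < 1e-9

    def test_transverse_gallop_templates_map_onto_each_other(self):
        assert mirror_point((0.75, 0.5, 0.25)) == pytest.approx((0.25, 0.5, 0.75))
        assert mirror_point((0.25, 0.5, 0.75)) == pytest.approx((0.75, 0.5, 0.25))

    def test_symmetric_gaits_are_fixed_points(self):
        for phi in [(0.5, 0.5, 0.0), (0.5, 0.0, 0.5), (0.0, 0.5, 0.5), (0.0, 0.0, 0.0)]:
            assert mirror_point(phi) == pytest.approx(phi)

    def test_dictionary_is_closed_under_mirroring(self):
        templates = {t.phases for t in TEMPLATES}
        for t in TEMPLATES:
            mirrored = mirror_point(t.phases)
            match = min(
                templates, key=lambda p: circular_gait_distance(p, mirrored)
            )
            assert circular_gait_distance(match, mirrored) < 1e-9

    def test_template_exact_points_classify_identically_after_mirroring(self):
        for t in TEMPLATES:
            for duty in (0.42, 0.55):
                _, cat, _, _ = classify_phases(t.phases, duty)
                _, cat_m, _, _ = classify_phases(mirror_point(t.phases), duty)
                assert cat == cat_m

    def test_noisy_points_classify_consistently(self, rng):
        kappa = 50.0
        agree = total = 0
        for t in TEMPLATES:
            for _ in range(100):
                phi = (np.array(t.phases) + rng.vonmises(0, kappa, 3) / (2 * np.pi)) % 1
                _, cat, _, _ = classify_phases(phi, 0.42)
                _, cat_m, _, _ = classify_phases(mirror_point(phi), 0.42)
                total += 1
                agree += cat == cat_m
        assert agree / total >= 0.99


class TestLeadLimbs:
    def test_left_lead_gallop_touchdown_order(self):
        cfg = make_fixed_gait_config(
            "gallop", lead_bias=1.0, speed_profile=(122.0, 122.0),
            duty_law=(0.40, 0.0), stride_law=(24.0, 0.0),
        )
        cycles = extract_step_cycles(simulate_bout(cfg).bout).cycles
        for cyc in cycles:
            lab = classify_step(cyc)
            assert lab.category == "transverse gallop"
            assert lab.lead_forelimb is Limb.LF
            assert lab.lead_hindlimb is Limb.LH

    def test_right_lead_is_mirrored(self):
        cfg = make_fixed_gait_config(
            "gallop", lead_bias=0.0, speed_profile=(122.0, 122.0),
            duty_law=(0.40, 0.0), stride_law=(24.0, 0.0),
        )
        cycles = extract_step_cycles(simulate_bout(cfg).bout).cycles
        for cyc in cycles:
            lab = classify_step(cyc)
            assert lab.category == "transverse gallop"
            assert lab.lead_forelimb is Limb.RF
            assert lab.lead_hindlimb is Limb.RH

    def test_synchronous_pair_has_no_lead(self):
        cfg = make_fixed_gait_config(
            "bound", speed_profile=(174.0, 174.0),
            duty_law=(0.34, 0.0), stride_law=(30.0, 0.0),
        )
        cycles = extract_step_cycles(simulate_bout(cfg).bout).cycles
        for cyc in cycles:
            lab = classify_step(cyc)
            assert lab.category == "bound"
            assert lab.lead_hindlimb is None
            assert lab.lead_forelimb is None

    def test_canter_heuristic_cross_check_agrees(self):
        cfg = make_fixed_gait_config(
            "canter", lead_bias=1.0, speed_profile=(106.0, 106.0),
            duty_law=(0.44, 0.0), stride_law=(22.4, 0.0),
        )
        cycles = extract_step_cycles(simulate_bout(cfg).bout).cycles
        for cyc in cycles:
            lab = classify_step(cyc)
            assert lab.category == "canter"
            assert lab.touchdown_lead_forelimb is lab.lead_forelimb


class TestTransitions:
    def test_direct_count_example(self):
        tm = transition_stats([["trot", "trot", "transverse gallop", "trot"]])
        assert tm.counts.loc["trot", "trot"] == 1
        assert tm.counts.loc["trot", "transverse gallop"] == 1
        assert tm.counts.loc["transverse gallop", "trot"] == 1
        assert tm.conditional.loc["trot", "transverse gallop"] == pytest.approx(0.5)
        assert (tm.frequencies.to_numpy() > 0).sum() == 3
        assert tm.frequencies.to_numpy().sum() == pytest.approx(1.0)

    def test_single_step_bout_has_no_transitions(self):
        tm = transition_stats([["trot"]])
        assert tm.counts.to_numpy().sum() == 0

    def test_transitions_never_span_bouts(self):
        tm = transition_stats([["trot"], ["transverse gallop"]])
        assert tm.counts.to_numpy().sum() == 0

    def test_conditional_rows_and_frequencies_normalize(self, rng):
        gaits = ["trot", "canter", "transverse gallop", "bound"]
        seqs = [list(rng.choice(gaits, size=12)) for _ in range(5)]
        tm = transition_stats(seqs)
        sums = tm.conditional.sum(axis=1)
        for gait, s in sums.items():
            if tm.counts.loc[gait].sum() > 0:
                assert s == pytest.approx(1.0)
        assert tm.frequencies.to_numpy().sum() == pytest.approx(1.0)


class TestPrevalence:
    def test_all_one_gait(self, trot_cycles):
        frame = cycles_to_frame(trot_cycles, label_cycles(trot_cycles))
        prev = gait_prevalence(frame)
        assert len(prev) == 1
        assert prev.loc[0, "gait"] == "trot"
        assert prev.loc[0, "proportion"] == 1.0

    def test_three_to_one_split(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "condition": ["intact"] * 4,
                "animal_id": ["A1", "A1", "A2", "A2"],
                "gait": ["trot", "trot", "trot", "bound"],
            }
        )
        prev = gait_prevalence(frame).set_index("gait")
        assert prev.loc["trot", "proportion"] == 0.75
        assert prev.loc["bound", "proportion"] == 0.25
        assert prev.loc["trot", "n_animals"] == 2

    def test_empty(self):
        import pandas as pd

        assert gait_prevalence(pd.DataFrame()).empty


def test_dot_export_lists_nodes_and_edges(tmp_path):
    tm = transition_stats([["trot", "canter", "trot"]])
    graph = transition_graph(tm)
    path = tmp_path / "g.dot"
    write_dot(graph, path)
    text = path.read_text()
    assert text.startswith("digraph")
    assert '"trot" -> "canter"' in text
    assert '"canter" -> "trot"' in text
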