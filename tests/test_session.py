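"""Session events, deterministic replay, SSD-guided direction suggestion."""

import numpy as np
import pytest

from mgrefine import (
    EventError,
    MultilevelDeformation,
    RevisionEvent,
    RevisionSession,
    ScalarImage,
    apply_event,
    auto_revise,
    generate_phantom,
    make_case,
    replay,
    suggest_direction,
    support_slices,
    warp_image,
)


@pytest.fixture
def pair():
    """Reference phantom and a version whose content is shifted by (-3, 0)."""
    ref = generate_phantom((96, 96), n_blobs=3, seed=11)
    d = MultilevelDeformation.initial((96, 96), 16.0)
    # stored +3 in x moves content by -3 (backward warping)
    for idx in np.ndindex(d.levels[0].grid_shape):
        d = d.with_moved_control_point(1, idx, (3.0, 0.0))
    trans, mask = warp_image(ref, d)
    return ref, trans, mask


class TestApplyEvent:
    def test_drag_stores_negated_content_motion(self):
        state = MultilevelDeformation.initial((64, 64), 16.0)
        ev = RevisionEvent(kind="drag", level=1, index=(2, 2),
                           content_motion=(4.0, 0.0))
        out = apply_event(state, ev)
        assert tuple(out.levels[0].displacements[2, 2]) == (-4.0, 0.0)
        assert np.count_nonzero(out.levels[0].displacements) == 1

    def test_refine_keeps_dense_field(self):
        from mgrefine import render_dense_field

        state = MultilevelDeformation.initial((64, 64), 16.0)
        state = apply_event(state, RevisionEvent(kind="drag", level=1,
                                                 index=(3, 3),
                                                 content_motion=(2.0, -1.0)))
        before = render_dense_field(state).vectors
        refined = apply_event(state, RevisionEvent(kind="refine"))
        assert len(refined.levels) == 2
        assert np.array_equal(render_dense_field(refined).vectors, before)

    def test_opposite_drags_cancel(self):
        state = MultilevelDeformation.initial((64, 64), 16.0)
        ev = RevisionEvent(kind="drag", level=1, index=(2, 2),
                           content_motion=(4.0, -2.0))
        inv = RevisionEvent(kind="drag", level=1, index=(2, 2),
                            content_motion=(-4.0, 2.0))
        out = apply_event(apply_event(state, ev), inv)
        assert np.array_equal(out.levels[0].displacements,
                              state.levels[0].displacements)

    def test_invalid_event_reports_ordinal(self):
        state = MultilevelDeformation.initial((64, 64), 16.0)
        bad = RevisionEvent(kind="drag", level=3, index=(0, 0),
                            content_motion=(1.0, 0.0))
        with pytest.raises(EventError, match="event 7"):
            apply_event(state, bad, ordinal=7)

    def test_event_validation(self):
        with pytest.raises(ValueError):
            RevisionEvent(kind="drag", level=1)  # missing payload
        with pytest.raises(ValueError):
            RevisionEvent(kind="refine", level=1)  # spurious payload
        with pytest.raises(ValueError):
            RevisionEvent(kind="wiggle")


class TestSessionSerialization:
    def test_json_round_trip(self):
        session = RevisionSession(
            initial_spacing=16.0,
            events=[
                RevisionEvent(kind="drag", level=1, index=(2, 2),
                              content_motion=(4.0, -1.5)),
                RevisionEvent(kind="refine"),
                RevisionEvent(kind="drag", level=2, index=(5, 3),
                              content_motion=(0.5, 0.0)),
            ],
            metadata={"interpolation": "linear", "reference": "ref.tif"},
        )
        loaded = RevisionSession.from_json(session.to_json())
        assert loaded == session

    def test_rejects_foreign_json(self):
        with pytest.raises(ValueError, match="format"):
            RevisionSession.from_json('{"events": []}')

    def test_load_missing_file(self, tmp_path):
        with pytest.raises(IOError, match="nope.json"):
            RevisionSession.load(tmp_path / "nope.json")


class TestReplay:
    def test_empty_session_returns_input_and_baseline(self, pair):
        ref, trans, _ = pair
        result = replay(ref, trans, RevisionSession(initial_spacing=16.0))
        assert np.array_equal(result.image.data, trans.data)
        assert len(result.trace.entries) == 1
        assert result.trace.entries[0][0] == 0

    def test_trace_length_is_events_plus_one(self, pair):
        ref, trans, _ = pair
        session = RevisionSession(
            initial_spacing=16.0,
            events=[
                RevisionEvent(kind="drag", level=1, index=(3, 3),
                              content_motion=(1.0, 0.0)),
                RevisionEvent(kind="refine"),
            ],
        )
        result = replay(ref, trans, session)
        assert len(result.trace.entries) == 3
        assert [o for o, _ in result.trace.entries] == [0, 1, 2]

    def test_bit_identical_across_runs(self, pair):
        ref, trans, mask = pair
        session = RevisionSession(
            initial_spacing=16.0,
            events=[
                RevisionEvent(kind="drag", level=1, index=(3, 3),
                              content_motion=(1.5, -0.5)),
                RevisionEvent(kind="refine"),
                RevisionEvent(kind="drag", level=2, index=(6, 6),
                              content_motion=(0.5, 0.25)),
            ],
        )
        r1 = replay(ref, trans, session, transformed_mask=mask)
        r2 = replay(ref, trans, session, transformed_mask=mask)
        assert np.array_equal(r1.image.data, r2.image.data)
        assert r1.trace == r2.trace
        for l1, l2 in zip(r1.deformation.levels, r2.deformation.levels):
            assert np.array_equal(l1.displacements, l2.displacements)

    def test_rewarps_from_original_not_cumulative(self, pair):
        """The replayed image equals a single warp by the accumulated
        deformation — resampling blur must not compound."""
        ref, trans, _ = pair
        events = [
            RevisionEvent(kind="drag", level=1, index=(3, 3),
                          content_motion=(2.0, 0.0)),
            RevisionEvent(kind="drag", level=1, index=(4, 4),
                          content_motion=(0.0, 1.0)),
        ]
        session = RevisionSession(initial_spacing=16.0, events=events)
        result = replay(ref, trans, session)
        state = MultilevelDeformation.initial(ref.shape, 16.0)
        for ev in events:
            state = apply_event(state, ev)
        once, _ = warp_image(trans, state)
        assert np.array_equal(result.image.data, once.data)

    def test_event_error_carries_ordinal(self, pair):
        ref, trans, _ = pair
        session = RevisionSession(
            initial_spacing=16.0,
            events=[
                RevisionEvent(kind="refine"),
                RevisionEvent(kind="drag", level=9, index=(0, 0),
                              content_motion=(1.0, 0.0)),
            ],
        )
        with pytest.raises(EventError, match="event 2"):
            replay(ref, trans, session)

    def test_shape_mismatch_rejected(self, pair):
        ref, _, _ = pair
        small = ScalarImage(np.zeros((32, 32)))
        with pytest.raises(ValueError, match="shape"):
            replay(ref, small, RevisionSession(initial_spacing=16.0))


class TestSuggestDirection:
    def test_known_shift_suggests_corrective_motion(self, pair):
        """Content sits at -3 in x, so the corrective content motion is +x."""
        ref, trans, mask = pair
        state = MultilevelDeformation.initial(ref.shape, 16.0)
        # probe a control point near the image centre
        signs = suggest_direction(state, ref, trans, level=1, index=(4, 4),
                                  probe_step=1.0, transformed_mask=mask)
        assert signs[0] == +1

    def test_perfectly_registered_suggests_nothing(self):
        ref = generate_phantom((96, 96), n_blobs=3, seed=11)
        state = MultilevelDeformation.initial(ref.shape, 16.0)
        signs = suggest_direction(state, ref, ref, level=1, index=(4, 4),
                                  probe_step=1.0)
        assert signs == (0, 0)

    def test_sign_flips_when_images_swapped(self, pair):
        ref, trans, mask = pair
        state = MultilevelDeformation.initial(ref.shape, 16.0)
        fwd = suggest_direction(state, ref, trans, level=1, index=(4, 4),
                                probe_step=1.0, transformed_mask=mask)
        rev = suggest_direction(state, trans, ref, level=1, index=(4, 4),
                                probe_step=1.0)
        assert fwd[0] == -rev[0] != 0

    def test_pure_function_state_unchanged(self, pair):
        ref, trans, _ = pair
        state = MultilevelDeformation.initial(ref.shape, 16.0)
        before = state.levels[0].displacements.copy()
        suggest_direction(state, ref, trans, level=1, index=(4, 4),
                          probe_step=1.0)
        assert np.array_equal(state.levels[0].displacements, before)

    def test_invalid_probe_arguments(self, pair):
        ref, trans, _ = pair
        state = MultilevelDeformation.initial(ref.shape, 16.0)
        with pytest.raises(ValueError, match="probe_step"):
            suggest_direction(state, ref, trans, 1, (4, 4), probe_step=0.0)
        with pytest.raises(IndexError):
            suggest_direction(state, ref, trans, 1, (99, 4), probe_step=1.0)


class TestSupportSlices:
    def test_support_covers_four_cells(self):
        state = MultilevelDeformation.initial((96, 96), 16.0)
        region = support_slices(state, 1, (4, 4))  # conceptual (3,3) at 48
        assert region == (slice(16, 80), slice(16, 80))

    def test_margin_point_clips_to_domain(self):
        state = MultilevelDeformation.initial((96, 96), 16.0)
        region = support_slices(state, 1, (0, 0))  # conceptual (-1,-1)
        assert region == (slice(0, 16), slice(0, 16))


class TestGreedyDescent:
    def test_auto_revise_reduces_ssd_on_synthetic_case(self):
        """SSD supervision is sound: greedy probing at shrinking steps takes
        a known misregistration most of the way down."""
        case = make_case((96, 96), spacing=16.0, max_magnitude=3.0, seed=4,
                         n_blobs=4)
        d0 = MultilevelDeformation.initial((96, 96), 16.0)
        _, trace = auto_revise(case.reference, case.transformed, d0,
                               steps=(2.0, 1.0, 0.5),
                               transformed_mask=case.valid_mask)
        assert trace[-1] < trace[0]
        assert all(b <= a * 1.001 for a, b in zip(trace, trace[1:]))
        assert trace[-1] <= 0.4 * trace[0]
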