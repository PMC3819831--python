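"""Replayable revision sessions: drag events, refinements, SSD supervision.

The interactive workflow — drag a control point, watch the SSD and the
overlay, refine the grid when the coarse level has done its work — is
recorded as an ordered event list and replayed deterministically, which is
what makes manual revision scriptable, diffable and testable.

Two conventions matter:

* Drag events store the desired CONTENT motion in voxels.  Because warping
  is backward (pull-back), the engine negates the vector before adding it
  to the lattice, so "drag content right" moves content right.
* After every event the transformed image is re-warped from the ORIGINAL
  input with the accumulated deformation — never cumulatively resampled —
  so interpolation blur does not compound and the replayed result equals a
  single warp by the final deformation.

SSD is recorded before any event (the baseline) and after each one; if a
drag makes the SSD rise, the drag direction should be inverted — the rule
:func:`suggest_direction` automates by probing both signs per axis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Sequence

import numpy as np

from .deformation import MultilevelDeformation, displacement_on_grid
from .overlay import ssd
from .warping import ScalarImage, warp_image, INTERPOLATION_ORDERS

__all__ = [
    "RevisionEvent",
    "RevisionSession",
    "SsdTrace",
    "EventError",
    "ReplayResult",
    "apply_event",
    "replay",
    "suggest_direction",
    "auto_revise",
    "support_slices",
]

SESSION_FORMAT_VERSION = 1


class EventError(ValueError):
    """An event failed validation or application; carries its 1-based ordinal."""

    def __init__(self, ordinal: int, message: str):
        super().__init__(f"event {ordinal}: {message}")
        self.ordinal = ordinal


@dataclass(frozen=True)
class RevisionEvent:
    """One revision step: a control-point drag or a grid refinement.

    Drags carry the 1-based ``level``, the storage ``index`` of the control
    point, and ``content_motion`` — the voxel motion the user wants the
    image content to make.  Refine events carry no payload.
    """

    kind: str
    level: int | None = None
    index: tuple[int, ...] | None = None
    content_motion: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("drag", "refine"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "drag":
            if self.level is None or self.index is None or self.content_motion is None:
                raise ValueError("drag events need level, index and content_motion")
            object.__setattr__(self, "index", tuple(int(i) for i in self.index))
            object.__setattr__(
                self, "content_motion", tuple(float(m) for m in self.content_motion)
            )
        else:
            if (self.level, self.index, self.content_motion) != (None, None, None):
                raise ValueError("refine events carry no payload")

    def to_dict(self) -> dict:
        if self.kind == "refine":
            return {"kind": "refine"}
        return {
            "kind": "drag",
            "level": self.level,
            "index": list(self.index),  # type: ignore[arg-type]
            "content_motion": list(self.content_motion),  # type: ignore[arg-type]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RevisionEvent":
        return cls(
            kind=d["kind"],
            level=d.get("level"),
            index=tuple(d["index"]) if "index" in d else None,
            content_motion=tuple(d["content_motion"])
            if "content_motion" in d
            else None,
        )


@dataclass
class RevisionSession:
    """Ordered, replayable record of a revision process.

    ``initial_spacing`` seeds the level-1 lattice; ``metadata`` carries the
    interpolation choice, a display threshold and free-form image
    identifiers.  Serialised as versioned JSON (diffable, hand-editable).
    """

    initial_spacing: float | tuple[float, ...]
    events: list[RevisionEvent] = dataclass_field(default_factory=list)
    metadata: dict = dataclass_field(default_factory=dict)

    @property
    def interpolation(self) -> str:
        interp = self.metadata.get("interpolation", "linear")
        if interp not in INTERPOLATION_ORDERS:
            raise ValueError(f"unknown interpolation {interp!r} in session metadata")
        return interp

    def to_json(self) -> str:
        spacing = (
            self.initial_spacing
            if np.isscalar(self.initial_spacing)
            else list(self.initial_spacing)  # type: ignore[arg-type]
        )
        return json.dumps(
            {
                "format": "mgrefine-session",
                "version": SESSION_FORMAT_VERSION,
                "initial_spacing": spacing,
                "metadata": self.metadata,
                "events": [e.to_dict() for e in self.events],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RevisionSession":
        d = json.loads(text)
        if d.get("format") != "mgrefine-session":
            raise ValueError("not a mgrefine session file (missing format tag)")
        if d.get("version") != SESSION_FORMAT_VERSION:
            raise ValueError(f"unsupported session version {d.get('version')!r}")
        spacing = d["initial_spacing"]
        if isinstance(spacing, list):
            spacing = tuple(spacing)
        return cls(
            initial_spacing=spacing,
            events=[RevisionEvent.from_dict(e) for e in d["events"]],
            metadata=d.get("metadata", {}),
        )

    def save(self, path: "str | Path") -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: "str | Path") -> "RevisionSession":
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise IOError(f"cannot read session file {path}: {exc}") from exc
        return cls.from_json(text)


@dataclass(frozen=True)
class SsdTrace:
    """(event ordinal, SSD) pairs; ordinal 0 is the pre-revision baseline."""

    entries: tuple[tuple[int, float], ...]

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.entries]

    @property
    def baseline(self) -> float:
        return self.entries[0][1]

    @property
    def final(self) -> float:
        return self.entries[-1][1]


@dataclass(frozen=True)
class ReplayResult:
    image: ScalarImage
    valid_mask: np.ndarray
    deformation: MultilevelDeformation
    trace: SsdTrace


def apply_event(
    state: MultilevelDeformation, event: RevisionEvent, ordinal: int = 0
) -> MultilevelDeformation:
    """Apply one event: drag stores the NEGATED content motion; refine appends."""
    try:
        if event.kind == "refine":
            return state.refined()
        delta = tuple(-m for m in event.content_motion)  # type: ignore[union-attr]
        return state.with_moved_control_point(event.level, event.index, delta)  # type: ignore[arg-type]
    except (ValueError, IndexError) as exc:
        raise EventError(ordinal, str(exc)) from exc


def replay(
    reference: ScalarImage,
    transformed: ScalarImage,
    session: RevisionSession,
    roi: np.ndarray | None = None,
    transformed_mask: np.ndarray | None = None,
) -> ReplayResult:
    """Replay a session, recording SSD after each event.

    SSD is always computed over the current warp validity mask intersected
    with the optional ROI; the baseline (ordinal 0) uses the unwarped
    transformed input.  ``transformed_mask`` marks which voxels of the
    transformed input are real data (its own overlap mask when it came out
    of an upstream warp); outside voxels never enter the SSD.
    """
    if reference.shape != transformed.shape:
        raise ValueError(
            f"reference shape {reference.shape} != transformed shape "
            f"{transformed.shape}"
        )
    interp = session.interpolation
    state = MultilevelDeformation.initial(reference.shape, session.initial_spacing)

    def _and_masks(*masks: "np.ndarray | None") -> np.ndarray:
        out = np.ones(reference.shape, dtype=bool)
        for m in masks:
            if m is not None:
                out &= np.asarray(m, dtype=bool)
        return out

    entries = [(0, ssd(reference, transformed, _and_masks(roi, transformed_mask)))]
    current = transformed
    mask = _and_masks(roi, transformed_mask)
    for ordinal, event in enumerate(session.events, start=1):
        state = apply_event(state, event, ordinal)
        current, valid = warp_image(transformed, state, interpolation=interp,
                                    input_mask=transformed_mask)
        mask = _and_masks(valid, roi)
        entries.append((ordinal, ssd(reference, current, mask)))
    return ReplayResult(
        image=current,
        valid_mask=mask,
        deformation=state,
        trace=SsdTrace(entries=tuple(entries)),
    )


def support_slices(
    deformation: MultilevelDeformation, level: int, index: Sequence[int]
) -> tuple[slice, ...]:
    """Voxel slices of the region a control point can influence.

    Conceptual control point c (storage index - 1) on an axis with spacing
    s reaches lattice coordinates (c-2, c+2), i.e. image coordinates
    ((c-2) s, (c+2) s), clipped to the domain.
    """
    lat = deformation.levels[level - 1]
    slices = []
    for i, sp, extent, g in zip(index, lat.spacing, lat.domain_shape, lat.grid_shape):
        if not 0 <= i < g:
            raise IndexError(f"control-point index {i} out of bounds [0, {g})")
        c = i - 1
        lo = max(0, int(np.ceil((c - 2) * sp)))
        hi = min(extent, int(np.ceil((c + 2) * sp)))
        slices.append(slice(lo, max(lo, hi)))
    return tuple(slices)


def _region_ssd(
    state: MultilevelDeformation,
    reference: ScalarImage,
    transformed: ScalarImage,
    region: tuple[slice, ...],
    interpolation: str,
    transformed_mask: np.ndarray | None = None,
) -> float:
    """SSD over one region, warping only that region (locality shortcut)."""
    from scipy import ndimage

    axis_coords = [np.arange(s.start, s.stop, dtype=float) for s in region]
    if any(c.size == 0 for c in axis_coords):
        return float("nan")
    disp = displacement_on_grid(state, axis_coords)
    grid = np.stack(np.meshgrid(*axis_coords, indexing="ij"), axis=-1)
    sample = grid + disp
    mask = np.ones(sample.shape[:-1], dtype=bool)
    for axis, extent in enumerate(reference.shape):
        c = sample[..., axis]
        mask &= (c >= 0.0) & (c <= extent - 1.0)
    if transformed_mask is not None:
        covered = ndimage.map_coordinates(
            np.asarray(transformed_mask, dtype=float),
            np.moveaxis(sample, -1, 0),
            order=1, mode="constant", cval=0.0,
        )
        mask &= covered >= 1.0 - 1e-9
    if not mask.any():
        return float("nan")
    warped = ndimage.map_coordinates(
        transformed.data,
        np.moveaxis(sample, -1, 0),
        order=INTERPOLATION_ORDERS[interpolation],
        mode="constant",
        cval=0.0,
    )
    ref_region = reference.data[region]
    d = ref_region[mask] - warped[mask]
    return float(np.mean(d * d))


def suggest_direction(
    state: MultilevelDeformation,
    reference: ScalarImage,
    transformed: ScalarImage,
    level: int,
    index: Sequence[int],
    probe_step: float,
    interpolation: str = "linear",
    transformed_mask: np.ndarray | None = None,
) -> tuple[int, ...]:
    """Per-axis sign of the content motion that lowers SSD, 0 if neither does.

    Probes +/-``probe_step`` content motion of one control point and
    compares SSD restricted to that point's support region (equivalent in
    effect to the global SSD for a single point, by B-spline locality, and
    much cheaper).  Pure: ``state`` is not modified.
    """
    if probe_step <= 0:
        raise ValueError(f"probe_step must be > 0, got {probe_step}")
    if not 1 <= level <= len(state.levels):
        raise IndexError(f"level {level} does not exist")
    index = tuple(int(i) for i in index)
    region = support_slices(state, level, index)
    base = _region_ssd(state, reference, transformed, region, interpolation,
                       transformed_mask)
    ndim = state.ndim
    signs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # probing a coarse level is fine
        for axis in range(ndim):
            best_sign = 0
            best = base
            for sign in (+1, -1):
                motion = np.zeros(ndim)
                motion[axis] = sign * probe_step
                cand = state.with_moved_control_point(level, index, -motion)
                val = _region_ssd(cand, reference, transformed, region,
                                  interpolation, transformed_mask)
                if np.isfinite(val) and (not np.isfinite(best) or val < best):
                    best = val
                    best_sign = sign
            signs.append(best_sign)
    return tuple(signs)


def auto_revise(
    reference: ScalarImage,
    transformed: ScalarImage,
    deformation: MultilevelDeformation,
    steps: Sequence[float] = (2.0, 1.0, 0.5),
    max_moves: int = 8,
    interpolation: str = "linear",
    transformed_mask: np.ndarray | None = None,
) -> tuple[MultilevelDeformation, list[float]]:
    """Greedy SSD descent over the finest level, one sweep per step size.

    For every control point of the finest lattice and every axis, ask
    :func:`suggest_direction` for the improving sign at the current step
    size, then keep stepping in that direction (up to ``max_moves`` quanta)
    while the support-region SSD strictly decreases.  Shrinking steps across
    sweeps mirror the coarse-to-fine practice of manual revision.

    Returns the revised deformation and the global SSD after each sweep
    (element 0 is the starting SSD).
    """
    state = deformation
    level = len(state.levels)

    def global_ssd(s: MultilevelDeformation) -> float:
        warped, valid = warp_image(transformed, s, interpolation=interpolation,
                                   input_mask=transformed_mask)
        return ssd(reference, warped, valid)

    trace = [global_ssd(state)]
    for step in steps:
        for index in np.ndindex(state.levels[level - 1].grid_shape):
            region = support_slices(state, level, index)
            if any(s.stop <= s.start for s in region):
                continue
            signs = suggest_direction(
                state, reference, transformed, level, index, probe_step=step,
                interpolation=interpolation, transformed_mask=transformed_mask,
            )
            for axis, sign in enumerate(signs):
                if sign == 0:
                    continue
                current = _region_ssd(state, reference, transformed, region,
                                      interpolation, transformed_mask)
                for _ in range(max_moves):
                    motion = np.zeros(state.ndim)
                    motion[axis] = sign * step
                    cand = state.with_moved_control_point(level, index, -motion)
                    val = _region_ssd(cand, reference, transformed, region,
                                      interpolation, transformed_mask)
                    if np.isfinite(val) and val < current:
                        state, current = cand, val
                    else:
                        break
        trace.append(global_ssd(state))
    return state, trace
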