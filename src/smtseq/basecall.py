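"""Track assembly and flow-order base calling.

Incorporation spots are grouped into per-anchor *tracks*: the set of
incorporation-spot centroids falling within a fixed pixel radius of a
template-channel anchor across cycles.  Tracks anchored at positions
closer than twice the radius to another anchor are ambiguous and
excluded.  A track decodes to a read by mapping each event cycle c to
the flowed base ``flow_order[(c - 1) % 4]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .imageproc import (
    DetectionParams,
    IncorporationSpot,
    Spot,
    detect_spots,
    register_stack,
)
from .imagesim import ImageStack
from .simcore import FlowProtocol, ReadSet


@dataclass(frozen=True)
class TrackingParams:
    track_radius: float = 1.6  # pixels

    def __post_init__(self):
        if self.track_radius <= 0:
            raise ValueError("track_radius must be positive")


@dataclass
class Track:
    anchor_id: int
    anchor_x: float
    anchor_y: float
    events: List[Tuple[int, IncorporationSpot]]  # (1-based cycle, spot), ascending
    ambiguous: bool = False

    @property
    def event_cycles(self) -> List[int]:
        return [c for c, _ in self.events]


def build_tracks(
    anchors: Sequence[Spot],
    incorporation_spots_by_cycle: Mapping[int, Sequence[Spot]],
    params: TrackingParams = TrackingParams(),
) -> List[Track]:
    """Group incorporation spots into per-anchor tracks.

    Every incorporation spot is assigned to its nearest anchor when
    within ``track_radius`` (one event per anchor per cycle: nearest
    wins, ties to the lower spot index); anchors with a neighbour closer
    than 2 x radius are flagged ambiguous, and their tracks are excluded
    from base calling.
    """
    n = len(anchors)
    tracks = [
        Track(anchor_id=i, anchor_x=a.x, anchor_y=a.y, events=[]) for i, a in enumerate(anchors)
    ]
    if n == 0:
        return tracks
    ax = np.array([a.x for a in anchors])
    ay = np.array([a.y for a in anchors])
    # ambiguity: any anchor pair closer than twice the track radius
    for i in range(n):
        d2 = (ax - ax[i]) ** 2 + (ay - ay[i]) ** 2
        d2[i] = np.inf
        if d2.min() < (2.0 * params.track_radius) ** 2:
            tracks[i].ambiguous = True
    for cycle in sorted(incorporation_spots_by_cycle):
        spots = incorporation_spots_by_cycle[cycle]
        claimed: Dict[int, Tuple[float, int]] = {}
        for si, s in enumerate(spots):
            d = np.hypot(ax - s.x, ay - s.y)
            ai = int(np.argmin(d))
            dist = float(d[ai])
            if dist > params.track_radius:
                continue
            prev = claimed.get(ai)
            if prev is None or (dist, si) < prev:
                claimed[ai] = (dist, si)
        for ai, (dist, si) in claimed.items():
            tracks[ai].events.append(
                (cycle, IncorporationSpot(spot=spots[si], cycle=cycle, anchor_id=ai,
                                          distance=dist))
            )
    for t in tracks:
        t.events.sort(key=lambda e: e[0])
    return tracks


def decode_track(track: Track, protocol: FlowProtocol) -> str:
    """Convert a track to its read by the flow order (cycles ascending)."""
    if track.ambiguous:
        raise ValueError(f"track {track.anchor_id} is ambiguous and cannot be decoded")
    return "".join(protocol.flow_base(c) for c in track.event_cycles)


def call_field(
    stack: ImageStack,
    protocol: FlowProtocol,
    detection: DetectionParams = DetectionParams(),
    tracking: TrackingParams = TrackingParams(),
    field_id: int = 0,
    reference_cycle: int = 1,
) -> Tuple[ReadSet, List[Track]]:
    """End-to-end image pipeline: register, detect, track, decode.

    Registers all cycles to the reference cycle, detects anchors on the
    registered template channel of that cycle and incorporation spots on
    every registered incorporation image, assembles tracks and decodes
    the unambiguous ones.  Read ids encode the field and the anchor
    coordinates.
    """
    registered, _ = register_stack(stack, reference_cycle=reference_cycle)
    anchors = detect_spots(registered.template[reference_cycle - 1], detection)
    spots_by_cycle = {
        c + 1: detect_spots(registered.incorporation[c], detection)
        for c in range(registered.n_cycles)
    }
    tracks = build_tracks(anchors, spots_by_cycle, tracking)
    ids, seqs = [], []
    for t in tracks:
        if t.ambiguous:
            continue
        ids.append(f"f{field_id}_a{t.anchor_id}_x{t.anchor_x:.2f}_y{t.anchor_y:.2f}")
        seqs.append(decode_track(t, protocol))
    n = len(ids)
    reads = ReadSet(
        ids=ids,
        seqs=seqs,
        template_index=np.full(n, -1, dtype=np.int32),
        origin=np.zeros(n, dtype=np.int8),
        batch=np.full(n, field_id, dtype=np.int32),
        provenance="pipeline-called",
    )
    return reads, tracks
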