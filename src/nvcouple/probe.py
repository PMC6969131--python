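"""Optical probe geometry: two hexagonal patches, one per hemisphere.

Each patch carries 8 sources and 2 detectors on a round (hexagonal) grid
with 15 mm between neighbouring optodes.  The two detectors sit on adjacent
grid sites; the sources occupy every remaining site at one grid step from a
detector.  Two of the eight sources are equidistant from both detectors, so
each detector sees exactly 5 sources at 15 mm and the patch yields 10
source-detector channels.  Only inter-optode distances enter the analysis,
so the geometry is kept planar per patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

GRID_STEP_MM = 15.0
DEFAULT_ADJACENCY_RADIUS_MM = 20.0

#: Right-temporal channel retaining residual coupling in the IVH simulator arm:
#: the most inferior channel of the right patch (set after build_probe below).
RIGHT_TEMPORAL_CHANNEL = "R_D1-S6"


@dataclass(frozen=True)
class Optode:
    optode_id: str
    kind: str  # "source" | "detector"
    hemisphere: str  # "L" | "R"
    x_mm: float
    y_mm: float


@dataclass(frozen=True)
class Channel:
    channel_id: str
    source_id: str
    detector_id: str
    hemisphere: str
    midpoint_mm: tuple[float, float]
    separation_mm: float


@dataclass
class ProbeLayout:
    optodes: list[Optode]
    channels: list[Channel]

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def hemisphere_of(self) -> dict[str, str]:
        return {c.channel_id: c.hemisphere for c in self.channels}

    def channels_of(self, hemisphere: str) -> list[str]:
        return [c.channel_id for c in self.channels if c.hemisphere == hemisphere]

    def midpoints(self) -> dict[str, np.ndarray]:
        return {c.channel_id: np.asarray(c.midpoint_mm) for c in self.channels}

    def to_json(self, path) -> None:
        payload = {
            "optodes": [vars(o) for o in self.optodes],
            "channels": [
                {
                    "channel_id": c.channel_id,
                    "source_id": c.source_id,
                    "detector_id": c.detector_id,
                    "hemisphere": c.hemisphere,
                    "midpoint_mm": list(c.midpoint_mm),
                    "separation_mm": c.separation_mm,
                }
                for c in self.channels
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ProbeLayout":
        with open(path) as fh:
            payload = json.load(fh)
        optodes = [Optode(**o) for o in payload["optodes"]]
        channels = [
            Channel(
                channel_id=c["channel_id"],
                source_id=c["source_id"],
                detector_id=c["detector_id"],
                hemisphere=c["hemisphere"],
                midpoint_mm=tuple(c["midpoint_mm"]),
                separation_mm=c["separation_mm"],
            )
            for c in payload["channels"]
        ]
        return cls(optodes=optodes, channels=channels)


def _hex_patch(hemisphere: str) -> tuple[list[Optode], list[Channel]]:
    """One patch: detectors on two adjacent hexagonal-grid sites, sources on
    every other site one step from a detector."""
    s = GRID_STEP_MM
    h = s * np.sqrt(3) / 2  # hex row height
    detectors = {"D1": (0.0, 0.0), "D2": (s, 0.0)}

    # All hexagonal neighbours of either detector, minus the detectors themselves.
    def neighbours(p):
        x, y = p
        return [
            (x + s, y), (x - s, y),
            (x + s / 2, y + h), (x - s / 2, y + h),
            (x + s / 2, y - h), (x - s / 2, y - h),
        ]

    src_pos: list[tuple[float, float]] = []
    for d in detectors.values():
        for q in neighbours(d):
            if any(np.hypot(q[0] - dx, q[1] - dy) < 1e-9 for dx, dy in detectors.values()):
                continue
            if any(np.hypot(q[0] - px, q[1] - py) < 1e-9 for px, py in src_pos):
                continue
            src_pos.append(q)
    # Sort for a stable, readable ordering: by y descending then x.
    src_pos.sort(key=lambda p: (-round(p[1], 6), round(p[0], 6)))
    sources = {f"S{i + 1}": p for i, p in enumerate(src_pos)}

    optodes = [
        Optode(f"{hemisphere}_{name}", "detector", hemisphere, *pos)
        for name, pos in detectors.items()
    ] + [
        Optode(f"{hemisphere}_{name}", "source", hemisphere, *pos)
        for name, pos in sources.items()
    ]

    channels = []
    for dname, dpos in detectors.items():
        for sname, spos in sources.items():
            sep = float(np.hypot(spos[0] - dpos[0], spos[1] - dpos[1]))
            if abs(sep - s) < 1e-9:
                mid = ((spos[0] + dpos[0]) / 2, (spos[1] + dpos[1]) / 2)
                channels.append(
                    Channel(
                        channel_id=f"{hemisphere}_{dname}-{sname}",
                        source_id=f"{hemisphere}_{sname}",
                        detector_id=f"{hemisphere}_{dname}",
                        hemisphere=hemisphere,
                        midpoint_mm=mid,
                        separation_mm=sep,
                    )
                )
    return optodes, channels


def build_probe() -> ProbeLayout:
    """Canonical two-patch layout: 8 sources + 2 detectors and 10 channels
    per hemisphere, 15 mm source-detector separation throughout."""
    optodes, channels = [], []
    for hemi in ("L", "R"):
        o, c = _hex_patch(hemi)
        optodes.extend(o)
        channels.extend(c)
    return ProbeLayout(optodes=optodes, channels=channels)


def channel_adjacency(
    layout: ProbeLayout, radius_mm: float = DEFAULT_ADJACENCY_RADIUS_MM
) -> dict[str, set[str]]:
    """Spatial neighbourhood used by the cluster statistics.

    Two channels are adjacent iff they lie on the same hemisphere and their
    midpoints are within ``radius_mm``.  The relation is symmetric and
    irreflexive; channels never connect across hemispheres.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius_mm must be > 0, got {radius_mm}")
    mids = layout.midpoints()
    hemi = layout.hemisphere_of()
    adj: dict[str, set[str]] = {cid: set() for cid in layout.channel_ids}
    ids = layout.channel_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if hemi[a] != hemi[b]:
                continue
            if np.linalg.norm(mids[a] - mids[b]) <= radius_mm:
                adj[a].add(b)
                adj[b].add(a)
    return adj


def right_temporal_channel(layout: ProbeLayout) -> str:
    """The designated right-temporal channel: lowest midpoint of the right
    patch (ties broken by x).  Used as the residual-coupling site in the IVH
    simulator arm."""
    right = [c for c in layout.channels if c.hemisphere == "R"]
    c = min(right, key=lambda c: (c.midpoint_mm[1], c.midpoint_mm[0]))
    return c.channel_id
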