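"""Arena geometry and constraint-satisfying goal placement.

The paradigm takes place in square virtual rooms (40 x 40 arbitrary
units, a.u.) in which a participant navigates to a hidden goal box.
Goal locations are not free: they must keep clear of walls so the goal
box can be circled, keep a minimum walking distance from the starting
corners so naive navigation cannot stumble into them immediately, and
collectively tile the floor roughly evenly.  New (NPA) goal locations
additionally keep away from the room's old (OPA) goal and from every
other room's OPA, so that the old and new association never overlap
within or across rooms.

All placement here is rejection sampling against explicit distance
constraints; every generated layout is therefore exactly verifiable
after the fact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ArenaGeometry",
    "Location",
    "RoomConfig",
    "ParticipantConfig",
    "InfeasibleLayoutError",
    "WALLS",
    "OPPOSITE_WALL",
    "sample_opa_locations",
    "sample_npa_locations",
    "build_participant",
]

#: Wall labels, in the fixed order used for start-point bookkeeping.
WALLS = ("north", "east", "south", "west")
OPPOSITE_WALL = {"north": "south", "south": "north", "east": "west", "west": "east"}


class InfeasibleLayoutError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the placement constraints."""


class Location(NamedTuple):
    """A point on the arena floor, in arbitrary units."""

    x: float
    y: float

    def distance_to(self, other: "Location") -> float:
        return float(np.hypot(self.x - other.x, self.y - other.y))


@dataclass(frozen=True)
class ArenaGeometry:
    """Fixed paradigm constants of one virtual room.

    Parameters
    ----------
    width, depth : float
        Floor dimensions in a.u. (square 40 x 40 rooms by default).
    wall_height : float
        Wall height in a.u.; metadata only, navigation is planar.
    box_size : float
        Side of the cube carrying the goal stimulus.
    visibility_diameter : float
        Diameter of the circle within which a hidden goal becomes
        visible to the navigator ("arrival" trigger).
    contact_threshold : float
        Diameter of the circle within which walking into the goal ends
        the trial.
    speed : float
        Walking speed in a.u. per second.  Converts the "3-second
        walking distance" placement rule into a metric distance.
    wall_margin : float
        Minimum distance of any goal location from every wall, so the
        goal box can be circled on all sides.
    """

    width: float = 40.0
    depth: float = 40.0
    wall_height: float = 10.0
    box_size: float = 3.0
    visibility_diameter: float = 7.0
    contact_threshold: float = 2.0
    speed: float = 4.0
    wall_margin: float = 3.0

    def __post_init__(self) -> None:
        for name in ("width", "depth", "wall_height", "box_size",
                     "visibility_diameter", "contact_threshold", "speed",
                     "wall_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.visibility_diameter / 2 <= self.contact_threshold / 2:
            raise ValueError("visibility radius must exceed contact radius")
        if self.wall_margin < self.box_size:
            raise ValueError("wall_margin must be >= box_size so the goal "
                             "box can be circled on all sides")

    @property
    def visibility_radius(self) -> float:
        return self.visibility_diameter / 2.0

    @property
    def contact_radius(self) -> float:
        return self.contact_threshold / 2.0

    @property
    def corners(self) -> tuple[Location, ...]:
        return (Location(0.0, 0.0), Location(self.width, 0.0),
                Location(self.width, self.depth), Location(0.0, self.depth))

    @property
    def center(self) -> Location:
        return Location(self.width / 2.0, self.depth / 2.0)

    @property
    def start_clearance(self) -> float:
        """Metric form of the 3-second walking-distance placement rule."""
        return 3.0 * self.speed

    def wall_midpoint(self, wall: str) -> Location:
        mids = {
            "north": Location(self.width / 2.0, self.depth),
            "south": Location(self.width / 2.0, 0.0),
            "east": Location(self.width, self.depth / 2.0),
            "west": Location(0.0, self.depth / 2.0),
        }
        return mids[wall]

    def contains(self, p: Location, margin: float = 0.0) -> bool:
        return (margin <= p.x <= self.width - margin
                and margin <= p.y <= self.depth - margin)


@dataclass
class RoomConfig:
    """One room's stimulus/goal assignment for one participant."""

    room_id: int
    wallpaper_id: int
    face_id: int
    opa: Location
    full_wallpaper_wall: str
    npa: Location | None = None
    corner_starts: tuple[Location, ...] = ()

    def __post_init__(self) -> None:
        if self.full_wallpaper_wall not in WALLS:
            raise ValueError(f"unknown wall {self.full_wallpaper_wall!r}")

    def npa_start(self, geometry: ArenaGeometry) -> Location:
        """NPA trials start against the middle of the wall opposite the
        full-wallpaper wall."""
        return geometry.wall_midpoint(OPPOSITE_WALL[self.full_wallpaper_wall])


@dataclass
class ParticipantConfig:
    """A full constraint-satisfying paradigm configuration for one participant."""

    participant_id: str
    geometry: ArenaGeometry
    rooms: list[RoomConfig]
    seed: int

    @property
    def n_rooms(self) -> int:
        return len(self.rooms)

    def npa_start(self, room: RoomConfig) -> Location:
        return room.npa_start(self.geometry)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "participant_id": self.participant_id,
            "seed": self.seed,
            "geometry": asdict(self.geometry),
            "rooms": [
                {
                    "room_id": r.room_id,
                    "wallpaper_id": r.wallpaper_id,
                    "face_id": r.face_id,
                    "opa": list(r.opa),
                    "npa": list(r.npa) if r.npa is not None else None,
                    "full_wallpaper_wall": r.full_wallpaper_wall,
                    "corner_starts": [list(c) for c in r.corner_starts],
                }
                for r in self.rooms
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ParticipantConfig":
        payload = json.loads(text)
        geometry = ArenaGeometry(**payload["geometry"])
        rooms = [
            RoomConfig(
                room_id=r["room_id"],
                wallpaper_id=r["wallpaper_id"],
                face_id=r["face_id"],
                opa=Location(*r["opa"]),
                npa=Location(*r["npa"]) if r["npa"] is not None else None,
                full_wallpaper_wall=r["full_wallpaper_wall"],
                corner_starts=tuple(Location(*c) for c in r["corner_starts"]),
            )
            for r in payload["rooms"]
        ]
        return cls(participant_id=payload["participant_id"], geometry=geometry,
                   rooms=rooms, seed=payload["seed"])


# ---------------------------------------------------------------------------
# Placement samplers
# ---------------------------------------------------------------------------

def _occupancy_grid_index(points: np.ndarray, geometry: ArenaGeometry,
                          n_cells: int) -> np.ndarray:
    """Cell index of each point on an n x n grid over the wall-margin
    admissible floor [margin, width-margin] x [margin, depth-margin]."""
    m = geometry.wall_margin
    span_x = geometry.width - 2 * m
    span_y = geometry.depth - 2 * m
    ix = np.clip(((points[:, 0] - m) / span_x * n_cells).astype(int), 0, n_cells - 1)
    iy = np.clip(((points[:, 1] - m) / span_y * n_cells).astype(int), 0, n_cells - 1)
    return ix * n_cells + iy


def occupancy_counts(points: Sequence[Location], geometry: ArenaGeometry,
                     n_cells: int = 6) -> np.ndarray:
    """Per-cell counts of goal locations on the evenness grid."""
    arr = np.asarray([(p.x, p.y) for p in points], dtype=float)
    idx = _occupancy_grid_index(arr, geometry, n_cells)
    return np.bincount(idx, minlength=n_cells * n_cells)


def _admissible_opa(p: np.ndarray, geometry: ArenaGeometry) -> bool:
    m = geometry.wall_margin
    if not (m <= p[0] <= geometry.width - m and m <= p[1] <= geometry.depth - m):
        return False
    clearance = geometry.start_clearance
    for c in geometry.corners:
        if np.hypot(p[0] - c.x, p[1] - c.y) < clearance:
            return False
    return True


def sample_opa_locations(n: int, geometry: ArenaGeometry = ArenaGeometry(),
                         seed: int = 0, *, n_cells: int = 6,
                         max_cell_count: int = 2,
                         max_attempts: int = 10_000) -> list[Location]:
    """Sample ``n`` OPA goal locations satisfying the placement rules.

    Each location keeps ``wall_margin`` from every wall, at least a
    3-second walking distance (``3 * speed``) from each starting corner,
    and the set tiles the floor approximately evenly: on an
    ``n_cells x n_cells`` grid over the admissible floor no cell holds
    more than ``max_cell_count`` locations.

    Deterministic given ``seed``.  Raises :class:`InfeasibleLayoutError`
    after ``max_attempts`` rejected draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = geometry.wall_margin
    counts = np.zeros(n_cells * n_cells, dtype=int)
    out: list[Location] = []
    attempts = 0
    while len(out) < n:
        if attempts >= max_attempts:
            raise InfeasibleLayoutError(
                f"could not place {n} OPA locations after {max_attempts} draws")
        attempts += 1
        p = rng.uniform([m, m], [geometry.width - m, geometry.depth - m])
        if not _admissible_opa(p, geometry):
            continue
        cell = _occupancy_grid_index(p[None, :], geometry, n_cells)[0]
        if counts[cell] >= max_cell_count:
            continue
        counts[cell] += 1
        out.append(Location(float(p[0]), float(p[1])))
    return out


def sample_npa_locations(config: ParticipantConfig, seed: int = 0, *,
                         max_attempts: int = 10_000) -> list[Location]:
    """Sample one NPA location per room of ``config``.

    Constraints: wall margin as for OPAs; at least a 3-second walking
    distance from the room's NPA start point; at least 7 a.u. from the
    same room's OPA; at least 2 a.u. from every other room's OPA.
    """
    geometry = config.geometry
    missing = [r.room_id for r in config.rooms if r.opa is None]
    if missing:
        raise ValueError(f"rooms missing OPA assignment: {missing}")
    rng = np.random.default_rng(seed)
    m = geometry.wall_margin
    all_opas = np.asarray([(r.opa.x, r.opa.y) for r in config.rooms])
    out: list[Location] = []
    for i, room in enumerate(config.rooms):
        start = config.npa_start(room)
        other = np.delete(all_opas, i, axis=0)
        placed = False
        for _ in range(max_attempts):
            p = rng.uniform([m, m], [geometry.width - m, geometry.depth - m])
            if np.hypot(p[0] - start.x, p[1] - start.y) < geometry.start_clearance:
                continue
            if np.hypot(p[0] - room.opa.x, p[1] - room.opa.y) < 7.0:
                continue
            if other.size and np.min(np.hypot(*(other - p).T)) < 2.0:
                continue
            out.append(Location(float(p[0]), float(p[1])))
            placed = True
            break
        if not placed:
            raise InfeasibleLayoutError(
                f"could not place NPA for room {room.room_id} "
                f"after {max_attempts} draws")
    return out


def build_participant(n_rooms: int = 36,
                      geometry: ArenaGeometry = ArenaGeometry(),
                      seed: int = 0,
                      participant_id: str | None = None) -> ParticipantConfig:
    """Build a fully populated, constraint-satisfying participant configuration.

    Wallpaper and face identities are assigned to rooms as independent
    permutations (pseudo-random, without replacement), OPA locations are
    drawn by :func:`sample_opa_locations` and assigned to rooms in
    shuffled order, NPAs by :func:`sample_npa_locations`; the four
    corner starts are attached to every room.
    """
    if n_rooms < 1:
        raise ValueError("n_rooms must be >= 1")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=3)
    opas = sample_opa_locations(n_rooms, geometry, seed=int(sub_seeds[0]))
    rng.shuffle(opas)
    wallpapers = rng.permutation(n_rooms)
    faces = rng.permutation(n_rooms)
    walls = rng.choice(len(WALLS), size=n_rooms)
    rooms = [
        RoomConfig(
            room_id=i,
            wallpaper_id=int(wallpapers[i]),
            face_id=int(faces[i]),
            opa=opas[i],
            full_wallpaper_wall=WALLS[walls[i]],
            corner_starts=geometry.corners,
        )
        for i in range(n_rooms)
    ]
    config = ParticipantConfig(
        participant_id=participant_id or f"sim{seed:04d}",
        geometry=geometry, rooms=rooms, seed=seed)
    npas = sample_npa_locations(config, seed=int(sub_seeds[1]))
    for room, npa in zip(rooms, npas):
        room.npa = npa
    return config
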