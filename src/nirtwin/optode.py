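"""Optode array geometry, measurement channels, and the TDM illumination schedule.

The instrument arranges sources and detectors on a rectangular grid in a
checkerboard pattern (every orthogonal neighbour of a source is a detector and
vice versa).  A *measurement channel* is an orthogonally adjacent
source-detector pair, so its separation equals the grid pitch.  Sources are
time-division multiplexed: they are partitioned into groups that fire in
sequence, and the grouping must be unambiguous -- no detector may see two
simultaneously active adjacent sources, otherwise their contributions cannot
be separated.

Channel ordering is deterministic: row-major by detector, then row-major by
source within each detector's neighbourhood.  Ids are 1-based.  Published
channel numberings of comparable instruments are not guaranteed to match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

__all__ = [
    "OptodeGrid",
    "Channel",
    "ChannelMap",
    "TDMSchedule",
    "GroupingError",
    "GroupingReport",
    "build_grid",
    "enumerate_channels",
    "build_tdm_schedule",
    "validate_grouping",
]

Node = Tuple[int, int]


class GroupingError(ValueError):
    """Raised when no valid TDM grouping exists for the requested group count.

    Carries a ``certificate``: a (detector_id, source_id, source_id) triple
    witnessing the conflict, when one is available.
    """

    def __init__(self, message: str, certificate: Tuple[int, int, int] | None = None):
        super().__init__(message)
        self.certificate = certificate


@dataclass(frozen=True)
class OptodeGrid:
    """Checkerboard source/detector layout on a ``rows x cols`` grid.

    ``pitch_mm`` is the orthogonal node spacing and therefore the
    source-detector separation of every channel.  With
    ``sources_at_corners=True`` (default) the nodes with even ``row+col``
    parity are sources, so a 3x11 grid holds 17 sources and 16 detectors.
    """

    rows: int
    cols: int
    pitch_mm: float
    sources_at_corners: bool = True

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid dimensions must be positive, got {self.rows}x{self.cols}")
        if self.pitch_mm <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch_mm}")

    def role(self, row: int, col: int) -> str:
        even = (row + col) % 2 == 0
        return "source" if even == self.sources_at_corners else "detector"

    @property
    def source_nodes(self) -> List[Node]:
        return [(r, c) for r in range(self.rows) for c in range(self.cols)
                if self.role(r, c) == "source"]

    @property
    def detector_nodes(self) -> List[Node]:
        return [(r, c) for r in range(self.rows) for c in range(self.cols)
                if self.role(r, c) == "detector"]

    @property
    def n_sources(self) -> int:
        return len(self.source_nodes)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_nodes)

    # 1-based ids in row-major order over nodes of each role
    @property
    def source_ids(self) -> Dict[Node, int]:
        return {node: i + 1 for i, node in enumerate(self.source_nodes)}

    @property
    def detector_ids(self) -> Dict[Node, int]:
        return {node: i + 1 for i, node in enumerate(self.detector_nodes)}

    def neighbours(self, row: int, col: int) -> List[Node]:
        out = []
        for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
            r, c = row + dr, col + dc
            if 0 <= r < self.rows and 0 <= c < self.cols:
                out.append((r, c))
        return out


@dataclass(frozen=True)
class Channel:
    channel_id: int
    source_id: int
    detector_id: int
    separation_mm: float


@dataclass(frozen=True)
class ChannelMap:
    grid: OptodeGrid
    channels: Tuple[Channel, ...]

    def __len__(self) -> int:
        return len(self.channels)

    def sources_of_detector(self, detector_id: int) -> List[int]:
        return [ch.source_id for ch in self.channels if ch.detector_id == detector_id]

    def channel_for(self, source_id: int, detector_id: int) -> Channel:
        for ch in self.channels:
            if ch.source_id == source_id and ch.detector_id == detector_id:
                return ch
        raise KeyError(f"no channel for source {source_id}, detector {detector_id}")


def build_grid(rows: int, cols: int, pitch_mm: float, *,
               sources_at_corners: bool = True) -> OptodeGrid:
    """Construct a checkerboard optode grid; e.g. ``(3, 11, 30)`` gives 17 S / 16 D."""
    return OptodeGrid(rows, cols, pitch_mm, sources_at_corners)


def enumerate_channels(grid: OptodeGrid) -> ChannelMap:
    """One channel per orthogonally adjacent source-detector pair.

    Deterministic ordering: detectors in row-major node order; within a
    detector, its neighbouring sources in row-major node order.
    """
    sids, dids = grid.source_ids, grid.detector_ids
    channels: List[Channel] = []
    for dnode in grid.detector_nodes:
        for nb in grid.neighbours(*dnode):
            if grid.role(*nb) == "source":
                channels.append(Channel(
                    channel_id=len(channels) + 1,
                    source_id=sids[nb],
                    detector_id=dids[dnode],
                    separation_mm=grid.pitch_mm,
                ))
    return ChannelMap(grid=grid, channels=tuple(channels))


@dataclass(frozen=True)
class TDMSchedule:
    """Time-division multiplexing schedule: sources grouped into sequential slots.

    A full cycle visits every group once; each slot is ``on_ms`` of
    illumination followed by ``off_ms`` dark, so the channel sampling rate is
    ``1000 / (n_groups * (on_ms + off_ms))`` Hz.
    """

    n_groups: int
    on_ms: float
    off_ms: float
    group_of_source: Dict[int, int] = field(hash=False)

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.on_ms <= 0 or self.off_ms <= 0:
            raise ValueError("on/off durations must be positive")
        bad = {s: g for s, g in self.group_of_source.items()
               if not (0 <= g < self.n_groups)}
        if bad:
            raise ValueError(f"group index out of range for sources {sorted(bad)}")

    @property
    def cycle_ms(self) -> float:
        return self.n_groups * (self.on_ms + self.off_ms)

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / self.cycle_ms

    def sources_in_group(self, group: int) -> List[int]:
        return sorted(s for s, g in self.group_of_source.items() if g == group)


def _conflict_graph(grid: OptodeGrid) -> Dict[int, set]:
    """Source-conflict graph: edge between sources sharing an adjacent detector."""
    sids = grid.source_ids
    conflicts: Dict[int, set] = {sid: set() for sid in sids.values()}
    for dnode in grid.detector_nodes:
        adj = [sids[nb] for nb in grid.neighbours(*dnode) if grid.role(*nb) == "source"]
        for i, a in enumerate(adj):
            for b in adj[i + 1:]:
                conflicts[a].add(b)
                conflicts[b].add(a)
    return conflicts


def _lattice_colouring(grid: OptodeGrid) -> Dict[int, int]:
    # Sources live on one parity class of the grid; in the rotated sublattice
    # u=(r+c)/2 (rounded), v=(c-r), conflicts are king moves, which the
    # (u mod 2, v mod 2)... use floor-division form that is exact for either parity.
    out = {}
    for node, sid in grid.source_ids.items():
        r, c = node
        u, v = (r + c) // 2, (c - r) // 2
        out[sid] = 2 * (u % 2) + (v % 2)
    return out


def build_tdm_schedule(grid: OptodeGrid, n_groups: int = 4,
                       on_ms: float = 25.0, off_ms: float = 25.0) -> TDMSchedule:
    """Assign sources to TDM groups so no detector sees two same-group sources.

    Deterministic greedy colouring of the shared-detector conflict graph in
    source-id order; if greedy exceeds ``n_groups``, the closed-form
    sublattice 4-colouring is tried before declaring infeasibility.
    """
    conflicts = _conflict_graph(grid)
    colour: Dict[int, int] = {}
    for sid in sorted(conflicts):
        used = {colour[nb] for nb in conflicts[sid] if nb in colour}
        c = next(i for i in range(len(used) + 1) if i not in used)
        colour[sid] = c
    if colour and max(colour.values()) >= n_groups:
        if n_groups >= 4:
            colour = _lattice_colouring(grid)
        if colour and max(colour.values()) >= n_groups:
            raise GroupingError(
                f"no valid grouping with {n_groups} groups "
                f"(needs at least {max(colour.values()) + 1})")
    schedule = TDMSchedule(n_groups, on_ms, off_ms, colour)
    report = validate_grouping(schedule, enumerate_channels(grid))
    if not report.valid:
        d, a, b = report.conflicts[0]
        raise GroupingError(
            f"grouping invalid: detector {d} sees same-group sources {a} and {b}",
            report.conflicts[0])
    return schedule


@dataclass(frozen=True)
class GroupingReport:
    valid: bool
    conflicts: Tuple[Tuple[int, int, int], ...]  # (detector_id, source_a, source_b)


def validate_grouping(schedule: TDMSchedule, cmap: ChannelMap) -> GroupingReport:
    """Check demultiplexing unambiguity; on failure list (detector, s, s) triples."""
    sources = set(cmap.grid.source_ids.values())
    if set(schedule.group_of_source) != sources:
        raise ValueError("schedule and channel map refer to different grids")
    conflicts: List[Tuple[int, int, int]] = []
    dids = sorted({ch.detector_id for ch in cmap.channels})
    for did in dids:
        adj = cmap.sources_of_detector(did)
        for i, a in enumerate(adj):
            for b in adj[i + 1:]:
                if schedule.group_of_source[a] == schedule.group_of_source[b]:
                    conflicts.append((did, min(a, b), max(a, b)))
    return GroupingReport(valid=not conflicts, conflicts=tuple(conflicts))
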