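"""Frame-to-frame linking of cell masks and lineage construction.

Linking maximizes pixel overlap between consecutive frames within a
trench: each mask maps to 0 (disappearance), 1 (continuation) or 2
(division) masks in the next frame.  Chains become lineages rooted at the
t = 0 resident of the trench; unmatched new masks near the open end are
flagged as washed-in and excluded, a single-frame detection gap is
bridged, and a net appearance of extra cells connected to the resident
(e.g. across the 6 h -> 24 h jump of the imaging schedule) is recorded as
division evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import CellMask

__all__ = ["FrameLink", "Lineage", "TrackingResult",
           "link_frames", "build_lineages"]


@dataclass
class FrameLink:
    """Assignment between the masks of two consecutive frames."""

    children: dict[int, tuple[int, ...]]     # parent label -> child labels
    washed_in: frozenset[int]                # unmatched children, open end
    unmatched: frozenset[int]                # other unmatched children


def _centroid_dist(a: CellMask, b: CellMask) -> float:
    return float(np.hypot(a.centroid[0] - b.centroid[0],
                          a.centroid[1] - b.centroid[1]))


def link_frames(masks_t: list[CellMask], masks_t1: list[CellMask],
                open_end_frac: float = 0.7) -> FrameLink:
    """Greedy overlap-maximizing assignment from frame t to frame t+1.

    Ties are broken by smaller centroid displacement, then by smaller
    child label, which makes the assignment deterministic and invariant
    to input ordering.  A parent may claim a second child (division) only
    if the second overlap covers a non-trivial part of the child.
    """
    by_label_t1 = {m.label: m for m in masks_t1}
    pairs = []
    for p in masks_t:
        for c in masks_t1:
            ov = p.overlap(c)
            if ov > 0:
                pairs.append((ov, p, c))
    pairs.sort(key=lambda x: (-x[0], _centroid_dist(x[1], x[2]), x[2].label,
                              x[1].label))

    children: dict[int, list[int]] = {m.label: [] for m in masks_t}
    claimed: set[int] = set()
    for ov, p, c in pairs:
        if c.label in claimed or len(children[p.label]) >= 2:
            continue
        if len(children[p.label]) == 1 and ov < 0.1 * c.area_px:
            continue  # second-child overlap too small to be a daughter
        children[p.label].append(c.label)
        claimed.add(c.label)

    washed, other = set(), set()
    for c in masks_t1:
        if c.label in claimed:
            continue
        height = c.trench_shape[0]
        if c.centroid[0] >= open_end_frac * height:
            washed.add(c.label)
        else:
            other.add(c.label)
    return FrameLink(children={k: tuple(v) for k, v in children.items()},
                     washed_in=frozenset(washed), unmatched=frozenset(other))


@dataclass
class Lineage:
    """A t = 0 cell and everything it becomes over the movie."""

    lineage_id: int
    trench_id: int
    masks_by_frame: dict[int, list[CellMask]] = field(default_factory=dict)
    events: list[tuple[float, str]] = field(default_factory=list)

    def alive_at(self, frame_idx: int) -> bool:
        return bool(self.masks_by_frame.get(frame_idx))

    def count_at(self, frame_idx: int) -> int:
        return len(self.masks_by_frame.get(frame_idx, ()))

    def mother_mask(self, frame_idx: int) -> CellMask | None:
        """Topmost (closed-end) mask at the frame, or None."""
        masks = self.masks_by_frame.get(frame_idx)
        if not masks:
            return None
        return min(masks, key=lambda m: m.centroid[0])

    def division_times(self) -> list[float]:
        return sorted(t for t, kind in self.events if kind == "division")

    def disappearance_time(self) -> float | None:
        for t, kind in self.events:
            if kind == "disappearance":
                return t
        return None

    def divided_after(self, t_h: float, times: tuple[float, ...]) -> bool:
        """Division evidence after ``t_h``: an observed division event, or
        a net increase in connected cell count relative to the last frame
        at or before ``t_h``."""
        if any(te > t_h for te, kind in self.events if kind == "division"):
            return True
        ref_idx = max((i for i, t in enumerate(times) if t <= t_h),
                      default=None)
        if ref_idx is None:
            return False
        ref = self.count_at(ref_idx)
        return any(self.count_at(i) > ref
                   for i, t in enumerate(times) if t > t_h)


@dataclass
class TrackingResult:
    lineages: list[Lineage]
    washed_in: int  # masks excluded as washed-in / unattachable

    def __iter__(self):
        return iter(self.lineages)


def build_lineages(masks_per_frame: list[list[CellMask]],
                   times_h: tuple[float, ...],
                   trench_id: int = -1,
                   open_end_frac: float = 0.7) -> TrackingResult:
    """Chain per-frame masks of one trench into lineages.

    Every frame-0 mask roots a lineage.  A mask with no successor is
    bridged over a single missing frame when an unclaimed mask two frames
    later overlaps it; otherwise a disappearance event is recorded at the
    first missing frame.  Unmatched new masks are attached to the trench's
    living lineage as regrowth daughters (division event) when exactly one
    lineage is alive, flagged washed-in otherwise.
    """
    n_frames = len(masks_per_frame)
    if len(times_h) != n_frames:
        raise ValueError("times_h length must match masks_per_frame")
    lineages = [Lineage(lineage_id=i, trench_id=trench_id,
                        masks_by_frame={0: [m]})
                for i, m in enumerate(
                    sorted(masks_per_frame[0], key=lambda m: m.centroid[0]))]
    washed_total = 0
    active: dict[int, list[CellMask]] = {
        lin.lineage_id: list(lin.masks_by_frame[0]) for lin in lineages}
    # masks lost at the previous transition, eligible for a 1-frame bridge:
    pending: dict[int, list[CellMask]] = {lin.lineage_id: [] for lin in lineages}

    for k in range(n_frames - 1):
        link = link_frames(masks_per_frame[k], masks_per_frame[k + 1],
                           open_end_frac)
        by_label = {m.label: m for m in masks_per_frame[k + 1]}
        claimed: set[int] = set()
        new_active: dict[int, list[CellMask]] = {}
        new_pending: dict[int, list[CellMask]] = {}
        for lin in lineages:
            lid = lin.lineage_id
            nxt: list[CellMask] = []
            lost: list[CellMask] = []
            for mask in active[lid]:
                kids = link.children.get(mask.label, ())
                if len(kids) == 2:
                    lin.events.append((times_h[k + 1], "division"))
                if kids:
                    for c in kids:
                        nxt.append(by_label[c])
                        claimed.add(c)
                else:
                    lost.append(mask)
            # bridge masks lost at the previous transition (absent at k)
            for mask in pending[lid]:
                bridge = None
                for c in masks_per_frame[k + 1]:
                    if c.label in claimed or c.label in link.washed_in:
                        continue
                    if any(c.label in link.children.get(p.label, ())
                           for p in masks_per_frame[k]):
                        continue
                    if mask.overlap(c) > 0:
                        bridge = c
                        break
                if bridge is not None:
                    nxt.append(bridge)
                    claimed.add(bridge.label)
                else:
                    lin.events.append((times_h[k], "disappearance"))
            new_pending[lid] = lost
            new_active[lid] = nxt
        # leftover new masks: regrowth of the trench resident, or washed-in
        leftovers = [by_label[lab] for lab in
                     (set(by_label) - claimed
                      - {lab for lab in by_label
                         if any(lab in kids for kids in link.children.values())})
                     if lab not in link.washed_in]
        washed_total += len(link.washed_in)
        living = [lin for lin in lineages if new_active[lin.lineage_id]]
        for m in sorted(leftovers, key=lambda m: m.label):
            if len(living) == 1:
                lid = living[0].lineage_id
                new_active[lid].append(m)
                living[0].events.append((times_h[k + 1], "division"))
            else:
                washed_total += 1
        active, pending = new_active, new_pending
        for lin in lineages:
            if active[lin.lineage_id]:
                lin.masks_by_frame[k + 1] = sorted(
                    active[lin.lineage_id], key=lambda m: m.centroid[0])

    last = n_frames - 1
    for lin in lineages:
        if pending[lin.lineage_id]:
            lin.events.append((times_h[last], "disappearance"))
        elif active[lin.lineage_id]:
            lin.events.append((times_h[last], "end_of_movie"))
        lin.events.sort(key=lambda e: e[0])
    # conservation: every mask is either in a lineage or excluded
    assigned = sum(len(masks) for lin in lineages
                   for masks in lin.masks_by_frame.values())
    total = sum(len(f) for f in masks_per_frame)
    return TrackingResult(lineages=lineages, washed_in=total - assigned)
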