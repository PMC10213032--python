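"""Lattice-free stochastic growth of a binary-tree-with-laterals mycelium.

Each hypha is an autonomous polyline whose tip advances at the shared,
ramping elongation velocity; per 20 µm of advance the heading is
perturbed by the spontaneous-curvature law.  Apical (subapical)
branchings replace one apex by two — the *operating* daughter makes the
widest angle with the mother's projection and starts a new hypha at an
anchor placed L_api behind the tip; the *exploratory* daughter (smallest
angle) continues the mother hypha.  Lateral branchings insert a V3l
junction on the flank of a hypha, never closer than the lateral
dominance length (480 µm) to the owning apex, as the superposition of
uniformly seeded isolated events (fired within a 90-min aging window of
newly eligible length) and bursts clustered near existing laterals.

Apexes never die and anastomosis is not modelled: hyphae that meet
simply overlap (geometric V3i crossings).
"""

from __future__ import annotations

import heapq
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .branching import BranchEvent
from .graph import NetworkGraph
from .laws import (
    LN2,
    branch_side,
    cumulative_growth,
    elongation_velocity,
    exp2,
    sample_curvature_angle,
    sample_subapical_offset,
    schedule_apical_branch,
)
from .params import GrowthConfig

__all__ = ["Simulation", "Trajectory", "run"]

_EPS = 1e-9


class _Hypha:
    """Mutable per-hypha growth state (internal)."""

    __slots__ = (
        "hid", "btype", "birth_h", "parent", "vids", "px", "py", "vt",
        "varc", "vprov", "x", "y", "heading", "arclen", "dist_to_kick",
        "next_branch_arc", "last_branch_arc", "curv_sign", "elig_frontier",
    )

    def __init__(self, hid: int, btype: str, birth_h: float, parent: int,
                 x: float, y: float, heading: float, first_vid: int):
        self.hid = hid
        self.btype = btype
        self.birth_h = birth_h
        self.parent = parent
        self.vids = [first_vid]
        self.px = [x]
        self.py = [y]
        self.vt = [birth_h]
        self.varc = [0.0]
        self.vprov: list[str | None] = [None]
        self.x = x
        self.y = y
        self.heading = heading
        self.arclen = 0.0
        self.dist_to_kick = 0.0
        self.next_branch_arc = math.inf
        self.last_branch_arc = 0.0
        self.curv_sign = 0.0
        self.elig_frontier = 0.0

    def insert_vertex(self, arc: float, t_pass: float, vid: int,
                      prov: str | None) -> int:
        """Insert an interpolated vertex at ``arc``; return its index."""
        i = bisect_right(self.varc, arc)
        a0, a1 = self.varc[i - 1], self.varc[i] if i < len(self.varc) else self.arclen
        if i < len(self.varc):
            f = 0.0 if a1 <= a0 else (arc - a0) / (a1 - a0)
            x = self.px[i - 1] + f * (self.px[i] - self.px[i - 1])
            y = self.py[i - 1] + f * (self.py[i] - self.py[i - 1])
            t = self.vt[i - 1] + f * (self.vt[i] - self.vt[i - 1])
        else:
            # beyond the last recorded vertex: along the current heading
            d = arc - a0
            x = self.px[-1] + d * math.cos(self.heading)
            y = self.py[-1] + d * math.sin(self.heading)
            t = t_pass
        self.vids.insert(i, vid)
        self.px.insert(i, x)
        self.py.insert(i, y)
        self.vt.insert(i, min(t, t_pass))
        self.varc.insert(i, arc)
        self.vprov.insert(i, prov)
        return i

    def append_vertex(self, vid: int, t: float, prov: str | None = None) -> None:
        self.vids.append(vid)
        self.px.append(self.x)
        self.py.append(self.y)
        self.vt.append(t)
        self.varc.append(self.arclen)
        self.vprov.append(prov)

    def position_at_arc(self, arc: float) -> tuple[float, float]:
        arc = min(max(arc, 0.0), self.arclen)
        i = bisect_right(self.varc, arc)
        if i >= len(self.varc):
            d = arc - self.varc[-1]
            return (self.px[-1] + d * math.cos(self.heading),
                    self.py[-1] + d * math.sin(self.heading))
        a0, a1 = self.varc[i - 1], self.varc[i]
        f = 0.0 if a1 <= a0 else (arc - a0) / (a1 - a0)
        return (self.px[i - 1] + f * (self.px[i] - self.px[i - 1]),
                self.py[i - 1] + f * (self.py[i] - self.py[i - 1]))

    def local_direction(self, idx: int) -> float:
        j0 = max(idx - 1, 0)
        j1 = min(idx + 1, len(self.varc) - 1)
        dx = self.px[j1] - self.px[j0]
        dy = self.py[j1] - self.py[j0]
        if dx == 0.0 and dy == 0.0:
            return self.heading
        return math.atan2(dy, dx)

    def local_curv_sign(self, idx: int) -> float:
        """Sign of the bend around vertex ``idx`` (positive = rightward)."""
        for j in (idx, idx - 1, idx + 1, idx - 2, idx + 2):
            if 1 <= j <= len(self.varc) - 2:
                h1 = math.atan2(self.py[j] - self.py[j - 1], self.px[j] - self.px[j - 1])
                h2 = math.atan2(self.py[j + 1] - self.py[j], self.px[j + 1] - self.px[j])
                d = (h2 - h1 + math.pi) % (2.0 * math.pi) - math.pi
                if abs(d) > 1e-9:
                    return -math.copysign(1.0, d)
        return 0.0


@dataclass
class Trajectory:
    """Time-ordered record of one simulated thallus.

    Snapshots are taken at a fixed cadence (18 min by default); each
    holds the positions of every apex (V1 + V1l) alive at that time.
    Branch events carry type, time, position, side and the distances the
    calibration statistics need.  Full :class:`NetworkGraph` snapshots
    are rebuilt on demand from the stored polylines.
    """

    config: GrowthConfig
    times: np.ndarray
    apex_xy: list[np.ndarray]
    events: list[BranchEvent]
    hyphae: list[_Hypha] = field(repr=False, default_factory=list)
    t_end_h: float = 0.0

    @property
    def n1(self) -> np.ndarray:
        """Apex count per snapshot (nondecreasing: apexes never die)."""
        return np.array([len(p) for p in self.apex_xy], dtype=np.int64)

    def snapshots(self) -> Iterator[tuple[float, np.ndarray]]:
        yield from zip(self.times, self.apex_xy)

    def graph(self, t: float | None = None) -> NetworkGraph:
        """Rebuild the spatial graph at time ``t`` (default: end of run)."""
        if t is None:
            t = self.t_end_h
        ids: list[int] = []
        xs: list[float] = []
        ys: list[float] = []
        births: list[float] = []
        provs: list[str] = []
        e_a: list[int] = []
        e_b: list[int] = []
        e_ty: list[str] = []
        next_extra = max((max(h.vids) for h in self.hyphae if h.vids), default=0) + 1
        germ = self.config.germination
        f_t = float(cumulative_growth(t, germ))
        for h in self.hyphae:
            if h.birth_h > t + _EPS:
                continue
            if t >= self.t_end_h - _EPS:
                arc_t = h.arclen  # exact discrete arclength at the end of run
            else:
                arc_t = max(f_t - float(cumulative_growth(h.birth_h, germ)), 0.0)
                arc_t = min(arc_t, h.arclen)
            # prefix of vertices already passed at time t
            k = len(h.vt)
            while k > 1 and (h.vt[k - 1] > t + _EPS or h.varc[k - 1] > arc_t + _EPS):
                k -= 1
            chain = list(range(k))
            for j in chain:
                if j == 0 and h.parent >= 0:
                    continue  # anchor vertex owned by the mother hypha
                ids.append(h.vids[j])
                xs.append(h.px[j])
                ys.append(h.py[j])
                births.append(min(h.vt[j], t))
                provs.append(h.vprov[j] or h.btype)
            # tip node at the interpolated apex position
            if arc_t > h.varc[k - 1] + 1e-6 or k == 1:
                tip_arc = max(arc_t, h.varc[k - 1] + 1e-6)
                tx, ty = h.position_at_arc(tip_arc)
                tip_id = next_extra
                next_extra += 1
                ids.append(tip_id)
                xs.append(tx)
                ys.append(ty)
                births.append(t)
                provs.append(h.btype)
                chain_ids = [h.vids[j] for j in chain] + [tip_id]
            else:
                chain_ids = [h.vids[j] for j in chain]
            for a, b in zip(chain_ids[:-1], chain_ids[1:]):
                e_a.append(a)
                e_b.append(b)
                e_ty.append(h.btype)
        return NetworkGraph(
            node_ids=np.array(ids, dtype=np.int64),
            xy=np.column_stack([xs, ys]) if ids else np.empty((0, 2)),
            birth_h=np.array(births, dtype=float),
            provenance=np.array(provs, dtype=object),
            edges=np.column_stack([e_a, e_b]) if e_a else np.empty((0, 2), dtype=np.int64),
            branch_type=np.array(e_ty, dtype=object),
            snapshot_time=float(t),
        )

    @property
    def final_graph(self) -> NetworkGraph:
        return self.graph(self.t_end_h)


class Simulation:
    """Stepping engine; use :func:`run` unless you need manual control."""

    def __init__(self, config: GrowthConfig, rng: np.random.Generator | None = None):
        self.cfg = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.t = 0.0
        self.hyphae: list[_Hypha] = []
        self.events: list[BranchEvent] = []
        self._pending: list[tuple[float, int, int, float]] = []  # (t, seq, hid, arc)
        self._seq = 0
        self._next_vid = 0
        self.snapshot_times: list[float] = []
        self.snapshot_xy: list[np.ndarray] = []
        self._germinate()

    # -- setup -------------------------------------------------------------
    def _new_vid(self) -> int:
        v = self._next_vid
        self._next_vid += 1
        return v

    def _germinate(self) -> None:
        g = self.cfg.germination
        base = self.rng.uniform(0.0, 2.0 * math.pi)
        jitter = math.radians(self.cfg.angle_jitter_deg)
        n = g.n_initial_hyphae
        for k in range(n):
            heading = base + 2.0 * math.pi * k / n + self.rng.normal(0.0, jitter)
            # each germ tube starts at its own point on the spore boundary,
            # so base vertices stay degree-1 (the spore body is not a node)
            x0 = g.spore_radius_um * math.cos(heading)
            y0 = g.spore_radius_um * math.sin(heading)
            h = _Hypha(hid=len(self.hyphae), btype="germination", birth_h=0.0,
                       parent=-1, x=x0, y=y0, heading=heading,
                       first_vid=self._new_vid())
            h.vprov[0] = "germination"
            h.dist_to_kick = self.cfg.curvature_for("germination").step_length_um
            if self.cfg.apical_enabled:
                h.next_branch_arc = float(schedule_apical_branch(self.rng, self.cfg.apical))
            self.hyphae.append(h)
        self._record_snapshot()

    # -- observation -------------------------------------------------------
    def _record_snapshot(self) -> None:
        self.snapshot_times.append(self.t)
        xy = np.array([[h.x, h.y] for h in self.hyphae], dtype=float)
        self.snapshot_xy.append(xy)

    # -- branching ---------------------------------------------------------
    def _resolve_sign(self, sign: float) -> float:
        if sign == 0.0:
            return 1.0 if self.rng.random() < 0.5 else -1.0
        return sign

    def _spawn(self, mother: _Hypha, btype: str, t: float, anchor_idx: int,
               heading: float) -> _Hypha:
        h = _Hypha(hid=len(self.hyphae), btype=btype, birth_h=t,
                   parent=mother.hid, x=mother.px[anchor_idx],
                   y=mother.py[anchor_idx], heading=heading,
                   first_vid=mother.vids[anchor_idx])
        h.dist_to_kick = self.cfg.curvature_for(btype).step_length_um
        if self.cfg.apical_enabled:
            h.next_branch_arc = float(schedule_apical_branch(self.rng, self.cfg.apical))
        self.hyphae.append(h)
        return h

    def _apical_branch(self, h: _Hypha, t: float) -> None:
        ap = self.cfg.apical
        s = h.arclen
        l_api = sample_subapical_offset(self.rng, ap)
        anchor_arc = min(max(s - l_api, 1e-3), s - 1e-3)
        idx = h.insert_vertex(anchor_arc, t, self._new_vid(), "apical")
        sign = self._resolve_sign(h.curv_sign)
        side = branch_side(self.rng, sign, ap.p_opposite_curvature)
        jit = math.radians(self.cfg.angle_jitter_deg)
        ang_op = math.radians(ap.operating_angle_deg) + self.rng.normal(0.0, jit)
        ang_ex = math.radians(ap.exploratory_angle_deg) + self.rng.normal(0.0, jit)
        s_op = 1.0 if side == "left" else -1.0  # ccw-positive headings
        op_heading = h.heading + s_op * abs(ang_op)
        self._spawn(h, "operating", t, idx, op_heading)
        h.heading = h.heading - s_op * abs(ang_ex)  # exploratory continuation
        self.events.append(BranchEvent(
            type="apical", time_h=t, x_um=h.px[idx], y_um=h.py[idx],
            L_lat_um=s - anchor_arc, L_hypha_um=s,
            side=("ccw" if side == "left" else "cw"),
            side_vs_curvature=("opposite" if (sign > 0) == (side == "left") else "same"),
            hypha_id=h.hid, arclength_um=anchor_arc,
            spacing_um=s - h.last_branch_arc,
        ))
        h.last_branch_arc = s
        h.next_branch_arc = s + float(schedule_apical_branch(self.rng, ap))

    def _fire_lateral(self, hid: int, arc: float, t: float) -> None:
        lp = self.cfg.lateral
        h = self.hyphae[hid]
        bound = h.arclen - lp.L_dominance_um
        if bound <= 1e-6:
            return
        arc = min(max(arc, 1e-6), bound)
        # avoid stacking two junctions on one vertex (degree would exceed 3)
        i = bisect_right(h.varc, arc)
        for j in (i - 1, i):
            if 0 <= j < len(h.varc) and abs(h.varc[j] - arc) < 1e-6:
                arc = min(max(arc + 1e-3, 1e-6), bound)
                break
        idx = h.insert_vertex(arc, t, self._new_vid(), "lateral")
        sign = self._resolve_sign(h.local_curv_sign(idx))
        side = branch_side(self.rng, sign, lp.p_opposite_curvature)
        jit = math.radians(self.cfg.angle_jitter_deg)
        ang = math.radians(lp.lateral_angle_deg) + self.rng.normal(0.0, jit)
        base = h.local_direction(idx)
        s_lat = 1.0 if side == "left" else -1.0
        self._spawn(h, "lateral", t, idx, base + s_lat * abs(ang))
        self.events.append(BranchEvent(
            type="lateral", time_h=t, x_um=h.px[idx], y_um=h.py[idx],
            L_lat_um=h.arclen - arc, L_hypha_um=h.arclen,
            side=("ccw" if side == "left" else "cw"),
            side_vs_curvature=("opposite" if (sign > 0) == (side == "left") else "same"),
            hypha_id=h.hid, arclength_um=arc,
        ))
        # burst follow-up near this branch keeps the isolated share at
        # uniform_fraction exactly
        if self.rng.random() < 1.0 - lp.uniform_fraction:
            dt_next = float(exp2(self.rng, lp.temporal_rate_per_min)) / 60.0
            step = float(exp2(self.rng, lp.gamma1_per_um))
            arc2 = arc + (step if self.rng.random() < 0.5 else -step)
            arc2 = min(max(arc2, 1e-6), bound)
            self._push_lateral(t + dt_next, hid, arc2)

    def _push_lateral(self, t: float, hid: int, arc: float) -> None:
        heapq.heappush(self._pending, (t, self._seq, hid, arc))
        self._seq += 1

    def _seed_isolated(self, h: _Hypha, t: float) -> None:
        lp = self.cfg.lateral
        bound = h.arclen - lp.L_dominance_um
        if bound <= h.elig_frontier:
            return
        new_len = bound - h.elig_frontier
        lam = lp.p_isolated_per_um * lp.rate_multiplier * new_len
        k = self.rng.poisson(lam)
        window_h = lp.aging_window_min / 60.0
        for _ in range(int(k)):
            arc = self.rng.uniform(h.elig_frontier, bound)
            self._push_lateral(t + self.rng.uniform(0.0, window_h), h.hid, arc)
        h.elig_frontier = bound

    # -- stepping ----------------------------------------------------------
    def _advance(self, h: _Hypha, dist: float, t0: float, dt: float) -> None:
        curv = self.cfg.curvature_for(h.btype)
        total = dist
        while dist > 1e-12:
            step = min(dist, h.dist_to_kick)
            to_branch = h.next_branch_arc - h.arclen
            branching = self.cfg.apical_enabled and to_branch <= step
            if branching:
                step = max(to_branch, 0.0)
            h.x += step * math.cos(h.heading)
            h.y += step * math.sin(h.heading)
            h.arclen += step
            h.dist_to_kick -= step
            dist -= step
            t_pt = t0 + dt * (1.0 - dist / total) if total > 0 else t0
            if branching:
                self._apical_branch(h, t_pt)
                continue
            if h.dist_to_kick <= 1e-12:
                theta = float(sample_curvature_angle(curv, self.rng))
                h.heading += theta
                if theta != 0.0:
                    h.curv_sign = -math.copysign(1.0, theta)
                h.append_vertex(self._new_vid(), t_pt)
                h.dist_to_kick = curv.step_length_um

    def step(self, dt: float | None = None) -> None:
        """Advance the whole thallus by one time step."""
        if dt is None:
            dt = self.cfg.dt_h
        if dt <= 0:
            raise ValueError("dt must be positive")
        t0 = self.t
        t1 = t0 + dt
        if t1 > self.cfg.t_end_h + self.cfg.dt_h + _EPS:
            raise ValueError("stepping past t_end")
        v = elongation_velocity(t0 + dt / 2.0, self.cfg.germination)
        dist = v * dt
        n_existing = len(self.hyphae)
        for h in self.hyphae[:n_existing]:
            self._advance(h, dist, t0, dt)
        if self.cfg.lateral_enabled:
            for h in self.hyphae[:n_existing]:
                self._seed_isolated(h, t1)
            while self._pending and self._pending[0][0] <= t1:
                t_ev, _, hid, arc = heapq.heappop(self._pending)
                self._fire_lateral(hid, arc, max(t_ev, t0))
        self.t = t1

    def run(self) -> Trajectory:
        cadence_h = self.cfg.snapshot_cadence_min / 60.0
        next_snap = cadence_h
        n_steps = int(round(self.cfg.t_end_h / self.cfg.dt_h))
        for _ in range(n_steps):
            self.step()
            if self.t + _EPS >= next_snap:
                self._record_snapshot()
                next_snap += cadence_h
        for h in self.hyphae:  # freeze the tip as a final vertex
            if h.arclen > h.varc[-1] + 1e-6:
                h.append_vertex(self._new_vid(), self.t)
        return Trajectory(
            config=self.cfg,
            times=np.array(self.snapshot_times, dtype=float),
            apex_xy=self.snapshot_xy,
            events=self.events,
            hyphae=self.hyphae,
            t_end_h=self.t,
        )


def run(config: GrowthConfig, rng: np.random.Generator | None = None) -> Trajectory:
    """Simulate one thallus under ``config`` and return its trajectory."""
    return Simulation(config, rng=rng).run()
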