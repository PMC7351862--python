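"""Event-driven simulation of axon firing triggered by a travelling packet.

The plasmon-polariton wave packet moves along the chain at a fixed velocity
v and ignites the Hodgkin-Huxley cycle at each node of Ranvier it passes:
node j (healthy) is triggered at t = |j - origin| d / v.  Because the
trigger is a wave of synchronized oscillations and not a local diffusive
current, damaged nodes and small breaks in the cord are traversed without
delaying downstream ignition; and since fired nodes sit in a long
refractory state, the firing front never re-enters territory behind it.
All event times are exact multiples of d/v -- there is no time-stepping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .plasma import InvalidParameterError

REST = "rest"
TRIGGERED = "triggered"
FIRING = "firing"
REFRACTORY = "refractory"
DAMAGED = "damaged"

#: default HH spike marker duration [s]
DEFAULT_SPIKE_DURATION = 1e-3
#: default refractory lockout [s] (gate restoration is of order a second)
DEFAULT_REFRACTORY = 1.0


@dataclass(frozen=True)
class NodeState:
    index: int
    state: str
    ignition_time: float | None = None


@dataclass
class FiringTimeline:
    """Time-ordered ignition record of one packet traversal.

    ``events`` holds (time [s], node index, transition) tuples with
    non-decreasing times; each healthy reachable node fires exactly once.
    """

    packet_velocity: float
    segment_length: float
    n_nodes: int
    origin: int
    duration: float
    hh_spike_duration: float
    refractory: float
    damaged_set: frozenset = field(default_factory=frozenset)
    break_set: tuple = ()  # ((gap_index, width_m), ...) gap i between nodes i, i+1
    events: list = field(default_factory=list)
    ignition_times: dict = field(default_factory=dict)  # node -> time

    def node_state(self, index: int, t: float) -> NodeState:
        if index in self.damaged_set:
            return NodeState(index, DAMAGED)
        t_ign = self.ignition_times.get(index)
        if t_ign is None or t < t_ign:
            return NodeState(index, REST)
        if t < t_ign + self.hh_spike_duration:
            return NodeState(index, FIRING, t_ign)
        if t < t_ign + self.hh_spike_duration + self.refractory:
            return NodeState(index, REFRACTORY, t_ign)
        return NodeState(index, REST, t_ign)


def simulate_firing(n_nodes: int, segment_length: float, packet_velocity: float,
                    origin: int = 0, duration: float = 1e-3,
                    hh_spike_duration: float = DEFAULT_SPIKE_DURATION,
                    refractory: float = DEFAULT_REFRACTORY,
                    damaged_set=(), break_set=(),
                    max_jumpable_width: float | None = None) -> FiringTimeline:
    """Run the event-driven packet traversal.

    Parameters
    ----------
    n_nodes, segment_length, packet_velocity
        Chain size, period d [m] and packet speed v [m/s].
    origin
        Index of the initially excited node; ignition spreads to both sides
        (one-sided if the origin is an end node).
    duration
        Simulated window [s]; ignition events with t <= duration are kept
        (closed interval, so a front exactly at the boundary still counts).
    damaged_set
        Nodes that never fire; the wave passes over them without delay.
    break_set
        Iterable of (gap_index, width_m): physical interruptions of the
        cord between nodes gap_index and gap_index + 1.  A break jumps
        without added delay if its width is at most ``max_jumpable_width``
        (default: one period d); wider breaks stop the front on that side.
    """
    if packet_velocity <= 0:
        raise InvalidParameterError("packet velocity must be > 0")
    if segment_length <= 0:
        raise InvalidParameterError("segment length must be > 0")
    if duration < 0:
        raise InvalidParameterError("duration must be >= 0")
    if not 0 <= origin < n_nodes:
        raise InvalidParameterError("origin outside the chain")
    damaged = frozenset(int(i) for i in damaged_set)
    if origin in damaged:
        raise InvalidParameterError("origin node is damaged")
    if max_jumpable_width is None:
        max_jumpable_width = segment_length
    breaks = tuple((int(i), float(w)) for i, w in break_set)

    # blocking breaks truncate reachability on each side of the origin
    lo, hi = 0, n_nodes - 1
    for gap, width in breaks:
        if width > max_jumpable_width:
            if gap >= origin:
                hi = min(hi, gap)
            if gap < origin:
                lo = max(lo, gap + 1)

    dt = segment_length / packet_velocity
    tl = FiringTimeline(packet_velocity, segment_length, n_nodes, origin,
                        duration, hh_spike_duration, refractory,
                        damaged, breaks)
    raw = []
    for j in range(lo, hi + 1):
        t = abs(j - origin) * dt
        if t > duration:
            continue
        if j in damaged:
            continue
        raw.append((t, j))
    raw.sort()
    for t, j in raw:
        tl.ignition_times[j] = t
        tl.events.append((t, j, TRIGGERED))
        tl.events.append((t, j, FIRING))
        t_refr = t + hh_spike_duration
        if t_refr <= duration:
            tl.events.append((t_refr, j, REFRACTORY))
    tl.events.sort(key=lambda e: e[0])
    return tl


def count_ignited(timeline: FiringTimeline, t: float) -> int:
    """Number of nodes with ignition time <= t (origin included).

    For one-sided undamaged propagation this equals
    min(floor(v t / d) + 1, reachable nodes).
    """
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    return sum(1 for t_ign in timeline.ignition_times.values() if t_ign <= t)


def phase_snapshot(timeline: FiringTimeline, t: float,
                   hh_spike_duration: float | None = None) -> list:
    """Per-node HH phase at time t.

    Returns a list of (state, phase) per node: phase = (t - ignition)/spike
    duration clipped to [0, 1] for firing nodes, 1.0 for refractory ones,
    and None for nodes at rest or damaged.
    """
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    spike = (timeline.hh_spike_duration if hh_spike_duration is None
             else hh_spike_duration)
    out = []
    for j in range(timeline.n_nodes):
        if j in timeline.damaged_set:
            out.append((DAMAGED, None))
            continue
        t_ign = timeline.ignition_times.get(j)
        if t_ign is None or t < t_ign:
            out.append((REST, None))
            continue
        phase = (t - t_ign) / spike
        if phase <= 1.0:
            out.append((FIRING, phase))
        else:
            out.append((REFRACTORY, 1.0))
    return out
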