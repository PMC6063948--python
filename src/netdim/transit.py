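"""Build transport networks from public-transport schedule (GTFS) data.

Stops become nodes and pairs of successive stops of the same trip
become edges.  In ``travel_time`` mode the weight of one traversal is
the difference of stop "midpoints", where the midpoint of a stop event
is the arithmetic mean of its arrival and departure times; repeated
service over the same stop pair is collapsed to a single edge whose
weight follows a configurable policy (mean of the traversal times by
default, minimum optionally).  Times are parsed as GTFS clock strings
(hours may exceed 24 for after-midnight service) and carried in
minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph import SpatialGraph

__all__ = ["TransportEvent", "parse_gtfs_time", "gtfs_to_network", "read_gtfs"]


@dataclass(frozen=True)
class TransportEvent:
    """One scheduled stop of one trip; times in minutes."""

    trip_id: str
    stop_id: str
    arrival: float
    departure: float
    sequence: int

    def __post_init__(self) -> None:
        if self.arrival > self.departure:
            raise ValueError(
                f"arrival after departure at stop {self.stop_id!r} of trip {self.trip_id!r}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.arrival + self.departure)


def parse_gtfs_time(value: str | float) -> float:
    """Parse ``HH:MM:SS`` (hours may exceed 23) into minutes."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    parts = str(value).strip().split(":")
    if len(parts) != 3:
        raise ValueError(f"cannot parse GTFS time {value!r}")
    h, m, s = (int(p) for p in parts)
    return h * 60.0 + m + s / 60.0


def gtfs_to_network(
    events,
    mode: str = "travel_time",
    merge: str = "mean",
    known_stops: set | None = None,
) -> SpatialGraph:
    """Turn stop events into an undirected stop-to-stop network.

    Parameters
    ----------
    events:
        Iterable of :class:`TransportEvent` (or a DataFrame with columns
        trip_id, stop_id, arrival, departure, sequence — times already
        in minutes).
    mode:
        ``travel_time`` weights each traversal by the midpoint
        difference between successive stops, in minutes;
        ``hop`` sets every weight to 1.
    merge:
        How repeated traversals of the same stop pair collapse:
        ``mean`` (default) or ``min`` of the traversal times.
    known_stops:
        When given, any referenced stop id outside this set raises.
    """
    if mode not in ("travel_time", "hop"):
        raise ValueError(f"unknown mode {mode!r}")
    if merge not in ("mean", "min"):
        raise ValueError(f"unknown merge policy {merge!r}")
    if isinstance(events, pd.DataFrame):
        events = [
            TransportEvent(str(r.trip_id), str(r.stop_id), float(r.arrival),
                           float(r.departure), int(r.sequence))
            for r in events.itertuples(index=False)
        ]
    else:
        events = list(events)

    if known_stops is not None:
        unknown = {e.stop_id for e in events} - set(known_stops)
        if unknown:
            raise ValueError(f"unknown stop ids: {sorted(unknown)[:5]}")

    by_trip: dict[str, list[TransportEvent]] = {}
    for e in events:
        by_trip.setdefault(e.trip_id, []).append(e)

    occurrences: dict[tuple, list[float]] = {}
    stops_seen: set = set()
    for trip_id, evs in by_trip.items():
        evs.sort(key=lambda e: e.sequence)
        if len({e.sequence for e in evs}) != len(evs):
            warnings.warn(f"trip {trip_id!r}: duplicate sequence indices; dropped")
            continue
        mids = [e.midpoint for e in evs]
        if any(b < a for a, b in zip(mids, mids[1:])):
            warnings.warn(f"trip {trip_id!r}: non-monotone times; dropped")
            continue
        stops_seen.update(e.stop_id for e in evs)
        for e1, e2 in zip(evs, evs[1:]):
            if e1.stop_id == e2.stop_id:
                continue  # dwell split across rows; no self-loop
            pair = tuple(sorted((e1.stop_id, e2.stop_id)))
            occurrences.setdefault(pair, []).append(e2.midpoint - e1.midpoint)

    g = nx.Graph()
    g.add_nodes_from(sorted(stops_seen))
    for (u, v), times in occurrences.items():
        if mode == "hop":
            w = 1.0
        elif merge == "mean":
            w = float(np.mean(times))
        else:
            w = float(np.min(times))
        g.add_edge(u, v, weight=w)
    return SpatialGraph(g, units="minutes" if mode == "travel_time" else "hops")


def read_gtfs(
    feed_dir: str | Path,
    mode: str = "travel_time",
    merge: str = "mean",
) -> SpatialGraph:
    """Read ``stop_times.txt`` (and ``stops.txt`` if present) from a feed.

    Stop coordinates from ``stops.txt`` are attached when available;
    they are raw latitude/longitude pairs, adequate for small regions.
    """
    feed_dir = Path(feed_dir)
    st = pd.read_csv(feed_dir / "stop_times.txt", dtype={"trip_id": str, "stop_id": str})
    events = [
        TransportEvent(
            str(row.trip_id),
            str(row.stop_id),
            parse_gtfs_time(row.arrival_time),
            parse_gtfs_time(row.departure_time),
            int(row.stop_sequence),
        )
        for row in st.itertuples(index=False)
    ]
    stops_path = feed_dir / "stops.txt"
    known = coords = None
    if stops_path.exists():
        stops = pd.read_csv(stops_path, dtype={"stop_id": str})
        known = set(stops["stop_id"])
        if {"stop_lat", "stop_lon"} <= set(stops.columns):
            coords = {
                str(r.stop_id): np.asarray([float(r.stop_lon), float(r.stop_lat)])
                for r in stops.itertuples(index=False)
            }
    g = gtfs_to_network(events, mode=mode, merge=merge, known_stops=known)
    if coords is not None:
        coords = {n: coords[n] for n in g.graph.nodes() if n in coords}
        if len(coords) == g.n_nodes:
            g = SpatialGraph(g.graph, coords=coords, units=g.units)
    return g
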