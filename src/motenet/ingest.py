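"""Reading and cleaning proximity-sensor ping logs.

A wearable sensor ("mote") broadcasts its id every two minutes; any other
mote within ~3 m stores the message. The raw log is therefore a directed
record ``emitter,receiver,timestamp``. This module parses such logs,
applies the daytime observation window, collapses directed detections to
undirected dyad-slot events (the unit of a social contact), and computes
pairwise co-presence exposure from camp entry/exit records so that contact
counts can later be expressed as rates.

File dialects
-------------
ping log   : CSV ``emitter,receiver,timestamp`` (ISO-8601 timestamps)
presence   : CSV ``individual,camp,enter,exit``
swap table : CSV ``time,old_id,new_id`` (sensor handed to a new wearer)
"""

from __future__ import annotations

import logging
from datetime import time as dtime

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Observation window used throughout: half-open [05:00, 20:00), i.e. the
#: 15 daylight hours during which wearers are awake and moving about camp.
DEFAULT_WINDOW: tuple[dtime, dtime] = (dtime(5, 0), dtime(20, 0))

PING_COLUMNS = ["emitter", "receiver", "timestamp"]
PRESENCE_COLUMNS = ["individual", "camp", "enter", "exit"]
SWAP_COLUMNS = ["time", "old_id", "new_id"]


def read_ping_log(path) -> pd.DataFrame:
    """Read a ping-log CSV into a frame of directed detection records.

    Ids are kept as strings (never coerced to numbers). Malformed rows —
    unparseable timestamps, missing fields, or self-detections
    (emitter == receiver) — are dropped and logged with their row numbers.

    Raises
    ------
    FormatError
        If the header does not contain ``emitter,receiver,timestamp``.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ping log {path!r} missing columns: {missing}")
    if df.empty:
        logger.warning("ping log %r is empty", path)
        return df.assign(timestamp=pd.to_datetime(df["timestamp"]))

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna() | df["emitter"].isna() | df["receiver"].isna()
    self_ping = (~bad) & (df["emitter"] == df["receiver"])
    for label, mask in (("malformed", bad), ("self-detection", self_ping)):
        if mask.any():
            rows = (mask[mask].index + 2).tolist()  # 1-based incl. header
            logger.warning("rejected %d %s row(s) in %r at lines %s",
                           mask.sum(), label, path, rows[:20])
    keep = ~(bad | self_ping)
    out = df.loc[keep, ["emitter", "receiver"]].copy()
    out["timestamp"] = ts[keep]
    return out.reset_index(drop=True)


def read_presence(path) -> pd.DataFrame:
    """Read a presence-interval CSV (``individual,camp,enter,exit``)."""
    df = pd.read_csv(path, dtype={"individual": str, "camp": str})
    missing = [c for c in PRESENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"presence file {path!r} missing columns: {missing}")
    df["enter"] = pd.to_datetime(df["enter"])
    df["exit"] = pd.to_datetime(df["exit"])
    if (df["enter"] >= df["exit"]).any():
        raise FormatError(f"presence file {path!r} has enter >= exit rows")
    return df


def read_swaps(path) -> pd.DataFrame:
    """Read a mote-swap table (``time,old_id,new_id``)."""
    df = pd.read_csv(path, dtype={"old_id": str, "new_id": str})
    missing = [c for c in SWAP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"swap file {path!r} missing columns: {missing}")
    df["time"] = pd.to_datetime(df["time"])
    return df.sort_values("time").reset_index(drop=True)


def apply_swaps(pings: pd.DataFrame, swaps: pd.DataFrame) -> pd.DataFrame:
    """Remap sensor ids to wearer ids after recorded hand-overs.

    Each swap row says: from ``time`` onward, detections attributed to
    ``old_id`` belong to ``new_id``. Swaps are applied in time order so
    chained hand-overs resolve correctly.
    """
    out = pings.copy()
    for row in swaps.itertuples(index=False):
        after = out["timestamp"] >= row.time
        for col in ("emitter", "receiver"):
            out.loc[after & (out[col] == row.old_id), col] = row.new_id
    return out


def filter_daytime(pings: pd.DataFrame,
                   window: tuple[dtime, dtime] = DEFAULT_WINDOW) -> pd.DataFrame:
    """Keep records whose timestamp falls in the half-open daytime window.

    A ping at exactly the window start is kept; one at the window end is
    dropped. Record order is preserved.
    """
    start, end = window
    if not (isinstance(start, dtime) and isinstance(end, dtime) and start < end):
        raise ValueError(f"invalid daytime window {window!r}")
    tod = pings["timestamp"].dt.time
    keep = (tod >= start) & (tod < end)
    return pings.loc[keep].reset_index(drop=True)


def collapse_to_dyad_slots(pings: pd.DataFrame, slot_minutes: int = 2,
                           reciprocal_only: bool = False) -> pd.DataFrame:
    """Collapse directed detections to one event per unordered dyad per slot.

    A->B and B->A within the same 2-minute slot are the same physical
    contact and yield a single event. By default a one-sided detection
    (radio loss in one direction) still counts as co-presence; with
    ``reciprocal_only=True`` only slots detected in both directions are
    kept.

    Returns a frame ``id_a,id_b,slot`` with ``id_a < id_b`` and at most one
    row per (dyad, slot).
    """
    if pings.empty:
        return pd.DataFrame(columns=["id_a", "id_b", "slot"])
    slot = pings["timestamp"].dt.floor(f"{slot_minutes}min")
    a = np.minimum(pings["emitter"].to_numpy(), pings["receiver"].to_numpy())
    b = np.maximum(pings["emitter"].to_numpy(), pings["receiver"].to_numpy())
    df = pd.DataFrame({"id_a": a, "id_b": b, "slot": slot.to_numpy(),
                       "directed_from": pings["emitter"].to_numpy()})
    if reciprocal_only:
        n_dir = df.groupby(["id_a", "id_b", "slot"])["directed_from"].nunique()
        keys = n_dir[n_dir >= 2].index
        out = pd.DataFrame(keys.tolist(), columns=["id_a", "id_b", "slot"])
    else:
        out = (df.drop(columns="directed_from")
                 .drop_duplicates(["id_a", "id_b", "slot"]))
    return out.sort_values(["id_a", "id_b", "slot"]).reset_index(drop=True)


def daytime_hours(start: pd.Timestamp, end: pd.Timestamp,
                  window: tuple[dtime, dtime] = DEFAULT_WINDOW) -> float:
    """Hours of [start, end) that fall inside the daily daytime window."""
    if end <= start:
        return 0.0
    w0, w1 = window
    total = 0.0
    day = start.normalize()
    last = end.normalize()
    while day <= last:
        lo = max(start, day + pd.Timedelta(hours=w0.hour, minutes=w0.minute))
        hi = min(end, day + pd.Timedelta(hours=w1.hour, minutes=w1.minute))
        if hi > lo:
            total += (hi - lo).total_seconds() / 3600.0
        day += pd.Timedelta(days=1)
    return total


def dyad_overlap_hours(presence_i: pd.DataFrame, presence_j: pd.DataFrame,
                       window: tuple[dtime, dtime] = DEFAULT_WINDOW) -> float:
    """Daytime hours during which two individuals were in the same camp.

    Arguments are each individual's presence rows (``camp,enter,exit``).
    The result is symmetric and bounded by each individual's own daytime
    presence; individuals who never share a camp get 0.
    """
    total = 0.0
    for ri in presence_i.itertuples(index=False):
        for rj in presence_j.itertuples(index=False):
            if ri.camp != rj.camp:
                continue
            lo = max(ri.enter, rj.enter)
            hi = min(ri.exit, rj.exit)
            if hi > lo:
                total += daytime_hours(lo, hi, window)
    return total
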