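"""T1 neighbour-exchange detection and productivity scoring.

A T1 swap is detected when a cell pair loses contact and, within the same
four-cell quartet, the opposite pair gains contact (via a transient 4-way
vertex). Each event carries a continuous productivity in [-1, 1] from the
orientation of the gaining pair's centroid-centroid line: +1 aligned with DV
(the exchange extends the tissue along AP), 0 at 45 degrees, -1 aligned with
AP. Exchange rates are expressed per DV-oriented interface per minute so they
are directly comparable to intercalation strain rates (pp/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import acute_angle_from_ap
from .kinematics import RATE_WINDOW_FRAMES, rate_of_change
from .mesh import TrackSet

DV_ORIENTED_MIN_DEG = 45.0  # strictly greater than 45 deg from AP


@dataclass
class T1Event:
    swap_time_min: float
    losing_pair: frozenset
    gaining_pair: frozenset
    centroid_angle_deg: float  # gaining pair centroid line, deg from AP [0, 90]
    productivity: float
    last_contact_frame: int  # last frame with the old contact
    first_contact_frame: int  # first frame with the new contact

    @property
    def quartet(self) -> frozenset:
        return self.losing_pair | self.gaining_pair


def t1_productivity(centroid_angle_deg: float, form: str = "cos") -> float:
    """Continuous productivity of a T1 from the gaining-pair centroid angle.

    Exactly +1 at 90 deg (DV), 0 at 45 deg, -1 at 0 deg (AP). ``form='cos'``
    uses -cos(2*angle), which equals the strain-projection factor and makes
    exchange rates directly comparable to intercalation strain rates;
    ``form='linear'`` interpolates linearly through the same anchors.
    """
    a = float(centroid_angle_deg)
    if not 0.0 <= a <= 90.0:
        raise ValueError("centroid angle must be in [0, 90] degrees")
    if form == "cos":
        return float(-np.cos(2 * np.radians(a)))
    if form == "linear":
        return (a - 45.0) / 45.0
    raise ValueError(f"unknown productivity form {form!r}")


def _contact_series(ts: TrackSet) -> dict:
    """Per unordered cell pair, boolean contact per frame."""
    pairs: dict = {}
    for idx, frame in enumerate(ts.frames):
        for pair in frame.interfaces:
            pairs.setdefault(pair, np.zeros(ts.n_frames, dtype=bool))[idx] = True
    return pairs


def _suppress_flickers(series: np.ndarray, persistence: int) -> np.ndarray:
    """Revert interior state runs shorter than ``persistence`` frames."""
    s = series.copy()
    n = len(s)
    i = 0
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        if (j - i) < persistence and i > 0 and j < n and s[i - 1] == s[j]:
            s[i:j] = s[i - 1]
            i = 0  # rescan: merges may create new short runs
            continue
        i = j
    return s


def detect_t1(
    ts: TrackSet,
    persistence_frames: int = 2,
    productivity_form: str = "cos",
    gain_search_frames: int = 4,
) -> list:
    """Detect T1 events from the per-frame neighbour graph.

    A contact change must persist at least ``persistence_frames`` frames to
    count (flicker suppression); events whose quartet is incomplete (field
    edge, lost tracks) are discarded. The swap time is the midpoint between
    the last frame with the old contact and the first frame with the new one.
    """
    contact = _contact_series(ts)
    clean = {p: _suppress_flickers(s, persistence_frames) for p, s in contact.items()}
    times = ts.times_min
    events: list = []
    for pair, s in clean.items():
        losses = np.nonzero(s[:-1] & ~s[1:])[0]  # index of last contact frame
        for k in losses:
            a, b = sorted(pair)
            frame = ts.frames[k]
            common = sorted(frame.neighbours(a) & frame.neighbours(b))
            if len(common) != 2:
                continue  # rosette or incomplete quartet: discard
            gain_pair = frozenset(common)
            gs = clean.get(gain_pair, np.zeros(ts.n_frames, dtype=bool))
            # first frame with the new contact, at or shortly after the loss
            window = range(k + 1, min(ts.n_frames, k + 1 + gain_search_frames))
            first = next(
                (j for j in window if gs[j] and not gs[max(j - 1, 0)]), None
            )
            if first is None:
                continue
            fgain = ts.frames[first]
            c, d = sorted(gain_pair)
            if c not in fgain.cells or d not in fgain.cells:
                continue
            vec = fgain.cells[d].centroid - fgain.cells[c].centroid
            angle = acute_angle_from_ap(vec)
            events.append(
                T1Event(
                    swap_time_min=0.5 * (times[k] + times[first]),
                    losing_pair=pair,
                    gaining_pair=gain_pair,
                    centroid_angle_deg=angle,
                    productivity=t1_productivity(angle, productivity_form),
                    last_contact_frame=int(k),
                    first_contact_frame=int(first),
                )
            )
    events.sort(key=lambda e: (e.swap_time_min, sorted(e.losing_pair)))
    return events


EVENT_COLUMNS = ("swap_time_min", "losing_a", "losing_b", "gaining_a",
                 "gaining_b", "centroid_angle_deg", "productivity")


def events_to_table(events) -> pd.DataFrame:
    if not events:
        return pd.DataFrame(columns=list(EVENT_COLUMNS))
    rows = []
    for e in events:
        la, lb = sorted(e.losing_pair)
        ga, gb = sorted(e.gaining_pair)
        rows.append(
            dict(swap_time_min=e.swap_time_min, losing_a=la, losing_b=lb,
                 gaining_a=ga, gaining_b=gb,
                 centroid_angle_deg=e.centroid_angle_deg,
                 productivity=e.productivity)
        )
    return pd.DataFrame(rows)


def count_dv_oriented_interfaces(frame) -> int:
    """Interfaces oriented strictly more than 45 degrees from the AP axis."""
    return sum(
        1 for it in frame.interfaces.values()
        if np.isfinite(it.orientation_deg)
        and it.orientation_deg > DV_ORIENTED_MIN_DEG
    )


def exchange_rates(
    events,
    ts: TrackSet,
    bin_edges_min: np.ndarray,
) -> pd.DataFrame:
    """Raw and productive neighbour-exchange rates per time bin (pp/min).

    Per bin: (number of swaps) / (mean number of DV-oriented interfaces) /
    (bin width in minutes); the productive rate replaces the count with the
    sum of the events' productivities. Bins with no DV-oriented interfaces
    are undefined (NaN).
    """
    edges = np.asarray(bin_edges_min, dtype=float)
    times = ts.times_min
    swap_t = np.array([e.swap_time_min for e in events])
    prod = np.array([e.productivity for e in events])
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (swap_t >= lo) & (swap_t < hi)
        frames_in = [f for f, t in zip(ts.frames, times) if lo <= t < hi]
        n_dv = (
            float(np.mean([count_dv_oriented_interfaces(f) for f in frames_in]))
            if frames_in else 0.0
        )
        minutes = hi - lo
        if n_dv > 0:
            raw = in_bin.sum() / n_dv / minutes
            productive = prod[in_bin].sum() / n_dv / minutes
        else:
            raw = productive = np.nan
        rows.append(dict(bin_start_min=lo, bin_end_min=hi, n_swaps=int(in_bin.sum()),
                         n_dv_interfaces=n_dv, swap_rate=raw,
                         productive_rate=productive))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time-to-swap aligned trajectories
# ---------------------------------------------------------------------------

def align_to_swap(
    events,
    ts: TrackSet,
    myosin_density: dict | None = None,
    window: int = RATE_WINDOW_FRAMES,
    min_pre_frames: int = 2,
) -> pd.DataFrame:
    """Interface trajectories re-indexed by time to T1 swap.

    For each event the shrinking (losing) interface is traced backward from
    the swap (negative lags) and the growing (gaining) interface forward
    (positive lags). Columns: event id, role (shrinking/growing), lag_min,
    length_um, rate_um_min (absolute), rate_pp_min (proportional), and
    myosin density when ``myosin_density`` maps (frame, pair) -> density.
    Shrinking interfaces with fewer than ``min_pre_frames`` pre-swap frames
    are excluded.
    """
    dt_min = ts.frame_interval_s / 60.0
    times = ts.times_min
    rows = []
    for eid, ev in enumerate(events):
        for role, pair in (("shrinking", ev.losing_pair),
                           ("growing", ev.gaining_pair)):
            idxs = [
                i for i, f in enumerate(ts.frames) if pair in f.interfaces
            ]
            if role == "shrinking":
                idxs = [i for i in idxs if i <= ev.last_contact_frame]
                if len(idxs) < min_pre_frames:
                    continue
            else:
                idxs = [i for i in idxs if i >= ev.first_contact_frame]
                if not idxs:
                    continue
            lengths = np.array(
                [ts.frames[i].interfaces[pair].length_um for i in idxs]
            )
            abs_rate = rate_of_change(lengths, dt_min, window)
            with np.errstate(divide="ignore", invalid="ignore"):
                prop_rate = np.where(lengths > 0, abs_rate / lengths, np.nan)
            for i, L, ar, pr in zip(idxs, lengths, abs_rate, prop_rate):
                row = dict(event=eid, role=role,
                           lag_min=times[i] - ev.swap_time_min,
                           length_um=L, rate_um_min=ar, rate_pp_min=pr)
                if myosin_density is not None:
                    row["myosin_density"] = myosin_density.get((i, pair), np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def aligned_ensemble(aligned: pd.DataFrame, value_col: str,
                     role: str = "shrinking") -> pd.DataFrame:
    """Ensemble mean +/- SE of an aligned-trajectory column per lag."""
    sub = aligned[aligned.role == role].copy()
    sub["lag_min"] = sub["lag_min"].round(6)
    g = sub.groupby("lag_min")[value_col]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_value", "sem": "se", "count": "n"})


def new_neighbour_angle(event: T1Event, ts: TrackSet,
                        n_frames: int | None = None) -> pd.DataFrame:
    """Per-lag acute angle (deg from AP) of the gaining pair's centroid line
    after the swap; truncated at track loss."""
    c, d = sorted(event.gaining_pair)
    times = ts.times_min
    stop = ts.n_frames if n_frames is None else min(
        ts.n_frames, event.first_contact_frame + n_frames
    )
    rows = []
    for i in range(event.first_contact_frame, stop):
        f = ts.frames[i]
        if c not in f.cells or d not in f.cells:
            break
        vec = f.cells[d].centroid - f.cells[c].centroid
        rows.append(dict(lag_min=times[i] - event.swap_time_min,
                         angle_deg=acute_angle_from_ap(vec)))
    return pd.DataFrame(rows)
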