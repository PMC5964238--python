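"""Flow-cytometry conjugate analysis: gating, conjugate frequency and
ionomycin-normalized calcium signal.

Event tables are plain DataFrames with one row per event and named channel
columns (``pkh26``, ``did``, ``fluo2``, ``dapi``, ``pulse_width``). Gating
proceeds: live (DAPI-negative) -> conjugate (PKH26+ DiD+ double-positive
quadrant) -> signal gate (conjugates with pulse width above a minimum, which
excludes small double-positive debris from dye transfer). The calcium
read-out is the Fluo-2 MFI inside the signal gate, expressed as a
percentage of the same gate's MFI after ionomycin saturates the dye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GateThresholds", "GatedEvents", "gate_events",
           "conjugate_frequency", "relative_calcium", "REQUIRED_CHANNELS"]

REQUIRED_CHANNELS = ("pkh26", "did", "fluo2", "dapi", "pulse_width")


@dataclass(frozen=True)
class GateThresholds:
    """Explicit gate positions (instrument-scale intensities).

    The defaults match the synthetic generator's channel scales; with real
    exports they must be set from single-stain controls.
    """

    dapi_max: float = 1000.0
    pkh26_min: float = 1000.0
    did_min: float = 1000.0
    pulse_width_min: float = 100.0


@dataclass
class GatedEvents:
    """Nested boolean masks over one event table."""

    table: pd.DataFrame
    live: np.ndarray
    conjugate: np.ndarray
    signal: np.ndarray

    @property
    def counts(self) -> dict:
        return {"events": len(self.table),
                "live": int(self.live.sum()),
                "conjugate": int(self.conjugate.sum()),
                "signal": int(self.signal.sum())}


def _check_channels(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_CHANNELS if c not in table.columns]
    if missing:
        raise ValueError(f"event table is missing channels: {missing}")


def gate_events(table: pd.DataFrame,
                thresholds: GateThresholds = GateThresholds()) -> GatedEvents:
    """Apply the live -> conjugate -> pulse-width gating hierarchy."""
    _check_channels(table)
    live = table["dapi"].to_numpy() < thresholds.dapi_max
    conjugate = (live
                 & (table["pkh26"].to_numpy() >= thresholds.pkh26_min)
                 & (table["did"].to_numpy() >= thresholds.did_min))
    signal = conjugate & (table["pulse_width"].to_numpy() > thresholds.pulse_width_min)
    return GatedEvents(table=table, live=live, conjugate=conjugate, signal=signal)


def conjugate_frequency(table: pd.DataFrame,
                        thresholds: GateThresholds = GateThresholds()) -> float:
    """Percentage of live events in the PKH26+DiD+ quadrant."""
    g = gate_events(table, thresholds)
    n_live = int(g.live.sum())
    if n_live == 0:
        raise ValueError("live gate is empty; conjugate frequency undefined")
    return 100.0 * float(g.conjugate.sum()) / n_live


def relative_calcium(pre: pd.DataFrame, post_ionomycin: pd.DataFrame,
                     thresholds: GateThresholds = GateThresholds(),
                     gate: str = "signal",
                     geometric: bool = False) -> float:
    """Fluo-2 MFI in the gated conjugates as % of the ionomycin maximum.

    Parameters
    ----------
    gate : ``"signal"`` (conjugate AND pulse width, default), ``"conjugate"``
        or ``"did"`` (all live DiD+ events) — the gate applied identically
        to both acquisitions.
    geometric : use the geometric instead of arithmetic mean.
    """
    results = []
    for tbl in (pre, post_ionomycin):
        g = gate_events(tbl, thresholds)
        if gate == "signal":
            mask = g.signal
        elif gate == "conjugate":
            mask = g.conjugate
        elif gate == "did":
            mask = g.live & (tbl["did"].to_numpy() >= thresholds.did_min)
        else:
            raise ValueError(f"unknown gate: {gate!r}")
        vals = tbl.loc[mask, "fluo2"].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"empty {gate!r} gate; relative calcium undefined")
        if geometric:
            if np.any(vals <= 0):
                raise ValueError("geometric MFI requires positive intensities")
            results.append(float(np.exp(np.log(vals).mean())))
        else:
            results.append(float(vals.mean()))
    mfi_pre, mfi_post = results
    if mfi_post <= 0:
        raise ValueError("post-ionomycin MFI is not positive")
    return 100.0 * mfi_pre / mfi_post
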