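"""Rule-based classification of single-cell calcium signatures.

A calcium signature is the 340:380 ratio of one tracked T cell over time.
Signatures fall into four categories:

``flat``
    no rise above baseline (short noise spikes allowed),
``transient``
    a rise followed by one or more returns to baseline,
``low``
    a rise that neither returns to baseline nor meets the 'high' criteria,
``high``
    an onset rising above 1.5 that stays above 1 for the rest of the
    recording, or any onset exceeding a ratio of 2.

The original assignment was done visually; the rules here are an explicit,
deterministic operationalisation with every threshold exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import fishers_exact, mann_whitney  # re-exported for convenience

__all__ = [
    "LABELS",
    "ClassifierParams",
    "classify_signature",
    "classify_signature_rule",
    "responder_counts",
    "signature_frequencies",
    "fishers_exact",
    "mann_whitney",
]

#: The four signature classes, in conventional display order.
LABELS = ("flat", "transient", "low", "high")


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds for the rule-based signature classifier.

    All ratio thresholds are dimensionless 340:380 values.

    Attributes
    ----------
    responder_threshold : population-level responder cut on max ratio.
    high_onset : onset level that a 'high' signature must exceed (1.5).
    high_sustain : level a 'high' signature must stay above after onset (1.0).
    high_absolute : any trace exceeding this is 'high' outright (2.0).
    rise_band : relative band above baseline that defines a "rise" (0.20,
        i.e. samples above 1.2x baseline count as elevated).
    spike_max_frames : elevated runs of at most this many frames are treated
        as sharp noise spikes and do not disqualify 'flat'.
    sustain_tolerance_frames : number of post-onset frames allowed below
        ``high_sustain`` before the sustain clause fails (default strict).
    """

    responder_threshold: float = 1.0
    high_onset: float = 1.5
    high_sustain: float = 1.0
    high_absolute: float = 2.0
    rise_band: float = 0.20
    spike_max_frames: int = 2
    sustain_tolerance_frames: int = 0

    def __post_init__(self):
        if not (self.high_absolute >= self.high_onset >= self.high_sustain > 0):
            raise ValueError("require high_absolute >= high_onset >= high_sustain > 0")
        if self.rise_band <= 0:
            raise ValueError("rise_band must be positive")


def _elevated_runs(elevated: np.ndarray):
    """Yield (start, stop) index pairs of consecutive True runs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], elevated.view(np.int8), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


def classify_signature_rule(values, baseline: float,
                            params: ClassifierParams = ClassifierParams()):
    """Classify one trace and report which rule fired.

    Returns ``(label, rule)`` where ``rule`` is one of ``"no_rise"``,
    ``"max_above_absolute"``, ``"sustained_onset"``, ``"return_to_baseline"``,
    ``"sustained_low"``.
    """
    r = np.asarray(values, dtype=float)
    if r.size == 0:
        raise ValueError("empty trace")
    if baseline <= 0:
        raise ValueError("baseline must be positive")

    rise_level = (1.0 + params.rise_band) * baseline
    elevated = r > rise_level
    runs = [(s, e) for (s, e) in _elevated_runs(elevated)
            if (e - s) > params.spike_max_frames]
    if not runs:
        return "flat", "no_rise"

    if r.max() > params.high_absolute:
        return "high", "max_above_absolute"
    onset_idx = np.flatnonzero(r > params.high_onset)
    if onset_idx.size:
        post = r[onset_idx[0]:]
        dips = int(np.count_nonzero(post <= params.high_sustain))
        if dips <= params.sustain_tolerance_frames:
            return "high", "sustained_onset"

    # A qualifying rise that ends before the trace does has returned to baseline.
    if any(e < r.size for (_, e) in runs):
        return "transient", "return_to_baseline"
    return "low", "sustained_low"


def classify_signature(values, baseline: float,
                       params: ClassifierParams = ClassifierParams()) -> str:
    """Classify one calcium trace into flat/transient/low/high."""
    return classify_signature_rule(values, baseline, params)[0]


def responder_counts(max_ratios_by_condition: dict, threshold: float = 1.0) -> pd.DataFrame:
    """Count responders (max ratio >= threshold) per condition.

    Parameters
    ----------
    max_ratios_by_condition : mapping condition -> sequence of per-cell
        maximum 340:380 ratios.

    Returns
    -------
    DataFrame indexed by condition with columns ``above`` and ``below``,
    suitable for :func:`fishers_exact` on two conditions.
    """
    rows = {}
    for cond, vals in max_ratios_by_condition.items():
        v = np.asarray(vals, dtype=float)
        rows[cond] = {"above": int(np.count_nonzero(v >= threshold)),
                      "below": int(np.count_nonzero(v < threshold))}
    return pd.DataFrame.from_dict(rows, orient="index")[["above", "below"]]


def signature_frequencies(labels: Sequence[str],
                          conditions: Sequence[str] | None = None) -> pd.DataFrame:
    """Percentage of signatures in each class, per condition.

    Rows are conditions (a single ``"all"`` row when no conditions are
    given); columns are the four classes, each row summing to 100.
    """
    labels = list(labels)
    if conditions is None:
        conditions = ["all"] * len(labels)
    df = pd.DataFrame({"label": labels, "condition": list(conditions)})
    counts = (df.groupby(["condition", "label"]).size()
                .unstack(fill_value=0)
                .reindex(columns=LABELS, fill_value=0))
    return counts.div(counts.sum(axis=1), axis=0) * 100.0
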