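"""Synthetic flow-cytometry event tables for a pre/post-ionomycin pair.

Events are composed of exact sub-population counts (rounded from the
configured fractions, so small tables hit their target frequencies
exactly): dead (DAPI+), true conjugates (PKH26+DiD+ with conjugate-sized
pulse width), small double-positive artifacts (dye transfer; low pulse
width), and single-positive/negative remainder. Channel intensities are
log-normal around well-separated negative/positive modes spanning the
default gate thresholds. The post-ionomycin table is the same sample with
Fluo-2 scaled so the gated pre/post MFI ratio equals the configured
relative calcium level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FlowSimConfig", "simulate_flow_events"]


@dataclass
class FlowSimConfig:
    """Composition and signal levels of the synthetic sample.

    Fractions: ``f_dead`` of all events; ``f_conjugate`` and
    ``f_artifact_lowpw`` of live events (the latter are double-positive but
    fail the pulse-width gate). ``relative_calcium`` is the target pre/post
    Fluo-2 MFI ratio as a fraction of the ionomycin maximum.
    """

    n_events: int = 10000
    f_dead: float = 0.10
    f_conjugate: float = 0.08
    f_artifact_lowpw: float = 0.02
    relative_calcium: float = 0.25
    neg_mean: float = 100.0
    pos_mean: float = 10000.0
    log_sd: float = 0.25
    pw_conjugate: float = 150.0
    pw_small: float = 60.0
    pw_sd: float = 10.0
    post_noise_sd: float = 0.0  # multiplicative log-normal noise on post Fluo-2

    def __post_init__(self):
        for name in ("f_dead", "f_conjugate", "f_artifact_lowpw", "relative_calcium"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.f_conjugate + self.f_artifact_lowpw > 1.0:
            raise ValueError("conjugate + artifact fractions exceed 1")


def _lognormal(rng, mean, sd_log, n):
    return mean * np.exp(rng.normal(0.0, sd_log, n))


def simulate_flow_events(config: FlowSimConfig = FlowSimConfig(),
                         rng: np.random.Generator | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a (pre, post_ionomycin) pair of event tables.

    Both tables carry an ``acquisition`` column (``"pre"`` /
    ``"post_ionomycin"``) and identical event composition; only Fluo-2
    changes between acquisitions.
    """
    rng = rng or np.random.default_rng()
    n = config.n_events
    n_dead = round(config.f_dead * n)
    n_live = n - n_dead
    n_conj = round(config.f_conjugate * n_live)
    n_art = round(config.f_artifact_lowpw * n_live)
    n_rest = n_live - n_conj - n_art

    def chan(n_pos, n_neg):
        return np.concatenate([_lognormal(rng, config.pos_mean, config.log_sd, n_pos),
                               _lognormal(rng, config.neg_mean, config.log_sd, n_neg)])

    # Order: conjugates, artifacts, other live, dead.
    pkh26 = np.concatenate([chan(n_conj + n_art, 0), chan(n_rest // 2, n_rest - n_rest // 2),
                            chan(n_dead // 2, n_dead - n_dead // 2)])
    did = np.concatenate([chan(n_conj + n_art, 0), chan(0, n_rest), chan(0, n_dead)])
    dapi = np.concatenate([_lognormal(rng, config.neg_mean, config.log_sd, n_live),
                           _lognormal(rng, config.pos_mean, config.log_sd, n_dead)])
    pulse_width = np.concatenate([
        rng.normal(config.pw_conjugate, config.pw_sd, n_conj),
        rng.normal(config.pw_small, config.pw_sd, n_art),
        rng.normal(config.pw_conjugate, config.pw_sd, n_rest + n_dead),
    ])
    fluo2_max = _lognormal(rng, config.pos_mean, config.log_sd, n)
    fluo2_pre = fluo2_max * config.relative_calcium

    pre = pd.DataFrame({"pkh26": pkh26, "did": did, "fluo2": fluo2_pre,
                        "dapi": dapi, "pulse_width": pulse_width,
                        "acquisition": "pre"})
    fluo2_post = fluo2_max.copy()
    if config.post_noise_sd > 0:
        fluo2_post *= np.exp(rng.normal(0.0, config.post_noise_sd, n))
    post = pre.copy()
    post["fluo2"] = fluo2_post
    post["acquisition"] = "post_ionomycin"
    return pre, post
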