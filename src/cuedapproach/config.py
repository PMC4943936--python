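"""Generator configuration: per-condition parameter sets for the synthetic task.

A :class:`GeneratorConfig` fully determines a simulated two-cue sucrose-seeking
session: trial timing (truncated-exponential inter-trial intervals, 5-s cue
windows), the latent two-state (responsive / non-responsive) Markov process and
its state- and cue-conditional response emissions, latency models for cued
receptacle entries, and the video-tracking trajectory model (chamber geometry,
locomotor bouts, jitter, missing frames).

Named configurations ship for the experimental conditions of the study design
this package emulates: vehicle (saline) control, and low/high doses of D1- and
D2-receptor agonists plus D1/D2 antagonists, which act on the transition
matrices of the latent state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "GeneratorConfig",
    "LatencyModel",
    "LocomotionParams",
    "InvalidConfigError",
    "CONDITIONS",
    "condition_config",
    "load_config",
    "save_config",
]

LARGE = "LARGE"
SMALL = "SMALL"


class InvalidConfigError(ValueError):
    """A generator configuration violates one of its invariants."""


@dataclass(frozen=True)
class LatencyModel:
    """Latencies of the cued approach, all in seconds.

    Receptacle-entry latency after cue onset is drawn from a normal
    distribution truncated to ``(entry_min, entry_max)``; ``entry_max`` must
    stay below the 5-s cue window so every generated response is in-window.
    Movement onset precedes entry by the approach travel time; its offset from
    cue onset is truncated-normal on ``(move_min, +inf)`` and additionally
    capped at a fraction of the entry latency during trace synthesis.
    ``consume_mean``/``consume_sd`` govern how long the animal stays in the
    receptacle after a rewarded entry.
    """

    entry_mean: float = 1.5
    entry_sd: float = 0.6
    entry_min: float = 0.3
    entry_max: float = 4.5
    move_mean: float = 0.35
    move_sd: float = 0.15
    move_min: float = 0.05
    consume_mean: float = 2.5
    consume_sd: float = 0.8


@dataclass(frozen=True)
class LocomotionParams:
    """Trajectory-model parameters for the tracking-trace synthesiser.

    Spontaneous locomotor bouts arise as a Poisson process whose rate depends
    on the latent state (``bout_rate_responsive`` / ``bout_rate_nonresponsive``,
    in Hz); each bout moves at ``bout_speed`` cm/s for an exponential duration
    with mean ``bout_duration_mean`` s. ``jitter_sd`` (cm) is per-frame
    positional noise on each LED. Missing-frame gaps start with per-frame
    probability ``gap_rate``; a gap is long (> 10 frames, discarded downstream)
    with probability ``long_gap_fraction``, otherwise 1-10 frames.
    """

    bout_rate_responsive: float = 0.08
    bout_rate_nonresponsive: float = 0.03
    bout_speed: float = 15.0
    bout_duration_mean: float = 1.0
    jitter_sd: float = 0.03
    gap_rate: float = 0.002
    long_gap_fraction: float = 0.15
    led_separation: float = 2.0


def _as_matrix(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.shape != (2, 2):
        raise InvalidConfigError(f"transition matrix must be 2x2, got {a.shape}")
    return a


@dataclass(frozen=True)
class GeneratorConfig:
    """Complete parameterisation of one synthetic session.

    Parameters
    ----------
    condition_label
        Name of the pharmacological condition (e.g. ``"saline"``).
    session_duration
        Session length in seconds (default 2 h).
    iti_mean, iti_bounds
        Realized mean and truncation bounds of the truncated-exponential
        inter-trial interval distribution, seconds.
    cue_duration_max
        Maximum cue presentation, seconds; entry during the cue terminates it.
    cue_mix
        Probability that a trial presents the large-reward cue.
    reward_volumes
        (large, small) reward volumes in microlitres.
    transition_matrix_by_hour
        Hour index -> right-stochastic 2x2 matrix over (responsive,
        non-responsive), rows indexed by the antecedent state. The matrix for
        the largest hour <= the current one applies.
    p_respond_given_state
        Cue type -> (P(respond | responsive), P(respond | non-responsive)).
    spontaneous_entry_rate
        Poisson rate (Hz) of uncued receptacle entries during ITIs.
    chamber_dims, receptacle_position
        Arena size and receptacle location, cm.
    frame_rate, cm_per_pixel
        Video-tracking sampling rate (frames/s) and spatial scale.
    """

    condition_label: str = "saline"
    session_duration: float = 7200.0
    iti_mean: float = 30.0
    iti_bounds: tuple[float, float] = (10.0, 90.0)
    cue_duration_max: float = 5.0
    cue_mix: float = 0.5
    reward_volumes: tuple[float, float] = (250.0, 150.0)
    transition_matrix_by_hour: Mapping[int, np.ndarray] = field(
        default_factory=lambda: {0: np.array([[0.88, 0.12], [0.12, 0.88]])}
    )
    p_respond_given_state: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {LARGE: (0.95, 0.13), SMALL: (0.60, 0.06)}
    )
    latency_model: LatencyModel = field(default_factory=LatencyModel)
    spontaneous_entry_rate: float = 0.02
    chamber_dims: tuple[float, float] = (30.0, 25.0)
    receptacle_position: tuple[float, float] = (15.0, 0.0)
    frame_rate: float = 30.0
    cm_per_pixel: float = 0.1
    locomotion_params: LocomotionParams = field(default_factory=LocomotionParams)
    seed: int | None = None

    def __post_init__(self):
        lo, hi = self.iti_bounds
        if lo < 1.0:
            raise InvalidConfigError("iti_bounds[0] must be >= 1 s")
        if hi < lo:
            raise InvalidConfigError("iti_bounds must satisfy lo <= hi")
        if not 0.0 <= self.cue_mix <= 1.0:
            raise InvalidConfigError("cue_mix must be a probability")
        if self.cue_duration_max <= 0:
            raise InvalidConfigError("cue_duration_max must be positive")
        if self.session_duration <= 0:
            raise InvalidConfigError("session_duration must be positive")
        mats = {int(h): _as_matrix(m) for h, m in self.transition_matrix_by_hour.items()}
        if 0 not in mats:
            raise InvalidConfigError("transition_matrix_by_hour must define hour 0")
        for h, m in mats.items():
            if np.any(m < 0) or np.any(m > 1):
                raise InvalidConfigError(f"hour-{h} matrix entries must lie in [0, 1]")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise InvalidConfigError(f"hour-{h} matrix rows must each sum to 1")
        object.__setattr__(self, "transition_matrix_by_hour", mats)
        for cue, (p_r, p_n) in self.p_respond_given_state.items():
            if not (0.0 <= p_n <= p_r <= 1.0):
                raise InvalidConfigError(
                    f"{cue}: need 0 <= P(respond|non-responsive) <= "
                    f"P(respond|responsive) <= 1, got ({p_r}, {p_n})"
                )
        lm = self.latency_model
        if lm.entry_max >= self.cue_duration_max:
            raise InvalidConfigError("entry_max must be below the cue window")
        if self.cm_per_pixel <= 0:
            raise InvalidConfigError("cm_per_pixel must be positive")

    def matrix_for_hour(self, hour: int) -> np.ndarray:
        """Transition matrix in force during ``hour`` (0-based).

        Hours beyond the last configured block reuse the latest matrix.
        """
        keys = [h for h in self.transition_matrix_by_hour if h <= hour]
        if not keys:
            raise InvalidConfigError(f"no transition matrix configured for hour {hour}")
        return self.transition_matrix_by_hour[max(keys)]

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transition_matrix_by_hour"] = {
            int(h): np.asarray(m).tolist() for h, m in self.transition_matrix_by_hour.items()
        }
        d["p_respond_given_state"] = {
            k: list(v) for k, v in self.p_respond_given_state.items()
        }
        for key in ("iti_bounds", "reward_volumes", "chamber_dims", "receptacle_position"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "latency_model" in d and isinstance(d["latency_model"], Mapping):
            d["latency_model"] = LatencyModel(**d["latency_model"])
        if "locomotion_params" in d and isinstance(d["locomotion_params"], Mapping):
            d["locomotion_params"] = LocomotionParams(**d["locomotion_params"])
        for key in ("iti_bounds", "reward_volumes", "chamber_dims", "receptacle_position"):
            if key in d:
                d[key] = tuple(d[key])
        if "p_respond_given_state" in d:
            d["p_respond_given_state"] = {
                k: tuple(v) for k, v in d["p_respond_given_state"].items()
            }
        return cls(**d)


def load_config(path) -> GeneratorConfig:
    """Read a YAML condition file into a :class:`GeneratorConfig`."""
    with open(path) as fh:
        return GeneratorConfig.from_dict(yaml.safe_load(fh))


def save_config(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Shipped condition library.
#
# The transition matrices encode the drug effects on the latent state: the
# control condition starts balanced (stationary occupancy 0.5/0.5) and shifts
# strongly toward non-responsiveness in hour 2; receptor agonists stabilise
# the responsive state across the whole session (no hour effect); antagonists
# impose, from the first hour, the transition structure the control condition
# only reaches in its second hour. Emission probabilities are shared across
# conditions and calibrated so the control first-hour response ratios are 54%
# (large-reward cue) and 33% (small-reward cue).
# ---------------------------------------------------------------------------

_SALINE_H1 = [[0.88, 0.12], [0.12, 0.88]]          # pi = (0.50, 0.50)
_SALINE_H2 = [[0.75, 0.25], [0.07, 0.93]]          # pi ~ (0.22, 0.78)
_AGONIST_HIGH = [[0.95, 0.05], [0.35, 0.65]]       # pi = (0.875, 0.125)
_AGONIST_LOW = [[0.90, 0.10], [0.18, 0.82]]        # pi ~ (0.64, 0.36)

_BASE_EMISSIONS = {LARGE: (0.95, 0.13), SMALL: (0.60, 0.06)}


def _make(label: str, h1, h2, spontaneous_entry_rate: float = 0.02) -> GeneratorConfig:
    return GeneratorConfig(
        condition_label=label,
        transition_matrix_by_hour={0: np.array(h1, float), 1: np.array(h2, float)},
        p_respond_given_state=dict(_BASE_EMISSIONS),
        spontaneous_entry_rate=spontaneous_entry_rate,
    )


CONDITIONS: dict[str, GeneratorConfig] = {
    "saline": _make("saline", _SALINE_H1, _SALINE_H2),
    "d1_agonist_low": _make("d1_agonist_low", _AGONIST_LOW, _AGONIST_LOW),
    "d1_agonist_high": _make("d1_agonist_high", _AGONIST_HIGH, _AGONIST_HIGH),
    "d1_antagonist": _make("d1_antagonist", _SALINE_H2, _SALINE_H2),
    "d2_agonist_low": _make("d2_agonist_low", _AGONIST_LOW, _AGONIST_LOW),
    "d2_agonist_high": _make("d2_agonist_high", _AGONIST_HIGH, _AGONIST_HIGH),
    "d2_antagonist": _make("d2_antagonist", _SALINE_H2, _SALINE_H2),
}


def condition_config(name: str) -> GeneratorConfig:
    """Return the shipped configuration for a named condition."""
    try:
        return CONDITIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; available: {sorted(CONDITIONS)}"
        ) from None
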