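"""Continuous-time Markov simulation of snRNP binding and trace rendering.

A :class:`KineticScheme` is a labeled continuous-time Markov chain over
assembly states (free pre-mRNA, B complex, activated spliceosome, ...);
each state emits fluorescence on a set of channels (U4, U5, NTC, U1).
Trajectories are sampled by the Gillespie algorithm over a fixed
observation window, converted to per-channel binding intervals, and then
rendered as noisy integrated-intensity traces at the acquisition timing
used in the experiments (1 s frames at 3 s spacing by default, 60 min).

Presets mirror the two ATP regimes studied: at 2 mM ATP B complex
resolves mostly by activation (irreversible U4 release followed by NTC
arrival), at 50 uM ATP activation is suppressed and the tri-snRNP mostly
releases intact, with a small stalled long-lived class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dwell import ConvolutionModel, MixtureModel

__all__ = [
    "Transition",
    "KineticScheme",
    "AcquisitionConfig",
    "MoleculeTruth",
    "IntensityTrace",
    "simulate_molecules",
    "sample_dwells",
    "render_traces",
    "render_background",
    "preset_scheme",
    "PRESETS",
]

CHANNELS = ("U4", "U5", "NTC", "U1")


class SchemeError(ValueError):
    """Invalid kinetic scheme configuration."""


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    rate: float  # per second


@dataclass(frozen=True)
class KineticScheme:
    """States, transitions and per-state channel emission.

    ``emission_map`` maps every state name to the set of channels visible
    while the molecule occupies that state.  A tri-snRNP binding step is a
    single transition into a state emitting both U4 and U5, so the two
    spots appear at the same instant.
    """

    emission_map: Mapping[str, frozenset]
    transitions: tuple[Transition, ...]
    initial_state: str = "FREE"
    atp_preset: str | None = None

    def __post_init__(self):
        states = set(self.emission_map)
        if self.initial_state not in states:
            raise SchemeError(f"unknown initial state {self.initial_state!r}")
        for tr in self.transitions:
            if tr.source not in states or tr.target not in states:
                raise SchemeError(f"transition {tr} references unknown state")
            if tr.rate < 0:
                raise SchemeError(f"negative rate in transition {tr}")
        for chans in self.emission_map.values():
            unknown = set(chans) - set(CHANNELS)
            if unknown:
                raise SchemeError(f"unknown channels {unknown}")

    def exits(self, state: str) -> list[Transition]:
        return [tr for tr in self.transitions if tr.source == state]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera timing, noise and illumination settings.

    Frames of ``frame_duration`` s are recorded every ``frame_spacing`` s
    over ``t_max`` s.  Intensities are baseline + spot_amplitude per bound
    fluorophore (fractionally weighted by overlap with the exposure) +
    Gaussian noise.  Photobleaching, when enabled, converts individual
    fluorophores to dark states at rate photobleach_coeff * laser_power
    per second of illumination.
    """

    frame_duration: float = 1.0
    frame_spacing: float = 3.0
    t_max: float = 3600.0
    baseline: float = 100.0
    noise_sigma: float = 1.0
    spot_amplitude: float = 8.0  # per fluorophore, in intensity units
    laser_power_uW: float = 150.0
    photobleach_coeff: float = 0.0  # per (uW * s of illumination)
    labels_per_channel: Mapping[str, int] = field(
        default_factory=lambda: {"U4": 1, "U5": 2, "NTC": 2, "U1": 2})

    def __post_init__(self):
        if self.frame_duration > self.frame_spacing:
            raise ValueError("frame_duration must be <= frame_spacing")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.t_max <= self.frame_spacing:
            raise ValueError("t_max must exceed frame_spacing")

    @property
    def frame_starts(self) -> np.ndarray:
        return np.arange(0.0, self.t_max - self.frame_duration + 1e-9,
                         self.frame_spacing)

    @property
    def frame_mids(self) -> np.ndarray:
        return self.frame_starts + 0.5 * self.frame_duration


@dataclass
class MoleculeTruth:
    """Ground-truth binding schedule for one pre-mRNA molecule.

    ``intervals`` maps channel -> list of (t_bind, t_release, censored);
    censored marks intervals still running at the end of the window.
    """

    molecule_id: int
    intervals: dict[str, list[tuple[float, float, bool]]]
    t_max: float

    def channels(self) -> list[str]:
        return [c for c, iv in self.intervals.items() if iv]


@dataclass
class IntensityTrace:
    """One channel's integrated AOI intensity versus frame time."""

    molecule_id: int
    channel: str
    t_mid: np.ndarray       # frame midpoints, s
    intensity: np.ndarray
    frame_spacing: float
    frame_duration: float

    def __len__(self) -> int:
        return self.t_mid.size


# ---------------------------------------------------------------------------
# Gillespie simulation
# ---------------------------------------------------------------------------

def _simulate_path(scheme: KineticScheme, t_max: float,
                   rng: np.random.Generator):
    """One Gillespie trajectory: list of (state, t_enter, t_exit)."""
    state = scheme.initial_state
    t = 0.0
    path = []
    while t < t_max:
        exits = scheme.exits(state)
        rates = np.array([tr.rate for tr in exits])
        total = rates.sum()
        if total <= 0:  # absorbing
            path.append((state, t, t_max))
            break
        dt = rng.exponential(1.0 / total)
        t_next = min(t + dt, t_max)
        path.append((state, t, t_next))
        if t + dt >= t_max:
            break
        state = exits[int(rng.choice(len(exits), p=rates / total))].target
        t = t_next
    return path


def _path_to_intervals(scheme: KineticScheme, path,
                       t_max: float) -> dict[str, list]:
    intervals: dict[str, list] = {c: [] for c in CHANNELS}
    for channel in CHANNELS:
        current = None
        for state, t0, t1 in path:
            visible = channel in scheme.emission_map[state]
            if visible and current is None:
                current = [t0, t1]
            elif visible:
                current[1] = t1
            elif current is not None:
                intervals[channel].append(
                    (current[0], current[1], False))
                current = None
        if current is not None:
            intervals[channel].append(
                (current[0], current[1], current[1] >= t_max - 1e-9))
    return intervals


def simulate_molecules(scheme: KineticScheme, n_molecules: int,
                       config: AcquisitionConfig,
                       seed: int) -> list[MoleculeTruth]:
    """Sample ground-truth binding histories for ``n_molecules`` molecules.

    Each molecule gets an independent generator spawned from the master
    seed, so results are reproducible and stable under partial generation.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_molecules)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        path = _simulate_path(scheme, config.t_max, rng)
        intervals = _path_to_intervals(scheme, path, config.t_max)
        out.append(MoleculeTruth(i, intervals, config.t_max))
    return out


def sample_dwells(model: MixtureModel | ConvolutionModel, n: int,
                  seed: int) -> np.ndarray:
    """Draw ``n`` dwell times from a censored dwell-time density."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return model.sample(n, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# trace rendering
# ---------------------------------------------------------------------------

def _occupancy(starts: np.ndarray, duration: float,
               a: float, b: float) -> np.ndarray:
    """Fractional overlap of [a, b] with each exposure [s, s+duration]."""
    return np.clip(np.minimum(b, starts + duration)
                   - np.maximum(a, starts), 0.0, None) / duration


def render_traces(truths: Iterable[MoleculeTruth], config: AcquisitionConfig,
                  seed: int, channels: Sequence[str] | None = None
                  ) -> list[IntensityTrace]:
    """Render binding schedules as noisy integrated-intensity traces.

    Per frame: intensity = baseline + spot_amplitude * (number of live
    bound fluorophores, fractionally weighted by exposure overlap) +
    Gaussian noise.  With photobleaching enabled each fluorophore carries
    an exponential bleach clock running at photobleach_coeff *
    laser_power_uW per second of illumination (duty-cycle corrected).
    """
    truths = list(truths)
    starts = config.frame_starts
    mids = config.frame_mids
    duty = config.frame_duration / config.frame_spacing
    bleach_rate = config.photobleach_coeff * config.laser_power_uW * duty
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    traces = []
    for truth in truths:
        chans = channels if channels is not None else [
            c for c in CHANNELS if truth.intervals.get(c)]
        if not chans:
            chans = ["U4"]
        for channel in chans:
            signal = np.zeros_like(mids)
            n_labels = config.labels_per_channel.get(channel, 1)
            for (t0, t1, _c) in truth.intervals.get(channel, []):
                for _ in range(n_labels):
                    end = t1
                    if bleach_rate > 0:
                        end = min(t1, t0 + rng.exponential(1.0 / bleach_rate))
                    signal += _occupancy(starts, config.frame_duration,
                                         t0, end)
            noise = rng.normal(0.0, config.noise_sigma, size=mids.size) \
                if config.noise_sigma > 0 else 0.0
            traces.append(IntensityTrace(
                truth.molecule_id, channel,
                mids.copy(),
                config.baseline + config.spot_amplitude * signal + noise,
                config.frame_spacing, config.frame_duration))
    return traces


def render_background(n_empty_aois: int, rate_per_min: float,
                      config: AcquisitionConfig, seed: int,
                      dwell_mean: float = 6.0, channel: str = "U4"
                      ) -> tuple[list[IntensityTrace], list[MoleculeTruth]]:
    """Poisson-process nonspecific binding at empty surface locations.

    Events arrive at ``rate_per_min`` per AOI per minute with short
    exponential dwells (mean ``dwell_mean`` s).  Returns rendered traces
    together with the ground-truth schedules.
    """
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    duration_min = config.t_max / 60.0
    truths = []
    for i in range(n_empty_aois):
        n_ev = rng.poisson(rate_per_min * duration_min)
        ivs = []
        for t0 in np.sort(rng.uniform(0, config.t_max, size=n_ev)):
            t1 = t0 + rng.exponential(dwell_mean)
            censored = t1 >= config.t_max
            ivs.append((t0, min(t1, config.t_max), censored))
        truths.append(MoleculeTruth(i, {channel: ivs}, config.t_max))
    traces = render_traces(truths, config, seed=int(rng.integers(2**31)),
                           channels=[channel])
    return traces, truths


# ---------------------------------------------------------------------------
# published-condition presets
# ---------------------------------------------------------------------------

def _branching(source: str, targets: Sequence[tuple[str, float]],
               total_rate: float) -> list[Transition]:
    """Competing first-order exits from ``source``: overall exit rate
    ``total_rate``, route probabilities given by the weights."""
    wsum = sum(w for _, w in targets)
    return [Transition(source, tgt, total_rate * w / wsum)
            for tgt, w in targets if w > 0]


def preset_scheme(preset: str) -> KineticScheme:
    """Kinetic scheme for one of the published ATP regimes.

    "2mM"  — physiological ATP: tri-snRNP binding (after a two-step
        arrival, tau 2105 and 417 s) forms B complex whose lifetime is a
        three-component mixture (4/34/660 s, equal default amplitudes);
        62% of B-complex exits proceed to activation (irreversible U4
        release, NTC arrival ~30 s later, U5 release after ~300 s), 38%
        discard the intact tri-snRNP.  Rebinding after an activation round
        is single-step (617 s), after a discard 492 s.

    "50uM" — limiting ATP: the release mixture has two components
        (52/780 s); activation is largely suppressed (10% of non-stalled
        exits) and 9% of bindings enter a long-lived stalled B complex.
        NTC recruitment is disabled.
    """
    arr1, arr2 = 2105.0, 417.0  # two-step initial arrival
    t_rebind_act, t_rebind_disc = 617.0, 492.0
    none = frozenset()
    u4u5 = frozenset({"U4", "U5"})
    u5 = frozenset({"U5"})

    if preset == "2mM":
        taus = (4.0, 34.0, 660.0)
        amps = (1 / 3, 1 / 3, 1 / 3)
        p_act = 0.62
        emission = {
            "FREE": none, "PRE": none,
            "B1": u4u5, "B2": u4u5, "B3": u4u5,
            "A_PRE": u4u5,  # committed to activation, U4 not yet released
            "ACT": u5, "ACT_NTC": frozenset({"U5", "NTC"}),
            "POST_ACT": none, "POST_DISC": none,
        }
        b_states = list(zip(("B1", "B2", "B3"), amps))
        transitions = [Transition("FREE", "PRE", 1.0 / arr1)]
        transitions += _branching("PRE", b_states, 1.0 / arr2)
        for (b, _w), tau in zip(b_states, taus):
            transitions += [
                Transition(b, "A_PRE", p_act / tau),
                Transition(b, "POST_DISC", (1 - p_act) / tau),
            ]
        transitions += [
            # multi-step, irreversible U4 loss: commitment then release
            Transition("A_PRE", "ACT", 1.0 / 60.0),
            Transition("ACT", "ACT_NTC", 1.0 / 30.0),
            Transition("ACT_NTC", "POST_ACT", 1.0 / 300.0),
        ]
        transitions += _branching("POST_ACT", b_states, 1.0 / t_rebind_act)
        transitions += _branching("POST_DISC", b_states, 1.0 / t_rebind_disc)
        return KineticScheme(emission, tuple(transitions), "FREE", "2mM")

    if preset == "50uM":
        taus = (52.0, 780.0)
        p_act = 0.10
        p_stall = 0.09
        emission = {
            "FREE": none, "PRE": none,
            "B1": u4u5, "B2": u4u5, "STALL": u4u5,
            "ACT": u5, "POST_ACT": none, "POST_DISC": none,
        }
        b_states = [("B1", (1 - p_stall) / 2), ("B2", (1 - p_stall) / 2),
                    ("STALL", p_stall)]
        transitions = [Transition("FREE", "PRE", 1.0 / arr1)]
        transitions += _branching("PRE", b_states, 1.0 / arr2)
        for b, tau in zip(("B1", "B2"), taus):
            transitions += [
                Transition(b, "ACT", p_act / tau),
                Transition(b, "POST_DISC", (1 - p_act) / tau),
            ]
        transitions += [
            Transition("STALL", "POST_DISC", 1.0 / 36000.0),
            Transition("ACT", "POST_ACT", 1.0 / 300.0),
        ]
        transitions += _branching("POST_ACT", b_states, 1.0 / t_rebind_act)
        transitions += _branching("POST_DISC", b_states, 1.0 / t_rebind_disc)
        return KineticScheme(emission, tuple(transitions), "FREE", "50uM")

    raise SchemeError(f"unknown preset {preset!r}; choose '2mM' or '50uM'")


PRESETS = ("2mM", "50uM")
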