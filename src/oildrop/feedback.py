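"""Discrete-time simulation of coupled negative-feedback loops.

One loop abstracts an enzyme (effector) producing a product and a receptor
that, when the product concentration exceeds its encoded sensitivity
threshold, sends an inhibition signal to the effector. With a non-zero
signalling delay the loop settles into a sustained relaxation oscillation —
the product concentration rises while active, overshoots the threshold,
is shut off after the delay, decays, and re-activates.

Loops couple through two channels: an *effector* coupling modulates the
target's production rate, a *receptor* coupling modulates the target's
sensitivity threshold. Modulation is multiplicative,
``base × (1 + gain · C_source / S_source)``, normalising the source
concentration by its own sensitivity so gains stay dimensionless.

Update rule per step t (synchronous across loops):

1. effective rate v′ and sensitivity S′ from the incoming couplings;
2. activity A(t) = 0 if the loop's own concentration ``delay`` steps
   earlier strictly exceeded S′, else 1 (before any history exists the
   ``initial_active`` flag is used);
3. C(t+1) = C(t) + v′·A(t) − decay·C(t), floored at 0.

The model is deterministic; the seed argument is recorded for provenance
and reserved for optional noise extensions.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, InputError

__all__ = [
    "LoopSpec", "CouplingSpec", "SystemSpec", "Trajectory",
    "OscillationSummary", "simulate", "measure_oscillation", "check_range",
    "disturbance_experiment", "load_system", "trajectory_frame",
    "DEFAULT_LOOP",
]

EFFECTOR = "effector"
RECEPTOR = "receptor"

# Documented default unit: oscillates with period ~13 steps.
DEFAULT_LOOP = dict(
    effector_rate=1.0, decay_rate=0.1, sensitivity=5.0, delay=3,
    initial_concentration=0.0, initial_active=True,
)


@dataclass
class LoopSpec:
    """Parameters of one receptor–effector unit.

    effector_rate is the product output per time step while active ("number
    of effector revolutions"), decay_rate the fraction of product removed
    per step, sensitivity the concentration threshold above which the
    receptor inhibits, and delay the number of steps the inhibition signal
    needs to act.
    """

    name: str
    effector_rate: float = 1.0
    decay_rate: float = 0.1
    sensitivity: float = 5.0
    delay: int = 3
    initial_concentration: float = 0.0
    initial_active: bool = True

    def validate(self) -> None:
        if self.effector_rate < 0:
            raise ConfigError(f"loop {self.name!r}: effector_rate must be >= 0")
        if not 0 <= self.decay_rate < 1:
            raise ConfigError(f"loop {self.name!r}: decay_rate must be in [0, 1)")
        if self.sensitivity < 0:
            raise ConfigError(f"loop {self.name!r}: sensitivity must be >= 0")
        if int(self.delay) != self.delay or self.delay < 1:
            raise ConfigError(f"loop {self.name!r}: delay must be an integer >= 1")
        if self.initial_concentration < 0:
            raise ConfigError(f"loop {self.name!r}: initial_concentration must be >= 0")


@dataclass
class CouplingSpec:
    """Directed modulation of one loop by another's product concentration."""

    source: str
    target: str
    mode: str = EFFECTOR  # effector: modulates rate; receptor: modulates threshold
    gain: float = 1.0

    def validate(self) -> None:
        if self.source == self.target:
            raise ConfigError("coupling source and target must differ")
        if self.mode not in (EFFECTOR, RECEPTOR):
            raise ConfigError(f"unknown coupling mode {self.mode!r}")


@dataclass
class SystemSpec:
    """A network of feedback loops; capped at 3 unless explicitly lifted."""

    loops: list[LoopSpec]
    couplings: list[CouplingSpec] = field(default_factory=list)
    allow_large: bool = False

    def validate(self) -> None:
        if not self.loops:
            raise ConfigError("system has no loops")
        names = [lp.name for lp in self.loops]
        if len(set(names)) != len(names):
            raise ConfigError("loop names must be unique")
        if len(self.loops) > 3 and not self.allow_large:
            raise ConfigError(
                "more than 3 loops requires allow_large=True"
            )
        for lp in self.loops:
            lp.validate()
        by_name = {lp.name: lp for lp in self.loops}
        for cp in self.couplings:
            cp.validate()
            for end in (cp.source, cp.target):
                if end not in by_name:
                    raise ConfigError(f"coupling endpoint {end!r} is not a loop")
            if by_name[cp.source].sensitivity <= 0:
                raise ConfigError(
                    f"coupling source {cp.source!r} needs sensitivity > 0 "
                    "(it normalises the coupling signal)"
                )

    def loop(self, name: str) -> LoopSpec:
        for lp in self.loops:
            if lp.name == name:
                return lp
        raise InputError(f"no loop named {name!r}")


@dataclass
class Trajectory:
    """Time-indexed concentrations and activity states, one series per loop."""

    time: np.ndarray
    concentration: dict[str, np.ndarray]
    activity: dict[str, np.ndarray]
    seed: int = 0

    @property
    def loops(self) -> list[str]:
        return list(self.concentration)


@dataclass
class OscillationSummary:
    """Amplitude / period / range statistics of one loop's post-burn-in series."""

    amplitude: float
    period: float       # NaN when no oscillation is detected
    frequency: float    # 0 when no oscillation is detected
    min: float
    max: float
    in_range: bool | None = None


def simulate(system: SystemSpec, steps: int, seed: int = 0) -> Trajectory:
    """Run the synchronous update rule for ``steps`` steps.

    Records the state *before* each update, so with never-inhibited unit
    rate and no decay the concentration series is exactly 0, 1, 2, ….
    Deterministic: identical systems give bit-identical trajectories.
    """
    if steps < 1:
        raise InputError("steps must be >= 1")
    system.validate()
    names = [lp.name for lp in system.loops]
    conc = {n: np.zeros(steps) for n in names}
    act = {n: np.zeros(steps, dtype=int) for n in names}
    state = {lp.name: float(lp.initial_concentration) for lp in system.loops}
    incoming: dict[str, list[CouplingSpec]] = {n: [] for n in names}
    for cp in system.couplings:
        incoming[cp.target].append(cp)
    by_name = {lp.name: lp for lp in system.loops}

    for t in range(steps):
        for n in names:
            conc[n][t] = state[n]
        new_state = {}
        for lp in system.loops:
            v_eff = lp.effector_rate
            s_eff = lp.sensitivity
            for cp in incoming[lp.name]:
                src = by_name[cp.source]
                factor = 1.0 + cp.gain * state[cp.source] / src.sensitivity
                if cp.mode == EFFECTOR:
                    v_eff *= factor
                else:
                    s_eff *= factor
            if v_eff < 0:
                raise ConfigError(
                    f"loop {lp.name!r}: coupling drove the effector rate negative"
                )
            back = t - lp.delay
            if back < 0:
                active = 1 if lp.initial_active else 0
            else:
                active = 0 if conc[lp.name][back] > s_eff else 1
            act[lp.name][t] = active
            c = state[lp.name]
            new_state[lp.name] = max(c + v_eff * active - lp.decay_rate * c, 0.0)
        state = new_state

    return Trajectory(
        time=np.arange(steps), concentration=conc, activity=act, seed=seed
    )


def measure_oscillation(
    trajectory: Trajectory, loop: str, burn_in: int = 100
) -> OscillationSummary:
    """Summarise one loop's oscillation over the post-burn-in window.

    The period is the mean interval between successive upward crossings of
    the window mean; windows with fewer than two crossings report an
    undefined period (NaN) and frequency 0.
    """
    if loop not in trajectory.concentration:
        raise InputError(f"no loop named {loop!r} in trajectory")
    series = trajectory.concentration[loop]
    if burn_in < 0 or burn_in >= len(series):
        raise InputError("burn_in leaves an empty analysis window")
    w = series[burn_in:]
    mn, mx = float(w.min()), float(w.max())
    mean = w.mean()
    up = np.nonzero((w[1:] > mean) & (w[:-1] <= mean))[0] + 1
    if len(up) >= 2:
        period = float(np.mean(np.diff(up)))
        freq = 1.0 / period
    else:
        period, freq = math.nan, 0.0
    return OscillationSummary(
        amplitude=(mx - mn) / 2.0, period=period, frequency=freq, min=mn, max=mx
    )


def check_range(summary: OscillationSummary, low: float, high: float) -> bool:
    """Flag whether the concentration stayed inside the normal range.

    Inclusive bounds; leaving the range is the model's notion of pathology.
    Sets ``summary.in_range`` and returns it.
    """
    if low > high:
        raise InputError("low must not exceed high")
    summary.in_range = bool(summary.min >= low and summary.max <= high)
    return summary.in_range


_DISTURBABLE = ("effector_rate", "sensitivity", "decay_rate")


def disturbance_experiment(
    system: SystemSpec,
    loop: str,
    parameter: str,
    factor: float,
    steps: int = 500,
    burn_in: int = 100,
) -> dict[str, tuple[OscillationSummary, OscillationSummary]]:
    """Scale one loop parameter and compare oscillations before and after.

    Returns ``{loop_name: (baseline_summary, disturbed_summary)}`` for every
    loop, so disturbance propagation through the couplings can be read off
    directly (e.g. a faster effector upstream raising the downstream
    frequency).
    """
    if parameter not in _DISTURBABLE:
        raise InputError(
            f"parameter must be one of {_DISTURBABLE}, got {parameter!r}"
        )
    if factor <= 0:
        raise InputError("factor must be positive")
    system.validate()
    system.loop(loop)  # raises if absent
    disturbed = copy.deepcopy(system)
    target = disturbed.loop(loop)
    setattr(target, parameter, getattr(target, parameter) * factor)
    target.validate()  # e.g. decay_rate pushed >= 1

    base_traj = simulate(system, steps)
    dist_traj = simulate(disturbed, steps)
    out = {}
    for lp in system.loops:
        out[lp.name] = (
            measure_oscillation(base_traj, lp.name, burn_in),
            measure_oscillation(dist_traj, lp.name, burn_in),
        )
    return out


def load_system(path: str) -> SystemSpec:
    """Read a SystemSpec from a YAML or JSON config mirroring the field names."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path!r}: {exc}") from exc
    if not isinstance(data, dict) or "loops" not in data:
        raise ConfigError("config must be a mapping with a 'loops' list")
    try:
        loops = [LoopSpec(**lp) for lp in data["loops"]]
        couplings = [CouplingSpec(**cp) for cp in data.get("couplings", [])]
    except TypeError as exc:
        raise ConfigError(f"bad config field: {exc}") from exc
    spec = SystemSpec(
        loops=loops, couplings=couplings,
        allow_large=bool(data.get("allow_large", False)),
    )
    spec.validate()
    return spec


def save_system(system: SystemSpec, path: str) -> None:
    """Write a SystemSpec as YAML (round-trips through :func:`load_system`)."""
    data = {
        "loops": [asdict(lp) for lp in system.loops],
        "couplings": [asdict(cp) for cp in system.couplings],
    }
    if system.allow_large:
        data["allow_large"] = True
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def trajectory_frame(trajectory: Trajectory):
    """Tidy (step, loop, concentration, active) table for CSV export."""
    import pandas as pd

    frames = []
    for name in trajectory.loops:
        frames.append(
            pd.DataFrame(
                {
                    "step": trajectory.time,
                    "loop": name,
                    "concentration": trajectory.concentration[name],
                    "active": trajectory.activity[name],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summary_dict(summary: OscillationSummary) -> dict:
    """JSON-safe dict form of a summary (NaN period serialised as None)."""
    d = asdict(summary)
    if isinstance(d["period"], float) and math.isnan(d["period"]):
        d["period"] = None
    return d
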