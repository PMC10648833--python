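"""Synthetic multi-cat world generator.

Produces procedurally rendered body-crop frames for a population of
individually distinguishable "cats", grouped into sessions (one litter-box
visit = one identity = an ordered burst of frames), with controllable
appearance drift over time and population churn (adoption / departure).

The appearance model is deliberately simple: each identity is an ellipse of
a characteristic coat color carrying a sinusoidal stripe pattern, on a
shared textured background, plus seeded pixel noise.  Two drift mechanisms
act with age: the body grows (logistic saturation of the body scale) and the
coat matures (the base color shifts partway toward its complement).  Ambient
lighting is modeled as a diagonal per-channel color-temperature filter.

Everything is a pure function of its explicit seed; there is no global
random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

SUPPORTED_KELVINS = (2700, 4100, 6500, 10000)

#: Fraction of the full coat-color shift reached at infinite age.
_COAT_MATURATION_CAP = 0.6
#: Adult body scale relative to the kitten scale (clipped to 0.95).
_ADULT_GROWTH_FACTOR = 1.6


@dataclass(frozen=True)
class AppearanceGenotype:
    """Stable per-identity appearance parameters.

    ``pattern_frequency`` is in stripes per image width; ``pattern_phase``
    in radians; ``body_scale`` is the kitten-age body height as a fraction
    of the frame height; ``growth_rate`` controls how fast the identity
    morphs (growth and coat maturation) per unit age.
    """

    identity_id: str
    base_color: tuple[float, float, float]
    pattern_frequency: float
    pattern_phase: float
    body_scale: float
    growth_rate: float

    def __post_init__(self) -> None:
        if not all(0.0 <= c <= 1.0 for c in self.base_color):
            raise ValueError("base_color components must lie in [0, 1]")
        if not 0.0 < self.body_scale <= 1.0:
            raise ValueError("body_scale must lie in (0, 1]")
        if self.pattern_frequency <= 0:
            raise ValueError("pattern_frequency must be positive")


@dataclass(frozen=True)
class DriftScenario:
    """A timed script of environmental and population change.

    ``env_events`` are (tick, kelvin) lighting switches; ``population_events``
    are (tick, "add" | "remove", identity_id) churn events.  Identities named
    by an "add" event are absent from the world until that tick.
    """

    duration: int
    morph_rate: float = 0.0
    env_events: tuple[tuple[int, int], ...] = ()
    population_events: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("duration must be >= 1 tick")
        if self.morph_rate < 0:
            raise ValueError("morph_rate must be nonnegative")
        for tick, kelvin in self.env_events:
            if not 0 <= tick <= self.duration:
                raise ValueError(f"env event tick {tick} outside [0, duration]")
            if kelvin not in SUPPORTED_KELVINS:
                raise ValueError(f"unsupported kelvin {kelvin}")
        for tick, kind, _ in self.population_events:
            if not 0 <= tick <= self.duration:
                raise ValueError(f"population event tick {tick} outside [0, duration]")
            if kind not in ("add", "remove"):
                raise ValueError(f"unknown population event kind {kind!r}")

    def kelvin_at(self, tick: int) -> int:
        """Lighting in effect at ``tick`` (most recent switch; 6500 K default)."""
        kelvin = 6500
        for ev_tick, ev_kelvin in sorted(self.env_events):
            if ev_tick <= tick:
                kelvin = ev_kelvin
        return kelvin


@dataclass
class SessionRecord:
    """One litter-box visit: an ordered frame burst with a single identity."""

    session_id: str
    identity_id: str
    frames: list[np.ndarray]
    tick: int

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a session must contain at least one frame")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames of a session must share dimensions")


class ScenarioError(ValueError):
    """Raised for inconsistent drift scenarios (e.g. removing an unknown id)."""


def generate_population(n_identities: int, seed: int) -> list[AppearanceGenotype]:
    """Draw ``n_identities`` appearance genotypes deterministically from ``seed``.

    Coat colors are sampled away from the extremes so that stripes and
    maturation stay visible; identity ids are ``cat_00``, ``cat_01``, ...
    """
    if n_identities < 1:
        raise ValueError("n_identities must be >= 1")
    rng = np.random.default_rng(seed)
    population = []
    for i in range(n_identities):
        color = tuple(rng.uniform(0.15, 0.95, size=3).round(6))
        population.append(
            AppearanceGenotype(
                identity_id=f"cat_{i:02d}",
                base_color=color,
                pattern_frequency=float(rng.uniform(2.0, 8.0)),
                pattern_phase=float(rng.uniform(0.0, 2.0 * math.pi)),
                body_scale=float(rng.uniform(0.35, 0.55)),
                growth_rate=float(rng.uniform(0.03, 0.08)),
            )
        )
    return population


def _coat_color(genotype: AppearanceGenotype, age: float) -> np.ndarray:
    """Coat color at ``age``: base color shifted partway toward its complement."""
    base = np.asarray(genotype.base_color, dtype=np.float64)
    adult = 1.0 - base
    m = _COAT_MATURATION_CAP * (1.0 - math.exp(-genotype.growth_rate * age))
    return base + m * (adult - base)


def _body_scale(genotype: AppearanceGenotype, age: float) -> float:
    """Body scale at ``age``: logistic-style saturation toward the adult size."""
    adult = min(0.95, genotype.body_scale * _ADULT_GROWTH_FACTOR)
    return adult - (adult - genotype.body_scale) * math.exp(-genotype.growth_rate * age)


def render_frame(
    genotype: AppearanceGenotype,
    age: float,
    noise_seed: int,
    size: tuple[int, int] = (32, 32),
    noise_sigma: float = 0.02,
) -> np.ndarray:
    """Render one H x W x 3 body-crop frame in [0, 1].

    The image is a deterministic function of (genotype, age) plus pixel
    noise drawn from ``noise_seed``.  Age drives growth (body scale) and
    coat maturation.
    """
    if age < 0:
        raise ValueError("age must be nonnegative")
    height, width = size
    if height < 16 or width < 16:
        raise ValueError("frame size must be at least 16 x 16")

    yy, xx = np.mgrid[0:height, 0:width]
    u = (xx + 0.5) / width
    v = (yy + 0.5) / height

    # Shared litter-box backdrop: mid gray with a faint diagonal weave.
    background = 0.40 + 0.05 * np.sin(2.0 * math.pi * (3.0 * u + 2.0 * v))
    img = np.repeat(background[:, :, None], 3, axis=2)

    scale = _body_scale(genotype, age)
    semi_b = 0.5 * scale          # vertical semi-axis, fraction of height
    semi_a = min(0.48, 0.65 * scale)  # horizontal, fraction of width
    inside = ((u - 0.5) / semi_a) ** 2 + ((v - 0.5) / semi_b) ** 2 <= 1.0

    stripes = 0.5 + 0.5 * np.sin(
        2.0 * math.pi * genotype.pattern_frequency * u + genotype.pattern_phase
    )
    coat = _coat_color(genotype, age)
    body = coat[None, None, :] * (0.65 + 0.35 * stripes[:, :, None])
    img = np.where(inside[:, :, None], body, img)

    noise = np.random.default_rng(noise_seed).normal(0.0, noise_sigma, img.shape)
    return np.clip(img + noise, 0.0, 1.0)


def _blackbody_rgb(kelvin: float) -> np.ndarray:
    """Approximate RGB (0-255 scale) of a blackbody radiator at ``kelvin``.

    Piecewise log/power fit to the Planckian locus, adequate for deriving
    relative channel gains of household lighting.
    """
    t = kelvin / 100.0
    if t <= 66:
        red = 255.0
        green = 99.4708025861 * math.log(t) - 161.1195681661
    else:
        red = 329.698727446 * (t - 60.0) ** -0.1332047592
        green = 288.1221695283 * (t - 60.0) ** -0.0755148492
    if t >= 66:
        blue = 255.0
    elif t <= 19:
        blue = 0.0
    else:
        blue = 138.5177312231 * math.log(t - 10.0) - 305.0447927307
    return np.clip([red, green, blue], 0.0, 255.0)


def color_filter_gains(kelvin: int) -> np.ndarray:
    """Per-channel gains for ``kelvin``, normalized so 6500 K is the identity."""
    if kelvin not in SUPPORTED_KELVINS:
        raise ValueError(f"unsupported kelvin {kelvin}; expected one of {SUPPORTED_KELVINS}")
    return _blackbody_rgb(kelvin) / _blackbody_rgb(6500)


def apply_color_filter(image: np.ndarray, kelvin: int) -> np.ndarray:
    """Apply a diagonal color-temperature filter; 6500 K is the identity map."""
    gains = color_filter_gains(kelvin)
    if kelvin == 6500:
        return image.copy()
    return np.clip(image * gains[None, None, :], 0.0, 1.0)


def generate_stream(
    population: Sequence[AppearanceGenotype],
    scenario: DriftScenario,
    frames_per_session: int = 5,
    sessions_per_tick: int = 2,
    seed: int = 0,
    size: tuple[int, int] = (32, 32),
    noise_sigma: float = 0.02,
) -> list[SessionRecord]:
    """Simulate the session stream described by ``scenario``.

    Identities named by an "add" event join the world at that tick; "remove"
    events retire them.  At each tick, session identities cycle through a
    seeded permutation of the alive set, so per-identity session counts stay
    near-uniform.  A frame at tick t is rendered at age ``t * morph_rate``
    under the lighting in force at t.
    """
    if frames_per_session < 1 or sessions_per_tick < 1:
        raise ValueError("frames_per_session and sessions_per_tick must be >= 1")
    genotypes = {g.identity_id: g for g in population}
    added_later = {ident for _, kind, ident in scenario.population_events if kind == "add"}
    for _, kind, ident in scenario.population_events:
        if ident not in genotypes:
            raise ScenarioError(f"population event references unknown identity {ident!r}")
    alive = [g.identity_id for g in population if g.identity_id not in added_later]
    if not alive:
        raise ScenarioError("population empty at tick 0")

    events_by_tick: dict[int, list[tuple[str, str]]] = {}
    for tick, kind, ident in scenario.population_events:
        events_by_tick.setdefault(tick, []).append((kind, ident))

    rng = np.random.default_rng(seed)
    sessions: list[SessionRecord] = []
    for tick in range(scenario.duration):
        for kind, ident in events_by_tick.get(tick, []):
            if kind == "add":
                if ident in alive:
                    raise ScenarioError(f"identity {ident!r} added twice")
                alive.append(ident)
            else:
                if ident not in alive:
                    raise ScenarioError(f"cannot remove unknown identity {ident!r}")
                alive.remove(ident)
        if not alive:
            continue
        kelvin = scenario.kelvin_at(tick)
        age = tick * scenario.morph_rate
        order = [alive[i] for i in rng.permutation(len(alive))]
        for s in range(sessions_per_tick):
            ident = order[s % len(order)]
            frames = []
            for _ in range(frames_per_session):
                noise_seed = int(rng.integers(0, 2**31 - 1))
                frame = render_frame(
                    genotypes[ident], age, noise_seed, size=size, noise_sigma=noise_sigma
                )
                frames.append(apply_color_filter(frame, kelvin))
            sessions.append(
                SessionRecord(
                    session_id=f"t{tick:03d}_s{s:02d}",
                    identity_id=ident,
                    frames=frames,
                    tick=tick,
                )
            )
    return sessions


def write_dataset(sessions: Sequence[SessionRecord], out_dir: str | Path,
                  kelvin_by_tick=None) -> Path:
    """Write sessions as PNG frames plus a manifest CSV; returns the manifest path.

    Layout: ``sessions/<session_id>/frame_<k>.png`` with a ``manifest.csv``
    holding session_id, tick, identity_id, kelvin, frame_count.
    """
    out_dir = Path(out_dir)
    rows = []
    for session in sessions:
        session_dir = out_dir / "sessions" / session.session_id
        session_dir.mkdir(parents=True, exist_ok=True)
        for k, frame in enumerate(session.frames):
            arr = (np.clip(frame, 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(arr).save(session_dir / f"frame_{k}.png")
        kelvin = kelvin_by_tick(session.tick) if kelvin_by_tick else 6500
        rows.append(
            {
                "session_id": session.session_id,
                "tick": session.tick,
                "identity_id": session.identity_id,
                "kelvin": kelvin,
                "frame_count": len(session.frames),
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(run_dir: str | Path) -> list[SessionRecord]:
    """Load sessions written by :func:`write_dataset`."""
    run_dir = Path(run_dir)
    manifest = pd.read_csv(run_dir / "manifest.csv")
    sessions = []
    for row in manifest.itertuples():
        session_dir = run_dir / "sessions" / row.session_id
        frames = []
        for k in range(int(row.frame_count)):
            with Image.open(session_dir / f"frame_{k}.png") as im:
                frames.append(np.asarray(im, dtype=np.float64) / 255.0)
        sessions.append(
            SessionRecord(
                session_id=str(row.session_id),
                identity_id=str(row.identity_id),
                frames=frames,
                tick=int(row.tick),
            )
        )
    return sessions
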