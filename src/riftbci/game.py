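"""Headless pong driven by the covert-attention decoder.

The world is the unit square (origin top-left, y downward).  A ball falls
from a random position in the top quarter toward a horizontal bar near the
bottom; every 100-ms tick the decoder's output moves the bar to the left or
right half of the screen.  If bar and ball share a side when the ball reaches
collision height the trial is a hit: the ball is deflected 90 degrees toward
the nearer side wall, bounces, and a new trial starts from the top.
Otherwise the ball falls through and is reset directly.  The first second
after every reset the ball moves at reduced speed (an orientation period).
Trials with a blink in the last second before the collision are flagged
invalid and excluded from accuracy, though they still appear in the score.

Geometry and speeds are configuration, chosen so a trial lasts ~3-4 s and a
5-minute game yields on the order of 80 trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .decode import TrainedDecoder, classify, extract_features
from .streaming import RingBuffer, flag_trial


@dataclass(frozen=True)
class GameConfig:
    fall_speed: float = 0.30  # screen units / s, downward
    slow_factor: float = 0.5  # speed multiplier during slow start
    slow_start_s: float = 1.0
    collision_y: float = 0.90
    bar_y: float = 0.92
    drift_speed_range: tuple = (0.04, 0.10)  # |horizontal velocity| range
    reflect_speed: float = 0.50  # horizontal speed after a hit
    wall_bounce_ticks: int = 3
    dt: float = 0.1  # one tick, seconds


@dataclass
class GameState:
    x: float = 0.5
    y: float = 0.1
    vx: float = 0.0
    vy: float = 0.0
    phase: str = "slow_start"  # slow_start | falling | reflected_up | wall_bounce
    bar_side: str = "left"
    tick: int = 0
    hits: int = 0
    misses: int = 0
    trial_id: int = 0
    resets: int = 0
    trial_start_tick: int = 0
    _bounce_left: int = 0

    @property
    def ball_side(self) -> str:
        return "left" if self.x < 0.5 else "right"


@dataclass
class TrialRecord:
    trial_id: int
    ball_side: str
    bar_side: str
    outcome: str  # hit | miss
    valid: bool
    reason: str
    collision_tick: int
    scores: list = field(default_factory=list)


@dataclass
class GameResult:
    trials: list
    hits: int
    misses: int
    duration_s: float
    partial: bool = False
    resets: int = 0

    @property
    def n_valid(self) -> int:
        return sum(1 for t in self.trials if t.valid)

    @property
    def accuracy(self):
        """Hit rate over blink-valid trials; None when no trial is valid."""
        valid = [t for t in self.trials if t.valid]
        if not valid:
            return None
        return sum(1 for t in valid if t.outcome == "hit") / len(valid)

    def to_csv(self, path) -> None:
        rows = [
            {
                "trial_id": t.trial_id,
                "ball_side": t.ball_side,
                "bar_side": t.bar_side,
                "outcome": t.outcome,
                "valid": t.valid,
                "collision_tick": t.collision_tick,
            }
            for t in self.trials
        ]
        pd.DataFrame(
            rows,
            columns=[
                "trial_id",
                "ball_side",
                "bar_side",
                "outcome",
                "valid",
                "collision_tick",
            ],
        ).to_csv(path, index=False)

    def summary(self, seed=None) -> dict:
        return {
            "hits": self.hits,
            "misses": self.misses,
            "n_trials": len(self.trials),
            "n_valid": self.n_valid,
            "accuracy": self.accuracy,
            "duration_s": self.duration_s,
            "partial": self.partial,
            "seed": seed,
        }

    def summary_json(self, path, seed=None) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(seed), fh, indent=1)


def reset_ball(state: GameState, rng: np.random.Generator, config: GameConfig | None = None) -> GameState:
    """Place the ball at a random position in the top quarter, slow start."""
    if config is None:
        config = GameConfig()
    state.x = float(rng.uniform(0.0, 1.0))
    state.y = float(rng.uniform(0.0, 0.25))
    lo, hi = config.drift_speed_range
    state.vx = float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
    state.vy = config.fall_speed
    state.phase = "slow_start"
    state.resets += 1
    state.trial_start_tick = state.tick
    state._bounce_left = 0
    return state


def step(
    state: GameState,
    decoded_side: str | None,
    config: GameConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Advance the world by one 100-ms tick.

    Returns ``(state, collision)`` where ``collision`` is None or a dict with
    the outcome of a trial completed at this tick.  A miss resets the ball
    immediately; a hit first plays the 90-degree reflection toward the nearer
    wall and the wall bounce, then resets.
    """
    if config is None:
        config = GameConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    if decoded_side is not None:
        state.bar_side = decoded_side
    dt = config.dt
    collision = None

    if state.phase in ("slow_start", "falling"):
        if (
            state.phase == "slow_start"
            and (state.tick - state.trial_start_tick) * dt >= config.slow_start_s
        ):
            state.phase = "falling"
        speed = config.slow_factor if state.phase == "slow_start" else 1.0
        state.x += state.vx * speed * dt
        state.y += state.vy * speed * dt
        if state.x <= 0.0:
            state.x = -state.x
            state.vx = abs(state.vx)
        elif state.x >= 1.0:
            state.x = 2.0 - state.x
            state.vx = -abs(state.vx)
        if state.y >= config.collision_y:
            state.y = config.collision_y
            ball_side = state.ball_side
            hit = ball_side == state.bar_side
            collision = {
                "trial_id": state.trial_id,
                "ball_side": ball_side,
                "bar_side": state.bar_side,
                "outcome": "hit" if hit else "miss",
                "tick": state.tick,
            }
            state.trial_id += 1
            if hit:
                state.hits += 1
                state.phase = "reflected_up"
                state.vx = config.reflect_speed * (1.0 if state.x >= 0.5 else -1.0)
                state.vy = 0.0
            else:
                state.misses += 1
                reset_ball(state, rng, config)
    elif state.phase == "reflected_up":
        state.x += state.vx * dt
        if state.x <= 0.0 or state.x >= 1.0:
            state.x = float(np.clip(state.x, 0.0, 1.0))
            state.phase = "wall_bounce"
            state._bounce_left = config.wall_bounce_ticks
    elif state.phase == "wall_bounce":
        state._bounce_left -= 1
        if state._bounce_left <= 0:
            reset_ball(state, rng, config)

    state.tick += 1
    return state, collision


def run_game(
    decoder,
    stream,
    config: GameConfig | None = None,
    seed: int = 0,
    srate: float = 1000.0,
    expected_duration_s: float | None = None,
    follow_ball: bool = True,
) -> GameResult:
    """Run the closed loop: stream blocks -> ring buffer -> decoder -> pong.

    ``decoder`` is a :class:`~riftbci.decode.TrainedDecoder`, or any callable
    ``f(window) -> (side, score)`` (useful for scripted or chance baselines).
    ``stream`` yields 100-ms Recording blocks; with ``follow_ball=True``
    (default) and a :class:`~riftbci.synthmeg.GameStream`, the simulated
    participant's attention policy is wired to the live ball side ("attend
    the side the ball is on"); pass ``follow_ball=False`` to keep a scripted
    policy installed on the stream.

    The first classification happens only once 1 s of data has accumulated;
    until then the bar holds its initial (left) position.
    """
    if config is None:
        config = GameConfig()
    rng = np.random.default_rng(seed)
    state = GameState()
    reset_ball(state, rng, config)
    state.resets = 1  # the initial placement

    block_n = None
    buf = None
    gaze_history: list = []
    trials: list = []
    scores_this_trial: list = []
    n_ticks = 0

    if follow_ball and hasattr(stream, "policy"):
        stream.policy = lambda tick: state.ball_side

    for block in stream:
        meg = block.meg()
        if buf is None:
            block_n = meg.shape[1]
            buf = RingBuffer(meg.shape[0], capacity=int(srate), block_size=block_n)
        buf.push_block(meg)
        gaze_history.append(block.gaze_x())
        if len(gaze_history) > buf.capacity // block_n:
            gaze_history.pop(0)

        side = None
        if buf.is_full:
            window = buf.current_window()
            if callable(decoder):
                side, score = decoder(window)
            else:
                fv = extract_features(window, srate)
                side, score = classify(decoder, fv)
            scores_this_trial.append(score)

        state_, collision = step(state, side, config, rng)
        if collision is not None:
            gaze_last_s = np.concatenate(gaze_history)
            flag = flag_trial(
                collision["trial_id"], gaze_last_s, "game_pre_collision", srate
            )
            trials.append(
                TrialRecord(
                    trial_id=collision["trial_id"],
                    ball_side=collision["ball_side"],
                    bar_side=collision["bar_side"],
                    outcome=collision["outcome"],
                    valid=flag.valid,
                    reason=flag.reason,
                    collision_tick=collision["tick"],
                    scores=scores_this_trial,
                )
            )
            scores_this_trial = []
        n_ticks += 1

    duration_s = n_ticks * config.dt
    partial = (
        expected_duration_s is not None and duration_s < expected_duration_s - 1e-9
    )
    return GameResult(
        trials=trials,
        hits=state.hits,
        misses=state.misses,
        duration_s=duration_s,
        partial=partial,
        resets=state.resets,
    )
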