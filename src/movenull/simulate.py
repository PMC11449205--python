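"""Agent-based simulator of biased-correlated random walks (BCRW).

Agents move in discrete steps on an unbounded plane.  Each step direction
is drawn from a Von Mises distribution centred on the bearing from the
agent's current position to its *bias target*; step lengths are gamma
distributed.  The bias target is the agent's home-range centre, or — for
sociable agents with a perceived neighbour in range — a weighted average
of the home-range centre and the nearest conspecific's position.  The
home-range centre itself performs one BCRW step per day, whose magnitude
and directional persistence define three scenarios: static, locally
changing, and directionally changing home ranges.

Randomness is organized as one seeded stream per agent, spawned
deterministically from the run seed, so simulations are bit-reproducible
regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import SimConfig
from .datasets import TrackingDataset

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angle(s) to [-pi, pi)."""
    return np.mod(np.asarray(theta) + np.pi, TWO_PI) - np.pi


def gamma_params_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (shape, scale) of a gamma with the given mean and sd.

    shape = (mean/sd)^2, scale = sd^2/mean.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma mean and sd must be positive")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def sample_direction(mu: float, kappa: float, rng: np.random.Generator,
                     size=None):
    """Draw direction(s) from Von Mises(mu, kappa), wrapped to [-pi, pi).

    kappa = 0 yields the uniform distribution on the circle.
    """
    if kappa < 0:
        raise ValueError("Von Mises concentration kappa must be >= 0")
    if kappa == 0:
        draws = rng.uniform(-np.pi, np.pi, size=size)
    else:
        draws = rng.vonmises(mu, kappa, size=size)
    return wrap_angle(draws)


def step_length_sampler(cfg: SimConfig, rng: np.random.Generator, size=None):
    """Draw agent step length(s) from the configured gamma distribution."""
    shape, scale = gamma_params_from_mean_sd(cfg.step_mean, cfg.step_sd)
    return rng.gamma(shape, scale, size=size)


@dataclass
class AgentState:
    """Instantaneous state of one agent: position, heading, and the state
    of its home-range bias point."""

    position: tuple[float, float]
    heading: float
    hr_centre: tuple[float, float]
    hr_heading: float

    def __post_init__(self):
        self.heading = float(wrap_angle(self.heading))
        self.hr_heading = float(wrap_angle(self.hr_heading))


def choose_bias_target(state: AgentState, neighbour_positions, cfg: SimConfig):
    """Bias target of one agent for one step.

    Non-sociable agents (or agents with no conspecific within the
    perception distance) target their home-range centre.  Sociable agents
    target ``w * p_nn + (1 - w) * hr_centre`` where ``p_nn`` is the nearest
    in-range neighbour position and ``w`` the social weight.  Distance ties
    go to the neighbour listed first (lowest individual id).
    """
    hr = np.asarray(state.hr_centre, dtype=float)
    if not cfg.social or len(neighbour_positions) == 0:
        return tuple(hr)
    pos = np.asarray(state.position, dtype=float)
    pts = np.asarray(neighbour_positions, dtype=float)
    d = np.hypot(pts[:, 0] - pos[0], pts[:, 1] - pos[1])
    i = int(np.argmin(d))  # argmin takes the first minimum: lowest id
    if d[i] > cfg.perception_distance:
        return tuple(hr)
    w = cfg.social_weight
    return tuple(w * pts[i] + (1.0 - w) * hr)


def advance_home_range(state: AgentState, cfg: SimConfig,
                       rng: np.random.Generator) -> AgentState:
    """One daily BCRW step of the home-range bias point.

    Step length ~ gamma(mean = step_mean * hr_step_mean_factor,
    sd = hr_step_sd_factor * that mean).  Direction is uniform for the
    static and locally changing scenarios, and Von Mises around the
    current home-range heading (which is then updated to the realized
    direction) for the directionally changing scenario.
    """
    shape, scale = gamma_params_from_mean_sd(cfg.hr_step_mean, cfg.hr_step_sd)
    length = rng.gamma(shape, scale)
    if cfg.hr_scenario == "directional":
        direction = float(sample_direction(state.hr_heading,
                                           cfg.kappa_hr_directional, rng))
        new_heading = direction
    else:
        direction = float(sample_direction(0.0, 0.0, rng))
        new_heading = state.hr_heading
    cx, cy = state.hr_centre
    new_centre = (cx + length * np.cos(direction),
                  cy + length * np.sin(direction))
    return replace(state, hr_centre=new_centre, hr_heading=new_heading)


# -- vectorized internals ---------------------------------------------------

def _bias_targets(pos: np.ndarray, hr: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Per-agent bias targets given all current positions (row i = agent i)."""
    if not cfg.social or cfg.social_weight == 0.0 or len(pos) < 2:
        return hr
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)  # first minimum -> lowest id on ties
    nnd = d[np.arange(len(pos)), nn]
    in_range = nnd <= cfg.perception_distance
    target = hr.copy()
    w = cfg.social_weight
    target[in_range] = w * pos[nn[in_range]] + (1.0 - w) * hr[in_range]
    return target


def _agent_draws(cfg: SimConfig):
    """Pre-draw all randomness, one independent substream per agent.

    Returns initial home-range centres and headings, daily home-range
    displacement vectors, per-step Von Mises direction noise (mean 0) and
    per-step gamma lengths, each with the agent as the leading axis.
    """
    n, D, S = cfg.n_agents, cfg.n_days, cfg.steps_per_day
    children = np.random.SeedSequence(cfg.seed).spawn(n)
    shape_hr, scale_hr = gamma_params_from_mean_sd(cfg.hr_step_mean, cfg.hr_step_sd)
    shape_s, scale_s = gamma_params_from_mean_sd(cfg.step_mean, cfg.step_sd)

    hr0 = np.empty((n, 2))
    heading0 = np.empty(n)
    hr_dx = np.empty((n, D))
    hr_dy = np.empty((n, D))
    noise = np.empty((n, D * S))
    lengths = np.empty((n, D * S))
    for i, ss in enumerate(children):
        g = np.random.Generator(np.random.PCG64(ss))
        hr0[i] = g.uniform(0.0, cfg.start_square_side, size=2)
        heading0[i] = g.uniform(-np.pi, np.pi)
        hr_heading0 = g.uniform(-np.pi, np.pi)
        hr_len = g.gamma(shape_hr, scale_hr, size=D)
        if cfg.hr_scenario == "directional":
            vm = g.vonmises(0.0, cfg.kappa_hr_directional, size=D)
            hr_dir = wrap_angle(hr_heading0 + np.cumsum(vm))
        else:
            hr_dir = g.uniform(-np.pi, np.pi, size=D)
        hr_dx[i] = hr_len * np.cos(hr_dir)
        hr_dy[i] = hr_len * np.sin(hr_dir)
        noise[i] = sample_direction(0.0, cfg.kappa_step, g, size=D * S)
        lengths[i] = g.gamma(shape_s, scale_s, size=D * S)
    return hr0, heading0, hr_dx, hr_dy, noise, lengths


def simulate(cfg: SimConfig) -> TrackingDataset:
    """Run the BCRW population simulation.

    Each day the home-range bias points advance once, then every agent
    takes ``steps_per_day`` steps; a fix is recorded after every step.
    The output has exactly ``n_agents * n_days * steps_per_day`` fixes
    and is bit-identical across runs with the same configuration.
    """
    n, D, S = cfg.n_agents, cfg.n_days, cfg.steps_per_day
    hr, heading, hr_dx, hr_dy, noise, lengths = _agent_draws(cfg)
    hr = hr.copy()
    pos = hr.copy()  # agents start at their home-range centre
    blend = cfg.heading_blend

    out_x = np.empty((D * S, n))
    out_y = np.empty((D * S, n))
    t = 0
    for d in range(D):
        hr[:, 0] += hr_dx[:, d]
        hr[:, 1] += hr_dy[:, d]
        for _ in range(S):
            target = _bias_targets(pos, hr, cfg)
            bearing = np.arctan2(target[:, 1] - pos[:, 1],
                                 target[:, 0] - pos[:, 0])
            if blend > 0.0:
                mu = np.arctan2(
                    blend * np.sin(heading) + (1 - blend) * np.sin(bearing),
                    blend * np.cos(heading) + (1 - blend) * np.cos(bearing),
                )
            else:
                mu = bearing
            theta = wrap_angle(mu + noise[:, t])
            pos = pos + lengths[:, t, None] * np.column_stack(
                (np.cos(theta), np.sin(theta)))
            out_x[t] = pos[:, 0]
            out_y[t] = pos[:, 1]
            heading = theta
            t += 1

    days = np.repeat(np.arange(1, D + 1), S)
    steps = np.tile(np.arange(1, S + 1), D)
    fixes = pd.DataFrame({
        "id": np.tile(np.arange(n), D * S),
        "day": np.repeat(days, n),
        "step": np.repeat(steps, n),
        "x": out_x.ravel(),
        "y": out_y.ravel(),
    })
    meta = {"time_unit": "day-step", "config": cfg.to_dict()}
    return TrackingDataset(fixes, metadata=meta)
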