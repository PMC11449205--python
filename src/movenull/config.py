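"""Simulation configuration.

All parameters of the biased-correlated random walk (BCRW) population
simulator live here, with defaults matching the validation study the
package reproduces: 30 agents tracked for 50 days at 50 steps per day,
gamma step lengths with mean 7 and standard deviation 5 (arbitrary length
units), a social perception distance of 1000 units, and home-range bias
points that are static, locally drifting, or directionally drifting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

HR_SCENARIOS = ("static", "local", "directional")

# Daily home-range drift is expressed as a multiple of the agent step mean:
# essentially zero for static home ranges, large for changing ones.
HR_STEP_MEAN_FACTORS = {"static": 0.01, "local": 10.0, "directional": 10.0}


@dataclass
class SimConfig:
    """Parameters of the BCRW population simulator.

    Attributes
    ----------
    n_agents, n_days, steps_per_day
        Population size and tracking duration (all >= 1).
    step_mean, step_sd
        Mean and standard deviation of the gamma step-length distribution,
        in length units.
    kappa_step
        Von Mises concentration of step directions around the bearing to
        the bias target.  The study only asks for a "semi-linear" path;
        4.0 gives visibly correlated but noisy tracks.
    heading_blend
        Optional circular mixing weight of the previous heading into the
        step-direction mean (0 = pure bias toward the target, the default).
    social
        Whether agents are attracted to conspecifics.
    social_weight
        Mixing fraction w in [0, 1] pulling the bias target toward the
        nearest perceived neighbour (w=1: pure social attraction).
    perception_distance
        Radius within which conspecifics are perceived, length units.
    hr_scenario
        'static', 'local' (tortuous daily home-range drift) or
        'directional' (persistent daily drift).
    hr_step_mean_factor
        Daily home-range step mean as a multiple of ``step_mean``.  If
        None, resolved from the scenario (0.01 static, 10 changing).
    hr_step_sd_factor
        Home-range step sd as a fraction of the home-range step mean (0.75).
    kappa_hr_directional
        Von Mises concentration of directional home-range headings
        ("heavily concentrated"; 20.0 by default).
    start_square_side
        Side of the square from which initial home-range centres are drawn;
        defaults to two-thirds of ``perception_distance`` so that all
        agents can perceive each other initially.
    seed
        Integer seed; identical seeds give bit-identical simulations.
    """

    n_agents: int = 30
    n_days: int = 50
    steps_per_day: int = 50
    step_mean: float = 7.0
    step_sd: float = 5.0
    kappa_step: float = 4.0
    heading_blend: float = 0.0
    social: bool = False
    social_weight: float = 0.75
    perception_distance: float = 1000.0
    hr_scenario: str = "static"
    hr_step_mean_factor: float | None = None
    hr_step_sd_factor: float = 0.75
    kappa_hr_directional: float = 20.0
    start_square_side: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("n_agents", "n_days", "steps_per_day"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if self.step_mean <= 0 or self.step_sd <= 0:
            raise ValueError("step_mean and step_sd must be positive")
        if not 0.0 <= self.social_weight <= 1.0:
            raise ValueError("social_weight must lie in [0, 1]")
        if not 0.0 <= self.heading_blend <= 1.0:
            raise ValueError("heading_blend must lie in [0, 1]")
        if self.perception_distance <= 0:
            raise ValueError("perception_distance must be positive")
        if self.hr_scenario not in HR_SCENARIOS:
            raise ValueError(
                f"hr_scenario must be one of {HR_SCENARIOS}, got {self.hr_scenario!r}"
            )
        if self.kappa_step < 0 or self.kappa_hr_directional < 0:
            raise ValueError("Von Mises concentrations must be >= 0")
        if self.hr_step_mean_factor is None:
            self.hr_step_mean_factor = HR_STEP_MEAN_FACTORS[self.hr_scenario]
        if self.hr_step_mean_factor <= 0:
            raise ValueError("hr_step_mean_factor must be positive")
        if self.hr_step_sd_factor <= 0:
            raise ValueError("hr_step_sd_factor must be positive")
        if self.start_square_side is None:
            self.start_square_side = 2.0 / 3.0 * self.perception_distance
        if self.start_square_side <= 0:
            raise ValueError("start_square_side must be positive")

    # Derived home-range step-length moments (length units).
    @property
    def hr_step_mean(self) -> float:
        return self.step_mean * self.hr_step_mean_factor

    @property
    def hr_step_sd(self) -> float:
        return self.hr_step_sd_factor * self.hr_step_mean

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def replace(self, **changes) -> "SimConfig":
        d = self.to_dict()
        d.update(changes)
        return SimConfig(**d)
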