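"""Study designs and ground-truth parameter containers for simulation.

The default designs mirror a pooled five-study experience-sampling (ESM)
collection in adolescents: every study scheduled either 10 assessments per
day for 7 days or 5 per day for 14 days (70 scheduled "beeps" per person in
both cases), with study-specific item counts for positive emotions (PA),
negative emotions (NA) and negative-emotion-regulation strategies (ER), and
an average compliance of about 74% of scheduled assessments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["StudyDesign", "SyntheticTruth", "default_designs"]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling scheme and instrument layout of one ESM dataset."""

    dataset_id: str
    n_persons: int
    beeps_per_day: int
    n_days: int
    n_pa_items: int
    n_na_items: int
    n_er_items: int
    item_scale_min: float = 0.0
    item_scale_max: float = 10.0
    missing_rate: float = 0.26
    age_mean: float = 17.4
    age_sd: float = 1.0
    prop_female: float = 0.59

    def __post_init__(self):
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if self.beeps_per_day <= 0 or self.n_days <= 0:
            raise ValueError("beeps_per_day and n_days must be positive")
        if self.item_scale_min >= self.item_scale_max:
            raise ValueError(
                f"item scale min ({self.item_scale_min}) must be below "
                f"max ({self.item_scale_max})"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.n_pa_items, self.n_na_items) < 2:
            raise ValueError("need >= 2 items per emotion valence")
        if self.n_er_items < 2:
            raise ValueError("need >= 2 regulation-strategy items")

    @property
    def n_obs(self) -> int:
        """Scheduled assessments per person."""
        return self.beeps_per_day * self.n_days

    def to_dict(self) -> dict:
        return asdict(self)


def default_designs() -> list[StudyDesign]:
    """The five pooled ESM study designs (778 persons before exclusions).

    Item counts, sample sizes, schedules, ages and sex ratios follow the
    per-study values of the pooled collection; native rating scales differ
    by study (sliders vs. Likert) and are rescaled to 0-10 downstream.
    """
    return [
        StudyDesign("ds1", 83, 10, 7, 4, 5, 5,
                    item_scale_min=1, item_scale_max=7,
                    age_mean=16.4, age_sd=0.7, prop_female=0.57),
        StudyDesign("ds2", 97, 10, 7, 2, 4, 6,
                    item_scale_min=0, item_scale_max=100,
                    age_mean=19.1, age_sd=1.3, prop_female=0.63),
        StudyDesign("ds3", 202, 10, 7, 3, 6, 6,
                    item_scale_min=0, item_scale_max=100,
                    age_mean=18.3, age_sd=1.0, prop_female=0.55),
        StudyDesign("ds4", 178, 5, 14, 7, 6, 7,
                    item_scale_min=1, item_scale_max=7,
                    age_mean=20.9, age_sd=1.7, prop_female=0.78),
        StudyDesign("ds5", 218, 5, 14, 3, 6, 8,
                    item_scale_min=0, item_scale_max=10,
                    age_mean=13.5, age_sd=0.6, prop_female=0.48),
    ]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of the index-level generator.

    The generator simulates, per person i, random cross-lag paths::

        (a_i, b_i) ~ BVN((a_true, b_true), sd_a, sd_b, rho_ab)

    an exogenous stationary AR(1) differentiation series D_t (unit marginal
    variance, coefficient ``phi``), and

        M_t = im_i + a_i * D_{t-1} + eps_M      (regulation variability)
        Y_t = iy_i + b_i * M_t + cprime_true * D_{t-1} + eps_Y   (intensity)

    ``sd_im``/``sd_iy`` are person-intercept SDs (trait-level differences in
    the mediator and outcome).  ``a_mod`` optionally makes a_i depend
    linearly on a standard-normal person covariate (for co-moderation
    studies).  The within-person indirect effect is

        indirect_true = a_true * b_true + rho_ab * sd_a * sd_b
    """

    a_true: float = -0.3
    b_true: float = 0.4
    cprime_true: float = 0.1
    sd_a: float = 0.15
    sd_b: float = 0.15
    rho_ab: float = 0.0
    phi: float = 0.4
    sigma_m: float = 1.0
    sigma_y: float = 1.0
    sd_im: float = 0.5
    sd_iy: float = 0.5
    a_mod: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not -1 <= self.rho_ab <= 1:
            raise ValueError("|rho_ab| must be <= 1")
        if not -1 < self.phi < 1:
            raise ValueError("phi must lie in (-1, 1)")
        if min(self.sigma_m, self.sigma_y) < 0 or min(self.sd_a, self.sd_b) < 0:
            raise ValueError("SDs must be nonnegative")

    @property
    def indirect_true(self) -> float:
        """True within-person indirect effect (path product + path covariance)."""
        return self.a_true * self.b_true + self.rho_ab * self.sd_a * self.sd_b

    def to_dict(self) -> dict:
        d = asdict(self)
        d["indirect_true"] = self.indirect_true
        return d
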