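"""Synthetic study-like cohorts with known ground truth.

The generator emulates the design of the motivating study: each pig
receives three applications (single 50 J, single 100 J, serial 4 x 50 J)
at separate pancreatic sites.  Ground truth is a per-pig necrosis
threshold: a shared animal-level random effect plus a per-group mean, so
the three conditions are genuinely within-subject (which is what makes
the repeated-measures analysis meaningful).

Generative model (defaults in :class:`SyntheticCohortConfig`):

* tissue thickness per *site*: discrete uniform integer mm over the
  published range;
* per-pulse peak currents: normal per group (published means/SDs),
  truncated positive;
* per-pulse peak voltages: current x a contact-resistance draw;
* per-pig threshold for group g: ``theta_ig = mean_g + u_i`` with
  ``u_i ~ N(0, sd_between)``, truncated positive.  The published group
  SDs mix animal physiology with measurement scatter, which cannot be
  separated from summary data; the default splits the published variance
  evenly, ``sd_between = mean(published SDs)/sqrt(2)``;
* success iff the delivered centre density reaches ``theta_ig``; the true
  necrotic half-width is the profile inversion ``max{x : J(x) I >=
  theta}`` (0 for failures); per-section half-widths add clipped Gaussian
  histology noise;
* the transition zone extends to where the delivered density falls to a
  fixed fraction (default 0.75) of the necrosis threshold.

All randomness flows from one seed, and the draw order is independent of
the threshold parameters, so raising a threshold with the seed fixed can
only turn successes into failures (tested).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError
from .field_model import MidplaneModel
from .records_io import (
    AblationSite,
    EXPECTED_PULSES,
    GROUP_ORDER,
    Group,
    HistologySection,
)
from .study import (
    GROUP_PEAK_CURRENT_A,
    N_PIGS,
    PADDLE_RADIUS_MM,
    PUBLISHED_THRESHOLDS_A_PER_CM2,
    THICKNESS_RANGE_MM,
)
from .thresholds import Estimator, SuccessFilter, group_thresholds

__all__ = ["SyntheticCohortConfig", "generate_cohort", "end_to_end_recovery", "truth_frame"]

_FLOOR = 1e-3  # positivity floor for truncated draws


def _default_current_params() -> dict[Group, tuple[float, float]]:
    return dict(GROUP_PEAK_CURRENT_A)


def _default_threshold_means() -> dict[Group, float]:
    return {g: m for g, (m, _) in PUBLISHED_THRESHOLDS_A_PER_CM2.items()}


def _default_between_pig_sd() -> float:
    sds = [sd for _, sd in PUBLISHED_THRESHOLDS_A_PER_CM2.values()]
    return float(np.mean(sds) / math.sqrt(2.0))


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Distributions and seed for generating study-like cohorts."""

    n_pigs: int = N_PIGS
    paddle_radius: float = PADDLE_RADIUS_MM
    thickness_range_mm: tuple[int, int] = THICKNESS_RANGE_MM
    group_current_params: dict[Group, tuple[float, float]] = field(
        default_factory=_default_current_params
    )
    true_threshold_mean: dict[Group, float] = field(default_factory=_default_threshold_means)
    true_threshold_sd_between_pigs: float = field(default_factory=_default_between_pig_sd)
    histology_noise_sd: float = 0.5  # mm on boundary half-widths
    transition_fraction: float = 0.75  # transition zone ends where J falls to this x theta
    contact_resistance_ohm: tuple[float, float] = (30.0, 5.0)  # (mean, sd)
    arcing_probability_100j: float = 1.0 / 6.0  # 2 of 12 single-100J applications arced
    sections_per_site: tuple[int, int] = (2, 4)  # inclusive range, mean ~3
    seed: int = 0

    def __post_init__(self):
        if self.n_pigs < 1:
            raise InputError("n_pigs must be >= 1")
        if self.paddle_radius <= 0:
            raise InputError("paddle_radius must be > 0")
        lo, hi = self.thickness_range_mm
        if not (1 <= lo <= hi <= 30):
            raise InputError("thickness bounds must lie within the 1-30 mm sanity window")
        for g in GROUP_ORDER:
            mean, sd = self.group_current_params[g]
            if mean <= 0 or sd < 0:
                raise InputError(f"group {g.value}: current mean must be > 0 and sd >= 0")
            if self.true_threshold_mean[g] <= 0:
                raise InputError(f"group {g.value}: true threshold mean must be > 0")
        if self.true_threshold_sd_between_pigs < 0:
            raise InputError("between-pig threshold sd must be >= 0")
        if self.histology_noise_sd < 0:
            raise InputError("histology noise sd must be >= 0")
        if not (0 < self.transition_fraction <= 1):
            raise InputError("transition_fraction must be in (0, 1]")
        lo, hi = self.sections_per_site
        if not (1 <= lo <= hi):
            raise InputError("sections_per_site must be an increasing range of counts >= 1")


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[AblationSite], dict[tuple[str, Group], float]]:
    """Generate one cohort; returns the sites and the per-(pig, group)
    true thresholds (A/cm^2).  Fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    model = MidplaneModel(paddle_radius=config.paddle_radius)
    lo, hi = config.thickness_range_mm
    s_lo, s_hi = config.sections_per_site

    sites: list[AblationSite] = []
    truth: dict[tuple[str, Group], float] = {}
    for p in range(config.n_pigs):
        pig_id = f"pig{p + 1:02d}"
        # one animal-level effect shared by the three conditions; drawn
        # before any site-level randomness so the draw order is fixed
        u = rng.normal(0.0, config.true_threshold_sd_between_pigs)
        for group in GROUP_ORDER:
            n_pulses = EXPECTED_PULSES[group]
            thickness = float(rng.integers(lo, hi + 1))
            i_mean, i_sd = config.group_current_params[group]
            currents = np.maximum(rng.normal(i_mean, i_sd, size=n_pulses), _FLOOR)
            resistances = np.maximum(
                rng.normal(*config.contact_resistance_ohm, size=n_pulses), _FLOOR
            )
            voltages = currents * resistances
            arcing = bool(
                group == Group.SINGLE_100J and rng.random() < config.arcing_probability_100j
            )
            n_sections = int(rng.integers(s_lo, s_hi + 1))
            noise = rng.normal(0.0, config.histology_noise_sd, size=(n_sections, 2))

            theta = max(config.true_threshold_mean[group] + u, _FLOOR)
            truth[(pig_id, group)] = theta

            current = float(currents.mean())
            delivered_center = model.delivered(thickness, 0.0, current)
            success = delivered_center >= theta
            hw_necrotic = model.lesion_halfwidth(thickness, current, theta)
            hw_transition = model.lesion_halfwidth(
                thickness, current, config.transition_fraction * theta
            )

            sections = []
            for k in range(n_sections):
                nec = max(hw_necrotic + noise[k, 0], 0.0)
                tra = max(hw_transition + noise[k, 1], nec)
                sections.append(
                    HistologySection(
                        necrotic_halfwidth=nec,
                        transition_halfwidth=tra,
                        # narrow dose margins leave vital islands amid necrosis
                        contains_vital_inside=bool(
                            success and delivered_center < 1.25 * theta
                        ),
                        spans_between_paddles=success,
                    )
                )
            sites.append(
                AblationSite(
                    pig_id=pig_id,
                    group=group,
                    thickness=thickness,
                    peak_voltages=tuple(float(v) for v in voltages),
                    peak_currents=tuple(float(c) for c in currents),
                    arcing=arcing,
                    sections=tuple(sections),
                )
            )
    return sites, truth


def truth_frame(truth: dict[tuple[str, Group], float]) -> pd.DataFrame:
    """Tidy frame of the true thresholds (one row per pig x group)."""
    rows = [
        {"pig_id": pig, "group": group.value, "true_threshold_a_per_cm2": theta}
        for (pig, group), theta in sorted(truth.items(), key=lambda kv: (kv[0][0], kv[0][1].value))
    ]
    return pd.DataFrame(rows, columns=["pig_id", "group", "true_threshold_a_per_cm2"])


def end_to_end_recovery(
    config: SyntheticCohortConfig,
    n_cohorts: int,
    estimator: Estimator = Estimator.BOUNDARY,
    success_filter: SuccessFilter = SuccessFilter.SUCCESS_ONLY,
) -> pd.DataFrame:
    """Generate -> estimate -> aggregate over ``n_cohorts`` seeded cohorts.

    For each group the frame reports the mean estimated group threshold,
    the matched truth (mean true threshold over the *same* sites that
    entered the estimate — the estimator can only be judged against the
    thresholds of the sites it saw), bias, RMSE of per-cohort group means
    about the matched truth, and Monte-Carlo standard errors.  Cohorts in
    which a group retains no measurable site are skipped for that group
    and counted.
    """
    if n_cohorts < 1:
        raise InputError("n_cohorts must be >= 1")
    model = MidplaneModel(paddle_radius=config.paddle_radius)
    seeds = np.random.SeedSequence(config.seed).generate_state(n_cohorts) % (2**31)
    est_means: dict[Group, list[float]] = {g: [] for g in GROUP_ORDER}
    true_means: dict[Group, list[float]] = {g: [] for g in GROUP_ORDER}
    skipped: dict[Group, int] = {g: 0 for g in GROUP_ORDER}
    for s in seeds:
        cohort_cfg = replace(config, seed=int(s))
        sites, truth = generate_cohort(cohort_cfg)
        for group in GROUP_ORDER:
            members = [x for x in sites if x.group == group]
            if success_filter == SuccessFilter.SUCCESS_ONLY:
                members = [x for x in members if any(s_.spans_between_paddles for s_ in x.sections)]
            if not members:
                skipped[group] += 1
                continue
            est = group_thresholds(
                members, model, estimator=estimator, success_filter=success_filter
            )[group]
            est_means[group].append(est.mean)
            true_means[group].append(
                float(np.mean([truth[(x.pig_id, group)] for x in members]))
            )
    rows = []
    for group in GROUP_ORDER:
        e = np.asarray(est_means[group])
        t = np.asarray(true_means[group])
        if len(e) == 0:
            raise InputError(f"group {group.value}: no cohort produced a measurable site")
        err = e - t
        rows.append(
            {
                "group": group.value,
                "n_cohorts_used": len(e),
                "n_cohorts_skipped": skipped[group],
                "mean_estimate": float(e.mean()),
                "mean_truth_matched": float(t.mean()),
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "mc_se": float(err.std(ddof=1) / math.sqrt(len(err))) if len(err) > 1 else float("nan"),
                "configured_mean": config.true_threshold_mean[group],
            }
        )
    return pd.DataFrame(rows)
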