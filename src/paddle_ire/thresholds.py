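"""Ablation-success classification and current-density threshold estimation.

Two estimators are provided, clearly labelled in every report:

``CENTER``
    The delivered density at the mid-plane centre, ``J_nominal(0; h) *
    I_peak``.  This is the dose-delivered reading taken at X = 0 between
    the paddles; it equals the necrosis threshold only in the marginal
    case where the lesion just reaches the centre.

``BOUNDARY``
    The delivered density at the lesion edge: the scaled profile evaluated
    at the median necrotic half-width across the site's sections.  At the
    necrosis/transition boundary the delivered dose equals the threshold
    by definition, making this the minimal-dose estimator; it requires
    measurable histology.

Group summaries report mean +/- SD (n-1 denominator) of per-site values,
optionally restricted to histologically successful sites.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from enum import Enum

from .errors import EstimationError, InputError
from .field_model import MidplaneModel
from .records_io import AblationSite, Group, GROUP_ORDER, HistologySection, summary_peak_current

__all__ = [
    "Estimator",
    "SuccessFilter",
    "ThresholdEstimate",
    "classify_success",
    "site_threshold_center",
    "site_threshold_boundary",
    "site_threshold",
    "group_thresholds",
]


class Estimator(str, Enum):
    CENTER = "center"
    BOUNDARY = "boundary"


class SuccessFilter(str, Enum):
    ALL = "all"
    SUCCESS_ONLY = "success"


@dataclass(frozen=True)
class ThresholdEstimate:
    """Per-group threshold summary (A/cm^2)."""

    group: Group
    per_site: tuple[tuple[str, float], ...]  # (pig_id, threshold)
    mean: float
    sd: float  # n-1 denominator; NaN when n < 2
    estimator: Estimator
    success_filter: SuccessFilter

    @property
    def n(self) -> int:
        return len(self.per_site)


def classify_success(sections: tuple[HistologySection, ...] | list[HistologySection]) -> bool:
    """A successful ablation: non-viable parenchyma spans the tissue
    between the paddles in at least one section."""
    if len(sections) == 0:
        raise InputError("cannot classify success with no histology sections")
    return any(s.spans_between_paddles for s in sections)


def site_threshold_center(
    site: AblationSite, model: MidplaneModel, current_mode: str = "mean"
) -> float:
    """Delivered mid-plane centre density (A/cm^2) at this site."""
    current = summary_peak_current(site, mode=current_mode)
    return model.delivered(site.thickness, 0.0, current)


def site_threshold_boundary(
    site: AblationSite, model: MidplaneModel, current_mode: str = "mean"
) -> float:
    """Delivered density (A/cm^2) at the lesion edge.

    The lesion edge is the median necrotic half-width across the site's
    sections (robust to the 2-4 sections per lesion); a half-width of 0
    degenerates to the centre reading.
    """
    if len(site.sections) == 0:
        raise EstimationError(
            f"site (pig {site.pig_id!r}, {site.group.value}) has no histology sections"
        )
    halfwidths = [s.necrotic_halfwidth for s in site.sections]
    if any(not math.isfinite(w) for w in halfwidths):
        raise EstimationError("non-finite necrotic half-width")
    x_edge = statistics.median(halfwidths)
    if x_edge > model.XMAX_FACTOR * model.paddle_radius:
        raise EstimationError(
            f"lesion half-width {x_edge} mm exceeds the model range "
            f"({model.XMAX_FACTOR * model.paddle_radius:.0f} mm)"
        )
    current = summary_peak_current(site, mode=current_mode)
    return model.delivered(site.thickness, x_edge, current)


def site_threshold(
    site: AblationSite,
    model: MidplaneModel,
    estimator: Estimator = Estimator.CENTER,
    current_mode: str = "mean",
) -> float:
    if estimator == Estimator.CENTER:
        return site_threshold_center(site, model, current_mode)
    return site_threshold_boundary(site, model, current_mode)


def group_thresholds(
    sites: list[AblationSite],
    model: MidplaneModel | None = None,
    estimator: Estimator = Estimator.CENTER,
    success_filter: SuccessFilter = SuccessFilter.ALL,
    current_mode: str = "mean",
) -> dict[Group, ThresholdEstimate]:
    """Per-group mean +/- SD of per-site threshold estimates.

    With ``SUCCESS_ONLY`` only histologically successful sites enter the
    summary.  A group present in ``sites`` that ends up empty after
    filtering raises :class:`EstimationError`; with a single site the SD
    is NaN.
    """
    if model is None:
        model = MidplaneModel()
    out: dict[Group, ThresholdEstimate] = {}
    for group in GROUP_ORDER:
        members = [s for s in sites if s.group == group]
        if not members:
            continue
        if success_filter == SuccessFilter.SUCCESS_ONLY:
            members = [s for s in members if classify_success(s.sections)]
        if not members:
            raise EstimationError(
                f"group {group.value}: no sites left after success filtering"
            )
        per_site = tuple(
            (s.pig_id, site_threshold(s, model, estimator, current_mode)) for s in members
        )
        values = [v for _, v in per_site]
        mean = sum(values) / len(values)
        sd = statistics.stdev(values) if len(values) >= 2 else float("nan")
        out[group] = ThresholdEstimate(
            group=group,
            per_site=per_site,
            mean=mean,
            sd=sd,
            estimator=estimator,
            success_filter=success_filter,
        )
    if not out:
        raise EstimationError("no sites given")
    return out
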