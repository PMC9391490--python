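"""Synthetic dentine growth with known ground truth.

Daily apposition lays down one increment per day; a tooth of age *a* days
therefore carries *a* increments whose widths are drawn i.i.d. from a
lognormal (or truncated-normal) distribution around a mean daily
apposition rate.  Replacement events at a fixed true interval start a new
tooth lingual to the functional one; the developing replacement erodes a
resorption pit whose height grows linearly with the replacement's age.
Measurement degradation is modelled separately: random line dropout
(merging adjacent increments), oblique-section width inflation by
1/cos(angle), boundary-position jitter, and unreadable gap masking.

Because every emitted record carries its generating truth, each estimator
in the analysis modules can be validated by parameter recovery — the same
logic as calibrating the resorption-pit rule on specimens whose
replacement tooth is preserved and of known age.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .increments import IncrementTransect, SectionPlane, count_total_increments, mean_increment_width, tooth_age_days
from .replacement import (
    ApexProfile,
    JawElement,
    ToothFamily,
    ToothRecord,
    dentine_extent_age,
    estimate_missing_replacement_age,
)

#: Default constant crown-height contribution per increment line, µm.
DEFAULT_HEIGHT_PER_INCREMENT = 8.0


class WidthDistribution(enum.Enum):
    LOGNORMAL = "lognormal"
    TRUNCATED_NORMAL = "truncated-normal"


@dataclass(frozen=True)
class GrowthParams:
    """Generative parameters for dentine growth.

    ``mean_daily_width`` is the daily dentine apposition rate in µm/day
    (default 12, the middle of the 1–30 µm plausibility band).
    ``height_per_increment`` maps the 1-based increment index (from the
    apex) to its crown-height contribution in µm; a bare float means a
    constant contribution (linear apex profile).  ``rp_growth_per_day``
    defaults to 1.5× the constant height contribution so the two-thirds
    resorption-pit rule is exactly calibrated under the default geometry;
    ``rp_miscalibration`` scales the pit growth away from that calibration
    for robustness experiments.
    """

    mean_daily_width: float = 12.0
    width_cv: float = 0.2
    width_distribution: WidthDistribution = WidthDistribution.LOGNORMAL
    height_per_increment: float | Callable[[int], float] = DEFAULT_HEIGHT_PER_INCREMENT
    true_replacement_interval: int = 105
    rp_growth_per_day: float | None = None
    rp_miscalibration: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_daily_width <= 30.0:
            raise ConfigurationError("mean_daily_width must be in (0, 30]")
        if self.width_cv < 0:
            raise ConfigurationError("width_cv must be >= 0")
        if self.true_replacement_interval <= 0:
            raise ConfigurationError("true_replacement_interval must be > 0")
        if self.rp_growth_per_day is None:
            h = (
                self.height_per_increment
                if isinstance(self.height_per_increment, (int, float))
                else DEFAULT_HEIGHT_PER_INCREMENT
            )
            object.__setattr__(self, "rp_growth_per_day", 1.5 * float(h))

    def height_at(self, index: int) -> float:
        """Crown-height contribution of the ``index``-th line from the apex."""
        if callable(self.height_per_increment):
            return float(self.height_per_increment(index))
        return float(self.height_per_increment)


def decelerating_height(
    h0: float = 10.0, half_life: float = 200.0
) -> Callable[[int], float]:
    """Alternative crown geometry: per-line height decaying with age."""
    return lambda i: h0 * 0.5 ** ((i - 1) / half_life)


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-degradation parameters.

    ``missed_line_prob``: per-boundary probability that a line boundary is
    not recognised (merging the two adjacent increments) — fossilization
    and imperfect grinding hide lines.  ``obliquity_angle``: degrees away
    from a perpendicular cut; widths inflate by 1/cos.  ``position_jitter_sd``:
    s.d. in µm of boundary-placement error.
    """

    missed_line_prob: float = 0.0
    obliquity_angle: float = 0.0
    position_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missed_line_prob < 1.0:
            raise ConfigurationError("missed_line_prob must be in [0, 1)")
        if not 0.0 <= self.obliquity_angle < 90.0:
            raise ConfigurationError("obliquity_angle must be in [0, 90)")
        if self.position_jitter_sd < 0:
            raise ConfigurationError("position_jitter_sd must be >= 0")


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground truth attached to a simulated tooth or family."""

    true_age_days: dict[str, int]
    true_replacement_rate: int | None
    true_mean_width: float


def _draw_widths(params: GrowthParams, n: int, rng: np.random.Generator) -> np.ndarray:
    m, cv = params.mean_daily_width, params.width_cv
    if cv == 0.0:
        return np.full(n, m)
    if params.width_distribution is WidthDistribution.LOGNORMAL:
        sigma2 = math.log1p(cv * cv)
        mu = math.log(m) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    # truncated normal on (0, inf): redraw the rare negatives
    w = rng.normal(m, cv * m, size=n)
    while np.any(w <= 0):
        bad = w <= 0
        w[bad] = rng.normal(m, cv * m, size=int(bad.sum()))
    return w


def simulate_tooth(
    params: GrowthParams,
    age_days: int,
    seed: int | np.random.Generator | None = None,
    tooth_id: str = "sim",
) -> tuple[IncrementTransect, ApexProfile, SimulatedTruth]:
    """One noise-free tooth: transect, apex profile, and truth.

    The transect has exactly ``age_days`` increments (``age_days + 1``
    boundaries starting at 0 µm at the pulp-cavity edge); the apex profile
    accumulates ``height_per_increment`` from the apex down.
    """
    if age_days < 1:
        raise ConfigurationError("age_days must be >= 1")
    rng = _as_rng(seed, params.seed)
    widths = _draw_widths(params, age_days, rng)
    positions = np.concatenate([[0.0], np.cumsum(widths)])
    transect = IncrementTransect(
        tooth_id=tooth_id, plane=SectionPlane.TR, boundary_positions=tuple(positions)
    )
    heights = np.cumsum([params.height_at(i) for i in range(1, age_days + 1)])
    profile = ApexProfile(cumulative_heights=tuple(heights))
    truth = SimulatedTruth(
        true_age_days={tooth_id: age_days},
        true_replacement_rate=None,
        true_mean_width=float(positions[-1] / age_days),
    )
    return transect, profile, truth


def _as_rng(
    seed: int | np.random.Generator | None, fallback: int | None
) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        seed = fallback
    return np.random.default_rng(seed)


def apply_section_noise(
    transect: IncrementTransect,
    noise: NoiseParams,
    seed: int | np.random.Generator | None = None,
) -> IncrementTransect:
    """Degrade a transect: line dropout, oblique inflation, jitter.

    Interior boundaries are each deleted with ``missed_line_prob``; all
    positions (and gap endpoints) are then scaled by 1/cos(angle); finally
    Gaussian jitter is added to interior boundaries, clipped to the open
    interval between the midpoints to their neighbours so the strict
    ordering is preserved.
    """
    rng = _as_rng(seed, None)
    pos = np.asarray(transect.boundary_positions, dtype=float)
    if noise.missed_line_prob > 0 and pos.size > 2:
        keep = np.ones(pos.size, dtype=bool)
        keep[1:-1] = rng.random(pos.size - 2) >= noise.missed_line_prob
        pos = pos[keep]
    scale = 1.0 / math.cos(math.radians(noise.obliquity_angle))
    pos = pos * scale
    gaps = tuple((a * scale, b * scale) for a, b in transect.gaps)
    if noise.position_jitter_sd > 0 and pos.size > 2:
        jit = pos.copy()
        eps = rng.normal(0.0, noise.position_jitter_sd, size=pos.size - 2)
        lo = (pos[:-2] + pos[1:-1]) / 2.0
        hi = (pos[1:-1] + pos[2:]) / 2.0
        margin = 1e-9 * (hi - lo)
        jit[1:-1] = np.clip(pos[1:-1] + eps, lo + margin, hi - margin)
        pos = jit
    return IncrementTransect(
        tooth_id=transect.tooth_id,
        plane=transect.plane,
        boundary_positions=tuple(pos.tolist()),
        gaps=gaps,
    )


def mask_random_gap(
    transect: IncrementTransect,
    n_lines_hidden: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[IncrementTransect, int]:
    """Hide a random contiguous stretch of boundaries behind a gap.

    ``n_lines_hidden`` increments are made unreadable by deleting the
    boundaries strictly inside a window and recording the window between
    the flanking retained boundaries as a gap.  Returns the masked
    transect and the number of increments the gap actually spans.
    """
    pos = np.asarray(transect.boundary_positions, dtype=float)
    n_inc = pos.size - 1
    if n_lines_hidden < 2 or n_lines_hidden > n_inc - 2:
        raise InvalidInputError(
            "n_lines_hidden must be in [2, n_increments - 2] so readable "
            "runs remain on both sides"
        )
    rng = _as_rng(seed, None)
    # gap spans increments i+1 .. i+n (boundaries i and i+n kept, interior deleted)
    i = int(rng.integers(1, n_inc - n_lines_hidden))
    a, b = pos[i], pos[i + n_lines_hidden]
    keep = np.concatenate([pos[: i + 1], pos[i + n_lines_hidden :]])
    masked = IncrementTransect(
        tooth_id=transect.tooth_id,
        plane=transect.plane,
        boundary_positions=tuple(keep.tolist()),
        gaps=transect.gaps + ((float(a), float(b)),),
    )
    return masked, n_lines_hidden


def simulate_family(
    params: GrowthParams,
    observation_day: int,
    seed: int | np.random.Generator | None = None,
    taxon: str = "synthetic",
    specimen_id: str = "sim-spec",
    position_label: str = "p01",
) -> tuple[ToothFamily, ApexProfile, SimulatedTruth]:
    """A functional tooth plus its in-place replacement at observation time.

    The replacement began depositing dentine ``true_replacement_interval``
    days after the functional tooth did, so at observation the functional
    tooth is ``observation_day`` days old and the replacement
    ``observation_day − interval``; the resorption pit has been growing at
    ``rp_growth_per_day`` (times any miscalibration factor) since the
    replacement initiated.
    """
    interval = params.true_replacement_interval
    if observation_day <= interval:
        raise ConfigurationError("observation_day must exceed the replacement interval")
    rng = _as_rng(seed, params.seed)
    func_tr, profile, _ = simulate_tooth(
        params, observation_day, rng, tooth_id=f"{position_label}-func"
    )
    repl_age = observation_day - interval
    rp_height = params.rp_growth_per_day * params.rp_miscalibration * repl_age
    functional = ToothRecord(
        taxon=taxon,
        specimen_id=specimen_id,
        element=JawElement.DENTARY,
        position_label=position_label,
        age_days=observation_day,
        rp_height=rp_height,
        ankylosed=True,
    )
    replacement = ToothRecord(
        taxon=taxon,
        specimen_id=specimen_id,
        element=JawElement.DENTARY,
        position_label=f"{position_label}-repl",
        age_days=repl_age,
    )
    family = ToothFamily(functional=functional, replacements=(replacement,))
    truth = SimulatedTruth(
        true_age_days={functional.position_label: observation_day,
                       replacement.position_label: repl_age},
        true_replacement_rate=interval,
        true_mean_width=float(
            func_tr.boundary_positions[-1] / observation_day
        ),
    )
    return family, profile, truth


# occupancy states for simulate_replacement_wave
FUNCTIONAL, GAP, NEW = 0, 1, 2


def simulate_replacement_wave(
    n_positions: int,
    interval: int,
    duration: int,
    seed: int | None = None,
) -> np.ndarray:
    """Alternating-wave replacement schedule along a tooth row.

    Returns an ``(n_positions, duration)`` int matrix of states
    {FUNCTIONAL, GAP, NEW}.  Odd and even positions shed in alternating
    waves offset by half the interval, so a shed (gap) position always has
    functional neighbours — replacement sweeps every other tooth per
    event.  The schedule is deterministic; the seed argument exists for
    interface uniformity with the other simulators.
    """
    if n_positions < 2:
        raise ConfigurationError("n_positions must be >= 2")
    if interval < 4:
        raise ConfigurationError("interval must be >= 4 days")
    if duration < 1:
        raise ConfigurationError("duration must be >= 1 day")
    gap_len = max(1, interval // 10)
    new_len = max(1, interval // 10)
    occ = np.full((n_positions, duration), FUNCTIONAL, dtype=np.int8)
    for p in range(n_positions):
        offset = (interval // 2) * (p % 2)
        shed = offset + interval
        while shed < duration:
            g_end = min(shed + gap_len, duration)
            n_end = min(shed + gap_len + new_len, duration)
            occ[p, shed:g_end] = GAP
            occ[p, g_end:n_end] = NEW
            shed += interval
    return occ


def recovery_experiment(
    param_grid: Sequence[dict],
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Bias and RMSE of every replacement-rate estimator per condition.

    Each condition dict may override :class:`GrowthParams` /
    :class:`NoiseParams` fields (plus an optional ``name``).  Per
    replicate, a tooth family is simulated, the functional and replacement
    transects are degraded per the condition, and the direct, RP-height
    and dentine-extent estimators are each compared against the true
    replacement interval.
    """
    rng = np.random.default_rng(seed)
    growth_fields = {
        "mean_daily_width", "width_cv", "width_distribution",
        "height_per_increment", "true_replacement_interval",
        "rp_growth_per_day", "rp_miscalibration",
    }
    noise_fields = {"missed_line_prob", "obliquity_angle", "position_jitter_sd"}
    rows = []
    for cond in param_grid:
        cond = dict(cond)
        name = cond.pop("name", None) or ",".join(
            f"{k}={v}" for k, v in sorted(cond.items())
        ) or "default"
        unknown = set(cond) - growth_fields - noise_fields
        if unknown:
            raise ConfigurationError(f"unknown condition keys: {sorted(unknown)}")
        params = GrowthParams(**{k: v for k, v in cond.items() if k in growth_fields})
        noise = NoiseParams(**{k: v for k, v in cond.items() if k in noise_fields})
        interval = params.true_replacement_interval
        errors: dict[str, list[float]] = {
            "direct": [], "rp_height": [], "dentine_extent": []
        }
        for _ in range(n_reps):
            obs_day = interval + int(rng.integers(30, 200))
            family, profile, truth = simulate_family(params, obs_day, rng)
            func_tr, _, _ = simulate_tooth(params, obs_day, rng, tooth_id="f")
            repl_age = obs_day - interval
            repl_tr, _, _ = simulate_tooth(params, repl_age, rng, tooth_id="r")
            func_tr = apply_section_noise(func_tr, noise, rng)
            repl_tr = apply_section_noise(repl_tr, noise, rng)
            func_age = tooth_age_days(count_total_increments(func_tr))
            repl_age_obs = tooth_age_days(count_total_increments(repl_tr))
            errors["direct"].append(func_age - repl_age_obs - interval)
            est_repl = estimate_missing_replacement_age(
                profile, family.functional.rp_height
            )
            errors["rp_height"].append(func_age - est_repl - interval)
            extent = repl_tr.span_um
            est_repl_de = dentine_extent_age(extent, mean_increment_width(func_tr))
            errors["dentine_extent"].append(func_age - est_repl_de - interval)
        for est, errs in errors.items():
            e = np.asarray(errs, dtype=float)
            rows.append(
                {
                    "condition": name,
                    "estimator": est,
                    "bias": float(e.mean()),
                    "rmse": float(np.sqrt(np.mean(e * e))),
                    "n": len(e),
                }
            )
    return pd.DataFrame(rows)
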