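"""Synthetic myopic high-tension-glaucoma cohort with known ground truth.

Generates per-eye optic-nerve-head landmark records, clinical covariates and
longitudinal 24-2 pattern-deviation series under a configurable causal
structure:

* the probability that the *inferior* hemifield is the first affected follows
  a logistic model in the trunk angular deviation alpha (default log-odds
  ln 0.83 per degree: superiorly shifted trunks produce superior defects);
* the probability of bi-hemispheric onset follows a logistic model in
  baseline mean deviation (worse MD -> more likely bi), with an extra
  log-odds bonus for severe shift (trunk outside the BMO);
* eyes may convert to bi-hemispheric involvement later at a constant yearly
  rate, and MD declines linearly over follow-up.

Covariate distributions are truncated normals whose *post-truncation* mean
and SD equal the configured cohort moments (the truncation bounds mirror the
study's eligibility rules), so large-sample covariate moments reproduce the
configured values. Per-eye substreams are keyed by (seed, eye index): adding
eyes never perturbs earlier eyes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit

from . import geometry
from .grid import Grid242, build_grid_242
from .types import EyeSeries, LandmarkRecord, VfExam

__all__ = ["SimConfig", "simulate_eye", "simulate_vf_series", "simulate_cohort",
           "simulate_covariates", "simulate_onset_labels", "write_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults encode the emulated cohort's moments.

    Continuous covariates list (mean, sd) of the *observed* (truncated)
    distribution; ``effect_logodds_per_degree`` is the true per-degree
    log-odds of inferior (vs superior) onset, ``bihemi_md_slope`` the
    per-dB log-odds of bi-hemispheric onset.
    """

    n_eyes: int = 81
    seed: int = 0
    age_mean_sd: tuple[float, float] = (54.7, 14.2)
    axial_mean_sd: tuple[float, float] = (25.5, 1.3)
    iop_mean_sd: tuple[float, float] = (25.2, 4.1)
    md0_mean_sd: tuple[float, float] = (-8.11, 5.85)
    followup_mean_sd: tuple[float, float] = (5.0, 2.7)
    female_prob: float = 25 / 81
    # trunk position: superior-biased two-component normal mixture for alpha
    alpha_mix_weight_superior: float = 0.55
    alpha_superior_mean_sd: tuple[float, float] = (40.0, 35.0)
    alpha_inferior_mean_sd: tuple[float, float] = (-35.0, 30.0)
    # shift index: Beta body plus a point mass at 1 (trunk outside the BMO)
    shift_beta_params: tuple[float, float] = (2.0, 2.3)
    severe_shift_prob: float = 6 / 81
    # BMO morphometry
    bmo_area_mean_sd_mm2: tuple[float, float] = (2.65, 0.55)
    lcd_mean_sd_um: tuple[float, float] = (540.0, 155.0)
    ppa_present_prob: float = 0.85
    beta_ppa_mean_sd: tuple[float, float] = (-20.0, 55.0)
    # ground-truth effects
    effect_logodds_per_degree: float = math.log(0.83)
    inferior_intercept: float = 0.0
    bihemi_md_slope: float = math.log(0.817)
    bihemi_intercept: float = -3.18
    severe_bihemi_bonus: float = 2.0
    # longitudinal structure
    visits_per_eye: int = 6
    progression_db_per_year: float = -0.5
    bi_conversion_rate_per_year: float = 0.06
    false_point_prob: float = 0.01
    reliability_failure_prob: float = 0.10
    mixed_laterality: bool = False

    def manifest(self) -> dict:
        return asdict(self)


def _eye_rng(seed: int, eye_index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), int(eye_index)])


@lru_cache(maxsize=64)
def _truncnorm_underlying(target_mean: float, target_sd: float,
                          low: float, high: float) -> tuple[float, float]:
    """Pre-truncation (mu, sigma) so the truncated normal has the target moments."""

    def resid(p):
        mu, ls = p
        s = math.exp(ls)
        a, b = (low - mu) / s, (high - mu) / s
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [m - target_mean, math.sqrt(v) - target_sd]

    sol = optimize.root(resid, x0=[target_mean, math.log(target_sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment matching failed for {target_mean}+/-{target_sd}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _draw_truncnorm(rng: np.random.Generator, n: int, mean_sd: tuple[float, float],
                    low: float = -np.inf, high: float = np.inf) -> np.ndarray:
    if not np.isfinite(low) and not np.isfinite(high):
        return rng.normal(mean_sd[0], mean_sd[1], size=n)
    mu, s = _truncnorm_underlying(mean_sd[0], mean_sd[1], low, high)
    a, b = (low - mu) / s, (high - mu) / s
    return sps.truncnorm.rvs(a, b, loc=mu, scale=s, size=n, random_state=rng)


def simulate_covariates(n: int, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Vectorized covariate draws honouring the eligibility-rule truncations."""
    return pd.DataFrame(
        {
            "age": _draw_truncnorm(rng, n, config.age_mean_sd, low=20.0),
            "axial_length": _draw_truncnorm(rng, n, config.axial_mean_sd, low=24.0),
            "highest_iop": _draw_truncnorm(rng, n, config.iop_mean_sd, low=21.0),
            "md0": _draw_truncnorm(rng, n, config.md0_mean_sd, low=-30.0, high=0.0),
            "followup_years": _draw_truncnorm(rng, n, config.followup_mean_sd, low=2.0),
            "female": (rng.random(n) < config.female_prob).astype(int),
        }
    )


def _draw_alpha(rng: np.random.Generator, config: SimConfig) -> float:
    if rng.random() < config.alpha_mix_weight_superior:
        m, s = config.alpha_superior_mean_sd
    else:
        m, s = config.alpha_inferior_mean_sd
    a = rng.normal(m, s)
    # wrap into (-180, 180]
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _draw_shift_index(rng: np.random.Generator, config: SimConfig) -> float:
    if rng.random() < config.severe_shift_prob:
        return 1.0
    a, b = config.shift_beta_params
    si = rng.beta(a, b)
    return min(si, 1.0 - 1e-6)


def _bmo_polygon(rng: np.random.Generator, config: SimConfig, n_vertices: int = 24):
    """Near-elliptical simple polygon; star-shaped about the origin."""
    area_mm2 = float(_draw_truncnorm(rng, 1, config.bmo_area_mean_sd_mm2, low=1.2)[0])
    area_um2 = area_mm2 * 1e6
    ratio = rng.uniform(1.0, 1.25)  # vertical/horizontal semi-axis
    ax = math.sqrt(area_um2 / (math.pi * ratio))
    ay = ax * ratio
    theta = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    jitter = rng.normal(1.0, 0.03, size=n_vertices)
    xs = ax * np.cos(theta) * jitter
    ys = ay * np.sin(theta) * jitter
    return tuple((float(x), float(y)) for x, y in zip(xs, ys))


def simulate_eye(config: SimConfig, eye_index: int) -> tuple[LandmarkRecord, dict, dict]:
    """One eye: landmark record, covariate dict and ground-truth label dict.

    The trunk is placed at the drawn angular deviation and shift index
    relative to the realized polygon's centroid, so measuring the record
    recovers the drawn values. A drawn shift index of 1 produces an
    absent-trunk record (severe shift).
    """
    rng = _eye_rng(config.seed, eye_index)
    cov = simulate_covariates(1, config, rng).iloc[0].to_dict()
    alpha = _draw_alpha(rng, config)
    si = _draw_shift_index(rng, config)
    severe = si >= 1.0

    margin = _bmo_polygon(rng, config)
    center = geometry.bmo_centroid(margin)
    # fovea ~3 mm temporal (here -x), fovea-BMO axis tilted ~7 deg downward
    tilt = math.radians(rng.normal(-7.0, 2.0))
    fovea = (center[0] - 3000.0 * math.cos(tilt), center[1] + 3000.0 * math.sin(tilt))
    temporal = geometry.fobmo_axis(center, fovea)
    nasal = -temporal

    trunk = None
    if not severe:
        rad = math.radians(alpha)
        direction = np.array(
            [
                nasal[0] * math.cos(rad) - nasal[1] * math.sin(rad),
                nasal[0] * math.sin(rad) + nasal[1] * math.cos(rad),
            ]
        )
        b = _boundary_distance(center, direction, margin)
        trunk = (center[0] + si * b * direction[0], center[1] + si * b * direction[1])

    lcd_um = float(_draw_truncnorm(rng, 1, config.lcd_mean_sd_um, low=100.0)[0])
    plane_depth = float(rng.normal(350.0, 40.0))
    ppa = None
    if rng.random() < config.ppa_present_prob:
        beta = math.radians(rng.normal(*config.beta_ppa_mean_sd))
        d = np.array(
            [
                temporal[0] * math.cos(beta) - temporal[1] * math.sin(beta),
                temporal[0] * math.sin(beta) + temporal[1] * math.cos(beta),
            ]
        )
        r = 1.3 * _boundary_distance(center, d, margin)
        ppa = (center[0] + r * d[0], center[1] + r * d[1])

    laterality = "right"
    if config.mixed_laterality and rng.random() < 0.5:
        laterality = "left"
    rec = LandmarkRecord(
        eye_id=f"eye{eye_index:04d}",
        laterality="right",
        bmo_margin=margin,
        fovea=fovea,
        trunk=trunk,
        trunk_depth_um=plane_depth + lcd_um if not severe else None,
        bmo_plane_depth_um=plane_depth if not severe else None,
        ppa_max_point=ppa,
    )
    if laterality == "left":
        rec = _mirror_to_left(rec)

    truth = _draw_truth(rng, config, alpha if not severe else None, si, cov["md0"])
    truth["alpha_true"] = None if severe else alpha
    truth["shift_index_true"] = si
    return rec, cov, truth


def _mirror_to_left(rec: LandmarkRecord) -> LandmarkRecord:
    """Re-encode a right-eye record as the anatomically identical left eye."""
    cx, _ = geometry.bmo_centroid(rec.bmo_margin)

    def m(p):
        return None if p is None else (2.0 * cx - p[0], p[1])

    return LandmarkRecord(
        eye_id=rec.eye_id,
        laterality="left",
        bmo_margin=tuple(m(p) for p in reversed(rec.bmo_margin)),
        fovea=m(rec.fovea),
        trunk=m(rec.trunk),
        trunk_depth_um=rec.trunk_depth_um,
        bmo_plane_depth_um=rec.bmo_plane_depth_um,
        ppa_max_point=m(rec.ppa_max_point),
    )


def _boundary_distance(center, direction, margin) -> float:
    from shapely.geometry import LinearRing, LineString

    arr = np.asarray(margin, dtype=float)
    reach = 4.0 * (arr.max() - arr.min()) + 1.0
    ray = LineString(
        [tuple(center), (center[0] + direction[0] * reach, center[1] + direction[1] * reach)]
    )
    hit = ray.intersection(LinearRing(arr))
    pts = [hit] if hit.geom_type == "Point" else list(getattr(hit, "geoms", []))
    dists = [
        math.hypot(x - center[0], y - center[1])
        for g in pts
        for x, y in getattr(g, "coords", [])
    ]
    dists = [d for d in dists if d > 1e-9]
    if not dists:
        raise RuntimeError("generator polygon/ray intersection failed")
    return min(dists)


def _draw_truth(rng, config: SimConfig, alpha: float | None, si: float, md0: float) -> dict:
    severe = si >= 1.0
    logit_bi = config.bihemi_intercept + config.bihemi_md_slope * md0
    if severe:
        logit_bi += config.severe_bihemi_bonus
    p_bi = float(expit(logit_bi))
    if rng.random() < p_bi:
        onset = "bi"
        p_inf = math.nan
    else:
        if alpha is None:
            p_inf = 0.5
        else:
            p_inf = float(expit(config.inferior_intercept + config.effect_logodds_per_degree * alpha))
        onset = "inferior" if rng.random() < p_inf else "superior"
    return {"onset": onset, "p_bi": p_bi, "p_inferior_given_single": p_inf}


def simulate_onset_labels(n: int, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Light-weight draw of (alpha, onset) pairs for parameter-recovery studies.

    Bypasses polygon construction and visual-field synthesis: draws alpha from
    the configured mixture and the onset hemisphere from the logistic truth
    model, with the bi-hemispheric stage disabled so that
    P(inferior | alpha) is exactly logistic in alpha.
    """
    alphas = np.empty(n)
    for i in range(n):
        alphas[i] = _draw_alpha(rng, config)
    p_inf = expit(config.inferior_intercept + config.effect_logodds_per_degree * alphas)
    inferior = rng.random(n) < p_inf
    return pd.DataFrame({"alpha": alphas, "inferior": inferior.astype(int)})


# ---------------------------------------------------------------------------
# visual-field series synthesis

#: seed clusters per hemifield in grid (x, y) coordinates; arcuate/nasal-step
#: shapes sized 4-5 points so the 3-point rule is met with margin.
_CLUSTER_TEMPLATES = {
    "superior": (
        ((-15, 9), (-9, 9), (-3, 9), (-9, 15)),          # superior arcuate
        ((3, 15), (9, 15), (3, 9), (9, 9), (15, 9)),     # supero-temporal
        ((-21, 3), (-21, 9), (-15, 3), (-15, 9)),        # superior nasal step
    ),
    "inferior": (
        ((-15, -9), (-9, -9), (-3, -9), (-9, -15)),
        ((3, -15), (9, -15), (3, -9), (9, -9), (15, -9)),
        ((-21, -3), (-21, -9), (-15, -3), (-15, -9)),
    ),
}


def _template_indices(grid: Grid242, hemifield: str, which: int) -> list[int]:
    by_pos = {(p.x_deg, p.y_deg): p.index for p in grid.points}
    return [by_pos[xy] for xy in _CLUSTER_TEMPLATES[hemifield][which]]


def simulate_vf_series(
    truth: dict,
    covariates: dict,
    config: SimConfig,
    rng: np.random.Generator,
    eye_id: str = "eye",
    grid: Grid242 | None = None,
) -> list[VfExam]:
    """Longitudinal 24-2 exams realizing an eye's ground-truth onset label.

    The onset hemifield's cluster is present from presentation for eyes whose
    baseline MD is already clearly depressed and from the second visit for
    very mild eyes; bi-hemispheric truth puts clusters in both hemifields on
    the first exam. Single-hemisphere eyes may add the opposite hemifield at
    an exponential conversion time. Isolated false-positive abnormal points
    and unreliable exams are sprinkled at configured rates; MD declines
    linearly.
    """
    grid = grid or build_grid_242()
    onset = truth["onset"]
    md0 = float(covariates["md0"])
    followup = float(covariates["followup_years"])
    n_visits = max(3, int(config.visits_per_eye))
    times = np.linspace(0.0, followup, n_visits)

    if onset == "bi":
        hemis_first = ["superior", "inferior"]
        second_visit = 0
    else:
        hemis_first = [onset]
        t_conv = rng.exponential(1.0 / config.bi_conversion_rate_per_year) \
            if config.bi_conversion_rate_per_year > 0 else math.inf
        second_visit = int(np.searchsorted(times, t_conv)) if t_conv <= followup else n_visits + 1
        second_visit = max(second_visit, 1)  # never bi at presentation unless true bi
    onset_visit = 0 if md0 <= -2.0 else 1

    scoreable = grid.scoreable
    idx_of = {p.index: k for k, p in enumerate(scoreable)}
    tmpl = {h: _template_indices(grid, h, int(rng.integers(len(_CLUSTER_TEMPLATES[h]))))
            for h in ("superior", "inferior")}

    exams: list[VfExam] = []
    for v, t in enumerate(times):
        levels = np.zeros(52, dtype=int)
        active: list[str] = []
        if v >= onset_visit:
            active += hemis_first
        if v >= second_visit and onset != "bi":
            active += [h for h in ("superior", "inferior") if h not in hemis_first]
        for h in active:
            for j, gi in enumerate(tmpl[h]):
                # core points at p<0.5%, edges at p<2%: satisfies both rules
                levels[idx_of[gi]] = 4 if j < 3 else 2
        if config.false_point_prob > 0:
            fp = rng.random(52) < config.false_point_prob
            levels = np.maximum(levels, fp.astype(int))
        md = md0 + config.progression_db_per_year * t
        defect = bool(active)
        unreliable = rng.random() < config.reliability_failure_prob
        exams.append(
            VfExam(
                eye_id=eye_id,
                visit=v,
                pd_levels=tuple(int(x) for x in levels),
                md_db=float(md),
                psd_prob=0.02 if defect else float(rng.uniform(0.2, 1.0)),
                ght="outside" if defect else "within",
                fixation_loss_rate=0.35 if unreliable else float(rng.uniform(0.0, 0.15)),
                false_pos_rate=float(rng.uniform(0.0, 0.20)),
                false_neg_rate=float(rng.uniform(0.0, 0.20)),
            )
        )
    return exams


def simulate_cohort(config: SimConfig) -> tuple[list[LandmarkRecord], list[EyeSeries], pd.DataFrame]:
    """Full cohort: landmark records, longitudinal series, and a truth table."""
    records: list[LandmarkRecord] = []
    series: list[EyeSeries] = []
    rows = []
    for i in range(config.n_eyes):
        rec, cov, truth = simulate_eye(config, i)
        rng = _eye_rng(config.seed, 10_000_000 + i)  # separate substream for the VF stage
        exams = simulate_vf_series(truth, cov, config, rng, eye_id=rec.eye_id)
        records.append(rec)
        series.append(EyeSeries(eye_id=rec.eye_id, exams=exams, covariates=cov))
        rows.append({"eye_id": rec.eye_id, **cov, **truth})
    return records, series, pd.DataFrame(rows)


def write_cohort(records, series, truth: pd.DataFrame, path: str | Path,
                 config: SimConfig | None = None) -> dict[str, Path]:
    """Serialize a cohort to the package's CSV/JSON interchange files."""
    from . import io as lio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {
        "landmarks": path / "landmarks.csv",
        "exams": path / "vf_exams.csv",
        "covariates": path / "covariates.csv",
        "truth": path / "truth.csv",
        "manifest": path / "manifest.json",
    }
    lio.write_landmarks_csv(records, out["landmarks"])
    lio.write_vf_exams_csv([e for s in series for e in s.exams], out["exams"])
    cov = pd.DataFrame([{"eye_id": s.eye_id, **s.covariates} for s in series])
    cov.to_csv(out["covariates"], index=False)
    truth.to_csv(out["truth"], index=False)
    manifest = {"config": config.manifest() if config else None}
    out["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
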