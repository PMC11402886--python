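"""Synthetic cohort generator.

Emulates the statistical structure of a cervical-vertebral-maturation study
cohort so that every downstream stage (feature extraction, agreement,
consensus labelling, classification, generalization) can be exercised
without any radiographs:

* stage-dependent vertebral morphology — the inferior-border concavity
  deepens with stage and the C3/C4 bodies progress from trapezoidal through
  horizontally rectangular and square to vertically rectangular;
* demographics — ages 4-21 y with stage-conditional means, female:male
  ratio 1.12:1;
* a three-rater panel whose stage labels follow a unimodal error model
  around the true stage, calibratable to target weighted-kappa ranges.

All randomness flows from explicit :class:`numpy.random.Generator` objects;
no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.stats import truncnorm

from .agreement import weighted_kappa
from .datamodel import (
    CohortTable,
    LandmarkSet,
    RatingPanel,
    STAGES,
    Subject,
)
from .morphometry import DEFAULT_SCHEME, LandmarkScheme

#: per-stage subject counts of the emulated cohort (n = 1380)
DEFAULT_STAGE_COUNTS = (201, 151, 181, 328, 294, 225)

#: per-stage mean chronological age (years); SD below, truncated to [4, 21]
DEFAULT_AGE_MEANS = (8.0, 10.0, 12.0, 13.5, 15.0, 17.0)
DEFAULT_AGE_SD = 1.5
AGE_RANGE = (4.0, 21.0)

#: stage marginal used when a calibration or simulation needs truth draws
DEFAULT_STAGE_PROBS = np.asarray(DEFAULT_STAGE_COUNTS, dtype=float) / sum(
    DEFAULT_STAGE_COUNTS)


@dataclass(frozen=True)
class StageMorphology:
    """Ideal vertebral geometry at one maturation stage.

    ``concavity_depth_frac`` maps vertebra name to concavity depth as a
    fraction of the inferior-border width (0 where the concavity has not yet
    appeared); ``hv_ratio_mean`` is the mean width/height ratio of the C3/C4
    bodies (>1 horizontal rectangle, 1 square, <1 vertical rectangle);
    ``taper_frac`` is the superior/inferior width ratio (trapezoid control).
    """

    stage: int
    concavity_depth_frac: dict[str, float]
    hv_ratio_mean: float
    taper_frac: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage {self.stage} outside 1..6")
        if any(f < 0 for f in self.concavity_depth_frac.values()):
            raise ValueError("negative concavity depth fraction")
        if self.hv_ratio_mean <= 0 or self.taper_frac <= 0:
            raise ValueError("ratios must be positive")


def default_morphology() -> list[StageMorphology]:
    """Default six-stage morphology table.

    Concavity onset follows the staging narrative: C2's inferior border
    becomes concave from stage 2, C3's from stage 3, C4's from stage 4, each
    deepening along 0.04 → 0.08 → 0.12 → 0.15 → 0.18 of the border width.
    Body h/v ratios fall from 2.0 (horizontal rectangle) through 1.0
    (square) to 0.8 (vertical rectangle); bodies are tapered (trapezoidal)
    at early stages.
    """
    ramp = (0.04, 0.08, 0.12, 0.15, 0.18)
    hv = (2.0, 1.9, 1.7, 1.4, 1.0, 0.8)
    taper = (0.8, 0.8, 0.8, 0.9, 1.0, 1.0)

    def depth(onset: int, stage: int) -> float:
        return 0.0 if stage < onset else ramp[min(stage - onset, len(ramp) - 1)]

    return [
        StageMorphology(
            stage=s,
            concavity_depth_frac={
                "C2": depth(2, s), "C3": depth(3, s), "C4": depth(4, s)},
            hv_ratio_mean=hv[s - 1],
            taper_frac=taper[s - 1],
        )
        for s in STAGES
    ]


def morphology_to_yaml(table: list[StageMorphology], path: str) -> None:
    doc = [
        {"stage": m.stage,
         "concavity_depth_frac": dict(m.concavity_depth_frac),
         "hv_ratio_mean": m.hv_ratio_mean,
         "taper_frac": m.taper_frac}
        for m in table
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def morphology_from_yaml(path: str) -> list[StageMorphology]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return [StageMorphology(**entry) for entry in doc]


@dataclass(frozen=True)
class RaterProfile:
    """Stochastic rating behaviour of one simulated rater.

    Two observation families share this container:

    *Categorical* (``sigma`` is None): a rating reproduces the true stage
    with probability ``p_exact``; of the remaining mass, ``p_far`` lands two
    or more stages away (uniform over those stages) and the rest on an
    adjacent stage, split ``adjacent_bias`` : (1 - adjacent_bias) between
    stage-1 and stage+1.  Probability on stages outside 1..6 is reassigned
    to the valid side.  ``p_repeat`` is the probability that a second
    session reproduces the rater's own primary rating (else it moves to an
    adjacent stage).

    *Perceptual* (``sigma`` set): the rater reads the subject's latent
    continuous maturity through Gaussian noise of SD ``sigma`` (stage
    units) and discretizes it at personal stage boundaries shifted by
    ``cut_shifts`` — systematic over-/under-staging at specific boundaries.
    With probability ``p_far`` the read is a blunder with much larger noise.
    In this family ``p_repeat`` is the correlation between the perceptual
    errors of the two sessions (a stable personal reading of a case).
    """

    rater_id: str
    p_exact: float
    adjacent_bias: float = 0.5
    p_far: float = 0.02
    p_repeat: float = 0.9
    sigma: float | None = None
    cut_shifts: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("p_exact", "adjacent_bias", "p_far", "p_repeat"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.sigma is None and self.p_exact + self.p_far > 1.0 + 1e-12:
            raise ValueError("p_exact + p_far exceeds 1")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if len(self.cut_shifts) != 5:
            raise ValueError("cut_shifts needs one value per stage boundary")

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 6x6 matrix P[true-1, rated-1]."""
        k = len(STAGES)
        T = np.zeros((k, k))
        p_adj = 1.0 - self.p_exact - self.p_far
        for t in range(k):
            T[t, t] += self.p_exact
            lo, hi = t - 1, t + 1
            if lo < 0:          # truncation: all adjacent mass to the valid side
                T[t, hi] += p_adj
            elif hi >= k:
                T[t, lo] += p_adj
            else:
                T[t, lo] += p_adj * self.adjacent_bias
                T[t, hi] += p_adj * (1.0 - self.adjacent_bias)
            far = [s for s in range(k) if abs(s - t) >= 2]
            for s in far:
                T[t, s] += self.p_far / len(far)
        return T

    def repeat_matrix(self) -> np.ndarray:
        """Row-stochastic 6x6 matrix R[primary-1, repeat-1]."""
        return replace(self, p_exact=self.p_repeat, p_far=0.0,
                       adjacent_bias=0.5).transition_matrix()


def _draw_from_rows(matrix: np.ndarray, rows: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical outcome per entry of ``rows`` (0-based)."""
    cum = matrix.cumsum(axis=1)[rows]
    u = rng.random(len(rows))
    return (cum < u[:, None]).sum(axis=1)


def rate(true_stage: int, profile: RaterProfile,
         rng: np.random.Generator) -> int:
    """Simulate one rating of a subject whose true stage is known."""
    if true_stage not in STAGES:
        raise ValueError(f"stage {true_stage} outside 1..6")
    idx = _draw_from_rows(profile.transition_matrix(),
                          np.array([true_stage - 1]), rng)
    return int(idx[0]) + 1


def rate_many(true_stages: np.ndarray, profile: RaterProfile,
              rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`rate` over an array of true stages (1-based)."""
    return _draw_from_rows(profile.transition_matrix(),
                           np.asarray(true_stages) - 1, rng) + 1


def repeat_ratings(primary: np.ndarray, profile: RaterProfile,
                   rng: np.random.Generator) -> np.ndarray:
    """Simulate a second rating session conditioned on the primary one."""
    return _draw_from_rows(profile.repeat_matrix(),
                           np.asarray(primary) - 1, rng) + 1


# ------------------------------------------------- perceptual rating path

#: noise SD of a blunder read (stage units): fatigue, poor image quality
_BLUNDER_SIGMA = 1.2


def perceptual_errors(n: int, profile: RaterProfile,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-subject perceptual error draws (stage units)."""
    eta = rng.normal(0.0, profile.sigma, n)
    blunder = rng.random(n) < profile.p_far
    eta[blunder] = rng.normal(0.0, _BLUNDER_SIGMA, int(blunder.sum()))
    return eta


def rate_latent(maturity: np.ndarray, profile: RaterProfile,
                rng: np.random.Generator,
                errors: np.ndarray | None = None) -> np.ndarray:
    """Rate subjects from their latent continuous maturity.

    ``maturity`` lies on the stage axis (true stage s covers
    [s - 0.5, s + 0.5)); the rater discretizes maturity-plus-noise at
    personal boundaries ``k + 0.5 + cut_shifts[k-1]``.  Pass precomputed
    ``errors`` to correlate sessions.
    """
    if profile.sigma is None:
        raise ValueError(f"rater {profile.rater_id} has no perceptual sigma")
    m = np.asarray(maturity, dtype=float)
    if errors is None:
        errors = perceptual_errors(len(m), profile, rng)
    perceived = m + errors
    cuts = np.arange(1, 6) + 0.5 + np.asarray(profile.cut_shifts)
    ratings = 1 + (perceived[:, None] > cuts[None, :]).sum(axis=1)
    return np.clip(ratings, 1, 6)


def repeat_latent(maturity: np.ndarray, profile: RaterProfile,
                  primary_errors: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Second-session ratings with error correlation ``p_repeat``."""
    rho = profile.p_repeat
    fresh = perceptual_errors(len(primary_errors), profile, rng)
    errors = rho * primary_errors + np.sqrt(1.0 - rho**2) * fresh
    return rate_latent(maturity, profile, rng, errors=errors)


@dataclass
class CohortSpec:
    """Sampling plan of a synthetic cohort.

    ``stage_counts`` are exact subject counts per stage; the defaults follow
    the emulated study cohort (total 1380, stages peaking around the
    circumpubertal range).  ``n_repeat`` subjects are re-rated in a second
    session (for the intra-rater study).  ``jitter_sd`` is the isotropic
    annotation noise in pixels.
    """

    stage_counts: tuple[int, ...] = DEFAULT_STAGE_COUNTS
    age_means: tuple[float, ...] = DEFAULT_AGE_MEANS
    age_sd: float = DEFAULT_AGE_SD
    female_male_ratio: float = 1.12
    jitter_sd: float = 1.5
    n_repeat: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_counts) != 6 or any(c < 0 for c in self.stage_counts):
            raise ValueError("stage_counts must be six non-negative integers")
        if sum(self.stage_counts) == 0:
            raise ValueError("empty cohort spec")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def scaled(self, factor: float) -> "CohortSpec":
        """Same composition at a different size (largest-remainder rounding)."""
        counts = _largest_remainder(np.asarray(self.stage_counts) * factor)
        return replace(self, stage_counts=tuple(int(c) for c in counts))

    @property
    def n(self) -> int:
        return int(sum(self.stage_counts))


def _largest_remainder(target: np.ndarray) -> np.ndarray:
    """Round non-negative reals to integers preserving the rounded total."""
    floor = np.floor(target).astype(int)
    remainder = target - floor
    short = int(round(target.sum())) - int(floor.sum())
    order = np.argsort(-remainder, kind="stable")
    floor[order[:short]] += 1
    return floor


# --------------------------------------------------------------- geometry

#: subject body-scale model: lognormal around ~60 px inferior width
_BASE_WIDTH = 60.0
_WIDTH_SIGMA = 0.08
_DEPTH_SIGMA = 0.25   # multiplicative spread of concavity depth
_RATIO_SIGMA = 0.10   # multiplicative spread of body h/v ratio
_TAPER_SD = 0.03


def _vertebra_points(vertebra: str, depth_frac: float, hv_mean: float,
                     taper_frac: float, jitter_sd: float,
                     rng: np.random.Generator,
                     width: float | None = None) -> np.ndarray:
    """Core point layout for one vertebra given its shape parameters."""
    if width is None:
        width = float(_BASE_WIDTH * rng.lognormal(0.0, _WIDTH_SIGMA))
    depth = (depth_frac * width * rng.lognormal(0.0, _DEPTH_SIGMA)
             if depth_frac > 0 else 0.0)
    pts = [
        (0.0, 0.0),
        (0.25 * width, -0.6 * depth),
        (0.50 * width, -depth),
        (0.75 * width, -0.6 * depth),
        (width, 0.0),
    ]
    if vertebra != "C2":
        ratio = hv_mean * rng.lognormal(0.0, _RATIO_SIGMA)
        height = width / ratio
        taper = float(np.clip(taper_frac + rng.normal(0.0, _TAPER_SD),
                              0.5, 1.1))
        top_w = taper * width
        x0 = (width - top_w) / 2.0
        pts.append((x0, -height))
        pts.append((x0 + top_w, -height))
    coords = np.asarray(pts, dtype=float)
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
    return coords


def generate_vertebra(stage: int, vertebra: str, morph: StageMorphology,
                      jitter_sd: float, rng: np.random.Generator,
                      width: float | None = None) -> np.ndarray:
    """Ideal-plus-noise landmark coordinates of one vertebra, local frame.

    Returns points ordered as the landmark scheme numbers them: inferior
    border posterior → anterior (interior points at 1/4, 1/2, 3/4 of the
    chord, the middle one deepest), then for C3/C4 the posterior-superior
    and anterior-superior corners.  The inferior border lies at y = 0 with
    the body extending to negative y (image convention: up = smaller y).
    """
    if morph.stage != stage:
        raise ValueError("morphology row does not match requested stage")
    return _vertebra_points(vertebra, morph.concavity_depth_frac[vertebra],
                            morph.hv_ratio_mean, morph.taper_frac, jitter_sd,
                            rng, width=width)


def _interp_params(morph_table: list[StageMorphology], maturity: float,
                   vertebra: str) -> tuple[float, float, float]:
    """Shape parameters at a continuous maturity position.

    Stage anchors sit at integer maturities; between anchors the depth
    fraction, h/v ratio and taper interpolate linearly, so subjects near a
    stage boundary are genuinely intermediate in morphology.
    """
    table = sorted(morph_table, key=lambda m: m.stage)
    stages = np.array([m.stage for m in table], dtype=float)
    depth = np.interp(maturity, stages,
                      [m.concavity_depth_frac[vertebra] for m in table])
    hv = np.interp(maturity, stages, [m.hv_ratio_mean for m in table])
    taper = np.interp(maturity, stages, [m.taper_frac for m in table])
    return float(depth), float(hv), float(taper)


def _assemble_landmarks(maturity: float, morph_table: list[StageMorphology],
                        jitter_sd: float, rng: np.random.Generator,
                        scheme: LandmarkScheme) -> np.ndarray:
    """Stack C2 above C3 above C4 and apply a random rigid placement."""
    subject_scale = float(_BASE_WIDTH * rng.lognormal(0.0, _WIDTH_SIGMA))
    gap = 0.15 * subject_scale
    blocks, y_border = [], 0.0
    for v in scheme.vertebrae:
        width = subject_scale * rng.lognormal(0.0, 0.04)
        depth, hv, taper = _interp_params(morph_table, maturity, v.name)
        pts = _vertebra_points(v.name, depth, hv, taper, jitter_sd, rng,
                               width=width)
        if v.name != "C2":
            body_height = -pts[5:, 1].mean()
            y_border += gap + body_height
        pts = pts + np.array([rng.normal(0.0, 2.0), y_border])
        blocks.append(pts)
    coords = np.vstack(blocks)
    # random rigid placement: small tilt, generous offset keeps pixels >= 0
    theta = np.radians(rng.normal(0.0, 5.0))
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    centroid = coords.mean(axis=0)
    coords = (coords - centroid) @ rot.T + centroid
    coords = coords + np.array([300.0, 300.0]) + rng.uniform(-20, 20, 2)
    return coords


def generate_cohort(spec: CohortSpec,
                    morph_table: list[StageMorphology] | None = None,
                    profiles: list[RaterProfile] | None = None,
                    scheme: LandmarkScheme = DEFAULT_SCHEME) -> CohortTable:
    """Draw a full synthetic cohort: truth, demographics, landmarks, ratings.

    Each subject carries a latent continuous maturity uniform within its
    true stage's interval; the morphology and (for perceptual rater
    profiles) the ratings both derive from it, so borderline subjects are
    both morphologically intermediate and hard to rate — the cases real
    panels disagree on.
    """
    if profiles is not None and len(profiles) == 0:
        raise ValueError("need at least one rater profile")
    morph_table = morph_table if morph_table is not None else default_morphology()
    rng = np.random.default_rng(spec.seed)

    stages = np.repeat(np.arange(1, 7), spec.stage_counts)
    n = len(stages)
    ids = [f"S{i:05d}" for i in range(1, n + 1)]
    maturity = stages - 0.5 + rng.random(n)

    p_female = spec.female_male_ratio / (1.0 + spec.female_male_ratio)
    sexes = np.where(rng.random(n) < p_female, "female", "male")

    lo, hi = AGE_RANGE
    means = np.asarray(spec.age_means)[stages - 1]
    a = (lo - means) / spec.age_sd
    b = (hi - means) / spec.age_sd
    ages = np.atleast_1d(
        truncnorm.rvs(a, b, loc=means, scale=spec.age_sd, random_state=rng))

    subjects = {sid: Subject(sid, float(age), str(sex))
                for sid, age, sex in zip(ids, ages, sexes)}
    landmark_sets = {
        sid: LandmarkSet.from_array(
            sid, _assemble_landmarks(float(m), morph_table, spec.jitter_sd,
                                     rng, scheme))
        for sid, m in zip(ids, maturity)
    }

    panels: dict[str, RatingPanel] = {}
    if profiles:
        primary: dict[str, np.ndarray] = {}
        errors: dict[str, np.ndarray] = {}
        for p in profiles:
            if p.sigma is not None:
                errors[p.rater_id] = perceptual_errors(n, p, rng)
                primary[p.rater_id] = rate_latent(maturity, p, rng,
                                                  errors=errors[p.rater_id])
            else:
                primary[p.rater_id] = rate_many(stages, p, rng)
        repeat_idx = (rng.choice(n, size=min(spec.n_repeat, n), replace=False)
                      if spec.n_repeat else np.array([], dtype=int))
        repeats = {}
        for p in profiles:
            if p.sigma is not None:
                repeats[p.rater_id] = repeat_latent(
                    maturity[repeat_idx], p, errors[p.rater_id][repeat_idx],
                    rng)
            else:
                repeats[p.rater_id] = repeat_ratings(
                    primary[p.rater_id][repeat_idx], p, rng)
        repeat_pos = {int(i): j for j, i in enumerate(repeat_idx)}
        for i, sid in enumerate(ids):
            ratings = {rid: int(vals[i]) for rid, vals in primary.items()}
            rep = {}
            if i in repeat_pos:
                j = repeat_pos[i]
                rep = {rid: int(vals[j]) for rid, vals in repeats.items()}
            panels[sid] = RatingPanel(sid, ratings, rep)

    return CohortTable(
        subjects=subjects,
        landmark_sets=landmark_sets,
        panels=panels,
        true_stage={sid: int(st) for sid, st in zip(ids, stages)},
    )


# ------------------------------------------------------------- calibration

#: personal stage-boundary shifts (stage units) of the three default
#: simulated raters.  The first two share an over-staging convention at the
#: CS-3/CS-4 boundary, the third under-stages at CS-2/3 and CS-4/5 — so the
#: first pair agrees best and pairs with the third agree least, spreading
#: the pairwise kappas the way real panels' do
DEFAULT_CUT_SHIFTS = (
    (0.0, 0.0, 0.2, 0.0, 0.0),
    (0.0, 0.1, 0.2, 0.0, -0.1),
    (0.0, -0.2, -0.1, -0.2, 0.0),
)

#: blunder probability of a perceptual read; sets the rate at which panels
#: reach complete three-way disagreement (~8% of subjects)
DEFAULT_BLUNDER_P = 0.10

#: adjacent-error bias of the three simulated raters: neutral, toward
#: earlier stages, toward later stages — systematic rating tendencies
DEFAULT_RATER_BIASES = (0.5, 0.8, 0.2)

#: relative error rates of the three raters.  Pairwise kappa falls roughly
#: linearly in the sum of the two raters' error rates, so a panel whose
#: pairwise kappas spread like 0.78 / 0.62 / 0.68 around their mean implies
#: per-rater error rates proportional to (0.14, 0.08, 0.24); normalized:
DEFAULT_RATER_ERROR_MULTIPLIERS = (0.913, 0.522, 1.565)


def _panel_profiles(eps_base: float, biases, multipliers,
                    p_far: float) -> list[RaterProfile]:
    profs = []
    for i, (bias, m) in enumerate(zip(biases, multipliers)):
        err = float(np.clip(m * eps_base, 0.0, 1.0))
        far = min(p_far, err)  # far errors are part of the error budget
        profs.append(RaterProfile(f"R{i + 1}", p_exact=1.0 - err,
                                  adjacent_bias=bias, p_far=far))
    return profs


def _panel_ratings(eps_base: float, biases, multipliers, truth: np.ndarray,
                   us: np.ndarray, p_far: float) -> list[np.ndarray]:
    out = []
    for prof, u in zip(_panel_profiles(eps_base, biases, multipliers, p_far),
                       us):
        cum = prof.transition_matrix().cumsum(axis=1)[truth - 1]
        out.append((cum < u[:, None]).sum(axis=1) + 1)
    return out


def _mean_pairwise_kappa(eps_base: float, biases, multipliers,
                         truth: np.ndarray, us: np.ndarray, scheme: str,
                         p_far: float) -> float:
    r = _panel_ratings(eps_base, biases, multipliers, truth, us, p_far)
    kappas = [weighted_kappa(r[i], r[j], scheme=scheme, k=6)
              for i in range(3) for j in range(i + 1, 3)]
    return float(np.mean(kappas))


def _simulated_intra_kappa(p_repeat: float, primary: np.ndarray,
                           u: np.ndarray, scheme: str) -> float:
    prof = RaterProfile("cal", p_exact=0.5, p_repeat=p_repeat)
    cum = prof.repeat_matrix().cumsum(axis=1)[primary - 1]
    second = (cum < u[:, None]).sum(axis=1) + 1
    return weighted_kappa(primary, second, scheme=scheme, k=6)


def _bisect_increasing(fun, target: float, lo: float = 0.0, hi: float = 1.0,
                       iters: int = 40) -> float:
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if fun(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _perceptual_panel(sigma: float, shifts, maturity: np.ndarray,
                      z: np.ndarray, zb: np.ndarray, ub: np.ndarray,
                      p_blunder: float) -> list[np.ndarray]:
    """Ratings of three perceptual raters from common random numbers."""
    out = []
    for i in range(3):
        eta = np.where(ub[i] < p_blunder, zb[i] * _BLUNDER_SIGMA, z[i] * sigma)
        cuts = np.arange(1, 6) + 0.5 + np.asarray(shifts[i])
        r = 1 + ((maturity + eta)[:, None] > cuts[None, :]).sum(axis=1)
        out.append(np.clip(r, 1, 6))
    return out


def _perceptual_mean_kappa(sigma, shifts, maturity, z, zb, ub, p_blunder,
                           scheme) -> float:
    r = _perceptual_panel(sigma, shifts, maturity, z, zb, ub, p_blunder)
    return float(np.mean([weighted_kappa(r[i], r[j], scheme=scheme, k=6)
                          for i in range(3) for j in range(i + 1, 3)]))


def _perceptual_intra_kappa(rho, sigma, shift, maturity, e1, z2, zb2, ub2,
                            p_blunder, scheme) -> float:
    fresh = np.where(ub2 < p_blunder, zb2 * _BLUNDER_SIGMA, z2 * sigma)
    e2 = rho * e1 + np.sqrt(max(1.0 - rho**2, 0.0)) * fresh
    cuts = np.arange(1, 6) + 0.5 + np.asarray(shift)
    r1 = np.clip(1 + ((maturity + e1)[:, None] > cuts[None, :]).sum(axis=1), 1, 6)
    r2 = np.clip(1 + ((maturity + e2)[:, None] > cuts[None, :]).sum(axis=1), 1, 6)
    return weighted_kappa(r1, r2, scheme=scheme, k=6)


def _calibrate_perceptual(target_inter, target_intra, n_sim, rng, scheme,
                          p_blunder, cut_shifts, stage_probs):
    truth = rng.choice(np.arange(1, 7), size=n_sim, p=stage_probs)
    maturity = truth - 0.5 + rng.random(n_sim)
    z = rng.normal(size=(3, n_sim))
    zb = rng.normal(size=(3, n_sim))
    ub = rng.random((3, n_sim))
    z2, zb2 = rng.normal(size=(2, n_sim))
    ub2 = rng.random(n_sim)

    inter_mid = 0.5 * (target_inter[0] + target_inter[1])
    sigma_max = 3.0
    k_lo = _perceptual_mean_kappa(sigma_max, cut_shifts, maturity, z, zb, ub,
                                  p_blunder, scheme)
    k_hi = _perceptual_mean_kappa(0.0, cut_shifts, maturity, z, zb, ub,
                                  p_blunder, scheme)
    if not k_lo <= inter_mid <= k_hi:
        raise ValueError(
            f"inter-rater kappa target {inter_mid:.3f} unattainable; "
            f"achievable range is [{k_lo:.3f}, {k_hi:.3f}]")
    # kappa decreases with sigma, so bisect on the negated objective
    sigma = _bisect_increasing(
        lambda s: -_perceptual_mean_kappa(s, cut_shifts, maturity, z, zb,
                                          ub, p_blunder, scheme),
        -inter_mid, lo=0.0, hi=sigma_max)

    e1 = np.where(ub[0] < p_blunder, zb[0] * _BLUNDER_SIGMA, z[0] * sigma)
    intra_mid = 0.5 * (target_intra[0] + target_intra[1])
    k_lo_i = _perceptual_intra_kappa(0.0, sigma, cut_shifts[0], maturity, e1,
                                     z2, zb2, ub2, p_blunder, scheme)
    k_hi_i = _perceptual_intra_kappa(1.0, sigma, cut_shifts[0], maturity, e1,
                                     z2, zb2, ub2, p_blunder, scheme)
    if not k_lo_i <= intra_mid <= k_hi_i:
        raise ValueError(
            f"intra-rater kappa target {intra_mid:.3f} unattainable; "
            f"achievable range is [{k_lo_i:.3f}, {k_hi_i:.3f}]")
    rho = _bisect_increasing(
        lambda r: _perceptual_intra_kappa(r, sigma, cut_shifts[0], maturity,
                                          e1, z2, zb2, ub2, p_blunder,
                                          scheme),
        intra_mid)

    profiles = [
        RaterProfile(f"R{i + 1}", p_exact=1.0, p_far=p_blunder,
                     p_repeat=rho, sigma=sigma, cut_shifts=tuple(cut_shifts[i]))
        for i in range(3)
    ]
    ratings = _perceptual_panel(sigma, cut_shifts, maturity, z, zb, ub,
                                p_blunder)
    pairwise = {
        f"inter_kappa_R{i + 1}_R{j + 1}": weighted_kappa(
            ratings[i], ratings[j], scheme=scheme, k=6)
        for i in range(3) for j in range(i + 1, 3)
    }
    achieved = {
        **pairwise,
        "inter_kappa_mean": float(np.mean(list(pairwise.values()))),
        "intra_kappa": _perceptual_intra_kappa(
            rho, sigma, cut_shifts[0], maturity, e1, z2, zb2, ub2, p_blunder,
            scheme),
        "sigma": sigma,
        "rho_repeat": rho,
    }
    return profiles, achieved


def calibrate_profiles(target_inter_kappa: tuple[float, float],
                       target_intra_kappa: tuple[float, float],
                       n_sim: int = 2000,
                       rng: np.random.Generator | int | None = None,
                       scheme: str = "linear",
                       family: str = "perceptual",
                       p_far: float = 0.02,
                       p_blunder: float = DEFAULT_BLUNDER_P,
                       cut_shifts=DEFAULT_CUT_SHIFTS,
                       biases: tuple[float, float, float] = DEFAULT_RATER_BIASES,
                       multipliers: tuple[float, float, float] = DEFAULT_RATER_ERROR_MULTIPLIERS,
                       stage_probs: np.ndarray = DEFAULT_STAGE_PROBS,
                       ) -> tuple[list[RaterProfile], dict[str, float]]:
    """Find rater profiles whose simulated weighted kappas hit target ranges.

    Two noise families are supported.  The default *perceptual* family
    reads each subject's latent maturity through Gaussian noise and
    discretizes it at rater-specific shifted boundaries; the common noise
    SD is bisected until the mean pairwise inter-rater kappa sits at the
    centre of ``target_inter_kappa``, and the session-to-session error
    correlation likewise for the intra-rater target.  The *categorical*
    family is feature-independent: raters differ in adjacent-error
    direction (``biases``) and relative error rate (``multipliers``), and
    a base error rate (one minus ``p_exact``) and ``p_repeat`` are bisected
    the same way.  Common random numbers keep each objective monotone in
    its parameter.  Returns the three profiles (ids R1..R3) plus the
    achieved kappas.

    Raises ``ValueError`` when a target range is unattainable by the chosen
    noise family, reporting the nearest achievable values.
    """
    for name, (lo, hi) in (("inter", tuple(target_inter_kappa)),
                           ("intra", tuple(target_intra_kappa))):
        if not lo <= hi:
            raise ValueError(f"empty {name} target range [{lo}, {hi}]")
    rng = np.random.default_rng(rng)
    if family == "perceptual":
        return _calibrate_perceptual(
            tuple(target_inter_kappa), tuple(target_intra_kappa), n_sim, rng,
            scheme, p_blunder, cut_shifts, stage_probs)
    if family != "categorical":
        raise ValueError("family must be 'perceptual' or 'categorical'")
    truth = rng.choice(np.arange(1, 7), size=n_sim, p=stage_probs)
    us = rng.random((3, n_sim))
    u_intra = rng.random(n_sim)

    inter_mid = 0.5 * (target_inter_kappa[0] + target_inter_kappa[1])
    k_lo = _mean_pairwise_kappa(1.0, biases, multipliers, truth, us, scheme,
                                p_far)
    if inter_mid < k_lo or inter_mid > 1.0:
        raise ValueError(
            f"inter-rater kappa target {inter_mid:.3f} unattainable; "
            f"achievable range is [{k_lo:.3f}, 1.0]")
    eps_base = _bisect_increasing(
        lambda e: -_mean_pairwise_kappa(e, biases, multipliers, truth, us,
                                        scheme, p_far),
        -inter_mid)

    primary = _panel_ratings(eps_base, biases, multipliers, truth, us, p_far)
    intra_mid = 0.5 * (target_intra_kappa[0] + target_intra_kappa[1])
    k_lo_intra = _simulated_intra_kappa(0.0, primary[0], u_intra, scheme)
    if intra_mid < k_lo_intra or intra_mid > 1.0:
        raise ValueError(
            f"intra-rater kappa target {intra_mid:.3f} unattainable; "
            f"achievable range is [{k_lo_intra:.3f}, 1.0]")
    p_repeat = _bisect_increasing(
        lambda q: _simulated_intra_kappa(q, primary[0], u_intra, scheme),
        intra_mid)

    profiles = [replace(p, p_repeat=p_repeat)
                for p in _panel_profiles(eps_base, biases, multipliers, p_far)]
    pairwise = {
        f"inter_kappa_R{i + 1}_R{j + 1}": weighted_kappa(
            primary[i], primary[j], scheme=scheme, k=6)
        for i in range(3) for j in range(i + 1, 3)
    }
    achieved = {
        **pairwise,
        "inter_kappa_mean": float(np.mean(list(pairwise.values()))),
        "intra_kappa": _simulated_intra_kappa(p_repeat, primary[0], u_intra,
                                              scheme),
        "p_exact": [p.p_exact for p in profiles],
        "p_repeat": p_repeat,
    }
    return profiles, achieved
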