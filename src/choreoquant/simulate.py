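"""Seeded synthetic mother-machine dataset generator with ground truth.

The generator emulates the *statistical structure* of slow-growing
*E. coli* cell cycles in a mother machine: exponential single-cell growth
(mean cycle 133 min, mean birth length 1.71 um), grid-valued cell-cycle
event times (ori duplication, ter/MatP centralisation, stable nucleoid
constriction, ter-sister separation), asymmetric segregation of sister
origins to the quarter positions, a small inverted-orientation
subpopulation, localisation noise, missed focus detections and an
injectable device-frame channel offset.

Timing model
------------
Event times are drawn on the frame grid (multiples of the frame interval)
so that frame-grid detection is unbiased.  Marginal shapes are not printed
in the source data (only mean/sd/median), so they are fitted once from
parametric families at construction time:

* ``t_ori`` -- round-to-grid normal, clamped below at ``t_ori_floor_frames``
  (duplications earlier than that are truncated so mother backtracking is
  exercised but bounded);
* ``lag_delta = T_MatP - T_ori`` -- mixture of a short-lag cluster (floor
  to just under the median, geometric decay) and a ``median + Exp`` tail;
  the printed combination (median above the mean with sd comparable to the
  mean and a hard floor) forces substantial mass onto the shortest lag;
* ``nuc_lag = T_Nucleoid - T_MatP`` -- shifted gamma.

A Gaussian copula couples the draws.  The correlation between ``t_ori``
and ``lag_delta`` (-0.49) is derived from the printed standard deviations
(independent draws would give sd(T_MatP) = sqrt(28^2 + 23.2^2) = 36.4, far
above the printed 26.1); likewise the small negative correlation of
``nuc_lag`` with the upstream times.  Positive correlations with cycle
duration keep event times inside their own cycles, as they trivially are
in measured data; residual infeasibility is resolved by conditional
(inverse-CDF truncated) draws, mirroring the fact that the printed
statistics are statistics of *detected* (hence feasible) events.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import CellCycle, ChannelFoci, ChoreoQuantError, Dataset

__all__ = ["GeneratorParams", "GroundTruth", "ParameterError",
           "generate_dataset", "make_newborn_profiles"]


class ParameterError(ChoreoQuantError):
    """Inconsistent generator parameterisation."""


# ---------------------------------------------------------------------------
# grid-valued distributions
# ---------------------------------------------------------------------------

@dataclass
class GridDist:
    """A probability mass function on an equally spaced value grid."""

    values: np.ndarray
    pmf: np.ndarray
    cdf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pmf = np.asarray(self.pmf, dtype=float)
        self.pmf = self.pmf / self.pmf.sum()
        self.cdf = np.cumsum(self.pmf)
        self.cdf[-1] = 1.0

    @property
    def mean(self) -> float:
        return float((self.values * self.pmf).sum())

    @property
    def sd(self) -> float:
        return float(math.sqrt((self.values ** 2 * self.pmf).sum()
                               - self.mean ** 2))

    @property
    def median(self) -> float:
        return float(self.values[np.searchsorted(self.cdf, 0.5,
                                                 side="left")])

    def ppf(self, u: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.cdf, u, side="right")
        return self.values[np.clip(idx, 0, len(self.values) - 1)]

    def ppf_window(self, u: np.ndarray, lo, hi) -> np.ndarray:
        """Quantile of the distribution conditioned on ``lo <= X <= hi``.

        ``lo``/``hi`` may be per-sample arrays.  An empty window collapses
        to the grid value nearest its lower edge.
        """
        u = np.asarray(u, dtype=float)
        lo = np.broadcast_to(np.asarray(lo, dtype=float), u.shape)
        hi = np.broadcast_to(np.asarray(hi, dtype=float), u.shape)
        i_lo = np.searchsorted(self.values, lo, side="left")
        i_hi = np.searchsorted(self.values, hi, side="right") - 1
        i_lo = np.clip(i_lo, 0, len(self.values) - 1)
        i_hi_c = np.clip(i_hi, 0, len(self.values) - 1)
        f_lo = np.where(i_lo > 0, self.cdf[np.maximum(i_lo - 1, 0)], 0.0)
        f_hi = self.cdf[i_hi_c]
        span = np.maximum(f_hi - f_lo, 0.0)
        u2 = f_lo + u * span
        idx = np.searchsorted(self.cdf, u2, side="right")
        idx = np.clip(idx, i_lo, np.maximum(i_hi_c, i_lo))
        return self.values[idx]


def grid_normal(mean: float, sd: float, lo: float, hi: float,
                grid: float) -> GridDist:
    """Normal rounded to the grid, with tail mass clamped onto the ends."""
    v = np.arange(lo, hi + grid / 2, grid)
    upper = stats.norm.cdf(v + grid / 2, mean, sd)
    lower = stats.norm.cdf(v - grid / 2, mean, sd)
    p = upper - lower
    p[0] += stats.norm.cdf(v[0] - grid / 2, mean, sd)
    p[-1] += stats.norm.sf(v[-1] + grid / 2, mean, sd)
    return GridDist(v, p)


def _fit_short_lag_mixture(mean: float, sd: float, median: float,
                           floor: float, grid: float,
                           under_median_mass: float = 0.46) -> GridDist:
    """Fit the ori->ter lag family to (mean, sd, grid median).

    Mixture of a geometric-decay cluster on ``{floor, ..., median - grid}``
    and a discretised ``median + Exp(tau)`` tail; the mixture weight, the
    cluster decay scale and ``tau`` are solved so that the pmf reproduces
    the target mean and sd with ``P(X < median) = under_median_mass``
    (which pins the sample median to ``median`` at large n).
    """
    lv = np.arange(floor, median, grid)
    rv = np.arange(median, median + 60 * grid, grid)

    def build(m, lam, tau):
        lw = np.exp(-(lv - floor) / lam)
        lw = lw / lw.sum()
        rw = np.exp(-(rv - median) / tau)
        rw = rw / rw.sum()
        return np.concatenate([lv, rv]), np.concatenate(
            [m * lw, (1 - m) * rw])

    def resid(x):
        m, lam, tau = x
        v, p = build(m, abs(lam), abs(tau))
        mu = (v * p).sum()
        s2 = (v ** 2 * p).sum() - mu ** 2
        return [mu - mean, math.sqrt(max(s2, 0)) - sd,
                p[v < median].sum() - under_median_mass]

    sol = optimize.root(resid, [under_median_mass, grid / 3, sd * 0.75])
    if not sol.success or not (0 < sol.x[0] < 1):
        raise ParameterError(
            f"cannot realise lag distribution with mean={mean}, sd={sd}, "
            f"median={median}, floor={floor}")
    v, p = build(sol.x[0], abs(sol.x[1]), abs(sol.x[2]))
    return GridDist(v, p)


def _fit_shifted_gamma(mean: float, sd: float, median: float,
                       floor: float, grid: float) -> GridDist:
    """Fit the MatP->nucleoid lag family: shift + gamma, rounded, floored."""
    vv = np.arange(floor, mean + 15 * sd, grid)

    def build(k, theta, s):
        hi = stats.gamma.cdf(vv + grid / 2 - s, k, scale=theta)
        lo = stats.gamma.cdf(vv - grid / 2 - s, k, scale=theta)
        p = hi - lo
        p[0] += stats.gamma.cdf(vv[0] - grid / 2 - s, k, scale=theta)
        return p

    def resid(x):
        k, theta, s = abs(x[0]), abs(x[1]), x[2]
        p = build(k, theta, s)
        tot = p.sum()
        if tot <= 0:
            return [1e3, 1e3, 1e3]
        p = p / tot
        mu = (vv * p).sum()
        s2 = (vv ** 2 * p).sum() - mu ** 2
        med_cont = s + stats.gamma.ppf(0.5, k, scale=theta)
        return [mu - mean, math.sqrt(max(s2, 0)) - sd,
                med_cont - (median - grid / 10)]

    sol = optimize.root(resid, [(mean / sd) ** 2, sd ** 2 / mean, floor])
    if not sol.success:
        raise ParameterError(
            f"cannot realise lag distribution with mean={mean}, sd={sd}, "
            f"median={median}")
    p = build(abs(sol.x[0]), abs(sol.x[1]), sol.x[2])
    return GridDist(vv, p)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class GeneratorParams:
    """Full parameterisation of the synthetic mother-machine world.

    Defaults reproduce the slow-growth (glucose) study conditions; mutant
    datasets are alternative parameterisations (e.g. ``p_seg_defect ~ 0.46``
    for an ori-segregation-defective labelling system).  Spreads that are
    not printed in the source data (cycle-duration sd, birth-length sd,
    noise levels) are generator knobs with stated defaults, not claims
    about measured data.
    """

    n_cycles: int = 1000
    seed: int = 0
    frame_interval_min: float = 5.0
    pixel_size_um: float = 0.065

    # growth
    cycle_duration_mean_min: float = 133.0
    cycle_duration_sd_min: float = 27.0
    birth_length_um: float = 1.71
    birth_length_sd_um: float = 0.17
    cell_width_um: float = 0.70

    # event timing (all minutes, drawn on the frame grid)
    t_ori_mean_min: float = 26.6
    t_ori_sd_min: float = 28.0
    t_ori_floor_frames: int = -4
    lag_delta_mean_min: float = 26.5
    lag_delta_sd_min: float = 23.2
    lag_delta_median_min: float = 30.0
    lag_delta_floor_min: float = 5.0
    nuc_lag_mean_min: float = 51.5
    nuc_lag_sd_min: float = 38.1
    nuc_lag_median_min: float = 40.0
    tersep_before_division_frames: int = 2

    # copula correlations (latent, Gaussian)
    corr_ori_delta: float = -0.49
    corr_nuclag_upstream: float = -0.06
    corr_duration_timing: float = 0.30
    corr_duration_nuclag: float = 0.60

    # geometry of the locus choreography (fractions of cell length)
    ori_birth_offset_frac: float = 0.05
    ori_target_frac: float = 0.25
    matp_birth_frac: float = -0.40
    matp_edge_frac: float = -0.30
    left_locus_frac: float | None = None
    right_locus_frac: float | None = None
    arm_sister_frac: float = 0.10

    # nucleoid profiles
    emit_profiles: bool = True
    nucleoid_bias: float = 0.05
    dip_depth_onset: float = 0.20
    dip_depth_ramp: float = 0.03
    dip_depth_max: float = 0.85
    profile_noise_sd: float = 0.04

    # measurement imperfections
    loc_noise_px: float = 0.5
    p_missed: float = 0.03
    channel_offset_px: float = 0.0
    offset_channel: str = "ori"

    # subpopulations
    p_inverted: float = 0.007
    p_seg_defect: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_missed", "p_inverted", "p_seg_defect"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        for name in ("ori_birth_offset_frac", "ori_target_frac",
                     "matp_birth_frac", "matp_edge_frac",
                     "arm_sister_frac"):
            v = getattr(self, name)
            if not -0.5 <= v <= 0.5:
                raise ParameterError(f"{name} must be in [-0.5, 0.5]")
        if self.matp_edge_frac >= 0:
            raise ParameterError("matp_edge_frac must be negative "
                                 "(new-pole proximal)")
        if self.matp_birth_frac >= self.matp_edge_frac:
            raise ParameterError(
                "matp_birth_frac must lie new-pole-ward of matp_edge_frac")
        for name in ("frame_interval_min", "pixel_size_um",
                     "cycle_duration_mean_min", "cycle_duration_sd_min",
                     "birth_length_um", "birth_length_sd_um",
                     "cell_width_um", "t_ori_sd_min", "lag_delta_sd_min",
                     "nuc_lag_sd_min"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        try:
            np.linalg.cholesky(self.copula_matrix())
        except np.linalg.LinAlgError:
            raise ParameterError(
                "copula correlations do not form a positive-definite "
                "matrix") from None

    def copula_matrix(self) -> np.ndarray:
        """Latent correlations, order (duration, t_ori, lag_delta, nuc_lag)."""
        rdt = self.corr_duration_timing
        rdn = self.corr_duration_nuclag
        rol = self.corr_ori_delta
        rnu = self.corr_nuclag_upstream
        return np.array([
            [1.0, rdt, rdt, rdn],
            [rdt, 1.0, rol, rnu],
            [rdt, rol, 1.0, rnu],
            [rdn, rnu, rnu, 1.0],
        ])

    # marginal grid distributions --------------------------------------
    def duration_dist(self) -> GridDist:
        g = self.frame_interval_min
        return grid_normal(self.cycle_duration_mean_min,
                           self.cycle_duration_sd_min,
                           lo=10 * g, hi=59 * g, grid=g)

    def t_ori_dist(self) -> GridDist:
        g = self.frame_interval_min
        return grid_normal(self.t_ori_mean_min, self.t_ori_sd_min,
                           lo=self.t_ori_floor_frames * g,
                           hi=self.t_ori_mean_min + 12 * self.t_ori_sd_min,
                           grid=g)

    def lag_delta_dist(self) -> GridDist:
        return _fit_short_lag_mixture(
            self.lag_delta_mean_min, self.lag_delta_sd_min,
            self.lag_delta_median_min, self.lag_delta_floor_min,
            self.frame_interval_min)

    def nuc_lag_dist(self) -> GridDist:
        return _fit_shifted_gamma(
            self.nuc_lag_mean_min, self.nuc_lag_sd_min,
            self.nuc_lag_median_min, self.frame_interval_min,
            self.frame_interval_min)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class GroundTruth:
    """Generative truth for the subject cycles of a synthetic dataset."""

    table: pd.DataFrame
    channel_offset_px: float
    offset_channel: str

    def for_cycle(self, cell_id: str) -> pd.Series:
        return self.table.set_index("cell_id").loc[cell_id]


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def _nucleoid_profile(length_px: float, age: float, bias_frac: float,
                      inverted: bool, dip_depth: float,
                      noise_sd: float, rng: np.random.Generator
                      ) -> np.ndarray:
    """One line profile: plateau with shoulders, age-decaying new-pole bias
    and an optional central dip of given relative depth."""
    npix = int(round(length_px))
    xs = np.arange(npix) + 0.5
    bias = bias_frac * length_px * max(0.0, 1.0 - 2.0 * age)
    centre = length_px / 2.0 + (bias if inverted else -bias)
    width = 0.35 * length_px
    prof = 1.0 / (1.0 + ((xs - centre) / width) ** 8)
    if dip_depth > 0:
        sigma = 0.08 * length_px
        prof = prof * (1.0 - dip_depth
                       * np.exp(-((xs - length_px / 2.0) / sigma) ** 2))
    if noise_sd > 0:
        prof = prof * np.clip(
            1.0 + rng.normal(0.0, noise_sd, npix), 0.0, None)
    return prof


def make_newborn_profiles(params: GeneratorParams, n: int
                          ) -> list[np.ndarray]:
    """Unconstricted newborn nucleoid profiles (for threshold derivation)."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng([params.seed % (2 ** 31), 929])
    l0 = np.clip(rng.normal(params.birth_length_um,
                            params.birth_length_sd_um, n),
                 0.8, None) / params.pixel_size_um
    return [_nucleoid_profile(l, 0.0, params.nucleoid_bias, False, 0.0,
                              params.profile_noise_sd, rng)
            for l in l0]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _foci_track(per_frame: list[tuple[int, float]],
                intensities: np.ndarray) -> ChannelFoci:
    frames = np.array([f for f, _ in per_frame], dtype=np.int64)
    xs = np.array([x for _, x in per_frame], dtype=float)
    return ChannelFoci(frames, xs, intensities)


def generate_dataset(params: GeneratorParams
                     ) -> tuple[Dataset, GroundTruth]:
    """Generate a synthetic dataset plus its generative ground truth.

    Deterministic given ``params`` (including the seed).  Subject cycles
    are listed in the ground-truth table; auxiliary mother cycles (created
    whenever a subject's ori duplication pre-dates its birth, so that
    mother backtracking can recover the negative time) are part of the
    dataset but not of the subject cohort.
    """
    p = params
    g = p.frame_interval_min
    rng = np.random.default_rng(p.seed % (2 ** 31))
    n = p.n_cycles

    chol = np.linalg.cholesky(p.copula_matrix())
    z = rng.standard_normal((n, 4)) @ chol.T
    u = stats.norm.cdf(z)

    dur_dist = p.duration_dist()
    t_ori_dist = p.t_ori_dist()
    delta_dist = p.lag_delta_dist()
    nuclag_dist = p.nuc_lag_dist()

    d_min = dur_dist.ppf(u[:, 0])
    n_f = np.round(d_min / g).astype(int) + 1

    t_ori = t_ori_dist.ppf_window(
        u[:, 1], lo=np.full(n, t_ori_dist.values[0]), hi=(n_f - 8) * g)
    lo_d = np.maximum(p.lag_delta_floor_min, g - t_ori)
    hi_d = (n_f - 6) * g - t_ori
    delta = delta_dist.ppf_window(u[:, 2], lo_d, hi_d)
    t_matp = t_ori + delta
    # A cycle whose constriction would complete after division constricts
    # at division: overlong lags are clamped to the cycle end (pile-up at
    # the last frame) rather than redistributed over earlier frames.
    hi_lag = (n_f - 1) * g - t_matp
    nuc_lag = np.clip(nuclag_dist.ppf(u[:, 3]),
                      nuclag_dist.values[0], hi_lag)
    t_nuc = t_matp + nuc_lag

    l0_px = np.clip(rng.normal(p.birth_length_um, p.birth_length_sd_um, n),
                    0.8, None) / p.pixel_size_um
    width_px = p.cell_width_um / p.pixel_size_um

    seg_defect = rng.random(n) < p.p_seg_defect
    inverted = (rng.random(n) < p.p_inverted) & ~seg_defect
    flipped = rng.random(n) < 0.5
    as_daughter1 = rng.random(n) < 0.5

    cycles: list[CellCycle] = []
    truth_rows: list[dict] = []

    for i in range(n):
        cid = f"c{i:06d}"
        ni = int(n_f[i])
        t_o, t_m, t_nu = float(t_ori[i]), float(t_matp[i]), float(t_nuc[i])
        f_matp = int(round(t_m / g))
        f_nuc = int(round(t_nu / g))
        f_tersep = ni - 1 - p.tersep_before_division_frames
        t_min = np.arange(ni) * g
        lengths = l0_px[i] * 2.0 ** (np.arange(ni) / (ni - 1))
        areas = lengths * width_px
        sign = -1.0 if inverted[i] else 1.0

        per_channel: dict[str, list[tuple[int, float]]] = {}

        def add(channel: str, frame: int, r: float) -> None:
            x = (sign * r + 0.5) * lengths[frame]
            per_channel.setdefault(channel, []).append((frame, x))

        if seg_defect[i]:
            # unsegregated ori: single mid-cell focus throughout
            for f in range(ni):
                add("ori", f, 0.0)
            # MatP visits mid-cell only transiently, then sisters move
            # outward producing inverted daughters
            f_touch = min(f_matp, ni - 5)
            for f in range(ni):
                if f < f_touch:
                    frac = f / max(f_touch - 1, 1)
                    add("matp", f, p.matp_birth_frac
                        + (p.matp_edge_frac - p.matp_birth_frac) * frac)
                elif f < f_touch + 2:
                    add("matp", f, 0.0)
                else:
                    prog = (f - f_touch - 2) / max(ni - f_touch - 3, 1)
                    r_out = 0.10 + 0.25 * prog
                    add("matp", f, -r_out)
                    add("matp", f, +r_out)
            true_t_ori = np.nan
            true_t_matp = np.nan
            true_tersep = float(f_touch + 2)
        else:
            b = p.ori_birth_offset_frac
            tgt = p.ori_target_frac
            for f in range(ni):
                t = t_min[f]
                if t < t_o:
                    add("ori", f, b)
                else:
                    prog = min((t - t_o) / (t_m - t_o), 1.0)
                    split = 0.01 * (1.0 - prog)
                    add("ori", f, b + prog * (-tgt - b) - split)
                    add("ori", f, b + prog * (tgt - b) + split)
            for f in range(ni):
                if f < f_matp:
                    frac = f / max(f_matp - 1, 1)
                    add("matp", f, p.matp_birth_frac
                        + (p.matp_edge_frac - p.matp_birth_frac) * frac)
                elif f < f_tersep:
                    add("matp", f, 0.0)
                else:
                    r_sep = 0.10 + 0.04 * (f - f_tersep)
                    add("matp", f, -r_sep)
                    add("matp", f, +r_sep)
            for channel, frac in (("left", p.left_locus_frac),
                                  ("right", p.right_locus_frac)):
                if frac is None:
                    continue
                for f in range(ni):
                    if f < f_matp:
                        add(channel, f, frac)
                    else:
                        add(channel, f, -p.arm_sister_frac)
                        add(channel, f, +p.arm_sister_frac)
            true_t_ori = float(round(t_o / g))
            true_t_matp = float(f_matp)
            true_tersep = float(f_tersep)

        profiles = None
        if p.emit_profiles:
            profiles = []
            ages = np.arange(ni) / (ni - 1)
            for f in range(ni):
                depth = 0.0
                if f >= f_nuc:
                    depth = min(p.dip_depth_max, p.dip_depth_onset
                                + p.dip_depth_ramp * (f - f_nuc))
                profiles.append(_nucleoid_profile(
                    lengths[f], float(ages[f]), p.nucleoid_bias,
                    bool(inverted[i]), depth, p.profile_noise_sd, rng))

        foci: dict[str, ChannelFoci] = {}
        for channel, obs in per_channel.items():
            track = _foci_track(
                obs, rng.lognormal(0.0, 0.25, len(obs)))
            if p.loc_noise_px > 0:
                track.x_px = track.x_px + rng.normal(
                    0.0, p.loc_noise_px, len(track))
            if channel == p.offset_channel and p.channel_offset_px != 0:
                shift = (-p.channel_offset_px if flipped[i]
                         else p.channel_offset_px)
                track.x_px = track.x_px + shift
            track.x_px = np.clip(track.x_px, 0.0,
                                 lengths[track.frames])
            if p.p_missed > 0:
                keep = rng.random(len(track)) >= p.p_missed
                track = ChannelFoci(track.frames[keep], track.x_px[keep],
                                    track.intensity[keep])
            foci[channel] = track

        mother_id = None
        birth_abs = 0
        if not seg_defect[i] and true_t_ori < 0:
            mother, birth_abs = _make_mother(
                cid, int(-true_t_ori), bool(as_daughter1[i]),
                bool(flipped[i]), p, rng)
            mother_id = mother.cell_id
            cycles.append(mother)

        cycles.append(CellCycle(
            cell_id=cid,
            birth_frame_abs=birth_abs,
            lengths_px=lengths,
            areas_px2=areas,
            foci=foci,
            profiles=profiles,
            mother_id=mother_id,
            device_flipped=bool(flipped[i]),
            polarity_known=True,
        ))

        truth_rows.append({
            "cell_id": cid,
            "t_ori_frames": true_t_ori,
            "t_matp_frames": true_t_matp,
            "t_nuc_frames": float(f_nuc),
            "t_tersep_frames": true_tersep,
            "orientation": "inverted" if inverted[i] else "normal",
            "seg_defect": bool(seg_defect[i]),
        })

    truth = pd.DataFrame(truth_rows)
    for col in ("t_ori", "t_matp", "t_nuc", "t_tersep"):
        truth[f"{col}_min"] = truth[f"{col}_frames"] * g
    return Dataset(cycles), GroundTruth(truth, p.channel_offset_px,
                                        p.offset_channel)


def _make_mother(cid: str, k_frames: int, as_daughter1: bool,
                 subject_flipped: bool, p: GeneratorParams,
                 rng: np.random.Generator) -> tuple[CellCycle, int]:
    """Auxiliary mother cycle showing a second replication initiation
    ``k_frames`` before its division, in both halves."""
    g = p.frame_interval_min
    d = float(np.clip(round(rng.normal(p.cycle_duration_mean_min,
                                       p.cycle_duration_sd_min) / g) * g,
                      10 * g, 59 * g))
    n_m = max(int(round(d / g)) + 1, k_frames + 3)
    f_rise = n_m - k_frames
    l0 = float(np.clip(rng.normal(p.birth_length_um,
                                  p.birth_length_sd_um), 0.8, None)
               / p.pixel_size_um)
    lengths = l0 * 2.0 ** (np.arange(n_m) / (n_m - 1))
    areas = lengths * p.cell_width_um / p.pixel_size_um
    mother_flipped = subject_flipped if as_daughter1 else not subject_flipped
    per: dict[str, list[tuple[int, float]]] = {"ori": [], "matp": []}
    for f in range(n_m):
        if f < f_rise:
            per["ori"].append((f, (0.25 + 0.5) * lengths[f]))
            per["ori"].append(((f), (-0.25 + 0.5) * lengths[f]))
        else:
            for r in (0.22, 0.28, -0.22, -0.28):
                per["ori"].append((f, (r + 0.5) * lengths[f]))
        if f < n_m - 3:
            per["matp"].append((f, 0.5 * lengths[f]))
        else:
            per["matp"].append((f, (0.10 + 0.5) * lengths[f]))
            per["matp"].append((f, (-0.10 + 0.5) * lengths[f]))
    foci = {}
    for channel, obs in per.items():
        track = _foci_track(obs, rng.lognormal(0.0, 0.25, len(obs)))
        if p.loc_noise_px > 0:
            track.x_px = track.x_px + rng.normal(0.0, p.loc_noise_px,
                                                 len(track))
        if channel == p.offset_channel and p.channel_offset_px != 0:
            shift = (-p.channel_offset_px if mother_flipped
                     else p.channel_offset_px)
            track.x_px = track.x_px + shift
        track.x_px = np.clip(track.x_px, 0.0, lengths[track.frames])
        if p.p_missed > 0:
            keep = rng.random(len(track)) >= p.p_missed
            track = ChannelFoci(track.frames[keep], track.x_px[keep],
                                track.intensity[keep])
        foci[channel] = track
    mother = CellCycle(
        cell_id=cid + "m",
        birth_frame_abs=0,
        lengths_px=lengths,
        areas_px2=areas,
        foci=foci,
        daughter_ids=(cid, None) if as_daughter1 else (None, cid),
        device_flipped=mother_flipped,
        polarity_known=True,
    )
    return mother, n_m
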