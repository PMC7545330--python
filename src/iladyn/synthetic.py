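"""Synthetic multi-method ILA study generator.

All three assessment methods sample one shared per-person latent affect
process, a stationary bivariate VAR(1) on a fixed hourly grid with
person-random set-points, autoregressive/cross-lagged coefficients, and
innovation scales. This makes every downstream dynamics measure (SD,
RMSSD, autoregressive slope, network density, within-person correlation)
a quantity with a known population value, so the generator doubles as a
parameter-recovery oracle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import solve_discrete_lyapunov

from .data_model import (
    AffectObservation,
    DRMEpisode,
    Method,
    PersonSeries,
    StudyDataset,
    drm_raw_from_score,
    write_episodes_csv,
    write_health_csv,
    write_observations_csv,
)

__all__ = [
    "GeneratorConfig",
    "PersonParams",
    "GroundTruth",
    "generate_prompt_schedule",
    "draw_person_params",
    "simulate_latent_process",
    "sample_ema",
    "sample_eod",
    "sample_drm",
    "generate_health",
    "generate_study",
    "write_study",
]

BASE_DATE = date(2020, 1, 6)  # study day 1


@dataclass
class GeneratorConfig:
    """Latent-process, schedule, and health-model parameters with a seed.

    Person-level parameters are drawn per person: set-points (NA from a
    shifted right-skewed distribution so floor effects at 0 appear),
    AR/cross-lag coefficients (truncated for stationarity), and
    innovation SDs (log-normal, so within-person variance differs
    between persons).
    """

    n_persons: int = 90
    n_days: int = 7
    prompts_per_day: int = 6
    step_hours: float = 1.0
    window_start_hour: float = 8.0
    window_end_hour: float = 20.0
    eod_hour: float = 21.0

    pa_setpoint_mean: float = 66.0
    pa_setpoint_sd: float = 15.0
    na_setpoint_mean: float = 12.0
    na_setpoint_sd: float = 10.0

    ar_mean: float = 0.40
    ar_sd: float = 0.12
    cross_mean: float = -0.05
    cross_sd: float = 0.05

    innovation_sd_pa_mean: float = 8.0
    innovation_sd_pa_sd: float = 2.5
    innovation_sd_na_mean: float = 6.0
    innovation_sd_na_sd: float = 2.0
    # person-level PA-NA innovation correlation (the true dialecticism
    # driver); drawn per person so dialecticism carries real signal
    innovation_corr: float = -0.3
    innovation_corr_sd: float = 0.3

    # iid day-level latent shock (shared by every method sampling that day),
    # so end-of-day summaries retain real between-day variance
    day_shock_sd_pa: float = 6.0
    day_shock_sd_na: float = 4.0

    noise_sd_ema: float = 5.0
    noise_sd_eod: float = 4.0
    noise_sd_drm: float = 4.0

    eod_summary: str = "day_mean"  # or "peak_end"
    completion_prob: float = 1.0

    episode_count_mean: float = 12.0
    episode_count_min: int = 5
    episode_count_max: int = 20
    episode_duration_shape: float = 2.0

    # daily health outcomes as linear functions of true person parameters
    gh_intercept: float = 4.4
    gh_pa_set: float = 0.010
    gh_na_set: float = -0.050
    gh_noise_sd: float = 0.5
    pain_intercept: float = 4.0
    pain_na_set: float = 1.2
    pain_na_isd: float = 0.8
    pain_noise_sd: float = 12.0
    fatigue_intercept: float = 16.0
    fatigue_pa_set: float = -0.10
    fatigue_na_set: float = 1.4
    fatigue_noise_sd: float = 12.0

    seed: int = 0

    def __post_init__(self):
        if self.prompts_per_day < 1:
            raise ValueError("prompts_per_day must be >= 1")
        if self.window_end_hour <= self.window_start_hour:
            raise ValueError("waking window must have positive length")
        for f in fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.eod_summary not in ("day_mean", "peak_end"):
            raise ValueError(f"unknown eod_summary {self.eod_summary!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PersonParams:
    """True latent-process parameters of one person."""

    person_id: str
    pa_set: float
    na_set: float
    a_pp: float  # PA autoregression
    a_pn: float  # lagged NA -> PA
    a_np: float  # lagged PA -> NA
    a_nn: float  # NA autoregression
    isd_pa: float
    isd_na: float
    icorr: float = 0.0  # PA-NA innovation correlation

    @property
    def transition(self) -> np.ndarray:
        return np.array([[self.a_pp, self.a_pn], [self.a_np, self.a_nn]])

    @property
    def innovation_cov(self) -> np.ndarray:
        return np.array([[self.isd_pa**2, 0.0], [0.0, self.isd_na**2]])

    def innovation_cov_with_corr(self, corr: float) -> np.ndarray:
        c = corr * self.isd_pa * self.isd_na
        return np.array([[self.isd_pa**2, c], [c, self.isd_na**2]])

    def stationary_cov(self, innovation_corr: float = 0.0) -> np.ndarray:
        """Exact stationary covariance of the latent VAR(1)."""
        return solve_discrete_lyapunov(
            self.transition, self.innovation_cov_with_corr(innovation_corr)
        )


@dataclass
class GroundTruth:
    """Per-person true parameters plus the full latent traces."""

    params: pd.DataFrame  # one row per person
    traces: dict[str, np.ndarray]  # person -> (n_steps, 2) latent PA/NA
    grid_hours: np.ndarray
    config: GeneratorConfig

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "params": self.params.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def generate_prompt_schedule(
    window_start: float, window_end: float, n: int, rng: np.random.Generator
) -> list[float]:
    """Random prompt times (clock hours) for one day.

    The first prompt falls one random spacing after the window start;
    each spacing is uniform on ``[0.75 * W/n, 1.10 * W/n]`` where ``W``
    is the window length in hours. Prompts past the window end are
    truncated, so fewer than ``n`` prompts may be returned.
    """
    if window_end <= window_start:
        raise ValueError("degenerate prompt window")
    if n < 1:
        raise ValueError("n must be >= 1")
    w = window_end - window_start
    lo, hi = 0.75 * w / n, 1.10 * w / n
    times = []
    t = window_start
    for _ in range(n):
        t += rng.uniform(lo, hi)
        if t > window_end:
            break
        times.append(t)
    return times


def draw_person_params(
    person_id: str, cfg: GeneratorConfig, rng: np.random.Generator
) -> PersonParams:
    """Draw one person's true parameters; redraw until stationary."""
    pa_set = rng.normal(cfg.pa_setpoint_mean, cfg.pa_setpoint_sd)
    na_set = _shifted_lognormal(cfg.na_setpoint_mean, cfg.na_setpoint_sd, rng)
    isd_pa = _lognormal(cfg.innovation_sd_pa_mean, cfg.innovation_sd_pa_sd, rng)
    isd_na = _lognormal(cfg.innovation_sd_na_mean, cfg.innovation_sd_na_sd, rng)
    icorr = float(
        np.clip(rng.normal(cfg.innovation_corr, cfg.innovation_corr_sd), -0.9, 0.9)
    )
    for _ in range(100):
        a_pp = rng.normal(cfg.ar_mean, cfg.ar_sd)
        a_nn = rng.normal(cfg.ar_mean, cfg.ar_sd)
        a_pn = rng.normal(cfg.cross_mean, cfg.cross_sd)
        a_np = rng.normal(cfg.cross_mean, cfg.cross_sd)
        a = np.array([[a_pp, a_pn], [a_np, a_nn]])
        if np.all(np.abs(a.diagonal()) < 1) and _spectral_radius(a) < 0.95:
            break
    else:
        raise RuntimeError("could not draw a stationary transition matrix")
    return PersonParams(
        person_id, pa_set, na_set, a_pp, a_pn, a_np, a_nn, isd_pa, isd_na, icorr
    )


def _spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def _lognormal(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return mean
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _shifted_lognormal(mean: float, sd: float, rng: np.random.Generator) -> float:
    # right-skewed set-points with a hard floor at 0
    return _lognormal(mean, sd, rng) if sd > 0 else mean


def simulate_latent_process(
    params: PersonParams,
    n_steps: int,
    rng: np.random.Generator,
    innovation_corr: float = 0.0,
) -> np.ndarray:
    """Stationary bivariate VAR(1) trace of shape ``(n_steps, 2)``.

    Initialized from the exact stationary distribution and shifted by the
    person's set-points. The latent state is *not* clipped; clipping to
    [0, 100] happens only at sampling time.
    """
    a = params.transition
    if _spectral_radius(a) >= 1.0:
        raise ValueError("non-stationary transition matrix")
    sig = params.innovation_cov_with_corr(innovation_corr)
    mu = np.array([params.pa_set, params.na_set])
    if np.allclose(sig, 0.0):
        return np.tile(mu, (n_steps, 1))
    v0 = params.stationary_cov(innovation_corr)
    x = np.empty((n_steps, 2))
    chol_v0 = np.linalg.cholesky(v0 + 1e-12 * np.eye(2))
    chol_sig = np.linalg.cholesky(sig + 1e-12 * np.eye(2))
    dev = chol_v0 @ rng.standard_normal(2)
    innov = rng.standard_normal((n_steps, 2)) @ chol_sig.T
    for t in range(n_steps):
        x[t] = dev
        dev = a @ dev + innov[t]
    return x + mu


def _grid_index(t_hours: float, step_hours: float, n_steps: int) -> int:
    return int(np.clip(round(t_hours / step_hours), 0, n_steps - 1))


def sample_ema(
    trace: np.ndarray,
    schedule_hours: list[float],
    noise_sd: float,
    rng: np.random.Generator,
    step_hours: float = 1.0,
) -> np.ndarray:
    """Latent value at the nearest grid point plus noise, clipped to [0, 100]."""
    n_steps = trace.shape[0]
    idx = [_grid_index(t, step_hours, n_steps) for t in schedule_hours]
    vals = trace[idx] + rng.normal(0.0, noise_sd, size=(len(idx), 2)) if noise_sd > 0 else trace[idx].copy()
    return np.clip(vals, 0.0, 100.0)


def sample_eod(
    trace: np.ndarray,
    day_slice: slice,
    mode: str,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One end-of-day summary rating (PA, NA) for the day's waking window.

    ``day_mean`` averages the latent values over the window; ``peak_end``
    averages the window's maximum and final values (a recall-bias variant).
    """
    seg = trace[day_slice]
    if mode == "day_mean":
        v = seg.mean(axis=0)
    elif mode == "peak_end":
        v = (seg.max(axis=0) + seg[-1]) / 2.0
    else:
        raise ValueError(f"unknown EOD summary mode {mode!r}")
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=2)
    return np.clip(v, 0.0, 100.0)


def sample_drm(
    trace: np.ndarray,
    day: int,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    person_id: str = "p",
) -> list[DRMEpisode]:
    """Partition one day's waking window into rated contiguous episodes.

    The episode count is Poisson (clipped to the configured bounds);
    episode shares are Gamma draws renormalized so durations sum exactly
    to the window. Each rating is the mean latent value over the episode,
    quantized to raw 0-6 by inverting the ingest rescale formula.
    """
    k = int(rng.poisson(cfg.episode_count_mean))
    k = int(np.clip(k, cfg.episode_count_min, cfg.episode_count_max))
    if k < 1:
        raise ValueError("episode count must be >= 1")
    w = cfg.window_end_hour - cfg.window_start_hour
    shares = rng.gamma(cfg.episode_duration_shape, 1.0, size=k)
    durations = shares / shares.sum() * w
    bounds = cfg.window_start_hour + np.concatenate([[0.0], np.cumsum(durations)])
    bounds[-1] = cfg.window_end_hour
    day_date = BASE_DATE + timedelta(days=day - 1)
    n_steps = trace.shape[0]
    episodes = []
    for i in range(k):
        s_h, e_h = bounds[i], bounds[i + 1]
        abs_s = (day - 1) * 24.0 + s_h
        abs_e = (day - 1) * 24.0 + e_h
        i0 = _grid_index(abs_s, cfg.step_hours, n_steps)
        i1 = max(i0 + 1, _grid_index(abs_e, cfg.step_hours, n_steps) + 1)
        mean_val = trace[i0:i1].mean(axis=0)
        if cfg.noise_sd_drm > 0:
            mean_val = mean_val + rng.normal(0.0, cfg.noise_sd_drm, size=2)
        mean_val = np.clip(mean_val, 0.0, 100.0)
        start = datetime.combine(day_date, time(0)) + timedelta(hours=float(s_h))
        end = datetime.combine(day_date, time(0)) + timedelta(hours=float(e_h))
        episodes.append(
            DRMEpisode(
                person_id=person_id,
                start=_round_to_second(start),
                end=_round_to_second(end),
                raw_pa=drm_raw_from_score(float(mean_val[0])),
                raw_na=drm_raw_from_score(float(mean_val[1])),
                label=f"episode {i + 1}",
            )
        )
    # rounding start/end to whole seconds may create zero-length episodes
    return [e for e in episodes if e.end > e.start]


def _round_to_second(dt: datetime) -> datetime:
    if dt.microsecond >= 500_000:
        dt += timedelta(seconds=1)
    return dt.replace(microsecond=0)


def generate_health(
    params: pd.DataFrame, cfg: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Daily health outcomes as linear functions of true person parameters."""
    rows = []
    for rec in params.itertuples(index=False):
        for day in range(1, cfg.n_days + 1):
            gh = (
                cfg.gh_intercept
                + cfg.gh_pa_set * (rec.pa_set - 65.0)
                + cfg.gh_na_set * rec.na_set
                + rng.normal(0.0, cfg.gh_noise_sd)
            )
            pain = (
                cfg.pain_intercept
                + cfg.pain_na_set * rec.na_set
                + cfg.pain_na_isd * rec.isd_na
                + rng.normal(0.0, cfg.pain_noise_sd)
            )
            fatigue = (
                cfg.fatigue_intercept
                + cfg.fatigue_pa_set * (rec.pa_set - 65.0)
                + cfg.fatigue_na_set * rec.na_set
                + rng.normal(0.0, cfg.fatigue_noise_sd)
            )
            rows.append(
                {
                    "person_id": rec.person_id,
                    "day_index": day,
                    "general_health": int(np.clip(round(gh), 1, 5)),
                    "pain": float(np.clip(pain, 0.0, 100.0)),
                    "fatigue": float(np.clip(fatigue, 0.0, 100.0)),
                }
            )
    return pd.DataFrame(rows)


def generate_study(
    cfg: GeneratorConfig,
) -> tuple[StudyDataset, GroundTruth, list[DRMEpisode]]:
    """Generate one full multi-method study; deterministic given the seed.

    Every person gets one latent process sampled by all three methods:
    EMA prompts on all days (re-drawing a day's schedule until the full
    prompt count fits in the window), one diary each evening, and DRM
    episodes for one uniformly chosen day between study days 1 and
    ``n_days - 1`` (the day preceding a web administration on days
    2..n_days).
    """
    rng = np.random.default_rng(cfg.seed)
    n_steps = int(round(cfg.n_days * 24.0 / cfg.step_hours))
    width = len(str(cfg.n_persons))
    dataset = StudyDataset()
    param_rows = []
    traces: dict[str, np.ndarray] = {}
    episodes_all: list[DRMEpisode] = []
    drm_days: dict[str, int] = {}
    for i in range(cfg.n_persons):
        pid = f"p{i + 1:0{width}d}"
        params = draw_person_params(pid, cfg, rng)
        trace = simulate_latent_process(params, n_steps, rng, params.icorr)
        if cfg.day_shock_sd_pa > 0 or cfg.day_shock_sd_na > 0:
            shocks = rng.normal(
                0.0,
                [cfg.day_shock_sd_pa, cfg.day_shock_sd_na],
                size=(cfg.n_days, 2),
            )
            steps_per_day = int(round(24.0 / cfg.step_hours))
            for day in range(cfg.n_days):
                trace[day * steps_per_day : (day + 1) * steps_per_day] += shocks[day]
        traces[pid] = trace

        ema_obs = []
        for day in range(1, cfg.n_days + 1):
            for _ in range(200):
                sched = generate_prompt_schedule(
                    cfg.window_start_hour, cfg.window_end_hour, cfg.prompts_per_day, rng
                )
                if len(sched) == cfg.prompts_per_day:
                    break
            abs_hours = [(day - 1) * 24.0 + t for t in sched]
            vals = sample_ema(trace, abs_hours, cfg.noise_sd_ema, rng, cfg.step_hours)
            for t, v in zip(sched, vals):
                if cfg.completion_prob < 1.0 and rng.random() >= cfg.completion_prob:
                    continue
                ts = datetime.combine(
                    BASE_DATE + timedelta(days=day - 1), time(0)
                ) + timedelta(hours=float(t))
                ema_obs.append(
                    AffectObservation(
                        pid, Method.EMA, _round_to_second(ts), day,
                        float(v[0]), float(v[1]),
                    )
                )
        if ema_obs:
            dataset.add(PersonSeries(pid, Method.EMA, ema_obs))

        eod_obs = []
        for day in range(1, cfg.n_days + 1):
            i0 = _grid_index((day - 1) * 24.0 + cfg.window_start_hour, cfg.step_hours, n_steps)
            i1 = _grid_index((day - 1) * 24.0 + cfg.window_end_hour, cfg.step_hours, n_steps) + 1
            v = sample_eod(trace, slice(i0, i1), cfg.eod_summary, cfg.noise_sd_eod, rng)
            ts = datetime.combine(
                BASE_DATE + timedelta(days=day - 1), time(0)
            ) + timedelta(hours=cfg.eod_hour)
            eod_obs.append(
                AffectObservation(pid, Method.EOD, ts, day, float(v[0]), float(v[1]))
            )
        dataset.add(PersonSeries(pid, Method.EOD, eod_obs))

        admin_day = int(rng.integers(2, cfg.n_days + 1))
        drm_day = admin_day - 1  # the reconstructed day
        drm_days[pid] = drm_day
        episodes_all.extend(sample_drm(trace, drm_day, cfg, rng, person_id=pid))

        row = asdict(params)
        row["drm_day"] = drm_day
        param_rows.append(row)

    params_df = pd.DataFrame(param_rows)
    from .data_model import episodes_to_series

    for s in episodes_to_series(episodes_all, BASE_DATE):
        dataset.add(s)
    dataset.health = generate_health(params_df, cfg, rng)
    truth = GroundTruth(
        params=params_df,
        traces=traces,
        grid_hours=np.arange(n_steps) * cfg.step_hours,
        config=cfg,
    )
    return dataset, truth, episodes_all


def expected_ema_icc(truth: GroundTruth, affect: str = "pa") -> float:
    """Configured between/total variance ratio of EMA samples.

    Between-person variance is the variance of the drawn set-points;
    within-person variance averages each person's stationary latent
    variance plus the day-shock and EMA measurement-noise variances.
    Ignores clipping at the scale bounds.
    """
    cfg = truth.config
    j = 0 if affect == "pa" else 1
    between = float(truth.params[f"{affect}_set"].var(ddof=1))
    within = []
    for rec in truth.params.itertuples(index=False):
        p = PersonParams(
            rec.person_id, rec.pa_set, rec.na_set, rec.a_pp, rec.a_pn,
            rec.a_np, rec.a_nn, rec.isd_pa, rec.isd_na, rec.icorr,
        )
        within.append(p.stationary_cov(rec.icorr)[j, j])
    shock = cfg.day_shock_sd_pa if affect == "pa" else cfg.day_shock_sd_na
    within_var = float(np.mean(within)) + shock**2 + cfg.noise_sd_ema**2
    return between / (between + within_var)


def write_study(
    dataset: StudyDataset,
    truth: GroundTruth,
    episodes: list[DRMEpisode],
    outdir,
) -> dict[str, Path]:
    """Write observations.csv, episodes.csv, health.csv, and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": outdir / "observations.csv",
        "episodes": outdir / "episodes.csv",
        "health": outdir / "health.csv",
        "truth": outdir / "truth.json",
    }
    non_drm = StudyDataset(
        series={k: v for k, v in dataset.series.items() if k[1] is not Method.DRM}
    )
    write_observations_csv(non_drm, paths["observations"])
    write_episodes_csv(episodes, paths["episodes"])
    write_health_csv(dataset.health, paths["health"])
    truth.to_json(paths["truth"])
    return paths
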