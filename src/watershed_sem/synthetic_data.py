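"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator mirrors the hierarchical watershed truth: correlated tract
means feed two cognitive endophenotypes, which feed a downstream fluid
factor, with task indicators hanging off every latent.  All defaults are on
a standardized scale (unit-variance latents and task scores) with magnitudes
anchored to plausible cohort values: standardized loadings 0.7, tract
intercorrelations 0.4, and tract paths sized so the endophenotype and fluid
R^2 land near 0.32 / 0.38 / 0.51.

Speed tasks can be emitted as raw reaction times (``rt = exp(location -
score)``), which the published preprocessing (inversion ``y = 1/x``, log
transform, optional +/-2 SD trim) maps back onto the linear score scale.

Imaging columns are missing completely at random for ``1 -
imaging_fraction`` of subjects, emulating a cohort where only a subset was
scanned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .watershed_models import CALM_BATTERY, CohortBattery

__all__ = [
    "SpeedTaskSpec",
    "CohortConfig",
    "generate_cohort",
    "age_moderated_cohort",
    "preprocess_speed",
    "default_speed_config",
]

DEFAULT_IMAGING_FRACTION = 165.0 / 551.0

# Relative tract-path profiles (order UF, SLF, IFOF, ATR, CST, FMaj, FMin,
# CG, CH, ILF).  Deliberately non-proportional: memory rides association
# tracts (SLF, forceps major/minor, cingulate), speed rides thalamic and
# fronto-occipital projections, so the two endophenotypes are empirically
# distinguishable upstream.  Each profile is rescaled to hit the target R^2.
DEFAULT_WM_PROFILE = (0.2, 1.0, 0.3, 0.1, 0.1, 0.8, 0.6, 0.7, 0.2, 0.3)
DEFAULT_SPEED_PROFILE = (0.3, 0.15, 0.8, 1.0, 0.6, 0.1, 0.2, 0.1, 0.5, 0.3)


@dataclass(frozen=True)
class SpeedTaskSpec:
    """Preprocessing flags for one speed task."""

    invert_log: bool = True       # reaction-time task: y = log(1/x)
    trim_sd: float | None = None  # remove values beyond +/- k SD
    rt_location: float = 6.0      # rt = exp(rt_location - score)


def default_speed_config(battery: CohortBattery) -> dict[str, SpeedTaskSpec]:
    out = {}
    for task in battery.speed_tasks:
        out[task] = SpeedTaskSpec(
            invert_log=task in battery.rt_speed_tasks,
            trim_sd=2.0 if task in battery.trimmed_speed_tasks else None,
        )
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Generative truth for one synthetic cohort (standardized scale)."""

    n_subjects: int = 551
    battery: CohortBattery = CALM_BATTERY
    loading: float = 0.7
    tract_corr: float = 0.4
    r2_wm: float = 0.323
    r2_speed: float = 0.382
    tract_paths_wm: tuple[float, ...] | None = None
    tract_paths_speed: tuple[float, ...] | None = None
    beta_wm: float = 0.70
    beta_speed: float = 0.02
    resid_cov: float = 0.399          # wm <-> speed residual covariance
    imaging_fraction: float = DEFAULT_IMAGING_FRACTION
    age_range: tuple[float, float] = (5.17, 17.92)
    age_effect: Mapping[str, Sequence[tuple[float, float, float]]] | None = None
    topology: str = "watershed"       # or "chain": tracts->speed->wm->gf
    chain_wm_on_speed: float = 0.75
    chain_gf_on_wm: float = 0.72
    emit_raw_speed: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.imaging_fraction <= 1.0):
            raise ValueError("imaging_fraction must be in (0, 1]")
        if self.topology not in ("watershed", "chain"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.age_effect:
            lo, hi = self.age_range
            for name, segments in self.age_effect.items():
                segs = sorted(segments)
                if segs[0][0] > lo or segs[-1][1] < hi:
                    raise ValueError(
                        f"age_effect for {name!r} does not cover {self.age_range}")
        # the implied covariance must be PSD (zero-residual indicators make
        # it singular but still generable)
        _, sigma = self.implied_covariance()
        if np.linalg.eigvalsh(sigma)[0] < -1e-8:
            raise ValueError("config-implied covariance is not positive semidefinite")

    # -- derived truth ---------------------------------------------------

    def tract_cov(self) -> np.ndarray:
        C = np.full((10, 10), self.tract_corr)
        np.fill_diagonal(C, 1.0)
        return C

    def paths_wm(self) -> np.ndarray:
        if self.tract_paths_wm is not None:
            return np.asarray(self.tract_paths_wm, dtype=float)
        prof = np.asarray(DEFAULT_WM_PROFILE)
        C = self.tract_cov()
        return prof * np.sqrt(self.r2_wm / (prof @ C @ prof))

    def paths_speed(self) -> np.ndarray:
        if self.tract_paths_speed is not None:
            return np.asarray(self.tract_paths_speed, dtype=float)
        prof = np.asarray(DEFAULT_SPEED_PROFILE)
        C = self.tract_cov()
        return prof * np.sqrt(self.r2_speed / (prof @ C @ prof))

    def latent_covariance(self) -> tuple[list[str], np.ndarray]:
        """Covariance of (tracts..., wm, speed, gf), all latents unit variance."""
        C = self.tract_cov()
        names = list(self.battery.tract_names) + ["wm", "speed", "gf"]
        m = np.zeros((13, 13))
        m[:10, :10] = C
        if self.topology == "watershed":
            a, b = self.paths_wm(), self.paths_speed()
            cov_wm_t = C @ a
            cov_sp_t = C @ b
            cov_ws = float(a @ C @ b) + self.resid_cov
            bw, bs = self.beta_wm, self.beta_speed
            cov_gf_t = bw * cov_wm_t + bs * cov_sp_t
            cov_gf_wm = bw + bs * cov_ws
            cov_gf_sp = bw * cov_ws + bs
        else:  # chain
            b = self.paths_speed()
            g, bw = self.chain_wm_on_speed, self.chain_gf_on_wm
            cov_sp_t = C @ b
            cov_wm_t = g * cov_sp_t
            cov_ws = g
            cov_gf_t = bw * cov_wm_t
            cov_gf_wm = bw
            cov_gf_sp = bw * g
        m[:10, 10] = m[10, :10] = cov_wm_t
        m[:10, 11] = m[11, :10] = cov_sp_t
        m[:10, 12] = m[12, :10] = cov_gf_t
        m[10, 10] = m[11, 11] = m[12, 12] = 1.0
        m[10, 11] = m[11, 10] = cov_ws
        m[10, 12] = m[12, 10] = cov_gf_wm
        m[11, 12] = m[12, 11] = cov_gf_sp
        return names, m

    def _task_map(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Observed tasks as lam * latent + e: (names, lambda rows, e vars)."""
        battery = self.battery
        rows = []
        names = []
        evars = []
        groups = (("wm", battery.wm_tasks), ("speed", battery.speed_tasks),
                  ("gf", battery.gf_tasks))
        latent_idx = {"wm": 10, "speed": 11, "gf": 12}
        for latent, tasks in groups:
            single = len(tasks) == 1
            for task in tasks:
                lam = 1.0 if single else self.loading
                row = np.zeros(13)
                row[latent_idx[latent]] = lam
                rows.append(row)
                names.append(task)
                evars.append(0.0 if single else 1.0 - lam ** 2)
        return names, np.asarray(rows), np.asarray(evars)

    def implied_covariance(self) -> tuple[list[str], np.ndarray]:
        """Covariance of (tasks on the transformed scale, tracts)."""
        lat_names, lat_cov = self.latent_covariance()
        task_names, L, evars = self._task_map()
        m_obs = len(task_names) + 10
        M = np.zeros((m_obs, 13))
        M[:len(task_names), :] = L
        M[len(task_names):, :10] = np.eye(10)
        sigma = M @ lat_cov @ M.T
        sigma[:len(task_names), :len(task_names)] += np.diag(evars)
        names = task_names + list(self.battery.tract_names)
        return names, (sigma + sigma.T) / 2.0

    def standardized_truth(self) -> dict[str, float]:
        """True parameter values keyed like a fitted standardized solution."""
        battery = self.battery
        out: dict[str, float] = {}
        for latent, tasks in (("wm", battery.wm_tasks), ("gf", battery.gf_tasks),
                              ("speed", battery.speed_tasks)):
            if len(tasks) == 1:
                continue
            for task in tasks:
                out[f"{latent}=~{task}"] = self.loading
                out[f"{task}~~{task}"] = 1.0 - self.loading ** 2
        if self.topology == "watershed":
            a, b = self.paths_wm(), self.paths_speed()
            for t, val in zip(battery.tract_names, a):
                out[f"wm~{t}"] = float(val)
            for t, val in zip(battery.tract_names, b):
                out[f"speed~{t}"] = float(val)
            out["gf~wm"] = self.beta_wm
            out["gf~speed"] = self.beta_speed
            out["wm~~speed"] = self.resid_cov
            _, lat = self.latent_covariance()
            cov_ws = lat[10, 11]
            expl_gf = (self.beta_wm ** 2 + self.beta_speed ** 2
                       + 2 * self.beta_wm * self.beta_speed * cov_ws)
            out["wm~~wm"] = 1.0 - self.r2_wm
            out["speed~~speed"] = 1.0 - self.r2_speed
            out["gf~~gf"] = 1.0 - expl_gf
        for i, t1 in enumerate(battery.tract_names):
            out[f"{t1}~~{t1}"] = 1.0
            for t2 in battery.tract_names[i + 1:]:
                out[f"{t1}~~{t2}"] = self.tract_corr
        return out


def _piecewise(ages: np.ndarray, segments, default: float) -> np.ndarray:
    out = np.full(ages.shape, default, dtype=float)
    segs = sorted(segments)
    for lo, hi, val in segs:
        out[(ages >= lo) & (ages < hi)] = val
    lo, hi, val = segs[-1]
    out[ages == hi] = val
    return out


def _subject_coefs(config: CohortConfig, ages: np.ndarray, use_age_effect: bool):
    """Per-subject generative coefficients (arrays broadcastable over n)."""
    n = len(ages)
    battery = config.battery
    a = np.tile(config.paths_wm(), (n, 1))
    b = np.tile(config.paths_speed(), (n, 1))
    beta_wm = np.full(n, config.beta_wm)
    beta_speed = np.full(n, config.beta_speed)
    resid_cov = np.full(n, config.resid_cov)
    chain_g = np.full(n, config.chain_wm_on_speed)
    chain_b = np.full(n, config.chain_gf_on_wm)
    if use_age_effect and config.age_effect:
        tract_pos = {t: k for k, t in enumerate(battery.tract_names)}
        for name, segments in config.age_effect.items():
            if name == "gf~wm":
                beta_wm = _piecewise(ages, segments, config.beta_wm)
            elif name == "gf~speed":
                beta_speed = _piecewise(ages, segments, config.beta_speed)
            elif name == "wm~~speed":
                resid_cov = _piecewise(ages, segments, config.resid_cov)
            elif name == "wm~speed":
                chain_g = _piecewise(ages, segments, config.chain_wm_on_speed)
            elif name.startswith("wm~") and name[3:] in tract_pos:
                a[:, tract_pos[name[3:]]] = _piecewise(
                    ages, segments, config.paths_wm()[tract_pos[name[3:]]])
            elif name.startswith("speed~") and name[6:] in tract_pos:
                b[:, tract_pos[name[6:]]] = _piecewise(
                    ages, segments, config.paths_speed()[tract_pos[name[6:]]])
            else:
                raise ValueError(f"unknown age_effect target {name!r}")
    return a, b, beta_wm, beta_speed, resid_cov, chain_g, chain_b


def _generate(config: CohortConfig, seed: int | None, use_age_effect: bool
              ) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    battery = config.battery
    ages = rng.uniform(*config.age_range, size=n)
    a, b, beta_wm, beta_speed, resid_cov, chain_g, chain_b = _subject_coefs(
        config, ages, use_age_effect)

    C = config.tract_cov()
    tracts = rng.standard_normal((n, 10)) @ np.linalg.cholesky(C).T

    if config.topology == "watershed":
        u_var = 1.0 - np.einsum("ni,ij,nj->n", a, C, a)
        v_var = 1.0 - np.einsum("ni,ij,nj->n", b, C, b)
        if np.any(u_var <= 0) or np.any(v_var <= 0):
            raise ValueError("tract paths imply endophenotype variance > 1")
        z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
        su = np.sqrt(u_var)
        u = su * z1
        cond = v_var - resid_cov ** 2 / u_var
        if np.any(cond <= 0):
            raise ValueError("residual covariance too large for residual variances")
        v = (resid_cov / su) * z1 + np.sqrt(cond) * z2
        wm = np.einsum("ni,ni->n", tracts, a) + u
        speed = np.einsum("ni,ni->n", tracts, b) + v
        expl = (beta_wm ** 2 + beta_speed ** 2
                + 2 * beta_wm * beta_speed
                * (np.einsum("ni,ij,nj->n", a, C, b) + resid_cov))
        w_var = np.clip(1.0 - expl, 1e-8, None)
        gf = beta_wm * wm + beta_speed * speed + np.sqrt(w_var) * rng.standard_normal(n)
    else:  # chain
        v_var = 1.0 - np.einsum("ni,ij,nj->n", b, C, b)
        speed = np.einsum("ni,ni->n", tracts, b) + np.sqrt(v_var) * rng.standard_normal(n)
        wm = chain_g * speed + np.sqrt(1.0 - chain_g ** 2) * rng.standard_normal(n)
        gf = chain_b * wm + np.sqrt(1.0 - chain_b ** 2) * rng.standard_normal(n)

    latent = {"wm": wm, "speed": speed, "gf": gf}
    data = {"age": ages}
    speed_specs = default_speed_config(battery)
    for lat, tasks in (("wm", battery.wm_tasks), ("gf", battery.gf_tasks),
                       ("speed", battery.speed_tasks)):
        single = len(tasks) == 1
        for task in tasks:
            lam = 1.0 if single else config.loading
            evar = 0.0 if single else 1.0 - lam ** 2
            score = lam * latent[lat] + (
                np.sqrt(evar) * rng.standard_normal(n) if evar > 0 else 0.0)
            sp = speed_specs.get(task)
            if (config.emit_raw_speed and sp is not None and sp.invert_log):
                data[task] = np.exp(sp.rt_location - score)
            else:
                data[task] = score

    scanned = rng.random(n) < config.imaging_fraction
    for k, tract in enumerate(battery.tract_names):
        col = tracts[:, k].copy()
        col[~scanned] = np.nan
        data[tract] = col
    return pd.DataFrame(data)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table (age, task scores, tract means) from the truth.

    Reproducible: the same seed yields a byte-identical table.  Age effects
    in the config are ignored here; see :func:`age_moderated_cohort`.
    """
    return _generate(config, seed, use_age_effect=False)


def age_moderated_cohort(config: CohortConfig, seed: int | None = None
                         ) -> pd.DataFrame:
    """Like :func:`generate_cohort` but with age-varying path coefficients."""
    return _generate(config, seed, use_age_effect=True)


def preprocess_speed(table: pd.DataFrame,
                     task_specs: Mapping[str, SpeedTaskSpec]
                     ) -> tuple[pd.DataFrame, dict]:
    """Apply the speed-score transforms: invert (y = 1/x), log, +/-2 SD trim.

    Reaction-time tasks get ``y = log(1/x)`` so that faster raw times map to
    larger speed scores; flagged tasks get values beyond ``trim_sd`` standard
    deviations of the mean set to missing.  Nonpositive reaction times are
    flagged invalid and set missing.  Returns the transformed table and an
    exclusion log.
    """
    out = table.copy()
    log: dict = {"trimmed": {}, "invalid": {}}
    for task, sp in task_specs.items():
        if task not in out.columns:
            continue
        x = out[task].to_numpy(dtype=float)
        if sp.invert_log:
            bad = (x <= 0) & ~np.isnan(x)
            if bad.any():
                log["invalid"][task] = int(bad.sum())
                x = np.where(bad, np.nan, x)
            with np.errstate(divide="ignore", invalid="ignore"):
                x = np.log(1.0 / x)
        if sp.trim_sd is not None:
            m = np.nanmean(x)
            s = np.nanstd(x)
            outlier = np.abs(x - m) > sp.trim_sd * s
            outlier &= ~np.isnan(x)
            if outlier.any():
                log["trimmed"][task] = int(outlier.sum())
                x = np.where(outlier, np.nan, x)
            else:
                log["trimmed"][task] = 0
        out[task] = x
    return out, log
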