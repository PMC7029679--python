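"""Model library for the watershed analysis and the end-to-end driver.

Encodes the competing measurement models of cognition, the cognitive
regression models with their constrained variants, the single-factor
white-matter model, the hierarchical watershed model with its alternatives
(A-D) and constrained variants, and the single-path probe used to diagnose
suppression-driven sign flips.

Structural conventions (all forced by degrees-of-freedom bookkeeping):
tract residual inter-covariances free; the working-memory <-> speed residual
covariance free; marker-variable scaling; the single-task fluid factor is a
single-indicator latent with its indicator residual fixed to zero.

Alternative B (all tasks manifest) and alternative C ("inverted" hierarchy)
are interpretations of verbal descriptions: B wires each endophenotype task
onto all tracts and each fluid task onto all endophenotype tasks, with free
residual covariances within each level; C routes tracts -> fluid ->
{memory, speed}.  Their dfs are reported, not asserted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .estimation import DataInput, FitResult, fit, r_squared, standardize_solution
from .fit_compare import (
    classify_fit,
    fit_baseline,
    fit_indices,
    information_criteria,
    lrt_nested,
)
from .model_spec import ModelSpec, degrees_of_freedom, parse_model

__all__ = [
    "CohortBattery",
    "CALM_BATTERY",
    "NKI_BATTERY",
    "TRACTS",
    "MEASUREMENT_VARIANTS",
    "WATERSHED_VARIANTS",
    "build_measurement_model",
    "build_cognitive_regression",
    "build_wm_single_factor",
    "build_watershed",
    "single_path_probe",
    "run_full_analysis",
    "AnalysisReport",
]

TRACTS = ("UF", "SLF", "IFOF", "ATR", "CST", "FMaj", "FMin", "CG", "CH", "ILF")

MEASUREMENT_VARIANTS = ("single", "twoA", "twoB", "three")
WATERSHED_VARIANTS = (
    "original", "altA", "altB", "altC", "altD",
    "zero_paths_to_speed", "zero_paths_to_memory", "equal_tract_paths",
)


@dataclass(frozen=True)
class CohortBattery:
    """Task lists per cognitive domain plus the tract labels for one cohort."""

    label: str
    wm_tasks: tuple[str, ...]
    gf_tasks: tuple[str, ...]
    speed_tasks: tuple[str, ...]
    tract_names: tuple[str, ...] = TRACTS
    # speed tasks recorded as raw reaction times (inverted+logged upstream)
    rt_speed_tasks: tuple[str, ...] = ()
    # speed-native tasks needing the +/-2 SD trim
    trimmed_speed_tasks: tuple[str, ...] = ()

    def __post_init__(self):
        groups = (self.wm_tasks, self.gf_tasks, self.speed_tasks)
        tasks = [t for g in groups for t in g]
        if len(set(tasks)) != len(tasks):
            raise ValueError("task lists must be disjoint")
        if len(self.tract_names) != 10:
            raise ValueError("exactly 10 tract names required")
        if set(tasks) & set(self.tract_names):
            raise ValueError("tract names must not collide with task names")

    @property
    def tasks(self) -> tuple[str, ...]:
        return self.wm_tasks + self.gf_tasks + self.speed_tasks

    @property
    def all_columns(self) -> tuple[str, ...]:
        return self.tasks + self.tract_names

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "wm_tasks": list(self.wm_tasks),
            "gf_tasks": list(self.gf_tasks),
            "speed_tasks": list(self.speed_tasks),
            "tract_names": list(self.tract_names),
            "rt_speed_tasks": list(self.rt_speed_tasks),
            "trimmed_speed_tasks": list(self.trimmed_speed_tasks),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortBattery":
        return cls(
            label=d["label"],
            wm_tasks=tuple(d["wm_tasks"]),
            gf_tasks=tuple(d["gf_tasks"]),
            speed_tasks=tuple(d["speed_tasks"]),
            tract_names=tuple(d.get("tract_names", TRACTS)),
            rt_speed_tasks=tuple(d.get("rt_speed_tasks", ())),
            trimmed_speed_tasks=tuple(d.get("trimmed_speed_tasks", ())),
        )


CALM_BATTERY = CohortBattery(
    label="CALM",
    wm_tasks=("digit_recall", "backward_digit_recall", "dot_matrix", "mr_x"),
    gf_tasks=("matrix_reasoning",),
    speed_tasks=("trail_making", "rapid_naming", "rbbs"),
    rt_speed_tasks=("trail_making", "rapid_naming", "rbbs"),
)

NKI_BATTERY = CohortBattery(
    label="NKI-RS",
    wm_tasks=("digit_span_forward", "digit_span_backward", "n_back"),
    gf_tasks=("matrix_reasoning", "block_design", "similarities",
              "verbal_reasoning"),
    speed_tasks=("trail_making", "motor_speed", "sensory_motor_speed"),
    rt_speed_tasks=("trail_making", "sensory_motor_speed"),
    trimmed_speed_tasks=("motor_speed",),
)

BATTERIES = {"calm": CALM_BATTERY, "nki": NKI_BATTERY}


def _measurement_lines(battery: CohortBattery) -> list[str]:
    return [
        f"wm =~ {' + '.join(battery.wm_tasks)}",
        f"gf =~ {' + '.join(battery.gf_tasks)}",
        f"speed =~ {' + '.join(battery.speed_tasks)}",
    ]


def build_measurement_model(battery: CohortBattery, variant: str) -> ModelSpec:
    """One of the four competing measurement models of cognition."""
    if variant == "three":
        lines = _measurement_lines(battery)
    elif variant == "single":
        lines = [f"g =~ {' + '.join(battery.tasks)}"]
    elif variant == "twoA":  # fluid + speed unitary vs working memory
        lines = [
            f"gfspeed =~ {' + '.join(battery.gf_tasks + battery.speed_tasks)}",
            f"wm =~ {' + '.join(battery.wm_tasks)}",
        ]
    elif variant == "twoB":  # fluid + working memory unitary vs speed
        lines = [
            f"gfwm =~ {' + '.join(battery.gf_tasks + battery.wm_tasks)}",
            f"speed =~ {' + '.join(battery.speed_tasks)}",
        ]
    else:
        raise ValueError(f"unknown measurement variant {variant!r}")
    return parse_model("\n".join(lines))


def build_cognitive_regression(battery: CohortBattery, constraint: str = "free"
                               ) -> ModelSpec:
    """Fluid factor regressed on memory and speed latents (predictors covary)."""
    lines = _measurement_lines(battery)
    if constraint == "free":
        lines.append("gf ~ wm + speed")
    elif constraint == "equal_paths":
        lines.append("gf ~ b1*wm + b1*speed")
    elif constraint == "zero_memory":
        lines.append("gf ~ 0*wm + speed")
    elif constraint == "zero_speed":
        lines.append("gf ~ wm + 0*speed")
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    return parse_model("\n".join(lines))


def build_wm_single_factor(tract_names: Sequence[str] = TRACTS) -> ModelSpec:
    """Single 'global FA' factor over the 10 tract means."""
    tract_names = tuple(tract_names)
    if len(tract_names) != 10:
        raise ValueError("exactly 10 tracts required")
    return parse_model(f"FA =~ {' + '.join(tract_names)}")


def build_watershed(battery: CohortBattery, variant: str = "original") -> ModelSpec:
    """The hierarchical watershed model or one of its variants."""
    tracts = " + ".join(battery.tract_names)
    zero_tracts = " + ".join(f"0*{t}" for t in battery.tract_names)
    meas = _measurement_lines(battery)

    if variant == "original":
        lines = meas + [
            f"wm ~ {tracts}",
            f"speed ~ {tracts}",
            "gf ~ wm + speed",
            "wm ~~ speed",
        ]
    elif variant == "zero_paths_to_speed":
        lines = meas + [
            f"wm ~ {tracts}",
            f"speed ~ {zero_tracts}",
            "gf ~ wm + speed",
            "wm ~~ speed",
        ]
    elif variant == "zero_paths_to_memory":
        lines = meas + [
            f"wm ~ {zero_tracts}",
            f"speed ~ {tracts}",
            "gf ~ wm + speed",
            "wm ~~ speed",
        ]
    elif variant == "equal_tract_paths":
        wm_terms = " + ".join(f"bw*{t}" for t in battery.tract_names)
        sp_terms = " + ".join(f"bs*{t}" for t in battery.tract_names)
        lines = meas + [
            f"wm ~ {wm_terms}",
            f"speed ~ {sp_terms}",
            "gf ~ wm + speed",
            "wm ~~ speed",
        ]
    elif variant == "altA":  # chain: tracts -> speed -> memory -> fluid
        lines = meas + [
            f"speed ~ {tracts}",
            "wm ~ speed",
            "gf ~ wm",
        ]
    elif variant == "altB":  # all tasks manifest
        endo_tasks = battery.wm_tasks + battery.speed_tasks
        lines = [f"{t} ~ {tracts}" for t in endo_tasks]
        lines += [f"{g} ~ {' + '.join(endo_tasks)}" for g in battery.gf_tasks]
        for group in (endo_tasks, battery.gf_tasks):
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    lines.append(f"{a} ~~ {b}")
    elif variant == "altC":  # inverted hierarchy: tracts -> fluid -> endophenotypes
        lines = meas + [
            f"gf ~ {tracts}",
            "wm ~ gf",
            "speed ~ gf",
            "wm ~~ speed",
        ]
    elif variant == "altD":  # fluid regressed directly on everything
        lines = meas + [
            f"gf ~ {tracts} + wm + speed",
        ]
    else:
        raise ValueError(f"unknown watershed variant {variant!r}")
    return parse_model("\n".join(lines))


def build_single_path_model(battery: CohortBattery, tract: str,
                            endophenotype: str) -> ModelSpec:
    """Watershed with only one tract -> endophenotype path retained.

    All other tract paths are fixed to zero (equivalent to removing them),
    leaving the rest of the watershed structure untouched.
    """
    if tract not in battery.tract_names:
        raise ValueError(f"unknown tract {tract!r}")
    if endophenotype not in ("wm", "speed"):
        raise ValueError("endophenotype must be 'wm' or 'speed'")
    other = "speed" if endophenotype == "wm" else "wm"
    kept = " + ".join(t if t == tract else f"0*{t}"
                      for t in battery.tract_names)
    zeroed = " + ".join(f"0*{t}" for t in battery.tract_names)
    lines = _measurement_lines(battery)
    lines += [
        f"{endophenotype} ~ {kept}",
        f"{other} ~ {zeroed}",
        "gf ~ wm + speed",
        "wm ~~ speed",
    ]
    return parse_model("\n".join(lines))


def single_path_probe(battery: CohortBattery, tract: str, endophenotype: str,
                      data: DataInput) -> dict:
    """Refit with a single tract path free and report its standardized value."""
    spec = build_single_path_model(battery, tract, endophenotype)
    result = fit(spec, data)
    name = f"{endophenotype}~{tract}"
    std = standardize_solution(result)
    return {
        "tract": tract,
        "endophenotype": endophenotype,
        "estimate": result.theta_hat[name],
        "standardized": std[name],
        "converged": result.converged,
    }


# ---------------------------------------------------------------------------
# Full analysis driver
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """Per-cohort results; every number traces to a named FitResult."""

    cohorts: dict[str, dict]
    fits: dict[str, dict[str, FitResult]] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return _round_floats({"cohorts": self.cohorts})

    def to_json(self, **kw) -> str:
        kw.setdefault("sort_keys", True)
        kw.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kw)

    def to_markdown(self) -> str:
        parts = []
        for cohort, section in self.cohorts.items():
            parts.append(f"## {cohort}\n")
            meas = section["measurement"]["table_markdown"]
            parts.append("### Measurement models\n" + meas + "\n")
            ws = section["watershed"]
            parts.append("### Watershed\n" + ws["table_markdown"] + "\n")
            r2 = ws["r_squared"]
            parts.append(
                "R^2: " + ", ".join(f"{k} = {100 * v:.1f}%" for k, v in r2.items())
                + "\n"
            )
        return "\n".join(parts)


def _round_floats(obj, ndigits: int = 8):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _require_converged(name: str, result: FitResult) -> FitResult:
    if not result.converged:
        raise RuntimeError(
            f"model {name!r} did not converge "
            f"(gradient max-norm {result.grad_norm:.3g})"
        )
    return result


def run_full_analysis(datasets: Mapping[str, DataInput],
                      batteries: Mapping[str, CohortBattery],
                      probes: Mapping[str, Sequence[tuple[str, str]]] | None = None,
                      ) -> AnalysisReport:
    """Execute every fit and comparison of the analysis in fixed order.

    ``datasets`` maps cohort label to data covering battery tasks + tracts;
    ``probes`` optionally maps cohort label to (tract, endophenotype) pairs
    for single-path probes.  Deterministic given inputs.
    """
    if not datasets:
        raise ValueError("empty model list: no cohorts supplied")
    report: dict[str, dict] = {}
    all_fits: dict[str, dict[str, FitResult]] = {}
    for cohort in datasets:
        battery = batteries[cohort]
        data = datasets[cohort]
        section: dict = {}
        fits: dict[str, FitResult] = {}

        # 1. measurement-model competition
        meas_fits = {}
        for variant in MEASUREMENT_VARIANTS:
            spec = build_measurement_model(battery, variant)
            meas_fits[variant] = _require_converged(
                f"measurement:{variant}", fit(spec, data))
        table = information_criteria(meas_fits)
        fits.update({f"measurement:{k}": v for k, v in meas_fits.items()})
        three = meas_fits["three"]
        std3 = standardize_solution(three)
        latent_corr = {k: v for k, v in std3.items()
                       if "~~" in k and k.split("~~")[0] != k.split("~~")[1]
                       and k.split("~~")[0] in ("wm", "gf", "speed")}
        section["measurement"] = {
            "table": table.to_dict(),
            "table_markdown": table.to_markdown(),
            "latent_correlations": latent_corr,
        }

        # 2. cognitive regression comparisons
        reg_fits = {}
        for constraint in ("free", "equal_paths", "zero_memory", "zero_speed"):
            spec = build_cognitive_regression(battery, constraint)
            reg_fits[constraint] = _require_converged(
                f"regression:{constraint}", fit(spec, data))
        fits.update({f"regression:{k}": v for k, v in reg_fits.items()})
        free = reg_fits["free"]
        std_free = standardize_solution(free)
        tests = {}
        for constraint in ("equal_paths", "zero_memory", "zero_speed"):
            d, ddf, p = lrt_nested(reg_fits[constraint], free)
            tests[constraint] = {"delta_chisq": d, "delta_df": ddf, "p": p}
        section["cognitive_regression"] = {
            "paths": {"gf~wm": std_free.get("gf~wm"),
                      "gf~speed": std_free.get("gf~speed")},
            "r_squared": {"gf": r_squared(free, "gf")},
            "constrained_tests": tests,
        }

        # 3. white-matter dimensionality
        fa_spec = build_wm_single_factor(battery.tract_names)
        fa_fit = _require_converged("wm_single_factor", fit(fa_spec, data))
        fits["wm_single_factor"] = fa_fit
        fa_ix = fit_indices(fa_fit, fit_baseline(fa_fit.data))
        section["white_matter"] = {
            "single_factor": fa_ix.to_dict(),
            "classification": classify_fit(fa_ix),
        }

        # 4. watershed and alternatives
        ws_fits = {}
        for variant in ("original", "altA", "altB", "altC", "altD"):
            spec = build_watershed(battery, variant)
            ws_fits[variant] = _require_converged(
                f"watershed:{variant}", fit(spec, data))
        fits.update({f"watershed:{k}": v for k, v in ws_fits.items()})
        ws_table = information_criteria(ws_fits)
        original = ws_fits["original"]
        base = fit_baseline(original.data)
        ws_ix = fit_indices(original, base)
        constrained = {}
        for variant in ("zero_paths_to_speed", "zero_paths_to_memory",
                        "equal_tract_paths"):
            spec = build_watershed(battery, variant)
            cfit = _require_converged(f"watershed:{variant}", fit(spec, data))
            fits[f"watershed:{variant}"] = cfit
            d, ddf, p = lrt_nested(cfit, original)
            constrained[variant] = {"delta_chisq": d, "delta_df": ddf, "p": p}
        std_ws = standardize_solution(original)
        tract_paths = {k: v for k, v in std_ws.items()
                       if "~" in k and "~~" not in k
                       and k.split("~")[1] in battery.tract_names}
        section["watershed"] = {
            "fit": ws_ix.to_dict(),
            "classification": classify_fit(ws_ix),
            "table": ws_table.to_dict(),
            "table_markdown": ws_table.to_markdown(),
            "r_squared": {v: r_squared(original, v) for v in ("wm", "speed", "gf")},
            "tract_paths_standardized": tract_paths,
            "constrained_tests": constrained,
            "degrees_of_freedom": {
                v: degrees_of_freedom(build_watershed(battery, v))
                for v in WATERSHED_VARIANTS
            },
        }

        # 5. single-path probes
        probe_list = (probes or {}).get(cohort, ())
        section["probes"] = [
            single_path_probe(battery, tract, endo, data)
            for tract, endo in probe_list
        ]

        report[cohort] = section
        all_fits[cohort] = fits
    return AnalysisReport(cohorts=report, fits=all_fits)
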