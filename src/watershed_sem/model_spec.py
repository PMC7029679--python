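"""Symbolic latent-variable model specification and RAM compilation.

Models are written in a lavaan-style text syntax:

    wm =~ task1 + task2 + task3     # factor loadings
    gf ~ b1*wm + b1*speed           # regressions (shared label = equality)
    wm ~~ speed                     # (co)variance
    gf ~ 0*speed                    # fixed-to-zero path

Scaling follows the marker-variable convention: the first indicator of each
latent has its loading fixed to 1 unless it carries an explicit modifier or
the latent variance is fixed.  A latent with a single indicator additionally
gets the indicator residual variance fixed to 0, so the latent is an exact
proxy of its indicator.

Defaults (applied at RAM-compilation time, deterministically):

* every variable gets a free (residual) variance unless one is declared;
* exogenous latents, and exogenous manifest variables that appear as
  regression predictors, freely covary pairwise unless a covariance for the
  pair is declared.

Only the covariance structure is modeled; no mean/intercept structure.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ModelSyntaxError",
    "IdentificationError",
    "Loading",
    "Regression",
    "Covariance",
    "ResidualVariance",
    "ModelSpec",
    "RAMMatrices",
    "parse_model",
    "build_ram",
    "degrees_of_freedom",
    "check_identification",
    "IdentificationReport",
]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


class ModelSyntaxError(ValueError):
    """Raised when model text cannot be parsed."""


class IdentificationError(ValueError):
    """Raised when a model is structurally under-identified."""


@dataclass(frozen=True)
class Loading:
    latent: str
    manifest: str
    value: float | None = None  # None = free
    label: str | None = None


@dataclass(frozen=True)
class Regression:
    outcome: str
    predictor: str
    value: float | None = None
    label: str | None = None


@dataclass(frozen=True)
class Covariance:
    var1: str
    var2: str
    value: float | None = None
    label: str | None = None


@dataclass(frozen=True)
class ResidualVariance:
    var: str
    value: float | None = None
    label: str | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic SEM: latents, manifests, and the four parameter blocks."""

    latents: tuple[str, ...]
    manifests: tuple[str, ...]
    loadings: tuple[Loading, ...]
    regressions: tuple[Regression, ...]
    covariances: tuple[Covariance, ...]
    residual_variances: tuple[ResidualVariance, ...]

    # -- structural roles ------------------------------------------------

    @property
    def all_vars(self) -> tuple[str, ...]:
        return self.manifests + self.latents

    @property
    def endogenous(self) -> frozenset[str]:
        down = {ld.manifest for ld in self.loadings}
        down |= {r.outcome for r in self.regressions}
        return frozenset(down)

    @property
    def exogenous(self) -> frozenset[str]:
        return frozenset(self.all_vars) - self.endogenous

    @property
    def predictors(self) -> frozenset[str]:
        return frozenset(r.predictor for r in self.regressions)

    # -- serialization ---------------------------------------------------

    def to_text(self) -> str:
        """Serialize back to model syntax (round-trips through parse_model)."""

        def mod(value, label):
            if value is not None:
                return f"{value:g}*"
            if label is not None:
                return f"{label}*"
            return ""

        lines = []
        for lat in self.latents:
            lds = [ld for ld in self.loadings if ld.latent == lat]
            if lds:
                rhs = " + ".join(f"{mod(l.value, l.label)}{l.manifest}" for l in lds)
                lines.append(f"{lat} =~ {rhs}")
        by_outcome: dict[str, list[Regression]] = {}
        for r in self.regressions:
            by_outcome.setdefault(r.outcome, []).append(r)
        for outcome, regs in by_outcome.items():
            rhs = " + ".join(f"{mod(r.value, r.label)}{r.predictor}" for r in regs)
            lines.append(f"{outcome} ~ {rhs}")
        for c in self.covariances:
            lines.append(f"{c.var1} ~~ {mod(c.value, c.label)}{c.var2}")
        for rv in self.residual_variances:
            lines.append(f"{rv.var} ~~ {mod(rv.value, rv.label)}{rv.var}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "latents": list(self.latents),
            "manifests": list(self.manifests),
            "loadings": [vars(x).copy() for x in self.loadings],
            "regressions": [vars(x).copy() for x in self.regressions],
            "covariances": [vars(x).copy() for x in self.covariances],
            "residual_variances": [vars(x).copy() for x in self.residual_variances],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            latents=tuple(d["latents"]),
            manifests=tuple(d["manifests"]),
            loadings=tuple(Loading(**x) for x in d["loadings"]),
            regressions=tuple(Regression(**x) for x in d["regressions"]),
            covariances=tuple(Covariance(**x) for x in d["covariances"]),
            residual_variances=tuple(ResidualVariance(**x) for x in d["residual_variances"]),
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_term(term: str, lineno: int) -> tuple[str, float | None, str | None]:
    """Parse 'modifier*name' into (name, fixed_value, label)."""
    term = term.strip()
    if "*" in term:
        modifier, _, name = term.partition("*")
        modifier = modifier.strip()
        name = name.strip()
        try:
            return name, float(modifier), None
        except ValueError:
            if not _NAME_RE.match(modifier):
                raise ModelSyntaxError(f"line {lineno}: bad modifier {modifier!r}")
            return name, None, modifier
    return term, None, None


def _check_name(name: str, lineno: int) -> str:
    if not _NAME_RE.match(name):
        raise ModelSyntaxError(f"line {lineno}: invalid variable name {name!r}")
    return name


def parse_model(text: str) -> ModelSpec:
    """Parse model syntax into a :class:`ModelSpec`.

    Marker scaling and the single-indicator convention (see module docstring)
    are applied here so that the returned spec is fully explicit and
    round-trips through :meth:`ModelSpec.to_text`.
    """
    if not text or not text.strip():
        raise ModelSyntaxError("empty model text")

    loadings: list[Loading] = []
    regressions: list[Regression] = []
    covariances: list[Covariance] = []
    residuals: list[ResidualVariance] = []
    latent_order: list[str] = []
    appearance: list[str] = []

    def seen(name: str) -> None:
        if name not in appearance:
            appearance.append(name)

    for lineno, rawline in enumerate(text.splitlines(), start=1):
        line = rawline.split("#", 1)[0].strip()
        if not line:
            continue
        op = None
        for candidate in ("=~", "~~", "~"):
            if candidate in line:
                op = candidate
                break
        if op is None:
            raise ModelSyntaxError(
                f"line {lineno}: no operator found (expected one of =~, ~, ~~): {rawline!r}"
            )
        lhs, _, rhs = line.partition(op)
        lhs = _check_name(lhs.strip(), lineno)
        terms = [t for t in (s.strip() for s in rhs.split("+")) if t]
        if not terms:
            raise ModelSyntaxError(f"line {lineno}: empty right-hand side")

        if op == "=~":
            if lhs not in latent_order:
                latent_order.append(lhs)
            seen(lhs)
            for term in terms:
                name, value, label = _parse_term(term, lineno)
                _check_name(name, lineno)
                seen(name)
                loadings.append(Loading(lhs, name, value, label))
        elif op == "~":
            seen(lhs)
            for term in terms:
                name, value, label = _parse_term(term, lineno)
                _check_name(name, lineno)
                seen(name)
                regressions.append(Regression(lhs, name, value, label))
        else:  # ~~
            seen(lhs)
            if len(terms) != 1:
                raise ModelSyntaxError(f"line {lineno}: '~~' takes a single right-hand term")
            name, value, label = _parse_term(terms[0], lineno)
            _check_name(name, lineno)
            seen(name)
            if name == lhs:
                residuals.append(ResidualVariance(lhs, value, label))
            else:
                covariances.append(Covariance(lhs, name, value, label))

    latents = tuple(latent_order)
    manifests = tuple(n for n in appearance if n not in latent_order)
    if not manifests:
        raise ModelSyntaxError("model declares no manifest variables")

    # marker-variable scaling: fix the first modifier-free loading per latent
    fixed_var = {rv.var for rv in residuals if rv.value is not None}
    fixed_var |= {c.var1 for c in covariances if c.var1 == c.var2 and c.value is not None}
    for lat in latents:
        own = [i for i, ld in enumerate(loadings) if ld.latent == lat]
        if not own:
            continue
        if any(loadings[i].value is not None for i in own):
            continue  # user fixed a loading already
        if lat in fixed_var:
            continue  # latent variance fixed instead
        for i in own:
            ld = loadings[i]
            if ld.label is None:
                loadings[i] = Loading(ld.latent, ld.manifest, 1.0, None)
                break

    # single-indicator convention: indicator residual fixed to 0
    declared_resid = {rv.var for rv in residuals}
    for lat in latents:
        own = [ld for ld in loadings if ld.latent == lat]
        if len(own) == 1 and own[0].value is not None:
            ind = own[0].manifest
            if ind not in declared_resid and ind in manifests:
                residuals.append(ResidualVariance(ind, 0.0, None))
                declared_resid.add(ind)

    spec = ModelSpec(
        latents=latents,
        manifests=manifests,
        loadings=tuple(loadings),
        regressions=tuple(regressions),
        covariances=tuple(covariances),
        residual_variances=tuple(residuals),
    )
    _check_acyclic(spec)
    return spec


def _directed_edges(spec: ModelSpec) -> list[tuple[str, str]]:
    edges = [(ld.latent, ld.manifest) for ld in spec.loadings]
    edges += [(r.predictor, r.outcome) for r in spec.regressions]
    return edges


def _check_acyclic(spec: ModelSpec) -> None:
    """Kahn's algorithm; raises on a directed cycle among paths/loadings."""
    nodes = set(spec.all_vars)
    out: dict[str, set[str]] = {n: set() for n in nodes}
    indeg = {n: 0 for n in nodes}
    for a, b in _directed_edges(spec):
        if b not in out[a]:
            out[a].add(b)
            indeg[b] += 1
    queue = [n for n in nodes if indeg[n] == 0]
    visited = 0
    while queue:
        n = queue.pop()
        visited += 1
        for m in out[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                queue.append(m)
    if visited != len(nodes):
        cyclic = sorted(n for n in nodes if indeg[n] > 0)
        raise IdentificationError(f"directed cycle among variables: {cyclic}")


# ---------------------------------------------------------------------------
# RAM compilation
# ---------------------------------------------------------------------------

@dataclass
class RAMMatrices:
    """Reticular-action-model form: directed A, symmetric S, filter F.

    Variables are ordered manifests-first.  ``param_map`` sends each free
    parameter name to the list of cells it occupies; equality-labeled
    parameters occupy several cells.
    """

    var_names: tuple[str, ...]
    manifests: tuple[str, ...]
    latents: tuple[str, ...]
    A_fixed: np.ndarray
    S_fixed: np.ndarray
    F: np.ndarray
    param_names: tuple[str, ...]
    param_map: dict[str, list[tuple[str, int, int]]]
    # flat index arrays for fast assembly
    _a_cells: np.ndarray = field(repr=False, default=None)  # (k, 3): param, i, j
    _s_cells: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        a_cells, s_cells = [], []
        for k, name in enumerate(self.param_names):
            for mat, i, j in self.param_map[name]:
                (a_cells if mat == "A" else s_cells).append((k, i, j))
        self._a_cells = np.asarray(a_cells, dtype=np.intp).reshape(-1, 3)
        self._s_cells = np.asarray(s_cells, dtype=np.intp).reshape(-1, 3)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    @property
    def n_manifest(self) -> int:
        return len(self.manifests)

    @property
    def manifest_idx(self) -> np.ndarray:
        return np.arange(len(self.manifests), dtype=np.intp)

    def materialize(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, S) with free cells filled from ``theta``."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(f"theta must have length {self.n_free}")
        A = self.A_fixed.copy()
        S = self.S_fixed.copy()
        if len(self._a_cells):
            A[self._a_cells[:, 1], self._a_cells[:, 2]] = theta[self._a_cells[:, 0]]
        if len(self._s_cells):
            S[self._s_cells[:, 1], self._s_cells[:, 2]] = theta[self._s_cells[:, 0]]
            S[self._s_cells[:, 2], self._s_cells[:, 1]] = theta[self._s_cells[:, 0]]
        return A, S

    def theta_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names, np.asarray(theta, dtype=float)))


def _param_entries(spec: ModelSpec) -> list[tuple[str, str, str, str, float | None]]:
    """Enumerate all parameter cells as (kind, row_var, col_var, name, fixed).

    kind is 'A' or 'S'.  Free cells carry fixed=None; name is the equality
    label when present, else an auto-name.  Order is deterministic.
    """
    entries: list[tuple[str, str, str, str, float | None]] = []
    for ld in spec.loadings:
        name = ld.label or f"{ld.latent}=~{ld.manifest}"
        entries.append(("A", ld.manifest, ld.latent, name, ld.value))
    for r in spec.regressions:
        name = r.label or f"{r.outcome}~{r.predictor}"
        entries.append(("A", r.outcome, r.predictor, name, r.value))
    declared_cov = set()
    for c in spec.covariances:
        name = c.label or f"{c.var1}~~{c.var2}"
        entries.append(("S", c.var1, c.var2, name, c.value))
        declared_cov.add(frozenset((c.var1, c.var2)))
    declared_var = {rv.var for rv in spec.residual_variances}
    for rv in spec.residual_variances:
        name = rv.label or f"{rv.var}~~{rv.var}"
        entries.append(("S", rv.var, rv.var, name, rv.value))

    # default variances
    for v in spec.all_vars:
        if v not in declared_var:
            entries.append(("S", v, v, f"{v}~~{v}", None))
    # default covariances among exogenous latents and exogenous predictors
    exo = spec.exogenous
    pool = [
        v
        for v in spec.all_vars
        if v in exo and (v in spec.latents or v in spec.predictors)
    ]
    for i, a in enumerate(pool):
        for b in pool[i + 1:]:
            if frozenset((a, b)) not in declared_cov:
                entries.append(("S", a, b, f"{a}~~{b}", None))
    return entries


def build_ram(spec: ModelSpec) -> RAMMatrices:
    """Compile a ModelSpec into RAM matrices with default parameters applied."""
    _check_acyclic(spec)
    names = spec.all_vars
    idx = {n: i for i, n in enumerate(names)}
    m = len(names)
    p = len(spec.manifests)
    A_fixed = np.zeros((m, m))
    S_fixed = np.zeros((m, m))
    param_map: dict[str, list[tuple[str, int, int]]] = {}
    param_order: list[str] = []

    for kind, rv, cv, name, fixed in _param_entries(spec):
        for v in (rv, cv):
            if v not in idx:
                raise ModelSyntaxError(f"unknown variable {v!r} in parameter {name!r}")
        i, j = idx[rv], idx[cv]
        if kind == "S" and i > j:
            i, j = j, i
        if fixed is not None:
            if kind == "A":
                A_fixed[i, j] = fixed
            else:
                S_fixed[i, j] = fixed
                S_fixed[j, i] = fixed
            continue
        if name not in param_map:
            param_map[name] = []
            param_order.append(name)
        cell = (kind, i, j)
        if cell not in param_map[name]:
            param_map[name].append(cell)

    F = np.zeros((p, m))
    F[np.arange(p), np.arange(p)] = 1.0

    ram = RAMMatrices(
        var_names=names,
        manifests=spec.manifests,
        latents=spec.latents,
        A_fixed=A_fixed,
        S_fixed=S_fixed,
        F=F,
        param_names=tuple(param_order),
        param_map=param_map,
    )
    return ram


def degrees_of_freedom(spec: ModelSpec) -> int:
    """p(p+1)/2 minus the number of distinct free parameters."""
    ram = build_ram(spec)
    p = len(spec.manifests)
    df = p * (p + 1) // 2 - ram.n_free
    if df < 0:
        raise IdentificationError(
            f"model has {ram.n_free} free parameters but only "
            f"{p * (p + 1) // 2} observed moments (df = {df})"
        )
    return df


# ---------------------------------------------------------------------------
# Identification report
# ---------------------------------------------------------------------------

@dataclass
class IdentificationReport:
    passed: bool
    messages: tuple[str, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "passes necessary conditions" if self.passed else "identification problems"
        return status + ("" if not self.messages else ":\n  " + "\n  ".join(self.messages))


def check_identification(spec: ModelSpec) -> IdentificationReport:
    """Necessary-condition checks only (t-rule, scaling); never raises.

    A clean report does not guarantee identification; a flagged one indicates
    a definite structural problem.
    """
    messages: list[str] = []

    fixed_var = {
        rv.var for rv in spec.residual_variances if rv.value is not None
    }
    for lat in spec.latents:
        own = [ld for ld in spec.loadings if ld.latent == lat]
        if not own:
            continue
        if not any(ld.value is not None for ld in own) and lat not in fixed_var:
            messages.append(f"latent {lat!r}: no scaling constraint")
        if len(own) == 1:
            ind = own[0].manifest
            declared = {
                rv.var: rv.value for rv in spec.residual_variances
            }
            if declared.get(ind, None) is None:
                messages.append(
                    f"single-indicator latent {lat!r}: residual of {ind!r} not fixed"
                )

    try:
        ram = build_ram(spec)
        p = len(spec.manifests)
        df = p * (p + 1) // 2 - ram.n_free
        if df < 0:
            messages.append(
                f"t-rule violated: {ram.n_free} free parameters > "
                f"{p * (p + 1) // 2} observed moments"
            )
    except (IdentificationError, ModelSyntaxError) as exc:
        messages.append(str(exc))

    return IdentificationReport(passed=not messages, messages=tuple(messages))
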