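"""SEM Trees: recursive covariate splitting of a structural model.

A tree is grown for a single focus parameter.  At each node, candidate age
thresholds (midpoints between consecutive distinct covariate values leaving
at least ``min_group_n`` subjects on each side) are scored by k-fold
cross-validated log-likelihood gain: the two-group model (focus parameter
free per group, every other parameter equality-constrained across groups)
and the one-group model are both fit on the training folds, and the gain of
the two-group model is evaluated on the held-out fold.  A split is accepted
when its summed held-out gain is positive and consistently positive across
folds (one-sided t-test; guards against the best-of-many-candidates
selection effect on null data); ties break toward the younger threshold.
Growth is best-first across current leaves and stops at ``max_groups``
leaves.

After growing, a single multi-group fit over the leaf partition yields the
per-leaf focus estimates (so leaf estimates coincide exactly with a direct
multi-group fit) and the shared invariant parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .estimation import (
    GTOL,
    _FIMLObjective,
    _ram_internals,
    _start_values,
)
from .model_spec import ModelSpec, build_ram

__all__ = [
    "SEMTreeConfig",
    "TreeNode",
    "SEMTree",
    "candidate_splits",
    "evaluate_split",
    "grow_tree",
    "fit_multigroup",
    "MultiGroupFit",
]


@dataclass(frozen=True)
class SEMTreeConfig:
    focus_parameters: tuple[str, ...]
    covariate: str = "age"
    min_group_n: int = 50
    max_groups: int = 4
    folds: int = 10
    seed: int = 0
    # candidate thresholds are thinned to at most this many, evenly spaced
    max_candidates: int | None = 30
    # a split is accepted only if its held-out gain is positive AND
    # consistently so across folds (one-sided t-test at this level); guards
    # against the best-of-many-candidates selection effect on null data
    split_alpha: float = 0.01

    def __post_init__(self):
        if self.min_group_n < 1:
            raise ValueError("min_group_n must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.max_groups < 1:
            raise ValueError("max_groups must be >= 1")
        if not self.focus_parameters:
            raise ValueError("at least one focus parameter required")


def candidate_splits(ages: Sequence[float], min_group_n: int) -> np.ndarray:
    """Midpoints between consecutive distinct ages with both sides >= min_group_n."""
    ages = np.sort(np.asarray(ages, dtype=float))
    n = len(ages)
    if n < 2 * min_group_n:
        return np.empty(0)
    out = []
    for i in range(n - 1):
        left = i + 1
        right = n - left
        if ages[i] == ages[i + 1]:
            continue
        if left >= min_group_n and right >= min_group_n:
            out.append(0.5 * (ages[i] + ages[i + 1]))
    return np.unique(np.asarray(out))


# ---------------------------------------------------------------------------
# Multi-group FIML with parameter sharing
# ---------------------------------------------------------------------------

@dataclass
class MultiGroupFit:
    param_names: tuple[str, ...]       # global names (focus suffixed @g)
    x: np.ndarray
    loglik: float
    converged: bool
    grad_norm: float
    n_groups: int
    focus: tuple[str, ...]
    ram: object

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.x))

    def focus_by_group(self, name: str) -> list[float]:
        est = self.estimates
        return [est[f"{name}@{g}"] for g in range(self.n_groups)]

    def shared_estimates(self) -> dict[str, float]:
        return {k: v for k, v in self.estimates.items() if "@" not in k}


def _resolve_param(ram, name: str) -> str:
    """Match a parameter name, accepting 'a~~b' in either variable order."""
    if name in ram.param_names:
        return name
    if "~~" in name:
        a, _, b = name.partition("~~")
        swapped = f"{b}~~{a}"
        if swapped in ram.param_names:
            return swapped
    raise ValueError(f"focus parameters not in model: [{name!r}]")


class _MultiGroupObjective:
    """Sum of per-group FIML objectives with shared/focus parameter mapping.

    Global vector layout: shared theta params, then focus params per group,
    then a shared mean vector.
    """

    def __init__(self, ram, group_rows: list[np.ndarray], focus: Sequence[str]):
        self.ram = ram
        self.focus = tuple(_resolve_param(ram, f) for f in focus)
        self.n_groups = len(group_rows)
        self.n_total = sum(len(r) for r in group_rows)
        self.objs = [_FIMLObjective(ram, rows, scale=1.0 / self.n_total)
                     for rows in group_rows]
        p = ram.n_manifest
        shared = [n for n in ram.param_names if n not in self.focus]
        names = list(shared)
        for g in range(self.n_groups):
            names += [f"{f}@{g}" for f in self.focus]
        self.global_names = tuple(names)
        self.n_theta_global = len(names)
        pos = {n: k for k, n in enumerate(names)}
        self.mu_offset = self.n_theta_global
        self.n_global = self.n_theta_global + p
        # per-group index arrays into the global vector
        self.group_idx = []
        for g in range(self.n_groups):
            idx = np.empty(ram.n_free + p, dtype=np.intp)
            for j, name in enumerate(ram.param_names):
                idx[j] = pos[f"{name}@{g}"] if name in self.focus else pos[name]
            idx[ram.n_free:] = self.mu_offset + np.arange(p)
            self.group_idx.append(idx)

    def value_and_grad(self, x: np.ndarray):
        total = 0.0
        grad = np.zeros(self.n_global)
        for g in range(self.n_groups):
            v, gr = self.objs[g].value_and_grad(x[self.group_idx[g]])
            total += v
            np.add.at(grad, self.group_idx[g], gr)
        return total, grad

    def start(self, pooled_rows: np.ndarray) -> np.ndarray:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S_obs = pd.DataFrame(pooled_rows).cov(min_periods=2).to_numpy()
            mu = np.nanmean(pooled_rows, axis=0)
        S_obs = np.where(np.isnan(S_obs), 0.0, S_obs)
        theta0 = _start_values(self.ram, S_obs)
        base = dict(zip(self.ram.param_names, theta0))
        return self.start_from(base, mu)

    def start_from(self, values: dict, mu: np.ndarray) -> np.ndarray:
        """Assemble a start vector from per-parameter values + mean vector."""
        x0 = np.empty(self.n_global)
        for k, name in enumerate(self.global_names):
            x0[k] = values[name.split("@")[0]]
        x0[self.mu_offset:] = mu
        return x0


def fit_multigroup(spec: ModelSpec, group_rows: list[np.ndarray],
                   focus: Sequence[str] = (), start: np.ndarray | None = None,
                   warm: tuple[dict, np.ndarray] | None = None,
                   maxiter: int = 2000) -> MultiGroupFit:
    """FIML fit with all non-focus parameters shared across groups.

    ``warm`` = (param-value dict, mean vector) seeds the optimizer from a
    previous related solution.
    """
    from .estimation import newton_polish

    ram = build_ram(spec)
    obj = _MultiGroupObjective(ram, group_rows, focus)
    if start is not None:
        x0 = start
    elif warm is not None:
        x0 = obj.start_from(*warm)
    else:
        x0 = obj.start(np.vstack(group_rows))
    if warm is not None or start is not None:
        # near-optimal start: damped Newton converges in a few iterations
        x, fval, grad = newton_polish(obj.value_and_grad, x0, iters=25,
                                      chord=True)
        if np.abs(grad).max() > GTOL:  # fall back to the quasi-Newton stage
            res = optimize.minimize(obj.value_and_grad, x, jac=True,
                                    method="L-BFGS-B",
                                    options={"maxiter": maxiter, "ftol": 1e-11,
                                             "gtol": 1e-7})
            x, fval, grad = newton_polish(obj.value_and_grad, res.x)
    else:
        res = optimize.minimize(obj.value_and_grad, x0, jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 1e-11,
                                         "gtol": 1e-7})
        x, fval, grad = newton_polish(obj.value_and_grad, res.x)
    grad_norm = float(np.abs(grad).max())
    converged = np.isfinite(fval) and fval < _FIMLObjective.PENALTY / 2 \
        and grad_norm <= GTOL
    fit = MultiGroupFit(param_names=obj.global_names, x=x,
                        loglik=-float(fval) * obj.n_total,
                        converged=bool(converged),
                        grad_norm=grad_norm, n_groups=len(group_rows),
                        focus=tuple(focus), ram=ram)
    fit._objective = obj
    return fit


# ---------------------------------------------------------------------------
# Split scoring
# ---------------------------------------------------------------------------

def _fold_assignment(threshold: float, sides: np.ndarray, folds: int,
                     seed: int) -> np.ndarray:
    """Deterministic stratified fold labels (stratified by split side)."""
    key = abs(int(round(threshold * 1e6)))
    rng = np.random.default_rng([seed, key])
    labels = np.empty(len(sides), dtype=np.intp)
    for side in (False, True):
        idx = np.flatnonzero(sides == side)
        rng.shuffle(idx)
        labels[idx] = np.arange(len(idx)) % folds
    return labels


def evaluate_split(spec: ModelSpec, data: pd.DataFrame, threshold: float,
                   config: SEMTreeConfig,
                   warm: tuple[dict, np.ndarray] | None = None,
                   return_folds: bool = False):
    """Cross-validated log-likelihood gain of splitting at ``threshold``.

    For each fold, the two-group model (focus free per group, everything
    else shared) and the one-group model are fit on the training portion and
    the log-likelihood gain is evaluated on the held-out portion; the score
    is the sum over folds.  Returns -inf when any sub-fit fails to converge.
    With ``return_folds`` the per-fold gains are returned as well.
    """
    focus = config.focus_parameters
    cols = list(spec.manifests)
    ages = data[config.covariate].to_numpy(dtype=float)
    raw = data[cols].to_numpy(dtype=float)
    sides = ages > threshold
    labels = _fold_assignment(threshold, sides, config.folds, config.seed)
    ram = build_ram(spec)

    if warm is None:
        node_fit = fit_multigroup(spec, [raw], focus=())
        if not node_fit.converged:
            return (-np.inf, []) if return_folds else -np.inf
        warm = (node_fit.shared_estimates(),
                node_fit.x[node_fit._objective.mu_offset:])

    gains = []
    for f in range(config.folds):
        test = labels == f
        train = ~test
        tr_groups = [raw[train & ~sides], raw[train & sides]]
        te_groups = [raw[test & ~sides], raw[test & sides]]
        if min(g.shape[0] for g in tr_groups) < 2:
            return (-np.inf, []) if return_folds else -np.inf
        split_fit = fit_multigroup(spec, tr_groups, focus=focus, warm=warm)
        null_fit = fit_multigroup(spec, [raw[train]], focus=(), warm=warm)
        if not (split_fit.converged and null_fit.converged):
            return (-np.inf, []) if return_folds else -np.inf
        null_obj = null_fit._objective
        split_obj = split_fit._objective
        mu_s = split_fit.x[split_obj.mu_offset:]
        mu_n = null_fit.x[null_obj.mu_offset:]
        theta_n = null_fit.x[null_obj.group_idx[0]][:ram.n_free]
        *_, Sigma_n = _ram_internals(ram, theta_n)
        Sigma_n = (Sigma_n + Sigma_n.T) / 2
        ll_split = 0.0
        ll_null = 0.0
        for g, rows in enumerate(te_groups):
            if not rows.shape[0]:
                continue
            obj = _FIMLObjective(ram, rows)
            theta_g = split_fit.x[split_obj.group_idx[g]][:ram.n_free]
            *_, Sigma_g = _ram_internals(ram, theta_g)
            try:
                ll_split += obj.loglik_at((Sigma_g + Sigma_g.T) / 2, mu_s)
                ll_null += obj.loglik_at(Sigma_n, mu_n)
            except Exception:
                return (-np.inf, []) if return_folds else -np.inf
        gains.append(ll_split - ll_null)
    score = float(np.sum(gains))
    return (score, gains) if return_folds else score


# ---------------------------------------------------------------------------
# Tree growing
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    indices: np.ndarray
    depth: int
    threshold: float | None = None
    cv_score: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    estimate: float | None = None   # focus-parameter estimate (leaves)

    @property
    def n(self) -> int:
        return len(self.indices)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SEMTree:
    root: TreeNode
    focus_parameter: str
    config: SEMTreeConfig
    shared_estimates: dict[str, float]
    converged: bool

    @property
    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    @property
    def split_ages(self) -> list[float]:
        out = []

        def walk(node):
            if not node.is_leaf:
                out.append(node.threshold)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return sorted(out)

    def leaf_estimates(self) -> list[float]:
        """Focus estimates ordered by age segment (youngest first)."""
        return [leaf.estimate for leaf in self.leaves]

    def to_dict(self) -> dict:
        def node_dict(node):
            d = {"n": node.n, "estimate": node.estimate}
            if not node.is_leaf:
                d["threshold"] = node.threshold
                d["cv_score"] = node.cv_score
                d["children"] = [node_dict(c) for c in node.children]
            return d

        return {
            "focus_parameter": self.focus_parameter,
            "covariate": self.config.covariate,
            "split_ages": self.split_ages,
            "leaf_estimates": self.leaf_estimates(),
            "shared_estimates": self.shared_estimates,
            "tree": node_dict(self.root),
        }

    def to_markdown(self) -> str:
        """One row shaped like: estimate | split age | estimate | ..."""
        cells = []
        leaves = self.leaves
        splits = self.split_ages
        for k, leaf in enumerate(leaves):
            cells.append(f"{leaf.estimate:.2f}" if leaf.estimate is not None else "-")
            if k < len(splits):
                cells.append(f"**{splits[k]:.2f}**")
        header_cells = []
        for k in range(len(leaves)):
            header_cells.append("Estimate" if k == 0 else "Estimate Between")
            if k < len(splits):
                header_cells.append(f"Age Split {k + 1}")
        header = "| Path | " + " | ".join(header_cells) + " |"
        rule = "|" + "---|" * (len(cells) + 1)
        row = f"| {self.focus_parameter} | " + " | ".join(cells) + " |"
        return "\n".join([header, rule, row])


def grow_tree(spec: ModelSpec, data: pd.DataFrame, config: SEMTreeConfig
              ) -> SEMTree:
    """Grow a tree for a single focus parameter (best-first, greedy)."""
    if len(config.focus_parameters) != 1:
        raise ValueError("grow one tree per focus parameter")
    focus = _resolve_param(build_ram(spec), config.focus_parameters[0])
    cols = list(spec.manifests)
    missing_cols = [c for c in cols + [config.covariate] if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks columns {missing_cols}")
    ages_all = data[config.covariate].to_numpy(dtype=float)
    raw_all = data[cols].to_numpy(dtype=float)

    root_fit = fit_multigroup(spec, [raw_all], focus=())
    if not root_fit.converged:
        raise RuntimeError("root model fit did not converge")

    root = TreeNode(indices=np.arange(len(data)), depth=0)
    leaves = [root]
    t_crit = stats.t.ppf(1.0 - config.split_alpha, config.folds - 1)

    def best_split(node: TreeNode):
        sub = data.iloc[node.indices]
        ages = ages_all[node.indices]
        cands = candidate_splits(ages, config.min_group_n)
        if config.max_candidates is not None and len(cands) > config.max_candidates:
            pick = np.linspace(0, len(cands) - 1, config.max_candidates)
            cands = cands[np.round(pick).astype(int)]
        if not len(cands):
            return (None, 0.0)
        node_fit = fit_multigroup(spec, [raw_all[node.indices]], focus=())
        if not node_fit.converged:
            return (None, 0.0)
        warm = (node_fit.shared_estimates(),
                node_fit.x[node_fit._objective.mu_offset:])
        best = (None, 0.0)
        for t in cands:
            s, gains = evaluate_split(spec, sub, float(t), config, warm=warm,
                                      return_folds=True)
            if not np.isfinite(s) or s <= 0 or len(gains) < 2:
                continue
            sd = float(np.std(gains, ddof=1))
            tstat = np.inf if sd == 0 else \
                float(np.mean(gains)) / (sd / np.sqrt(len(gains)))
            if tstat <= t_crit:
                continue
            # strict improvement; ties break toward the younger threshold
            if s > best[1] + 1e-12:
                best = (float(t), s)
        return best

    pending: dict[int, tuple] = {}
    while len(leaves) < config.max_groups:
        for node in leaves:
            if id(node) not in pending:
                if node.n >= 2 * config.min_group_n:
                    pending[id(node)] = best_split(node)
                else:
                    pending[id(node)] = (None, 0.0)
        splittable = [(node, *pending[id(node)]) for node in leaves
                      if pending[id(node)][0] is not None]
        if not splittable:
            break
        node, thr, score = max(splittable, key=lambda item: (item[2], -item[1]))
        node.threshold = thr
        node.cv_score = score
        side = ages_all[node.indices] > thr
        node.children = [
            TreeNode(indices=node.indices[~side], depth=node.depth + 1),
            TreeNode(indices=node.indices[side], depth=node.depth + 1),
        ]
        leaves = _ordered_leaves(root, ages_all)

    # final multi-group fit over the leaf partition
    leaves = _ordered_leaves(root, ages_all)
    groups = [raw_all[leaf.indices] for leaf in leaves]
    final = fit_multigroup(spec, groups, focus=(focus,) if len(leaves) > 1 else ())
    if len(leaves) > 1:
        vals = final.focus_by_group(focus)
    else:
        vals = [final.estimates[focus]]
    for leaf, v in zip(leaves, vals):
        leaf.estimate = float(v)
    return SEMTree(root=root, focus_parameter=focus, config=config,
                   shared_estimates=final.shared_estimates(),
                   converged=final.converged)


def _ordered_leaves(root: TreeNode, ages_all: np.ndarray) -> list[TreeNode]:
    out = []

    def walk(node):
        if node.is_leaf:
            out.append(node)
        else:
            kids = sorted(node.children,
                          key=lambda c: ages_all[c.indices].mean())
            for c in kids:
                walk(c)

    walk(root)
    return out
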