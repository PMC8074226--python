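"""Maximum-likelihood fitting of codon site models.

Free parameters are optimized by bounded quasi-Newton (L-BFGS-B) in a
transformed space: positive parameters (kappa, omega, beta shapes, tree
scale, branch lengths) on a log scale, mixture proportions on the raw scale
with open-interval bounds. Three branch-length treatments are available:

* ``scale`` (default) — the input tree's relative branch lengths are kept
  and a single rate-scale factor is estimated. This is the recommended mode
  when the tree (with meaningful branch lengths) is trusted, and is what the
  cohort pipeline uses after an M0 fit.
* ``estimate`` — every branch length is a free parameter.
* ``fixed`` — branch lengths are used exactly as given.

Per-site class posteriors are computed empirical-Bayes style at the MLEs
(NEB); an optional BEB-style mode integrates the M8 posterior over a grid
prior on (p0, omega_s) to account for sampling error in those parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .likelihood import (
    SitePatterns,
    class_pattern_loglik,
    compress_alignment,
    mixture_loglik,
)
from .rates import (
    CodonRateModel,
    f3x4_frequencies,
    uniform_codon_freqs,
    validate_codon_freqs,
)
from .sitemodels import (
    MODEL_NAMES,
    SiteClassModel,
    m0_model,
    m2_model,
    m8_model,
    m8a_model,
)
from .trees import PhyloTree

OMEGA_BOUNDS = (1e-4, 50.0)
KAPPA_BOUNDS = (0.1, 50.0)
OMEGA_S_BOUNDS = (1.0, 50.0)
SHAPE_BOUNDS = (5e-3, 99.0)
PROP_BOUNDS = (1e-6, 1.0 - 1e-6)
SCALE_BOUNDS = (1e-3, 100.0)
BRANCH_BOUNDS = (1e-7, 10.0)


@dataclass
class FitOptions:
    freq_mode: str = "f3x4"          # f3x4 | f61 | uniform
    branch_mode: str = "scale"       # scale | estimate | fixed
    estimate_kappa: bool = True
    kappa_init: float = 2.0
    n_starts: int = 1
    maxiter: int = 500
    ftol: float = 1e-10               # relative; ~1e-6 lnL units at typical scales
    share_kappa: bool = True          # richer models inherit M0's kappa MLE
    seed: int = 0
    jitter: float = 0.3              # lognormal sd for extra starts
    site_cutoff: float = 0.5         # NEB selected-site posterior cutoff
    site_cutoff_high: float = 0.95   # "high confidence" tier


@dataclass
class FitResult:
    model: str
    lnl: float
    params: dict[str, float]
    kappa: float
    codon_freqs: np.ndarray
    tree: PhyloTree                      # with fitted branch lengths
    site_model: SiteClassModel
    n_sites_analyzed: int
    converged: bool
    n_iter: int
    n_evals: int
    n_starts: int
    message: str = ""
    patterns: SitePatterns | None = field(default=None, repr=False)

    @property
    def tree_length(self) -> float:
        return self.tree.tree_length()


class _Parameter:
    def __init__(self, name: str, init: float, bounds: tuple[float, float], log: bool):
        self.name, self.init, self.bounds, self.log = name, init, bounds, log

    def encode(self, v: float) -> float:
        lo, hi = self.bounds
        v = min(max(v, lo), hi)
        return math.log(v) if self.log else v

    def decode(self, x: float) -> float:
        return math.exp(x) if self.log else x

    def encoded_bounds(self) -> tuple[float, float]:
        lo, hi = self.bounds
        return (math.log(lo), math.log(hi)) if self.log else (lo, hi)


def _model_parameters(model_name: str, init: dict[str, float]) -> list[_Parameter]:
    g = init.get
    if model_name == "M0":
        return [_Parameter("omega", g("omega", 0.3), OMEGA_BOUNDS, log=True)]
    if model_name == "M2":
        return [
            _Parameter("p0", g("p0", 0.8), PROP_BOUNDS, log=False),
            _Parameter("p2_frac", g("p2_frac", 0.2), PROP_BOUNDS, log=False),
            _Parameter("omega0", g("omega0", 0.1), (1e-4, 1.0 - 1e-6), log=True),
            _Parameter("omega2", g("omega2", 2.0), OMEGA_S_BOUNDS, log=True),
        ]
    if model_name in ("M8", "M8a"):
        ps = [
            _Parameter("p0", g("p0", 0.9), PROP_BOUNDS, log=False),
            _Parameter("p", g("p", 0.5), SHAPE_BOUNDS, log=True),
            _Parameter("q", g("q", 1.0), SHAPE_BOUNDS, log=True),
        ]
        if model_name == "M8":
            ps.append(
                _Parameter("omega_s", g("omega_s", 2.0), OMEGA_S_BOUNDS, log=True)
            )
        return ps
    raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")


def build_site_model(model_name: str, params: dict[str, float]) -> SiteClassModel:
    if model_name == "M0":
        return m0_model(params["omega"])
    if model_name == "M2":
        p0 = params["p0"]
        p2 = (1.0 - p0) * params["p2_frac"]
        return m2_model(p0, p2, params["omega0"], params["omega2"])
    if model_name == "M8":
        return m8_model(params["p0"], params["p"], params["q"], params["omega_s"])
    if model_name == "M8a":
        return m8a_model(params["p0"], params["p"], params["q"])
    raise ValueError(f"unknown model {model_name!r}")


def build_class_models(
    site_model: SiteClassModel, kappa: float, codon_freqs: np.ndarray
) -> list[CodonRateModel]:
    cache: dict[float, CodonRateModel] = {}
    out = []
    for om in site_model.omegas:
        key = float(om)
        if key not in cache:
            cache[key] = CodonRateModel(kappa=kappa, omega=key, codon_freqs=codon_freqs)
        out.append(cache[key])
    return out


def resolve_frequencies(aln: CodonAlignment, mode: str) -> np.ndarray:
    if mode == "uniform":
        return uniform_codon_freqs()
    if mode == "f3x4":
        return f3x4_frequencies(aln)
    if mode == "f61":
        idx = aln.codon_indices()
        counts = np.bincount(idx[idx >= 0], minlength=61).astype(float) + 0.5
        return counts / counts.sum()
    raise ValueError(f"unknown frequency mode {mode!r}")


def _make_objective(
    model_name: str,
    parameters: list[_Parameter],
    patterns: SitePatterns,
    tree: PhyloTree,
    base_lengths: np.ndarray,
    branch_mode: str,
    n_branch_params: int,
    codon_freqs: np.ndarray,
    fixed_kappa: float | None,
) -> Callable[[np.ndarray], float]:
    n_model = len(parameters) - n_branch_params - (0 if fixed_kappa is not None else 1)
    # Finite-difference gradients perturb one parameter at a time, so most
    # per-class likelihood rows recur from one evaluation to the next: a
    # weight perturbation changes no row, an omega_s perturbation one row of
    # eleven. Cache per-class rows keyed by (kappa, class omega, branch
    # lengths) and only prune the missing classes.
    rate_cache: dict[tuple[float, float], CodonRateModel] = {}
    row_cache: dict[tuple[float, float, bytes], np.ndarray] = {}

    def cached_rate_model(kappa: float, omega: float) -> CodonRateModel:
        if len(rate_cache) > 400:
            rate_cache.clear()
        key = (float(kappa), float(omega))
        if key not in rate_cache:
            rate_cache[key] = CodonRateModel(
                kappa=kappa, omega=float(omega), codon_freqs=codon_freqs
            )
        return rate_cache[key]

    def logl_rows(
        kappa: float, omegas: np.ndarray, fitted: PhyloTree, lkey: bytes
    ) -> np.ndarray:
        rows = np.empty((len(omegas), patterns.n_patterns))
        missing: list[int] = []
        for k, om in enumerate(omegas):
            cached = row_cache.get((float(kappa), float(om), lkey))
            if cached is None:
                missing.append(k)
            else:
                rows[k] = cached
        if missing:
            models = [cached_rate_model(kappa, float(omegas[k])) for k in missing]
            fresh = class_pattern_loglik(fitted, patterns, models)
            if len(row_cache) > 4000:
                row_cache.clear()
            for r, k in enumerate(missing):
                rows[k] = fresh[r]
                row_cache[(float(kappa), float(omegas[k]), lkey)] = fresh[r]
        return rows

    def negloglik(x: np.ndarray) -> float:
        vals = [p.decode(xi) for p, xi in zip(parameters, x)]
        model_params = dict(
            (p.name, v) for p, v in zip(parameters[:n_model], vals[:n_model])
        )
        pos = n_model
        if fixed_kappa is None:
            kappa = vals[pos]
            pos += 1
        else:
            kappa = fixed_kappa
        if branch_mode == "scale":
            lengths = base_lengths * vals[pos]
        elif branch_mode == "estimate":
            lengths = base_lengths.copy()
            free = np.array(vals[pos:], dtype=float)
            lengths[_free_edges(tree)] = free
        else:
            lengths = base_lengths
        try:
            site_model = build_site_model(model_name, model_params)
            fitted = tree.with_edge_lengths(lengths)
            lkey = np.asarray(lengths, dtype=float).tobytes()
            logl_kp = logl_rows(kappa, site_model.omegas, fitted, lkey)
            lnl = mixture_loglik(logl_kp, site_model.weights, patterns.counts)
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(lnl):
            return 1e12
        return -lnl

    return negloglik


def _free_edges(tree: PhyloTree) -> np.ndarray:
    return np.arange(tree.n_nodes - 1)  # all but the root's zero-length entry


def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model_name: str,
    options: FitOptions | None = None,
    init: dict[str, float] | None = None,
) -> FitResult:
    """Fit one site model to one alignment by maximum likelihood.

    The tree is pruned to the taxa shared with the alignment. Deterministic
    given (data, options, init): multistart jitter derives from
    ``options.seed``.
    """
    options = options or FitOptions()
    init = dict(init or {})
    shared = [t for t in tree.leaf_names if t in set(aln.taxa)]
    if len(shared) < 2:
        raise ValueError("tree and alignment share fewer than 2 taxa")
    work_tree = tree.subtree(shared) if len(shared) < tree.n_leaves else tree

    codon_freqs = validate_codon_freqs(resolve_frequencies(aln, options.freq_mode))
    patterns = compress_alignment(aln, tuple(work_tree.leaf_names))

    parameters = _model_parameters(model_name, init)
    fixed_kappa = None if options.estimate_kappa else options.kappa_init
    if options.estimate_kappa:
        parameters.append(
            _Parameter("kappa", init.get("kappa", options.kappa_init), KAPPA_BOUNDS, log=True)
        )

    base_lengths = work_tree.edge_length.copy()
    n_branch = 0
    if options.branch_mode == "scale":
        if base_lengths.sum() <= 0:
            raise ValueError("scale mode needs a tree with positive length")
        parameters.append(
            _Parameter("tree_scale", init.get("tree_scale", 1.0), SCALE_BOUNDS, log=True)
        )
        n_branch = 1
    elif options.branch_mode == "estimate":
        free = _free_edges(work_tree)
        lo = BRANCH_BOUNDS[0]
        for e in free:
            parameters.append(
                _Parameter(f"b{e}", max(base_lengths[e], 10 * lo), BRANCH_BOUNDS, log=True)
            )
        n_branch = len(free)
    elif options.branch_mode != "fixed":
        raise ValueError(f"unknown branch mode {options.branch_mode!r}")

    objective = _make_objective(
        model_name, parameters, patterns, work_tree, base_lengths,
        options.branch_mode, n_branch, codon_freqs, fixed_kappa,
    )

    x0 = np.array([p.encode(p.init) for p in parameters])
    bounds = [p.encoded_bounds() for p in parameters]
    rng = np.random.default_rng(options.seed)
    starts = [x0]
    for _ in range(options.n_starts - 1):
        jit = x0 + rng.normal(0.0, options.jitter, size=len(x0))
        starts.append(np.clip(jit, [b[0] for b in bounds], [b[1] for b in bounds]))

    best = None
    total_evals = 0
    for s in starts:
        res = minimize(
            objective, s, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.maxiter, "ftol": options.ftol, "gtol": 1e-5},
        )
        total_evals += int(res.nfev)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    vals = [p.decode(xi) for p, xi in zip(parameters, best.x)]
    named = {p.name: v for p, v in zip(parameters, vals)}
    kappa = fixed_kappa if fixed_kappa is not None else named["kappa"]
    model_params = {
        p.name: named[p.name]
        for p in parameters
        if p.name not in ("kappa", "tree_scale") and not p.name.startswith("b")
    }
    if options.branch_mode == "scale":
        fitted_lengths = base_lengths * named["tree_scale"]
        model_params["tree_scale"] = named["tree_scale"]
    elif options.branch_mode == "estimate":
        fitted_lengths = base_lengths.copy()
        fitted_lengths[_free_edges(work_tree)] = [
            named[f"b{e}"] for e in _free_edges(work_tree)
        ]
    else:
        fitted_lengths = base_lengths

    site_model = build_site_model(
        model_name, {k: v for k, v in model_params.items() if k != "tree_scale"}
    )
    lnl = -float(best.fun)
    converged = bool(best.success) and np.isfinite(lnl)
    return FitResult(
        model=model_name,
        lnl=lnl,
        params={**model_params, "kappa": kappa},
        kappa=kappa,
        codon_freqs=codon_freqs,
        tree=work_tree.with_edge_lengths(fitted_lengths),
        site_model=site_model,
        n_sites_analyzed=patterns.n_sites_analyzed,
        converged=converged,
        n_iter=int(best.nit),
        n_evals=total_evals,
        n_starts=options.n_starts,
        message=str(best.message),
        patterns=patterns,
    )


def fit_all_models(
    aln: CodonAlignment,
    tree: PhyloTree,
    options: FitOptions | None = None,
    models: tuple[str, ...] = ("M0", "M2", "M8a", "M8"),
) -> dict[str, FitResult]:
    """Fit a set of site models to one gene, sharing information across fits.

    M0 is fitted first; its kappa and fitted tree seed the richer models
    (which then re-estimate the overall rate scale). The M8 fit starts from
    the M8a solution, which guarantees lnL(M8) >= lnL(M8a) up to optimizer
    tolerance — the nesting the likelihood-ratio test relies on.
    """
    options = options or FitOptions()
    out: dict[str, FitResult] = {}
    base_tree = tree
    kappa_init = options.kappa_init

    if "M0" in models or {"M2", "M8", "M8a"} & set(models):
        m0 = fit_model(aln, base_tree, "M0", options)
        out["M0"] = m0
        base_tree = m0.tree
        kappa_init = m0.kappa

    rich_opts = replace(
        options,
        branch_mode="scale",
        kappa_init=kappa_init,
        estimate_kappa=options.estimate_kappa and not options.share_kappa,
    )
    seed_init = {"kappa": kappa_init, "tree_scale": 1.0}

    if "M2" in models:
        out["M2"] = fit_model(aln, base_tree, "M2", rich_opts, init=seed_init)
    if "M8a" in models or "M8" in models:
        m8a = fit_model(aln, base_tree, "M8a", rich_opts, init=seed_init)
        if "M8a" in models:
            out["M8a"] = m8a
        if "M8" in models:
            # The M8 surface is multimodal: a basin near the null (selected
            # sites absorbed by a large near-neutral class) competes with the
            # selection basin (small class at omega_s >> 1). Start from both.
            null_init = {
                "p0": min(m8a.params["p0"], PROP_BOUNDS[1]),
                "p": m8a.params["p"],
                "q": m8a.params["q"],
                "omega_s": 2.0,
                "kappa": m8a.kappa,
                "tree_scale": m8a.params.get("tree_scale", 1.0),
            }
            sel_init = {
                "p0": 0.85,
                "p": 0.5,
                "q": 1.5,
                "omega_s": 3.0,
                "kappa": m8a.kappa,
                "tree_scale": m8a.params.get("tree_scale", 1.0),
            }
            m8 = fit_model(aln, base_tree, "M8", rich_opts, init=null_init)
            in_selection_basin = (
                m8.params["omega_s"] >= 1.5 and m8.params["p0"] >= 0.7
            )
            if not in_selection_basin:
                m8_sel = fit_model(aln, base_tree, "M8", rich_opts, init=sel_init)
                if m8_sel.lnl > m8.lnl:
                    m8 = m8_sel
            if m8.lnl < m8a.lnl:
                # fall back to the boundary (omega_s -> 1), where M8 == M8a
                bound_init = dict(null_init, omega_s=1.0 + 1e-9)
                m8b = fit_model(aln, base_tree, "M8", rich_opts, init=bound_init)
                if m8b.lnl > m8.lnl:
                    m8 = m8b
            out["M8"] = m8
    return out


# ---------------------------------------------------------------------------
# Per-site posteriors
# ---------------------------------------------------------------------------


@dataclass
class SitePosteriors:
    """Per-codon class membership posteriors for one fitted model."""

    columns: np.ndarray            # original 0-based codon columns analyzed
    posteriors: np.ndarray         # (n_sites_analyzed, n_classes)
    positive_class: int | None     # index of the omega>1 class, if the model has one
    selected_sites: list[tuple[int, float]]  # (1-based codon column, posterior)
    method: str = "NEB"

    def positive_posterior(self) -> np.ndarray:
        if self.positive_class is None:
            return np.zeros(len(self.columns))
        return self.posteriors[:, self.positive_class]


def site_posteriors(
    fit: FitResult,
    aln: CodonAlignment,
    tree: PhyloTree | None = None,
    cutoff: float = 0.5,
    method: str = "NEB",
    beb_grid: int = 10,
) -> SitePosteriors:
    """Empirical-Bayes class posteriors per analyzed codon column.

    NEB (default) evaluates posteriors at the MLEs. BEB (M8 only) averages
    the NEB posterior over a uniform grid prior on (p0, omega_s), weighting
    each grid point by the data likelihood — a grid-integration account of
    the sampling error in those two parameters.
    """
    if not fit.converged:
        raise ValueError("refusing site posteriors from an unconverged fit")
    work_tree = fit.tree if tree is None else tree
    patterns = fit.patterns
    if patterns is None or tuple(patterns.leaf_order) != tuple(work_tree.leaf_names):
        patterns = compress_alignment(aln, tuple(work_tree.leaf_names))

    if method == "NEB":
        post = _neb(fit.site_model, fit.kappa, fit.codon_freqs, work_tree, patterns)
    elif method == "BEB":
        if fit.model != "M8":
            raise ValueError("BEB integration is defined for M8 fits")
        post = _beb_m8(fit, work_tree, patterns, beb_grid)
    else:
        raise ValueError(f"unknown method {method!r}")

    site_post = post[patterns.site_to_pattern]
    pos_class = fit.site_model.positive_class_index()
    selected: list[tuple[int, float]] = []
    if pos_class is not None and fit.model == "M8":
        for col, row in zip(patterns.kept_columns, site_post):
            if row[pos_class] > cutoff:
                selected.append((int(col) + 1, float(row[pos_class])))
    return SitePosteriors(
        columns=patterns.kept_columns.copy(),
        posteriors=site_post,
        positive_class=pos_class,
        selected_sites=selected,
        method=method,
    )


def _neb(
    site_model: SiteClassModel,
    kappa: float,
    codon_freqs: np.ndarray,
    tree: PhyloTree,
    patterns: SitePatterns,
) -> np.ndarray:
    models = build_class_models(site_model, kappa, codon_freqs)
    logl_kp = class_pattern_loglik(tree, patterns, models)
    logw = np.log(np.maximum(site_model.weights, 1e-300))
    num = logl_kp + logw[:, None]
    num -= num.max(axis=0, keepdims=True)
    w = np.exp(num)
    w /= w.sum(axis=0, keepdims=True)
    return w.T  # (n_patterns, n_classes)


def _beb_m8(
    fit: FitResult, tree: PhyloTree, patterns: SitePatterns, grid: int
) -> np.ndarray:
    p0_grid = (np.arange(grid) + 0.5) / grid
    ws_grid = 1.0 + 10.0 * (np.arange(grid) + 0.5) / grid
    total_post = np.zeros((patterns.n_patterns, 11))
    log_marg = np.empty((grid, grid))
    posts = {}
    for i, p0 in enumerate(p0_grid):
        for j, ws in enumerate(ws_grid):
            sm = build_site_model(
                "M8", {"p0": p0, "p": fit.params["p"], "q": fit.params["q"], "omega_s": ws}
            )
            models = build_class_models(sm, fit.kappa, fit.codon_freqs)
            logl_kp = class_pattern_loglik(tree, patterns, models)
            lnl = mixture_loglik(logl_kp, sm.weights, patterns.counts)
            log_marg[i, j] = lnl
            posts[(i, j)] = _neb_from_logl(sm, logl_kp)
    log_marg -= log_marg.max()
    gw = np.exp(log_marg)
    gw /= gw.sum()
    for (i, j), p in posts.items():
        total_post += gw[i, j] * p
    return total_post


def _neb_from_logl(site_model: SiteClassModel, logl_kp: np.ndarray) -> np.ndarray:
    logw = np.log(np.maximum(site_model.weights, 1e-300))
    num = logl_kp + logw[:, None]
    num -= num.max(axis=0, keepdims=True)
    w = np.exp(num)
    w /= w.sum(axis=0, keepdims=True)
    return w.T
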