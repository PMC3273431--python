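"""Codon site-model positive-selection machinery.

Site models assign each alignment site to a latent omega (= dN/dS) class:

* M0 — one omega for all sites;
* M1a — nearly neutral: omega0 < 1 and omega1 = 1;
* M2a — M1a plus a positive-selection class omega2 > 1;
* M3 — three free discrete omega classes;
* M7 — omega ~ Beta(p, q), discretized into equal-probability categories;
* M8 — M7 plus an extra class omega_s > 1 with proportion 1 - p0.

Likelihoods use Felsenstein pruning with GY94 transition matrices per class;
nested pairs (M0/M3, M1a/M2a, M7/M8) are compared by likelihood ratio tests
against chi-square (df 4, 2, 2).  Sites are assigned to classes by naive
empirical Bayes (NEB) at the MLEs or Bayes empirical Bayes (BEB), which
averages the posterior over a discrete uniform grid on the class parameters.
A Nei-Gojobori counting estimate of dN/dS serves as a model-free cross-check.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import betainc, logsumexp

from .codon import (
    CODON_AA,
    N_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    ReversibleGenerator,
    codon_frequencies,
    gy94_matrix,
    thread_codon_alignment,  # noqa: F401  (re-export: part of this module's surface)
)
from .tree import PhyloTree

__all__ = [
    "SiteModel",
    "FitResult",
    "LRTResult",
    "SiteClassPosterior",
    "NeiGojoboriResult",
    "MODEL_NAMES",
    "beta_category_means",
    "site_mixture_loglik",
    "site_class_log_likelihoods",
    "fit_site_model",
    "fit_models",
    "likelihood_ratio_test",
    "lrt_critical_value",
    "site_posteriors",
    "nei_gojobori",
    "thread_codon_alignment",
]

MODEL_NAMES = ("M0", "M1a", "M2a", "M3", "M7", "M8")


# ---------------------------------------------------------------------------
# Site models
# ---------------------------------------------------------------------------

def beta_category_means(p: float, q: float, k: int) -> np.ndarray:
    """Means of k equal-probability categories of Beta(p, q)."""
    if p <= 0 or q <= 0:
        raise ValueError("beta parameters must be positive")
    if k < 2:
        raise ValueError("need at least 2 categories")
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, k + 1), p, q)
    mass = betainc(p + 1.0, q, edges[1:]) - betainc(p + 1.0, q, edges[:-1])
    means = mass * (p / (p + q)) * k
    return np.clip(means, 1e-8, 1.0 - 1e-8)


@dataclass
class SiteModel:
    """A codon site-class model: kappa, codon frequencies and class structure."""

    name: str
    kappa: float
    pi: np.ndarray
    params: dict
    freq_scheme: str = "F3x4"

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        self.pi = np.asarray(self.pi, dtype=float)
        probs = self.class_probs()
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("class proportions must sum to 1")
        if (probs < -1e-12).any():
            raise ValueError("class proportions must be non-negative")
        if self.name == "M1a" and not self.params["omega0"] < 1.0:
            raise ValueError("M1a requires omega0 < 1")
        if self.name == "M2a" and not self.params["omega2"] > 1.0:
            raise ValueError("M2a requires omega2 > 1")
        if self.name == "M8" and not self.params["omega_s"] > 1.0:
            raise ValueError("M8 requires omega_s > 1")

    def class_probs(self) -> np.ndarray:
        p = self.params
        if self.name == "M0":
            return np.array([1.0])
        if self.name == "M1a":
            return np.array([p["p0"], 1.0 - p["p0"]])
        if self.name == "M2a":
            return np.array([p["p0"], p["p1"], 1.0 - p["p0"] - p["p1"]])
        if self.name == "M3":
            return np.asarray(p["probs"], dtype=float)
        if self.name == "M7":
            k = p["ncat"]
            return np.full(k, 1.0 / k)
        if self.name == "M8":
            k = p["ncat"]
            return np.append(np.full(k, p["p0"] / k), 1.0 - p["p0"])
        raise AssertionError

    def class_omegas(self) -> np.ndarray:
        p = self.params
        if self.name == "M0":
            return np.array([p["omega"]])
        if self.name == "M1a":
            return np.array([p["omega0"], 1.0])
        if self.name == "M2a":
            return np.array([p["omega0"], 1.0, p["omega2"]])
        if self.name == "M3":
            return np.asarray(p["omegas"], dtype=float)
        if self.name == "M7":
            return beta_category_means(p["p"], p["q"], p["ncat"])
        if self.name == "M8":
            return np.append(
                beta_category_means(p["p"], p["q"], p["ncat"]), p["omega_s"]
            )
        raise AssertionError

    @property
    def n_free_parameters(self) -> int:
        return {"M0": 2, "M1a": 3, "M2a": 5, "M3": 6, "M7": 3, "M8": 5}[self.name]


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _prepare(tree: PhyloTree, alignment: CodonAlignment):
    X = alignment.to_indices()
    row = {sid: i for i, sid in enumerate(alignment.ids)}
    unknown = [l for l in tree.leaf_labels() if l not in row]
    if unknown:
        raise ValueError(f"tree leaves missing from alignment: {unknown}")
    nodes = list(tree.postorder())
    edges = [n for n in nodes if n.parent is not None]
    edge_index = {id(n): i for i, n in enumerate(edges)}
    return X, row, nodes, edges, edge_index


def _branch_vector(edges) -> np.ndarray:
    out = np.empty(len(edges))
    for i, node in enumerate(edges):
        if node.length is None:
            raise ValueError("all branches need lengths for likelihood computation")
        out[i] = node.length
    return out


def _class_site_logliks(nodes, edge_index, X, row, gen, pi, tvec) -> np.ndarray:
    """Per-site log-likelihood under a single omega class (scaled pruning)."""
    n_sites = X.shape[1]
    stash: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in nodes:
        if node.is_leaf():
            idx = X[row[node.label]]
            part = np.zeros((n_sites, N_CODONS))
            ambiguous = idx < 0
            part[np.arange(n_sites), np.where(ambiguous, 0, idx)] = 1.0
            part[ambiguous, :] = 1.0
            logs = np.zeros(n_sites)
        else:
            part = np.ones((n_sites, N_CODONS))
            logs = np.zeros(n_sites)
            for child in node.children:
                cpart, clogs = stash.pop(id(child))
                P = gen.transition(tvec[edge_index[id(child)]])
                part = part * (cpart @ P.T)
                logs = logs + clogs
            scale = part.max(axis=1)
            bad = scale <= 0
            if bad.any():
                logs = np.where(bad, -np.inf, logs)
                scale = np.where(bad, 1.0, scale)
            part = part / scale[:, None]
            logs = logs + np.where(np.isneginf(logs), 0.0, np.log(scale))
        stash[id(node)] = (part, logs)
    part, logs = stash[id(nodes[-1])]
    site = part @ pi
    with np.errstate(divide="ignore"):
        return np.log(site) + logs


def site_class_log_likelihoods(
    tree: PhyloTree,
    alignment: CodonAlignment,
    model: SiteModel,
    branch_lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Matrix of per-site log L_{s,k} for every omega class of *model*."""
    X, row, nodes, edges, edge_index = _prepare(tree, alignment)
    tvec = _branch_vector(edges) if branch_lengths is None else np.asarray(branch_lengths)
    omegas = model.class_omegas()
    out = np.empty((X.shape[1], len(omegas)))
    cache: dict[float, np.ndarray] = {}
    for k, w in enumerate(omegas):
        key = float(w)
        if key not in cache:
            gen = ReversibleGenerator.from_q(gy94_matrix(model.kappa, key, model.pi), model.pi)
            cache[key] = _class_site_logliks(nodes, edge_index, X, row, gen, model.pi, tvec)
        out[:, k] = cache[key]
    return out


def site_mixture_loglik(
    tree: PhyloTree,
    alignment: CodonAlignment,
    model: SiteModel,
    branch_lengths: np.ndarray | None = None,
) -> float:
    """Total log-likelihood: per site, a mixture over omega classes."""
    logL = site_class_log_likelihoods(tree, alignment, model, branch_lengths)
    with np.errstate(divide="ignore"):
        logp = np.log(np.maximum(model.class_probs(), 1e-300))
    site = logsumexp(logL + logp[None, :], axis=1)
    if not np.isfinite(site).all():
        return -np.inf
    return float(site.sum())


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

_LOG_K = (np.log(0.01), np.log(100.0))
_LOG_W = (np.log(1e-4), np.log(50.0))
_LOGIT = (-15.0, 15.0)
_LOG_WPOS = (np.log(1e-3), np.log(49.0))
_LOG_BETA = (np.log(0.05), np.log(50.0))
_LOG_T = (np.log(1e-7), np.log(20.0))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = min(max(p, 1e-6), 1.0 - 1e-6)
    return float(np.log(p / (1.0 - p)))


def _stick(raws: np.ndarray) -> np.ndarray:
    """K-1 unconstrained values -> K simplex proportions."""
    probs = []
    rest = 1.0
    for a in raws:
        share = _sigmoid(a) * rest
        probs.append(share)
        rest -= share
    probs.append(rest)
    return np.array(probs)


def _stick_inv(probs) -> list[float]:
    probs = np.asarray(probs, dtype=float)
    raws = []
    rest = 1.0
    for p in probs[:-1]:
        raws.append(_logit(p / rest if rest > 0 else 0.5))
        rest -= p
    return raws


def _spec_for(name: str, ncat: int):
    """Raw-vector parameterization (bounds, unpack, pack) for one model."""
    if name == "M0":
        bounds = [_LOG_K, _LOG_W]

        def unpack(v):
            return float(np.exp(v[0])), {"omega": float(np.exp(v[1]))}

        def pack(kappa, p):
            return [np.log(kappa), np.log(max(p["omega"], 1e-4))]

    elif name == "M1a":
        bounds = [_LOG_K, _LOGIT, _LOGIT]

        def unpack(v):
            return float(np.exp(v[0])), {
                "p0": float(_sigmoid(v[1])),
                "omega0": float(_sigmoid(v[2])),
            }

        def pack(kappa, p):
            return [np.log(kappa), _logit(p["p0"]), _logit(p["omega0"])]

    elif name == "M2a":
        bounds = [_LOG_K, _LOGIT, _LOGIT, _LOGIT, _LOG_WPOS]

        def unpack(v):
            probs = _stick(np.array(v[1:3]))
            return float(np.exp(v[0])), {
                "p0": float(probs[0]),
                "p1": float(probs[1]),
                "omega0": float(_sigmoid(v[3])),
                "omega2": float(1.0 + np.exp(v[4])),
            }

        def pack(kappa, p):
            sticks = _stick_inv([p["p0"], p["p1"], 1.0 - p["p0"] - p["p1"]])
            return [np.log(kappa), *sticks, _logit(p["omega0"]),
                    np.log(max(p["omega2"] - 1.0, 1e-3))]

    elif name == "M3":
        bounds = [_LOG_K, _LOGIT, _LOGIT, _LOG_W, _LOG_W, _LOG_W]

        def unpack(v):
            probs = _stick(np.array(v[1:3]))
            return float(np.exp(v[0])), {
                "probs": tuple(float(x) for x in probs),
                "omegas": tuple(float(np.exp(x)) for x in v[3:6]),
            }

        def pack(kappa, p):
            return [np.log(kappa), *_stick_inv(p["probs"]),
                    *[np.log(max(w, 1e-4)) for w in p["omegas"]]]

    elif name == "M7":
        bounds = [_LOG_K, _LOG_BETA, _LOG_BETA]

        def unpack(v):
            return float(np.exp(v[0])), {
                "p": float(np.exp(v[1])),
                "q": float(np.exp(v[2])),
                "ncat": ncat,
            }

        def pack(kappa, p):
            return [np.log(kappa), np.log(p["p"]), np.log(p["q"])]

    elif name == "M8":
        bounds = [_LOG_K, _LOG_BETA, _LOG_BETA, _LOGIT, _LOG_WPOS]

        def unpack(v):
            return float(np.exp(v[0])), {
                "p": float(np.exp(v[1])),
                "q": float(np.exp(v[2])),
                "p0": float(_sigmoid(v[3])),
                "omega_s": float(1.0 + np.exp(v[4])),
                "ncat": ncat,
            }

        def pack(kappa, p):
            return [np.log(kappa), np.log(p["p"]), np.log(p["q"]),
                    _logit(p["p0"]), np.log(max(p["omega_s"] - 1.0, 1e-3))]

    else:
        raise ValueError(f"unknown model {name!r}")
    return bounds, unpack, pack


def _default_inits(name: str, omega_init: float) -> dict:
    w = omega_init
    return {
        "M0": {"omega": w},
        "M1a": {"p0": 0.7, "omega0": min(w, 0.9)},
        "M2a": {"p0": 0.6, "p1": 0.3, "omega0": min(w, 0.9), "omega2": max(1.5, w)},
        "M3": {"probs": (0.5, 0.3, 0.2), "omegas": (min(w, 0.5), 1.0, max(1.5, w))},
        "M7": {"p": 0.5, "q": max(0.5, 1.0 / max(w, 0.05))},
        "M8": {"p": 0.5, "q": 1.0, "p0": 0.9, "omega_s": max(1.5, w)},
    }[name]


@dataclass
class FitResult:
    model: SiteModel
    lnL: float
    tree: PhyloTree
    converged: bool
    n_restarts_used: int
    notes: list[str] = field(default_factory=list)


#: initial omega values cycled across restarts ("run twice with different
#: initial omega" is the minimum; three starts by default).
_OMEGA_INITS = (0.4, 1.5, 0.05, 3.0, 0.1)


def fit_site_model(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model_name: str,
    *,
    freq_scheme: str = "F3x4",
    pi: np.ndarray | None = None,
    n_beta_categories: int = 10,
    n_restarts: int = 3,
    seed: int = 0,
    optimize_branch_lengths: bool | None = None,
    extra_inits: tuple[dict, ...] = (),
) -> FitResult:
    """Maximize the site-mixture likelihood for one model.

    Branch lengths are optimized jointly for M0 (the default pipeline then
    reuses the M0 branch lengths for the other models); pass
    ``optimize_branch_lengths`` to override.  ``extra_inits`` are parameter
    dictionaries used as additional starting points (e.g. the null model's
    MLE embedded in the alternative's space, which guarantees the nesting
    inequality).
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if optimize_branch_lengths is None:
        optimize_branch_lengths = model_name == "M0"
    if pi is None:
        pi = codon_frequencies(alignment, freq_scheme)
    pi = np.maximum(np.asarray(pi, dtype=float), 1e-10)
    pi = pi / pi.sum()

    work_tree = tree.copy()
    X, row, nodes, edges, edge_index = _prepare(work_tree, alignment)
    t0 = np.array([e.length if e.length is not None else 0.1 for e in edges])
    t0 = np.clip(t0, 1e-6, 20.0)

    notes: list[str] = []
    used = alignment.to_indices()
    if len(alignment.ids) > 1:
        ref = used[0]
        if all(
            np.array_equal(np.where(r >= 0, r, ref), np.where(ref >= 0, ref, r))
            for r in used
        ):
            notes.append(
                "all sequences identical: omega is not identifiable and branch "
                "lengths collapse toward zero"
            )

    bounds, unpack, pack = _spec_for(model_name, n_beta_categories)
    n_model_vars = len(bounds)
    if optimize_branch_lengths:
        bounds = bounds + [_LOG_T] * len(edges)

    def objective(v: np.ndarray) -> float:
        kappa, params = unpack(v[:n_model_vars])
        tvec = np.exp(v[n_model_vars:]) if optimize_branch_lengths else t0
        try:
            model = SiteModel(
                name=model_name, kappa=kappa, pi=pi, params=params,
                freq_scheme=freq_scheme,
            )
        except ValueError:
            return 1e12
        omegas = model.class_omegas()
        probs = model.class_probs()
        logL = np.empty((X.shape[1], len(omegas)))
        cache: dict[float, np.ndarray] = {}
        for k, w in enumerate(omegas):
            key = float(w)
            if key not in cache:
                gen = ReversibleGenerator.from_q(gy94_matrix(kappa, key, pi), pi)
                cache[key] = _class_site_logliks(nodes, edge_index, X, row, gen, pi, tvec)
            logL[:, k] = cache[key]
        with np.errstate(divide="ignore"):
            logp = np.log(np.maximum(probs, 1e-300))
        site = logsumexp(logL + logp[None, :], axis=1)
        total = site.sum()
        if not np.isfinite(total):
            return 1e12
        return -float(total)

    starts: list[np.ndarray] = []
    for params in extra_inits:
        kappa0 = params.get("kappa", 2.0)
        raw = pack(kappa0, params)
        if optimize_branch_lengths:
            raw = list(raw) + list(np.log(t0))
        starts.append(np.array(raw, dtype=float))
    for r in range(n_restarts):
        params = _default_inits(model_name, _OMEGA_INITS[r % len(_OMEGA_INITS)])
        raw = pack(2.0, params)
        if optimize_branch_lengths:
            raw = list(raw) + list(np.log(t0))
        starts.append(np.array(raw, dtype=float))

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    kappa_hat, params_hat = unpack(best.x[:n_model_vars])
    model_hat = SiteModel(
        name=model_name, kappa=kappa_hat, pi=pi, params=params_hat,
        freq_scheme=freq_scheme,
    )
    if optimize_branch_lengths:
        t_hat = np.exp(best.x[n_model_vars:])
        for e, t in zip(edges, t_hat):
            e.length = float(t)
    return FitResult(
        model=model_hat,
        lnL=-float(best.fun),
        tree=work_tree,
        converged=converged,
        n_restarts_used=len(starts),
        notes=notes,
    )


def _embedding_init(alt_name: str, null_fit: FitResult, eps: float = 1e-3) -> dict:
    """The null model's MLE expressed (up to epsilon) in the alternative's space.

    With ``eps=0`` this is the exact boundary point whose likelihood equals
    the null maximum (the positive class gets zero proportion / the extra
    classes collapse), which the logistic parameterization cannot reach.
    """
    p = null_fit.model.params
    kappa = null_fit.model.kappa
    if alt_name == "M2a":  # from M1a
        return {
            "kappa": kappa,
            "p0": p["p0"] * (1 - eps),
            "p1": (1 - p["p0"]) * (1 - eps),
            "omega0": p["omega0"],
            "omega2": 2.0,
        }
    if alt_name == "M3":  # from M0: equal omegas reproduce M0 exactly
        w = max(p["omega"], 1e-4)
        return {"kappa": kappa, "probs": (1 - 2 * eps / 3, eps / 3, eps / 3)
                if eps else (1.0, 0.0, 0.0),
                "omegas": (w, w, w)}
    if alt_name == "M8":  # from M7
        return {"kappa": kappa, "p": p["p"], "q": p["q"], "p0": 1 - eps,
                "omega_s": 2.0}
    raise ValueError(alt_name)


_NESTED_NULL = {"M2a": "M1a", "M3": "M0", "M8": "M7"}


def fit_models(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model_names=("M0", "M1a", "M2a"),
    *,
    freq_scheme: str = "F3x4",
    n_beta_categories: int = 10,
    n_restarts: int = 3,
    seed: int = 0,
    optimize_branch_lengths_m0: bool = True,
) -> dict[str, FitResult]:
    """Fit several site models, sharing M0-optimized branch lengths.

    M0 is always fitted first (with branch lengths unless disabled); the
    remaining models keep those branch lengths fixed.  Alternatives of nested
    pairs get the null MLE as an extra starting point.
    """
    names = list(model_names)
    if "M0" not in names:
        names = ["M0"] + names
    fits: dict[str, FitResult] = {}
    fits["M0"] = fit_site_model(
        alignment, tree, "M0",
        freq_scheme=freq_scheme, n_restarts=n_restarts, seed=seed,
        optimize_branch_lengths=optimize_branch_lengths_m0,
    )
    base_tree = fits["M0"].tree
    for name in names:
        if name == "M0":
            continue
        extra = ()
        null_name = _NESTED_NULL.get(name)
        if null_name and null_name in fits:
            extra = (_embedding_init(name, fits[null_name]),)
        fits[name] = fit_site_model(
            alignment, base_tree, name,
            freq_scheme=freq_scheme, n_beta_categories=n_beta_categories,
            n_restarts=n_restarts, seed=seed,
            optimize_branch_lengths=False, extra_inits=extra,
        )
        if null_name and null_name in fits and fits[name].lnL < fits[null_name].lnL:
            # the optimum sits on the boundary the logistic transform cannot
            # reach: evaluate the exact null embedding and keep the better fit
            boundary = _embedding_init(name, fits[null_name], eps=0.0)
            kappa_b = boundary.pop("kappa")
            if name in ("M7", "M8"):
                boundary["ncat"] = n_beta_categories
            model_b = SiteModel(
                name=name, kappa=kappa_b, pi=fits[name].model.pi,
                params=boundary, freq_scheme=freq_scheme,
            )
            lnl_b = site_mixture_loglik(base_tree, alignment, model_b)
            if lnl_b > fits[name].lnL:
                fits[name] = FitResult(
                    model=model_b, lnL=lnl_b, tree=fits[name].tree,
                    converged=fits[name].converged,
                    n_restarts_used=fits[name].n_restarts_used,
                    notes=fits[name].notes + [
                        "MLE on the null boundary (positive class proportion 0)"
                    ],
                )
    return fits


# ---------------------------------------------------------------------------
# Likelihood ratio tests
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    two_delta_l: float
    df: int
    p_value: float
    significant_1pct: bool


def lrt_critical_value(df: int, alpha: float = 0.01) -> float:
    """Upper-tail chi-square quantile (9.21 at df=2, 13.28 at df=4 for 1%)."""
    return float(stats.chi2.isf(alpha, df))


def likelihood_ratio_test(null: FitResult, alt: FitResult, df: int) -> LRTResult:
    """2(lnL_alt - lnL_null) against chi-square with *df* degrees of freedom."""
    if df < 1:
        raise ValueError("df must be positive")
    delta = 2.0 * (alt.lnL - null.lnL)
    if delta < 0:
        if delta > -1e-6:
            delta = 0.0
        else:
            raise ValueError(
                f"alternative lnL ({alt.lnL:.6f}) below null lnL ({null.lnL:.6f}): "
                "optimization failure"
            )
    p = float(stats.chi2.sf(delta, df))
    return LRTResult(
        two_delta_l=float(delta), df=df, p_value=p, significant_1pct=p < 0.01
    )


# ---------------------------------------------------------------------------
# Site posteriors (NEB / BEB)
# ---------------------------------------------------------------------------

@dataclass
class SiteClassPosterior:
    site_probs: np.ndarray  # (n_sites, n_classes)
    positive_sites: list[int]  # 0-based site indices
    positive_probability: np.ndarray  # per-site mass on omega > 1 classes
    method: str
    class_omegas: np.ndarray
    threshold: float = 0.95


def _positive_class_mask(model: SiteModel) -> np.ndarray:
    if model.name == "M2a":
        return np.array([False, False, True])
    if model.name == "M8":
        k = model.params["ncat"]
        return np.append(np.zeros(k, dtype=bool), True)
    raise ValueError(
        f"model {model.name} has no designated omega > 1 class; "
        "site posteriors are defined for M2a and M8"
    )


def _grid_models_m2a(model: SiteModel, d: int):
    """Uniform grid over (p0, p1) triangle, omega0 in (0,1), omega2 in (1,11)."""
    mids = (np.arange(d) + 0.5) / d
    omega2s = 1.0 + 10.0 * mids
    for p0, p1 in itertools.product(mids, mids):
        if p0 + p1 > 1.0:
            continue
        for w0 in mids:
            for w2 in omega2s:
                yield np.array([p0, p1, 1.0 - p0 - p1]), np.array([w0, 1.0, w2])


def _grid_models_m8(model: SiteModel, d: int):
    """Uniform grid over p0, beta shape parameters and omega_s."""
    k = model.params["ncat"]
    mids = (np.arange(d) + 0.5) / d
    shapes = np.geomspace(0.1, 10.0, d)
    omegas_s = 1.0 + 10.0 * mids
    for p, q in itertools.product(shapes, shapes):
        cats = beta_category_means(p, q, k)
        for p0 in mids:
            probs = np.append(np.full(k, p0 / k), 1.0 - p0)
            for ws in omegas_s:
                yield probs, np.append(cats, ws)


def site_posteriors(
    fit: FitResult,
    alignment: CodonAlignment,
    tree: PhyloTree | None = None,
    method: str = "NEB",
    threshold: float = 0.95,
    grid_points: int = 10,
) -> SiteClassPosterior:
    """Posterior class membership per site for an M2a or M8 fit.

    NEB plugs in the MLEs; BEB averages over a uniform discrete grid on the
    class proportions and omegas (kappa and branch lengths stay at their
    MLEs), which accounts for sampling error in those parameters.
    """
    model = fit.model
    pos_mask = _positive_class_mask(model)
    if tree is None:
        tree = fit.tree
    if method not in ("NEB", "BEB"):
        raise ValueError(f"unknown method {method!r}")

    if method == "NEB":
        logL = site_class_log_likelihoods(tree, alignment, model)
        with np.errstate(divide="ignore"):
            logp = np.log(np.maximum(model.class_probs(), 1e-300))
        joint = logL + logp[None, :]
        joint -= logsumexp(joint, axis=1, keepdims=True)
        post = np.exp(joint)
    else:
        grid = (
            _grid_models_m2a(model, grid_points)
            if model.name == "M2a"
            else _grid_models_m8(model, grid_points)
        )
        X, row, nodes, edges, edge_index = _prepare(tree, alignment)
        tvec = _branch_vector(edges)
        cache: dict[float, np.ndarray] = {}

        def logL_for(w: float) -> np.ndarray:
            key = round(float(w), 12)
            if key not in cache:
                gen = ReversibleGenerator.from_q(
                    gy94_matrix(model.kappa, float(w), model.pi), model.pi
                )
                cache[key] = _class_site_logliks(
                    nodes, edge_index, X, row, gen, model.pi, tvec
                )
            return cache[key]

        entries = []
        for probs, omegas in grid:
            logL = np.column_stack([logL_for(w) for w in omegas])
            with np.errstate(divide="ignore"):
                logp = np.log(np.maximum(probs, 1e-300))
            joint = logL + logp[None, :]
            site_log = logsumexp(joint, axis=1)
            post_g = np.exp(joint - site_log[:, None])
            entries.append((float(site_log.sum()), post_g))
        logF = np.array([e[0] for e in entries])
        weights = np.exp(logF - logsumexp(logF))
        post = np.zeros_like(entries[0][1])
        for w_g, (_, post_g) in zip(weights, entries):
            post += w_g * post_g

    positive_probability = post[:, pos_mask].sum(axis=1)
    positive_sites = [int(i) for i in np.nonzero(positive_probability > threshold)[0]]
    return SiteClassPosterior(
        site_probs=post,
        positive_sites=positive_sites,
        positive_probability=positive_probability,
        method=method,
        class_omegas=model.class_omegas(),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori counting (model-free cross-check)
# ---------------------------------------------------------------------------

@dataclass
class NeiGojoboriResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # nan when the Jukes-Cantor correction is undefined
    dN: float

    @property
    def omega(self) -> float:
        if np.isnan(self.dN) or np.isnan(self.dS) or self.dS == 0:
            return float("nan")
        return self.dN / self.dS


_AA_OF = dict(zip(SENSE_CODONS, CODON_AA))
_NT = "ACGT"


def _codon_site_fractions(codon: str) -> float:
    """Synonymous site count of one codon (changes to stops excluded)."""
    syn_sites = 0.0
    for pos in range(3):
        syn = sense = 0
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            sense += 1
            if _AA_OF[alt] == _AA_OF[codon]:
                syn += 1
        if sense:
            syn_sites += syn / sense
    return syn_sites


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over mutational
    pathways with equal weight; pathways through stop codons are excluded
    (all-blocked pairs fall back to counting stop steps as nonsynonymous)."""
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    if not diffs:
        return 0.0, 0.0

    def walk(order, allow_stops):
        syn = nonsyn = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                if not allow_stops:
                    return None
                nonsyn += 1.0
            elif _AA_OF[nxt] == _AA_OF[cur]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return syn, nonsyn

    results = [walk(order, False) for order in itertools.permutations(diffs)]
    valid = [r for r in results if r is not None]
    if not valid:
        valid = [walk(order, True) for order in itertools.permutations(diffs)]
    syn = float(np.mean([r[0] for r in valid]))
    nonsyn = float(np.mean([r[1] for r in valid]))
    return syn, nonsyn


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


def nei_gojobori(seq_a, seq_b) -> NeiGojoboriResult:
    """Counting-method dN/dS for a pair of aligned codon sequences.

    Accepts codon lists or nucleotide strings; codon pairs containing a gap
    are skipped.  Proportions are corrected with the Jukes-Cantor formula
    d = -(3/4) ln(1 - 4p/3) where defined.
    """

    def as_codons(seq):
        if isinstance(seq, str):
            if len(seq) % 3:
                raise ValueError("sequence length must be a multiple of 3")
            return [seq[i : i + 3].upper() for i in range(0, len(seq), 3)]
        return [c.upper() for c in seq]

    a, b = as_codons(seq_a), as_codons(seq_b)
    if len(a) != len(b):
        raise ValueError("sequences differ in codon length")
    S = N = Sd = Nd = 0.0
    compared = 0
    for ca, cb in zip(a, b):
        if "-" in ca or "-" in cb:
            continue
        for c in (ca, cb):
            if c not in _AA_OF:
                raise ValueError(f"invalid or stop codon {c!r}")
        compared += 1
        sa, sb = _codon_site_fractions(ca), _codon_site_fractions(cb)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = _pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    if compared == 0:
        raise ValueError("no comparable (gap-free) codon pairs")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return NeiGojoboriResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=_jukes_cantor(pS), dN=_jukes_cantor(pN),
    )
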