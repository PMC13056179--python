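"""Mixture modelling of k-mer count histograms.

The count histogram of a sequencing read set is modelled as a finite mixture

    F(x) = sum_i w_i f_i(x),   x = 1..c,

with one *error* component (k-mers created by sequencing errors; most occur
once) and ``p`` *genomic* components — for a diploid genome (p = 2) a
*heterozygous* peak near half coverage and a *homozygous* peak near full
k-mer coverage.  No family is assumed up front: the error component is drawn
from {gamma, exponential} and each genomic peak from {normal, skew-normal,
Poisson, negative binomial}, and a Differential Evolution (DE) search picks
families, parameters and weights jointly by minimizing the L1 objective

    Err(F) = sum_{x=1..c} | F(x) - h_x / sum_j h_j |.

Candidate genomes encode the categorical family choices as continuous genes
rounded at evaluation time, the component weights as normalized positive
genes, and the family parameters directly.  The optimized objective adds a
small parsimony term per continuous distribution parameter, which breaks
the near-ties between family combinations that would otherwise make the
selected decomposition seed-dependent.  After DE terminates, the solution
is refined locally — an exact linear program for the weights profiled
inside a Nelder-Mead search over distribution parameters, then a bounded
BFGS (L-BFGS-B) polish — each step accepted only if it improves the
objective.  All continuous densities are evaluated at the integer support
1..c and renormalized, so every component (and the mixture) sums to one
over the histogram support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .histogram import KmerHistogram

__all__ = [
    "ComponentSpec",
    "MixtureModel",
    "DEConfig",
    "FitResult",
    "SummaryStats",
    "component_pmf",
    "model_error",
    "fit",
    "summary_stats",
    "ERROR_FAMILIES",
    "GENOMIC_FAMILIES",
]

ERROR_FAMILIES = ("gamma", "exponential")
GENOMIC_FAMILIES = ("normal", "skewnorm", "poisson", "negbin")

_ORDERING_PENALTY = 10.0  # added to Err when genomic means are out of order

# Parsimony: the optimized objective adds this per continuous distribution
# parameter, so a more flexible family (e.g. skew-normal) is selected over a
# simpler one (e.g. Poisson) only when it buys a real error reduction.  At
# desk scale several family combinations fit a diploid histogram within
# ~1e-4 of each other while splitting the peak weights differently; without
# this tie-break the selected decomposition is a lottery.  The reported Err
# is always the plain L1 value.
_PARSIMONY = 2e-4

_PARAM_COUNT = {
    "exponential": 1,
    "gamma": 2,
    "normal": 2,
    "skewnorm": 3,
    "poisson": 1,
    "negbin": 2,
}


def _complexity(families) -> int:
    return sum(_PARAM_COUNT[f] for f in families)


class FitError(ValueError):
    """Raised for degenerate inputs or invalid component parameters."""


@dataclass
class ComponentSpec:
    """One mixture component: a distribution family, parameters, and weight.

    Families and parameters:

    * ``gamma``: shape, scale (error component)
    * ``exponential``: rate (error component)
    * ``normal``: mean, sd
    * ``skewnorm``: mean (location), sd (scale), shape
    * ``poisson``: mean
    * ``negbin``: mean, dispersion (the size parameter r; variance =
      mean + mean^2 / r, so r -> inf recovers the Poisson)
    """

    family: str
    params: dict[str, float]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ERROR_FAMILIES + GENOMIC_FAMILIES:
            raise FitError(f"unknown family {self.family!r}")
        if not 0.0 <= self.weight <= 1.0 + 1e-9:
            raise FitError(f"weight must be in [0, 1], got {self.weight}")

    @property
    def mean(self) -> float:
        """Nominal location of the component (used for ordering/ties)."""
        p = self.params
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "exponential":
            return 1.0 / p["rate"]
        return p["mean"]


def _raw_pmf(family: str, params: dict[str, float], x: np.ndarray) -> np.ndarray:
    if family == "gamma":
        return stats.gamma.pdf(x, a=params["shape"], scale=params["scale"])
    if family == "exponential":
        return stats.expon.pdf(x, scale=1.0 / params["rate"])
    if family == "normal":
        return stats.norm.pdf(x, loc=params["mean"], scale=params["sd"])
    if family == "skewnorm":
        # parameterized by the distribution mean (not the location), so the
        # component means stay comparable across families
        a = params["shape"]
        delta = a / math.sqrt(1.0 + a * a)
        loc = params["mean"] - params["sd"] * delta * math.sqrt(2.0 / math.pi)
        return stats.skewnorm.pdf(x, a, loc=loc, scale=params["sd"])
    if family == "poisson":
        return stats.poisson.pmf(x, mu=params["mean"])
    if family == "negbin":
        r = params["dispersion"]
        mu = params["mean"]
        return stats.nbinom.pmf(x, r, r / (r + mu))
    raise FitError(f"unknown family {family!r}")


def component_pmf(spec: ComponentSpec, c: int) -> np.ndarray:
    """Probability mass of one component over counts 1..c (renormalized).

    Continuous families are evaluated at the integer points and renormalized
    so every component sums to exactly one over the support.
    """
    for name, value in spec.params.items():
        if not math.isfinite(value):
            raise FitError(f"{spec.family} parameter {name}={value} out of bounds")
        if value <= 0 and not (spec.family == "skewnorm" and name == "shape"):
            raise FitError(f"{spec.family} parameter {name}={value} must be positive")
    x = np.arange(1, c + 1, dtype=np.float64)
    v = _raw_pmf(spec.family, spec.params, x)
    total = v.sum()
    if not np.isfinite(total) or total <= 0:
        raise FitError(f"{spec.family}{spec.params} has no mass on 1..{c}")
    return v / total


@dataclass
class MixtureModel:
    """Error + p genomic components; components ordered by increasing mean."""

    components: list[ComponentSpec]
    c: int

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise FitError("a mixture needs an error and at least one genomic component")
        w = sum(s.weight for s in self.components)
        if abs(w - 1.0) > 1e-6:
            raise FitError(f"component weights must sum to 1, got {w}")

    @property
    def p(self) -> int:
        """Number of genomic components (ploidy)."""
        return len(self.components) - 1

    @property
    def error(self) -> ComponentSpec:
        return self.components[0]

    @property
    def genomic(self) -> list[ComponentSpec]:
        return self.components[1:]

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.components])

    def component_pmfs(self) -> np.ndarray:
        """(n_components, c) matrix of renormalized component pmfs."""
        return np.vstack([component_pmf(s, self.c) for s in self.components])

    def pmf(self) -> np.ndarray:
        """The mixture F over 1..c; sums to 1."""
        return self.weights @ self.component_pmfs()

    def __call__(self, x: int | np.ndarray) -> np.ndarray | float:
        f = self.pmf()
        idx = np.asarray(x, dtype=np.int64) - 1
        return f[idx]


def model_error(model: MixtureModel, hist: KmerHistogram) -> float:
    """The L1 objective: sum_x |F(x) - h_x / sum_j h_j| over x = 1..c.

    Zero iff the mixture reproduces the normalized histogram exactly;
    invariant to scaling all h_i by a constant.
    """
    if model.c != hist.c:
        raise FitError(f"model support {model.c} != histogram support {hist.c}")
    return float(np.abs(model.pmf() - hist.normalized()).sum())


@dataclass
class DEConfig:
    """Differential Evolution hyper-parameters.

    Defaults: population of 16 candidates, mutation factor resampled
    uniformly in [0.5, 1.0] each generation (dither), recombination rate
    0.8, at most 500 generations with early stop once the best error has
    improved by less than ``tol`` for ``patience`` consecutive generations.
    """

    population_size: int = 16
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.8
    max_generations: int = 500
    tol: float = 1e-6
    patience: int = 50
    seed: int = 42

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise FitError("DE population must be >= 4")
        lo, hi = self.mutation
        if not (0 <= lo <= hi <= 2):
            raise FitError("mutation range must satisfy 0 <= lo <= hi <= 2")
        if not 0 < self.recombination <= 1:
            raise FitError("recombination rate must be in (0, 1]")


@dataclass
class FitResult:
    """Outcome of a histogram fit.

    ``err`` is the plain L1 objective of the final model; ``objective`` is
    the optimized value (L1 plus the parsimony term for the chosen family
    combination), which the refinement stages never worsen relative to the
    best DE candidate.  ``trace`` records the per-generation best objective
    and is non-increasing.
    """

    model: MixtureModel
    err: float
    n_generations: int
    trace: np.ndarray  # per-generation best objective (non-increasing)
    trace_solutions: list[np.ndarray]  # per-generation best gene vectors
    converged: bool
    refined: bool  # whether local refinement improved the DE solution
    seed: int
    objective: float = float("nan")
    stats: "SummaryStats | None" = None


# -- candidate encoding ---------------------------------------------------


class _Encoding:
    """Gene layout for p genomic components.

    [err_family, fam_1..fam_p,
     err_p1, err_p2,
     (mean_i, sigma_i, shape_i) for each genomic i,
     weight genes (p + 1)]
    """

    def __init__(self, c: int, p: int, families: tuple[str, ...] | None = None):
        self.c = c
        self.p = p
        self.families = families
        sigma_hi = max(3.0, c / 3.0)
        self.bounds: list[tuple[float, float]] = []
        if families is None:
            self.bounds.append((0.0, 2.0 - 1e-9))  # error family
            self.bounds += [(0.0, 4.0 - 1e-9)] * p  # genomic families
        else:
            if len(families) != p + 1:
                raise FitError(f"families must list {p + 1} entries (error + {p} genomic)")
            i = ERROR_FAMILIES.index(families[0])
            self.bounds.append((float(i), i + 1.0 - 1e-9))
            for fam in families[1:]:
                j = GENOMIC_FAMILIES.index(fam)
                self.bounds.append((float(j), j + 1.0 - 1e-9))
        self.bounds.append((0.01, 20.0))  # gamma shape / exponential rate
        self.bounds.append((0.05, 50.0))  # gamma scale (unused for exponential)
        for _ in range(p):
            self.bounds.append((1.0, float(c)))  # mean
            self.bounds.append((0.3, sigma_hi))  # sd
            self.bounds.append((-10.0, 10.0))  # skew shape / log-dispersion
        self.bounds += [(1e-4, 1.0)] * (p + 1)  # weight genes
        self.ndim = len(self.bounds)
        self.n_categorical = 1 + p

    def decode(self, x: np.ndarray) -> MixtureModel:
        p = self.p
        err_fam = ERROR_FAMILIES[min(int(x[0]), 1)]
        fams = [GENOMIC_FAMILIES[min(int(x[1 + i]), 3)] for i in range(p)]
        e1, e2 = x[1 + p], x[2 + p]
        wg = np.maximum(np.asarray(x[-(p + 1) :]), 1e-12)
        w = wg / wg.sum()
        comps = []
        if err_fam == "gamma":
            comps.append(ComponentSpec("gamma", {"shape": e1, "scale": e2}, w[0]))
        else:
            comps.append(ComponentSpec("exponential", {"rate": e1}, w[0]))
        off = 3 + p
        for i in range(p):
            mean, sd, shape = x[off + 3 * i : off + 3 * i + 3]
            fam = fams[i]
            if fam == "normal":
                params = {"mean": mean, "sd": sd}
            elif fam == "skewnorm":
                params = {"mean": mean, "sd": sd, "shape": shape}
            elif fam == "poisson":
                params = {"mean": mean}
            else:  # negbin: dispersion on a log10 grid from the shape gene
                params = {"mean": mean, "dispersion": float(10.0 ** (shape / 3.0))}
            comps.append(ComponentSpec(fam, params, w[1 + i]))
        return MixtureModel(comps, self.c)

    def continuous_slice(self) -> slice:
        return slice(self.n_categorical, self.ndim)


def _best_weights(P: np.ndarray, target: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Exact minimizer of ||w @ P - target||_1 over the weight simplex.

    With the component pmfs fixed, the weight subproblem is a small linear
    program (auxiliary variables t_x >= |F(x) - target_x|); solving it
    exactly removes the weight/parameter trade-off from the nonlinear
    search.  Returns (weights, err) or (None, inf) if the LP fails.
    """
    K, c = P.shape
    A_ub = np.block([[P.T, -np.eye(c)], [-P.T, -np.eye(c)]])
    b_ub = np.concatenate([target, -target])
    A_eq = np.zeros((1, K + c))
    A_eq[0, :K] = 1.0
    cvec = np.concatenate([np.zeros(K), np.ones(c)])
    res = optimize.linprog(
        cvec, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
        bounds=[(0.0, None)] * (K + c), method="highs",
    )
    if res.status != 0:
        return None, float("inf")
    return res.x[:K], float(res.fun)


def _combo_pmfs(fams: tuple[str, ...], theta: np.ndarray, c: int) -> np.ndarray | None:
    """Component pmf matrix for a family combination and parameter vector.

    ``theta`` = [err_p1, err_p2, (mean, sd, shape) per genomic component];
    returns None (infeasible) for invalid parameters or out-of-order means.
    """
    specs = []
    if fams[0] == "gamma":
        specs.append(ComponentSpec("gamma", {"shape": theta[0], "scale": theta[1]}))
    else:
        specs.append(ComponentSpec("exponential", {"rate": theta[0]}))
    means = []
    for i, fam in enumerate(fams[1:]):
        mu, sd, shape = theta[2 + 3 * i : 5 + 3 * i]
        means.append(mu)
        if fam == "normal":
            params = {"mean": mu, "sd": sd}
        elif fam == "skewnorm":
            params = {"mean": mu, "sd": sd, "shape": shape}
        elif fam == "poisson":
            params = {"mean": mu}
        else:
            params = {"mean": mu, "dispersion": float(10.0 ** (shape / 3.0))}
        specs.append(ComponentSpec(fam, params))
    if any(a >= b for a, b in zip(means, means[1:])):
        return None
    try:
        return np.vstack([component_pmf(s, c) for s in specs])
    except FitError:
        return None


def _objective(x: np.ndarray, enc: _Encoding, target: np.ndarray) -> float:
    try:
        model = enc.decode(x)
        f = model.pmf()
    except FitError:
        return 1e3
    err = float(np.abs(f - target).sum())
    err += _PARSIMONY * _complexity(s.family for s in model.components)
    means = [s.mean for s in model.genomic]
    for a, b in zip(means, means[1:]):
        if a >= b:  # enforce het mean < hom mean (ascending genomic peaks)
            err += _ORDERING_PENALTY + (a - b) / enc.c
    return err


def _histogram_anchors(hist: KmerHistogram) -> dict:
    """Crude method-of-moments reading of a diploid histogram.

    Estimates the exponential error rate from the h1/h2 ratio, the error
    weight from the height of bin 1, the dominant coverage peak as the
    argmax of h beyond the error/signal valley, and per-peak weights from
    peak heights assuming roughly Poisson spread.  These only steer the
    optimizer's starting population; the search remains free to leave them.
    """
    h = hist.normalized()
    c = hist.c
    lam = math.log(max(h[0], 1e-12) / max(h[1] if c > 1 else 1e-12, 1e-12))
    lam = min(max(lam, 0.05), 19.0)
    w_err = min(max(h[0] / -math.expm1(-lam), 0.02), 0.98)
    # valley = first rise of h after bin 2; the coverage peak lies beyond it
    valley = next((i for i in range(2, c - 1) if h[i] > h[i - 1]), max(2, c // 4))
    mode = int(np.argmax(h[valley:]) + valley + 1) if valley < c else c
    mode = max(mode, 3)

    def peak_weight(mean: float) -> float:
        i = int(min(max(round(mean), 1), c))
        return max(h[i - 1], 1e-9) * math.sqrt(2 * math.pi * max(mean, 1.0))

    return {"rate": lam, "w_err": w_err, "mode": mode, "peak_weight": peak_weight}


def _init_population(enc: _Encoding, hist: KmerHistogram, size: int, rng) -> np.ndarray:
    """Latin-hypercube start seeded with heuristic anchor individuals.

    Half the population is placed at method-of-moments anchors spanning the
    family combinations and both peak hypotheses (the dominant peak being
    homozygous with the heterozygous peak at half coverage, or vice versa);
    the rest is a Latin hypercube over the full bounds.  Anchoring avoids
    the degenerate attractor where a genomic component parks on the error
    bulk at count 1, without constraining where the search may go.
    """
    sampler = stats.qmc.LatinHypercube(d=enc.ndim, seed=rng)
    lo = np.array([b[0] for b in enc.bounds])
    hi = np.array([b[1] for b in enc.bounds])
    pop = lo + sampler.random(size) * (hi - lo)
    a = _histogram_anchors(hist)
    c, p = enc.c, enc.p
    mode = a["mode"]
    hypotheses = [tuple(mode * (i + 1) / p for i in range(p))]  # peak = top component
    if 2 * mode <= c:  # peak = second-highest component (half-coverage reading)
        hypotheses.append(tuple(mode * (i + 1) for i in range(p)))
    shape_gene = {"normal": 0.0, "skewnorm": 2.0, "poisson": 0.0, "negbin": 6.0}
    anchors = []
    for err_gene, fam, means in (
        [(1.5, f, m) for f in GENOMIC_FAMILIES for m in hypotheses[:1]]
        + [(1.5, "negbin", m) for m in hypotheses[1:]]
        + [(0.5, "negbin", m) for m in hypotheses[:1]]
    ):
        g = np.empty(enc.ndim)
        g[0] = err_gene
        g[1 : 1 + p] = GENOMIC_FAMILIES.index(fam) + 0.5
        g[1 + p] = a["rate"]  # exponential rate / gamma shape
        g[2 + p] = 1.0 / max(a["rate"], 0.05) if err_gene < 1 else 1.0  # gamma scale ~ mean
        off = 3 + p
        weights = [a["w_err"]]
        for i, mean in enumerate(means):
            mean = min(max(mean, 1.0), c)
            g[off + 3 * i] = mean
            g[off + 3 * i + 1] = min(max(0.5, math.sqrt(mean)), enc.bounds[off + 1][1])
            g[off + 3 * i + 2] = shape_gene[fam]
            weights.append(a["peak_weight"](mean))
        w = np.array(weights)
        w[1:] *= max(1.0 - w[0], 1e-3) / max(w[1:].sum(), 1e-9)
        g[-(p + 1) :] = np.clip(w, 1e-4, 1.0)
        anchors.append(np.clip(g, lo, hi))
    n_anchor = min(len(anchors), size // 2)
    pop[:n_anchor] = anchors[:n_anchor]
    return pop


def fit(
    hist: KmerHistogram,
    p: int = 2,
    de: DEConfig | None = None,
    families: tuple[str, ...] | None = None,
) -> FitResult:
    """Fit the mixture to a histogram with DE followed by local refinement.

    Parameters
    ----------
    hist:
        The count histogram; needs at least two non-zero bins.
    p:
        Number of genomic components (ploidy); 2 models a diploid genome
        with heterozygous and homozygous peaks.
    de:
        Optimizer configuration; defaults reproduce the standard settings
        (population 16, dithered mutation in [0.5, 1.0], recombination 0.8).
    families:
        Optional fixed family assignment (error family followed by the p
        genomic families).  By default every combination from the pool is
        searched.

    The returned trace of per-generation best errors is non-increasing
    (elitist selection), and the refinement step never increases the error.
    Identical seeds give identical results.
    """
    de = de or DEConfig()
    if int(np.count_nonzero(hist.values)) < 2:
        raise FitError("histogram is degenerate (fewer than two non-zero bins)")
    if p < 1:
        raise FitError("ploidy must be >= 1")
    enc = _Encoding(hist.c, p, families)
    target = hist.normalized()
    fun = lambda x: _objective(x, enc, target)

    rng = np.random.default_rng(de.seed)
    init = _init_population(enc, hist, de.population_size, rng)
    trace: list[float] = []
    trace_x: list[np.ndarray] = []
    converged = False

    def callback(xk, convergence=None):
        nonlocal converged
        trace.append(fun(xk))
        trace_x.append(np.array(xk))
        if len(trace) > de.patience and trace[-de.patience - 1] - trace[-1] < de.tol:
            converged = True
            return True
        return False

    result = optimize.differential_evolution(
        fun,
        enc.bounds,
        init=init,
        mutation=de.mutation,
        recombination=de.recombination,
        maxiter=de.max_generations,
        tol=0.0,
        atol=0.0,
        seed=de.seed,
        polish=False,
        callback=callback,
        updating="immediate",
    )
    best_x = np.array(result.x)
    best_err = fun(best_x)
    refined = False

    # Local refinement.  DE supplies the basin (peak locations, weights,
    # error decay); the refinement then (a) profiles out the weights exactly
    # — for fixed component pmfs the weight subproblem is a linear program —
    # while searching the distribution parameters with Nelder-Mead, for each
    # of the best-scoring family combinations (the categorical space is tiny:
    # 2 x 4^p), and (b) polishes the winning candidate's continuous genes
    # with bounded BFGS.  Each step is accepted only if it lowers Err, so
    # refinement never worsens the DE solution.
    import itertools

    ncat = enc.n_categorical
    n_theta = 2 + 3 * p
    theta_bounds = enc.bounds[ncat : ncat + n_theta]
    if families is not None:
        combos = [tuple(families)]
    elif 2 * 4**p <= 32:
        combos = [
            (ef,) + gs
            for ef in ERROR_FAMILIES
            for gs in itertools.product(GENOMIC_FAMILIES, repeat=p)
        ]
    else:  # large ploidy: refine only the DE-chosen family combination
        m = enc.decode(best_x)
        combos = [tuple(s.family for s in m.components)]

    a = _histogram_anchors(hist)
    mode = a["mode"]
    theta_anchor = np.array(
        [a["rate"], 1.0 / max(a["rate"], 0.05)]
        + sum(
            (
                [min(max(mode * (i + 1) / p, 1.0), enc.c),
                 max(0.5, math.sqrt(mode * (i + 1) / p)),
                 6.0]
                for i in range(p)
            ),
            [],
        )
    )
    theta_anchor = np.clip(theta_anchor, [b[0] for b in theta_bounds], [b[1] for b in theta_bounds])
    theta_de = best_x[ncat : ncat + n_theta].copy()

    def profiled(theta, fams):
        P = _combo_pmfs(fams, theta, enc.c)
        if P is None:
            return float("inf"), None
        w, e = _best_weights(P, target)
        return e, w

    # rank (combo, start) candidates by the cheap LP score plus the combo's
    # parsimony term; the DE optimum and the histogram anchor are ranked as
    # separate start classes so neither can crowd the other out
    shortlist = []
    for theta0 in (theta_de, theta_anchor):
        scored = []
        for fams in combos:
            e, _w = profiled(theta0, fams)
            scored.append((e + _PARSIMONY * _complexity(fams), fams, theta0))
        scored.sort(key=lambda t: t[0])
        shortlist.extend(scored[:8])

    de_fams = tuple(s.family for s in enc.decode(best_x).components)
    if not any(f == de_fams and th is theta_de for _e, f, th in shortlist):
        shortlist.append((0.0, de_fams, theta_de))  # always refine the DE solution

    best_candidate = None  # (penalized err, fams, theta, weights)
    for _score, fams, theta0 in shortlist:
        try:
            res2 = optimize.minimize(
                lambda th: profiled(th, fams)[0],
                theta0,
                method="Nelder-Mead",
                bounds=theta_bounds,
                options={"maxfev": 1200, "xatol": 1e-4, "fatol": 1e-9, "adaptive": True},
            )
        except Exception:
            continue
        e, w = profiled(res2.x, fams)
        e_pen = e + _PARSIMONY * _complexity(fams)
        if w is not None and (best_candidate is None or e_pen < best_candidate[0]):
            best_candidate = (e_pen, fams, np.array(res2.x), w)

    if best_candidate is not None and best_candidate[0] < best_err - 1e-12:
        e, fams, theta, w = best_candidate
        cand = best_x.copy()
        cand[0] = ERROR_FAMILIES.index(fams[0]) + 0.5
        for i in range(p):
            cand[1 + i] = GENOMIC_FAMILIES.index(fams[1 + i]) + 0.5
        cand[ncat : ncat + n_theta] = theta
        cand[-(p + 1) :] = np.clip(w, 1e-4, 1.0)
        cand_err = fun(cand)  # re-evaluate after weight clipping
        if cand_err < best_err:
            best_x, best_err, refined = cand, cand_err, True

    # final bounded-BFGS polish of all continuous genes, families fixed
    cont = enc.continuous_slice()
    cat = best_x[:ncat].copy()

    def cont_objective(xc):
        return fun(np.concatenate([cat, xc]))

    try:
        res3 = optimize.minimize(
            cont_objective,
            best_x[cont],
            method="L-BFGS-B",
            bounds=enc.bounds[ncat:],
            options={"maxiter": 80},
        )
        if np.isfinite(res3.fun) and res3.fun < best_err - 1e-12:
            best_x = np.concatenate([cat, res3.x])
            best_err = float(res3.fun)
            refined = True
    except Exception:
        pass

    model = enc.decode(best_x)
    return FitResult(
        model=model,
        err=model_error(model, hist),
        n_generations=len(trace),
        trace=np.array(trace),
        trace_solutions=trace_x,
        converged=converged,
        refined=refined,
        seed=de.seed,
        objective=best_err,
    )


# -- derived statistics ---------------------------------------------------


@dataclass
class SummaryStats:
    """Dataset-level statistics derived from a fitted model.

    Percentages are on the 0-100 scale.  ``heterozygosity_pct`` is
    distinct-k-mer weighted (het / (het + hom) component weights);
    ``heterozygosity_occ_pct`` weights by k-mer occurrences instead.
    ``robust_rate_pct`` is occurrence-weighted (1 - error occurrence
    fraction), matching a ground truth of robust occurrences over total
    occurrences.  NaN marks statistics undefined for a degenerate model
    (e.g. no genomic mass).
    """

    kmer_coverage: float
    heterozygosity_pct: float
    heterozygosity_occ_pct: float
    error_distinct_pct: float
    error_occ_pct: float
    robust_rate_pct: float
    genome_size: float
    err: float
    families: tuple[str, ...]
    weights: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "kmer_coverage": self.kmer_coverage,
            "heterozygosity_pct": self.heterozygosity_pct,
            "heterozygosity_occ_pct": self.heterozygosity_occ_pct,
            "error_distinct_pct": self.error_distinct_pct,
            "error_occ_pct": self.error_occ_pct,
            "robust_rate_pct": self.robust_rate_pct,
            "genome_size": self.genome_size,
            "model_err": self.err,
            "families": list(self.families),
            "weights": list(self.weights),
        }


def summary_stats(
    fit_result: FitResult | MixtureModel,
    hist: KmerHistogram,
    k: int | None = None,
    read_length: float | None = None,
) -> SummaryStats:
    """Dataset statistics from the relative areas of the model components.

    * k-mer coverage: mean of the highest-mean genomic (homozygous)
      component over the support;
    * heterozygosity: het weight over total genomic weight (distinct-
      weighted), plus the occurrence-weighted variant;
    * error fraction (occurrence-weighted): expected share of k-mer
      *instances* produced by the error component;
    * robust rate: 1 - error fraction;
    * genome size: total occurrences x (1 - error fraction) / coverage,
      with an optional L/(L - k + 1) correction for the k-1 bases per read
      that never start a k-mer (supply ``read_length`` and ``k``).
    """
    model = fit_result.model if isinstance(fit_result, FitResult) else fit_result
    err_value = fit_result.err if isinstance(fit_result, FitResult) else model_error(model, hist)
    x = np.arange(1, model.c + 1, dtype=np.float64)
    pmfs = model.component_pmfs()
    w = model.weights
    occ = w[:, None] * pmfs * x  # occurrence mass per component and count
    occ_totals = occ.sum(axis=1)
    total_occ_mass = occ_totals.sum()

    genomic = sorted(model.genomic, key=lambda s: s.mean)
    hom = genomic[-1]
    hom_idx = model.components.index(hom)
    coverage = float((pmfs[hom_idx] * x).sum()) if w[hom_idx] > 0 else float("nan")

    w_gen = w[1:].sum()
    if model.p >= 2 and w_gen > 0:
        het_weight = w_gen - w[hom_idx]
        het_pct = 100.0 * het_weight / w_gen
        occ_gen = occ_totals[1:].sum()
        het_occ_pct = (
            100.0 * (occ_gen - occ_totals[hom_idx]) / occ_gen if occ_gen > 0 else float("nan")
        )
    else:
        het_pct = float("nan")
        het_occ_pct = float("nan")

    error_occ = float(occ_totals[0] / total_occ_mass) if total_occ_mass > 0 else float("nan")
    robust_pct = 100.0 * (1.0 - error_occ)
    if np.isfinite(coverage) and coverage > 0 and np.isfinite(error_occ):
        genome_size = hist.total_occurrences * (1.0 - error_occ) / coverage
        if read_length is not None and k is not None and read_length > k - 1:
            genome_size *= read_length / (read_length - k + 1)
    else:
        genome_size = float("nan")

    return SummaryStats(
        kmer_coverage=coverage,
        heterozygosity_pct=float(het_pct),
        heterozygosity_occ_pct=float(het_occ_pct),
        error_distinct_pct=float(100.0 * w[0]),
        error_occ_pct=float(100.0 * error_occ),
        robust_rate_pct=float(robust_pct),
        genome_size=float(genome_size),
        err=float(err_value),
        families=tuple(s.family for s in model.components),
        weights=tuple(float(v) for v in w),
    )
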