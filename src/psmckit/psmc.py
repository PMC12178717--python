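"""Discretised-TMRCA coalescent HMM for historical effective population size.

The hidden state of a 100-bp (by default) genome bin is the discretised time
to the most recent common ancestor (TMRCA) of the two haplotypes; the
observation is 'K' (bin contains a heterozygote), 'T' (callable, none) or 'N'
(insufficient data).  Time is measured in units of 2·N0 generations and cut
into ``n_atomic`` log-spaced intervals whose relative population sizes λ_k are
tied into groups by a time-segmentation pattern such as ``"4+25*2+4+6"``.

Model pieces (all in coalescent units, rates per bin):

* equilibrium state distribution = pairwise coalescent prior under the
  piecewise-constant λ: P(T ∈ [t_j, t_{j+1})) from the piecewise-exponential
  survival function;
* emission P('K' | j) = 1 − exp(−θ·t̄_j) with t̄_j the interval's conditional
  mean TMRCA under the current λ ('N' is emitted with probability 1 in every
  state, so masked bins carry no emission information but keep the spatial
  chain intact);
* transition: with probability 1 − exp(−ρ·t̄_i) a recombination occurs on the
  current bin's genealogy; the breakpoint time is uniform on [0, t̄_i] and the
  erased lineage re-coalesces from there under the same λ (SMC kernel).  The
  re-coalescence integrals have closed forms, so the transition matrix is an
  exact array computation.

Fitting is expectation–maximisation: a scaled forward–backward pass collects
expected start/emission/transition counts, and the M-step numerically
maximises the expected complete-data log-likelihood over (θ, ρ, λ) with the
group ties enforced (a generalized-EM step: parameters are only accepted when
the surrogate improves, so the data log-likelihood is non-decreasing).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .formats import DiploidConsensus, PsmcFasta
from .hetstats import site_classes

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# time-segmentation pattern grammar

@dataclass(frozen=True)
class TimePattern:
    """Parsed time-segmentation pattern.

    ``groups`` is a list of ``(span, repetitions)``: the term ``a*b``
    contributes ``a`` groups each spanning ``b`` atomic intervals; a bare
    integer contributes one group of that span.
    """

    spec: str
    groups: tuple[tuple[int, int], ...]

    @property
    def n_atomic(self) -> int:
        return sum(span * rep for span, rep in self.groups)

    @property
    def n_free(self) -> int:
        return sum(rep for _, rep in self.groups)

    def group_of_atomic(self) -> np.ndarray:
        """Free-parameter index for each atomic interval."""
        out = np.empty(self.n_atomic, dtype=np.int64)
        pos = 0
        free = 0
        for span, rep in self.groups:
            for _ in range(rep):
                out[pos:pos + span] = free
                pos += span
                free += 1
        return out


_TERM = re.compile(r"(\d+)(?:\*(\d+))?")


def parse_pattern(spec: str) -> TimePattern:
    """Parse a pattern string like ``"4+25*2+4+6"``.

    Grammar: ``term ::= INT | INT "*" INT``, ``spec ::= term ("+" term)*``;
    ``a*b`` means ``a`` groups each spanning ``b`` atomic intervals.
    """
    compact = spec.replace(" ", "")
    if not compact:
        raise ValueError("empty pattern")
    groups: list[tuple[int, int]] = []
    pos = 0
    for i, term in enumerate(compact.split("+")):
        m = _TERM.fullmatch(term)
        if m is None:
            raise ValueError(
                f"malformed pattern {spec!r}: bad term {term!r} at position {pos}")
        if m.group(2) is None:
            span, rep = int(m.group(1)), 1
        else:
            rep, span = int(m.group(1)), int(m.group(2))
        if span < 1 or rep < 1:
            raise ValueError(
                f"malformed pattern {spec!r}: zero term {term!r} at position {pos}")
        groups.append((span, rep))
        pos += len(term) + 1
    return TimePattern(spec=compact, groups=tuple(groups))


# ---------------------------------------------------------------------------
# psmcfa binning and time discretisation

def make_psmcfa(c: DiploidConsensus, bin_size: int = 100,
                max_missing_fraction: float = 0.9) -> PsmcFasta:
    """Bin a diploid consensus into the K/T/N representation.

    Per window of ``bin_size`` sites: 'N' if more than ``max_missing_fraction``
    of the window is missing, else 'K' if it contains at least one
    heterozygous call, else 'T'.  The final partial window is classified by
    the same rule on its actual length.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    contigs: list[tuple[str, str]] = []
    for cname, seq in c.contigs:
        cls = site_classes(seq)
        L = len(cls)
        starts = np.arange(0, L, bin_size)
        win_len = np.diff(np.append(starts, L))
        n_miss = np.add.reduceat((cls == 2).astype(np.int64), starts)
        n_het = np.add.reduceat((cls == 1).astype(np.int64), starts)
        sym = np.where(n_miss > max_missing_fraction * win_len, ord("N"),
                       np.where(n_het > 0, ord("K"), ord("T"))).astype(np.uint8)
        contigs.append((cname, sym.tobytes().decode()))
    return PsmcFasta(contigs=contigs, bin_size=bin_size)


def discretize(n_atomic: int, t_max: float = 15.0) -> np.ndarray:
    """Log-spaced atomic interval boundaries in units of 2·N0 generations.

    t_j = 0.1·(exp((j/n)·ln(1 + 10·t_max)) − 1) for j = 0..n, so t_0 = 0 and
    t_n = t_max exactly.
    """
    if n_atomic < 1:
        raise ValueError("n_atomic must be >= 1")
    j = np.arange(n_atomic + 1, dtype=float)
    return 0.1 * (np.exp(j / n_atomic * math.log1p(10.0 * t_max)) - 1.0)


# ---------------------------------------------------------------------------
# HMM matrices (closed forms)

def interval_quantities(boundaries: np.ndarray, lam_atomic: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prior, conditional mean time and cumulative hazard per atomic interval.

    The last interval is treated as extending to infinity for probability
    mass, although ``boundaries[-1]`` reports the nominal t_max.
    """
    b = boundaries
    lam = lam_atomic
    n = len(lam)
    delta = np.diff(b)
    haz = np.empty(n)
    haz[:-1] = delta[:-1] / lam[:-1]
    haz[-1] = np.inf
    cumhaz = np.concatenate([[0.0], np.cumsum(haz)])   # length n+1, last inf
    em1 = -np.expm1(-haz)                               # 1 - exp(-Δ/λ), last 1
    prior = np.exp(-cumhaz[:-1]) * em1

    tbar = np.empty(n)
    # E[T | T in [a, a+Δ)] = a + λ − Δ·e^{−Δ/λ}/(1 − e^{−Δ/λ}); last: a + λ
    with np.errstate(over="ignore"):
        tbar[:-1] = b[:-1][:-1] + lam[:-1] - \
            delta[:-1] * np.exp(-haz[:-1]) / em1[:-1]
    tbar[-1] = b[-2] + lam[-1]
    return prior, tbar, cumhaz


def transition_matrix(boundaries: np.ndarray, lam_atomic: np.ndarray,
                      rho: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SMC transition matrix; returns (P, prior, tbar).

    P[i, j] = (1 − p_r(i))·δ_ij + p_r(i)·A[i, j] with p_r(i) = 1 − e^{−ρ·t̄_i}
    and A the uniform-breakpoint re-coalescence kernel, computed from exact
    piecewise-exponential integrals.
    """
    prior, tbar, ch = interval_quantities(boundaries, lam_atomic)
    b = boundaries
    lam = lam_atomic
    n = len(lam)
    delta = np.diff(b)

    # full-interval integrals I[k, j] = ∫_{b_k}^{b_{k+1}} P(re-coalesce in j | u) du
    k_idx = np.arange(n)
    j_idx = np.arange(n)
    jmask = j_idx[None, :] >= k_idx[:, None] + 1
    chk1 = ch[1:n + 1]
    lam_em1 = lam * -np.expm1(-np.where(np.isfinite(delta), delta, np.inf) / lam)
    with np.errstate(invalid="ignore"):
        exp1 = np.exp(np.where(jmask, chk1[:, None] - ch[None, :n], -np.inf))
        exp2 = np.exp(np.where(jmask, chk1[:, None] - ch[None, 1:n + 1], -np.inf))
    ifull = lam_em1[:, None] * (exp1 - exp2)
    diag = delta - lam_em1
    np.fill_diagonal(ifull, np.where(np.isfinite(diag), diag, 0.0))
    ifull[-1, :] = 0.0        # row n-1 is never summed (k < i <= n-1)

    cum_i = np.vstack([np.zeros(n), np.cumsum(ifull, axis=0)])[:n]

    # partial segment [b_i, tbar_i] of the current state's own interval
    w = tbar - b[:n]
    lam_w = lam * -np.expm1(-w / lam)
    hbar = ch[:n] + w / lam
    pmask = j_idx[None, :] >= k_idx[:, None] + 1
    with np.errstate(invalid="ignore"):
        p1 = np.exp(np.where(pmask, hbar[:, None] - ch[None, :n], -np.inf))
        p2 = np.exp(np.where(pmask, hbar[:, None] - ch[None, 1:n + 1], -np.inf))
    ipart = lam_w[:, None] * (p1 - p2)
    # diagonal: breakpoint u in [b_i, tbar_i], re-coalescence before b_{i+1};
    # the last interval extends to infinity, so its escape probability is 0
    delta_inf = delta.copy()
    delta_inf[-1] = np.inf
    escape = lam * (np.exp((w - delta_inf) / lam) - np.exp(-delta_inf / lam))
    np.fill_diagonal(ipart, w - escape)

    a_mat = (cum_i + ipart) / tbar[:, None]
    p_rec = -np.expm1(-rho * tbar)
    trans = p_rec[:, None] * a_mat
    trans[np.arange(n), np.arange(n)] += 1.0 - p_rec
    return trans, prior, tbar


def emission_matrix(theta: float, tbar: np.ndarray) -> np.ndarray:
    """Rows are observation symbols (0='T', 1='K', 2='N'); columns states."""
    p_het = -np.expm1(-theta * tbar)
    return np.vstack([1.0 - p_het, p_het, np.ones_like(p_het)])


# ---------------------------------------------------------------------------
# forward-backward

def _forward_backward_py(obs, trans, emis, prior):
    """Pure-numpy scaled forward–backward; reference implementation.

    Returns (loglik, g0, symbol-state counts, xi, gamma).
    """
    T = len(obs)
    n = trans.shape[0]
    alpha = np.empty((T, n))
    c = np.empty(T)
    a = prior * emis[obs[0]]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * emis[obs[t]]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum())

    gamma = np.empty((T, n))
    counts = np.zeros((3, n))
    xi = np.zeros((n, n))
    beta = np.ones(n)
    gamma[T - 1] = alpha[T - 1] * beta
    counts[obs[T - 1]] += gamma[T - 1]
    for t in range(T - 2, -1, -1):
        eb = emis[obs[t + 1]] * beta
        xi += np.outer(alpha[t], eb / c[t + 1]) * trans
        beta = (trans @ eb) / c[t + 1]
        gamma[t] = alpha[t] * beta
        counts[obs[t]] += gamma[t]
    return loglik, gamma[0].copy(), counts, xi, gamma


@njit(cache=True)
def _forward_backward_nb(obs, trans, emis, prior):  # pragma: no cover - numba
    T = obs.shape[0]
    n = trans.shape[0]
    alpha = np.empty((T, n))
    c = np.empty(T)
    a = prior * emis[obs[0]]
    s = a.sum()
    c[0] = s
    alpha[0] = a / s
    for t in range(1, T):
        a = np.dot(alpha[t - 1], trans) * emis[obs[t]]
        s = a.sum()
        c[t] = s
        alpha[t] = a / s
    loglik = np.log(c).sum()

    counts = np.zeros((3, n))
    xi = np.zeros((n, n))
    beta = np.ones(n)
    g = alpha[T - 1] * beta
    counts[obs[T - 1]] += g
    for t in range(T - 2, -1, -1):
        eb = emis[obs[t + 1]] * beta
        inv_c = 1.0 / c[t + 1]
        for i in range(n):
            ai = alpha[t, i] * inv_c
            for j in range(n):
                xi[i, j] += ai * trans[i, j] * eb[j]
        beta = np.dot(trans, eb) * inv_c
        g = alpha[t] * beta
        counts[obs[t]] += g
    return loglik, g, counts, xi


def _forward_backward(obs, trans, emis, prior):
    if _HAVE_NUMBA:
        return _forward_backward_nb(obs, trans, emis, prior)
    ll, g0, counts, xi, _ = _forward_backward_py(obs, trans, emis, prior)
    return ll, g0, counts, xi


# ---------------------------------------------------------------------------
# results / trajectories

@dataclass
class DemographicTrajectory:
    """Step function of effective population size over time in years.

    ``edges_years`` has one more entry than ``ne``; step k spans
    [edges_years[k], edges_years[k+1]).
    """

    edges_years: np.ndarray
    ne: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.edges_years) != len(self.ne) + 1:
            raise ValueError("edges must be one longer than ne")
        if (np.diff(self.edges_years) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.ne <= 0).any():
            raise ValueError("Ne must be positive")

    @property
    def span_years(self) -> tuple[float, float]:
        return float(self.edges_years[0]), float(self.edges_years[-1])

    def ne_at(self, t_years: float) -> float:
        """Ne of the step containing time ``t_years`` (steps are half-open)."""
        e = self.edges_years
        if not e[0] <= t_years < e[-1]:
            raise ValueError(f"time {t_years} outside trajectory span {self.span_years}")
        k = int(np.searchsorted(e, t_years, side="right")) - 1
        return float(self.ne[k])

    def steps(self):
        """Iterate (start_years, end_years, Ne)."""
        for k in range(len(self.ne)):
            yield float(self.edges_years[k]), float(self.edges_years[k + 1]), \
                float(self.ne[k])


@dataclass
class PsmcResults:
    """Fitted coalescent-HMM parameters with scaling and reporting helpers."""

    theta: float
    rho: float
    lambdas: np.ndarray        # per atomic interval (group ties applied)
    lambdas_free: np.ndarray   # one per free parameter group
    boundaries: np.ndarray     # atomic boundaries, coalescent units, t_0..t_n
    pattern: TimePattern
    loglik: float
    loglik_trace: np.ndarray
    bin_size: int
    n_bins: int
    objective_trace: np.ndarray | None = None
    smooth: float = 0.0

    def __post_init__(self) -> None:
        if not (self.theta > 0 and self.rho > 0 and (self.lambdas > 0).all()):
            raise ValueError("theta, rho and all lambdas must be > 0")
        if not math.isfinite(self.loglik):
            raise ValueError("final log-likelihood is not finite")

    def trajectory(self, mu_per_year: float = 2e-9, g_years: float = 5.0
                   ) -> DemographicTrajectory:
        return scale(self, mu_per_year, g_years, self.bin_size)

    def summary(self) -> str:
        n0_note = "N0 = theta / (4 mu_gen s); apply trajectory() for years"
        lines = [
            "Coalescent HMM fit (PSMC)",
            "=" * 58,
            f"pattern        {self.pattern.spec}  "
            f"({self.pattern.n_atomic} atomic / {self.pattern.n_free} free)",
            f"bins           {self.n_bins} of {self.bin_size} bp",
            f"theta (per bin)  {self.theta:.6g}",
            f"rho (per bin)    {self.rho:.6g}",
            f"log-likelihood   {self.loglik:.4f}  "
            f"({len(self.loglik_trace)} EM evaluations)",
            f"scaling          {n0_note}",
            "-" * 58,
            f"{'group':>5} {'t_start':>10} {'t_end':>10} {'lambda':>12}",
        ]
        group = self.pattern.group_of_atomic()
        for gidx in range(self.pattern.n_free):
            sel = np.flatnonzero(group == gidx)
            lines.append(f"{gidx:>5} {self.boundaries[sel[0]]:>10.5f} "
                         f"{self.boundaries[sel[-1] + 1]:>10.5f} "
                         f"{self.lambdas_free[gidx]:>12.6g}")
        return "\n".join(lines)


PsmcModel = PsmcResults


def scale(m: PsmcResults, mu_per_year: float, g_years: float,
          s: int | None = None) -> DemographicTrajectory:
    """Convert scaled HMM parameters to years and individuals.

    μ_gen = μ_year·g; N0 = θ/(4·μ_gen·s); times = 2·N0·t_j·g years;
    Ne_k = N0·λ_k individuals.
    """
    if mu_per_year <= 0 or g_years <= 0:
        raise ValueError("mu_per_year and g_years must be positive")
    s = s if s is not None else m.bin_size
    mu_gen = mu_per_year * g_years
    n0 = m.theta / (4.0 * mu_gen * s)
    edges = 2.0 * n0 * m.boundaries * g_years
    ne = n0 * m.lambdas
    return DemographicTrajectory(
        edges_years=edges, ne=ne,
        provenance={"mu_per_year": mu_per_year, "g_years": g_years,
                    "bin_size": s, "N0": n0, "theta": m.theta, "rho": m.rho})


# ---------------------------------------------------------------------------
# the model object

class PSMC:
    """Coalescent HMM over a binned genome, fitted by EM.

    Parameters
    ----------
    data
        Binned K/T/N genome (see :func:`make_psmcfa`).
    pattern
        Time-segmentation pattern string or parsed :class:`TimePattern`;
        the default ties 64 atomic intervals into 28 free parameters.
    t_max
        Most ancient boundary, in units of 2·N0 generations.
    """

    def __init__(self, data: PsmcFasta, pattern: str | TimePattern = "4+25*2+4+6",
                 t_max: float = 15.0) -> None:
        self.data = data
        self.pattern = parse_pattern(pattern) if isinstance(pattern, str) \
            else pattern
        self.t_max = float(t_max)
        self.boundaries = discretize(self.pattern.n_atomic, self.t_max)
        self._group = self.pattern.group_of_atomic()
        code = np.full(256, 255, dtype=np.uint8)
        code[ord("T")] = 0
        code[ord("K")] = 1
        code[ord("N")] = 2
        self._obs = [code[np.frombuffer(seq.encode(), dtype=np.uint8)]
                     .astype(np.int64) for _, seq in data.contigs]
        total = np.concatenate(self._obs) if self._obs else np.empty(0, np.int64)
        self.n_bins = int(total.size)
        self._n_k = int((total == 1).sum())
        self._n_t = int((total == 0).sum())
        if self._n_k + self._n_t == 0:
            raise ValueError("all bins are 'N': nothing to fit")

    def initial_theta(self) -> float:
        """Moment-matched θ: the het-bin fraction equals its expectation
        under the flat (λ = 1) coalescent prior.

        Solves Σ_j π_j·(1 − e^{−θ·t̄_j}) = frac_K for θ.  This pins the
        mutation scale, which the log-spaced grid leaves almost unidentified
        when θ, ρ and the overall λ level are all free (the model is nearly
        invariant under (θ, ρ, λ) → (cθ, cρ, λ/c)).
        """
        frac_k = self._n_k / (self._n_k + self._n_t)
        if frac_k <= 0:
            return 1e-6
        prior, tbar, _ = interval_quantities(self.boundaries,
                                             np.ones(self.pattern.n_atomic))

        def gap(theta: float) -> float:
            return float(prior @ -np.expm1(-theta * tbar)) - frac_k

        from scipy.optimize import brentq
        hi = 10.0
        if gap(hi) < 0:
            return hi
        return float(brentq(gap, 1e-9, hi, xtol=1e-12, rtol=1e-12))

    def _matrices(self, theta: float, rho: float, lam_free: np.ndarray):
        lam = lam_free[self._group]
        trans, prior, tbar = transition_matrix(self.boundaries, lam, rho)
        emis = emission_matrix(theta, tbar)
        return trans, prior, emis

    def _e_step(self, theta, rho, lam_free):
        trans, prior, emis = self._matrices(theta, rho, lam_free)
        n = self.pattern.n_atomic
        loglik = 0.0
        g0 = np.zeros(n)
        counts = np.zeros((3, n))
        xi = np.zeros((n, n))
        for obs in self._obs:
            ll, g, cts, x = _forward_backward(obs, trans, emis, prior)
            loglik += ll
            g0 += g
            counts += cts
            xi += x
        return loglik, (g0, counts, xi)

    def _neg_q(self, x, stats, theta=None, smooth=0.0):
        g0, counts, xi = stats
        if theta is None:
            theta, rho = math.exp(x[0]), math.exp(x[1])
            lam_free = np.exp(x[2:])
        else:
            rho = math.exp(x[0])
            lam_free = np.exp(x[1:])
        trans, prior, emis = self._matrices(theta, rho, lam_free)
        tiny = 1e-300
        q = float(g0 @ np.log(np.maximum(prior, tiny)))
        q += float(counts[0] @ np.log(np.maximum(emis[0], tiny)))
        q += float(counts[1] @ np.log(np.maximum(emis[1], tiny)))
        q += float(np.sum(xi * np.log(np.maximum(trans, tiny))))
        if smooth > 0 and len(lam_free) > 1:
            q -= smooth * float((np.diff(np.log(lam_free)) ** 2).sum())
        return -q

    def fit(self, n_iter: int = 25, theta0: float | None = None,
            rho0: float | None = None, update_theta: bool = False,
            smooth: float = 15.0, verbose: bool = False) -> PsmcResults:
        """Run ``n_iter`` EM iterations and return the fitted results.

        θ is anchored at the moment-matched initial estimate (see
        :meth:`initial_theta`) and the EM updates ρ and the tied λ; pass
        ``update_theta=True`` for a fully joint Baum–Welch update of θ as
        well (slower to converge and weakly identified on the log grid).
        ρ starts at θ/5 and all λ at 1.

        ``smooth`` is the weight of a quadratic penalty on adjacent
        log-λ differences (a smoothness prior on the size history, on top of
        the pattern's parameter tying).  It damps the wobble of weakly
        identified intervals; set it to 0 for plain maximum likelihood.
        With ``smooth`` > 0 the EM is a MAP-EM: the monotone quantity is the
        penalised objective reported in ``objective_trace``; the plain
        log-likelihood is reported alongside in ``loglik_trace``.
        """
        theta = theta0 if theta0 is not None else self.initial_theta()
        rho = rho0 if rho0 is not None else theta / 5.0
        lam_free = np.ones(self.pattern.n_free)
        lam_bounds = [(math.log(1e-4), math.log(1e4))] * self.pattern.n_free
        rate_bounds = [(math.log(1e-8), math.log(10.0))]
        bounds = (rate_bounds * 2 if update_theta else rate_bounds) + lam_bounds

        def penalty(lf: np.ndarray) -> float:
            if smooth > 0 and len(lf) > 1:
                return smooth * float((np.diff(np.log(lf)) ** 2).sum())
            return 0.0

        trace: list[float] = []
        obj_trace: list[float] = []
        for it in range(n_iter):
            loglik, stats = self._e_step(theta, rho, lam_free)
            if not math.isfinite(loglik):
                raise RuntimeError(f"non-finite likelihood at EM iteration {it}")
            trace.append(loglik)
            obj_trace.append(loglik - penalty(lam_free))
            if verbose:
                print(f"EM iter {it:3d}  loglik {loglik:.4f}")
            if update_theta:
                x0 = np.concatenate([[math.log(theta), math.log(rho)],
                                     np.log(lam_free)])
                args = (stats, None, smooth)
            else:
                x0 = np.concatenate([[math.log(rho)], np.log(lam_free)])
                args = (stats, theta, smooth)
            res = minimize(self._neg_q, x0, args=args, method="L-BFGS-B",
                           bounds=bounds, options={"maxiter": 100})
            if self._neg_q(res.x, *args) < self._neg_q(x0, *args):
                if update_theta:
                    theta, rho = math.exp(res.x[0]), math.exp(res.x[1])
                    lam_free = np.exp(res.x[2:])
                else:
                    rho = math.exp(res.x[0])
                    lam_free = np.exp(res.x[1:])
        loglik, _ = self._e_step(theta, rho, lam_free)
        if not math.isfinite(loglik):
            raise RuntimeError(f"non-finite likelihood at EM iteration {n_iter}")
        trace.append(loglik)
        obj_trace.append(loglik - penalty(lam_free))
        return PsmcResults(
            theta=theta, rho=rho, lambdas=lam_free[self._group],
            lambdas_free=lam_free, boundaries=self.boundaries,
            pattern=self.pattern, loglik=loglik,
            loglik_trace=np.asarray(trace),
            objective_trace=np.asarray(obj_trace),
            smooth=smooth, bin_size=self.data.bin_size,
            n_bins=self.n_bins)


def em_fit(p: PsmcFasta, pattern: str | TimePattern = "4+25*2+4+6",
           n_iter: int = 25, t_max: float = 15.0,
           theta0: float | None = None, rho0: float | None = None
           ) -> PsmcResults:
    """Functional wrapper around :class:`PSMC` and :meth:`PSMC.fit`."""
    return PSMC(p, pattern=pattern, t_max=t_max).fit(
        n_iter=n_iter, theta0=theta0, rho0=rho0)


# ---------------------------------------------------------------------------
# divergence read-off

@dataclass(frozen=True)
class DivergenceEstimate:
    """Oldest time back to which a pseudo-diploid's Ne stays 'exploded'.

    The divergence time of two individuals is read off their pseudo-diploid
    trajectory as the oldest step boundary such that at it and every more
    recent step the pseudo-diploid Ne exceeds C times the larger of the two
    single-individual Nes.  ``time_years`` is None when no step qualifies.
    """

    time_years: float | None
    c: float
    no_signal: bool
    reference: tuple[str, str] = ("single1", "single2")


def divergence_readoff(pseudo: DemographicTrajectory,
                       singles: tuple[DemographicTrajectory, DemographicTrajectory],
                       c: float = 10.0) -> DivergenceEstimate:
    """Read the divergence time off a pseudo-diploid trajectory.

    All three trajectories must have been scaled with the same μ and g and
    must overlap in time support.
    """
    s1, s2 = singles
    for t in (s1, s2):
        for key in ("mu_per_year", "g_years"):
            if t.provenance.get(key) != pseudo.provenance.get(key):
                raise ValueError(f"trajectories disagree on {key}")
    end = min(pseudo.span_years[1], s1.span_years[1], s2.span_years[1])
    start = max(pseudo.span_years[0], s1.span_years[0], s2.span_years[0])
    if end <= start:
        raise ValueError("trajectories have no overlapping time support")
    grid = np.unique(np.concatenate([
        np.clip(t.edges_years, start, end) for t in (pseudo, s1, s2)]))
    mids = 0.5 * (grid[:-1] + grid[1:])
    ok = np.array([
        pseudo.ne_at(m) > c * max(s1.ne_at(m), s2.ne_at(m)) for m in mids])
    # maximal run of qualifying cells starting at the most recent one
    k = 0
    while k < len(ok) and ok[k]:
        k += 1
    if k == 0:
        return DivergenceEstimate(time_years=None, c=c, no_signal=True)
    return DivergenceEstimate(time_years=float(grid[k]), c=c, no_signal=False)
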