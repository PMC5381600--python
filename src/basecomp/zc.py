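"""Long-timescale selection inference from the unpolarized SFS with fixed classes.

A two-allele (W = A/T vs S = G/C) Wright-Fisher model with reversible
mutation (v: W->S at rate theta = 4*N0*v; u = kappa*v: S->W), genic selection
of scaled intensity gamma = 4*N0*s favoring S, and a one-step change in
population size: the population is at equilibrium at size N1 = g*N0, changes
instantaneously to N0, and is sampled tau*2*N0 generations later.  Because
the model tracks absolute base composition (including monomorphic sites), it
retains information about selection over a much longer timescale than
polarized-SFS methods.

The data are the counts of S alleles among n sampled sequences, classes
0..n (class 0 = fixed W, class n = fixed S); the likelihood is multinomial.
Equilibrium sampling probabilities are exact (Wright's stationary density
integrated against the binomial kernel, in closed form via Kummer's 1F1);
the non-equilibrium phase is propagated with a discretized Wright-Fisher
transition matrix on a rescaled population of size n_grid, with the scaled
parameters theta, gamma, kappa and tau held fixed under the rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from basecomp.containers import ModelFit, SpectrumSet

__all__ = [
    "ZcParams",
    "FrequencyGrid",
    "stationary_sample_probs",
    "transient_sample_probs",
    "wf_transition_matrix",
    "zc_loglik",
    "fit_zc",
    "zc_model_tests",
    "zc_param_count",
]

VARIANTS = ("ZC0", "ZC1", "ZC0c", "ZC1c")
#: scaled times beyond which the post-change population is treated as being
#: back at equilibrium (the chain has mixed; see transient_sample_probs)
TAU_ERGODIC = 10.0
#: |gamma| clip applied inside the stationary quadrature to keep 1F1 finite
_GAMMA_CLIP = 100.0


@dataclass
class ZcParams:
    """Parameters of the reversible-mutation model.

    gamma : scaled selection 4*N0*s favoring S (0 in the ZC0 variants).
    theta : scaled W->S mutation input 4*N0*v.
    kappa : mutational bias u/v.
    g     : ancestral/current size ratio N1/N0 (1 in the constant-size
            variants).
    tau   : time since the size change in units of 2*N0 generations.
    """

    gamma: float
    theta: float
    kappa: float
    g: float = 1.0
    tau: float = 0.0
    variant: str = "ZC1"

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.kappa <= 0 or self.g <= 0:
            raise ValueError("theta, kappa and g must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class FrequencyGrid:
    """Discretization of the S-allele frequency for the transient phase.

    The chain lives on counts 0..2*n_grid out of 2*n_grid copies; mutation
    and selection increments are rescaled so that theta, kappa, gamma and tau
    keep their values on the rescaled population.
    """

    n_grid: int = 200

    def __post_init__(self) -> None:
        if self.n_grid < 10:
            raise ValueError("n_grid too small for a meaningful discretization")

    @property
    def n_states(self) -> int:
        return 2 * self.n_grid + 1

    def increments(self, p: ZcParams) -> tuple[float, float, float]:
        """(s_gen, v_gen, u_gen): per-generation selection and mutation."""
        s_gen = p.gamma / (4.0 * self.n_grid)
        v_gen = p.theta / (4.0 * self.n_grid)
        u_gen = p.kappa * p.theta / (4.0 * self.n_grid)
        return s_gen, v_gen, u_gen


def _stationary_logweights(gamma: float, a: float, b: float, n: int) -> np.ndarray:
    """log of P(i S alleles in n) under Wright's density e^{gamma x}
    x^{a-1} (1-x)^{b-1}, up to a common constant.

    Closed form: log C(n,i) + log B(a+i, b+n-i) + log 1F1(a+i; a+b+n; gamma).
    """
    i = np.arange(n + 1, dtype=float)
    gamma = float(np.clip(gamma, -_GAMMA_CLIP, _GAMMA_CLIP))
    log_binom = special.gammaln(n + 1) - special.gammaln(i + 1) - special.gammaln(n - i + 1)
    log_beta = special.betaln(a + i, b + n - i)
    # 1F1(a'; c; gamma) > 0 for a', c > 0; use the Kummer transform for
    # gamma < 0 to avoid cancellation in the alternating series
    if gamma >= 0:
        kummer = special.hyp1f1(a + i, a + b + n, gamma)
        log_kummer = np.log(kummer)
    else:
        kummer = special.hyp1f1(b + n - i, a + b + n, -gamma)
        log_kummer = gamma + np.log(kummer)
    return log_binom + log_beta + log_kummer


def stationary_sample_probs(p: ZcParams, n: int, epoch: str = "current") -> np.ndarray:
    """Sampling distribution of S-allele counts 0..n at equilibrium.

    ``epoch="ancestral"`` evaluates the pre-change population of size g*N0,
    for which the locally scaled parameters are (g*gamma, g*theta, kappa).
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    scale = p.g if epoch == "ancestral" else 1.0
    a = scale * p.theta            # 4*N*v exponent (S-allele input)
    b = scale * p.kappa * p.theta  # 4*N*u exponent
    logw = _stationary_logweights(scale * p.gamma, a, b, n)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def wf_transition_matrix(p: ZcParams, grid: FrequencyGrid) -> np.ndarray:
    """One-generation transition matrix of the discretized chain at size N0.

    Row j: binomial(2*n_grid, psi(x_j)) where psi applies deterministic
    selection and mutation to x_j = j / (2*n_grid).
    """
    s_gen, v_gen, u_gen = grid.increments(p)
    m = grid.n_states - 1
    x = np.arange(grid.n_states) / m
    psi = x + s_gen * x * (1.0 - x) + v_gen * (1.0 - x) - u_gen * x
    psi = np.clip(psi, 0.0, 1.0)
    k = np.arange(grid.n_states)
    return stats.binom.pmf(k[None, :], m, psi[:, None])


def _evolve(w: np.ndarray, T: np.ndarray, gens: int) -> np.ndarray:
    """w @ T^gens by binary powering (a handful of 4e6-flop matmuls)."""
    power = T
    out = w
    g = gens
    while g > 0:
        if g & 1:
            out = out @ power
        g >>= 1
        if g > 0:
            power = power @ power
    return out


def transient_sample_probs(
    p: ZcParams, n: int, grid: FrequencyGrid | None = None
) -> np.ndarray:
    """Sampling distribution 0..n after the one-step size change.

    The chain starts from the ancestral equilibrium (size g*N0), evolves for
    round(tau * 2 * n_grid) generations under the current-size dynamics, and
    is binomially subsampled to n.  tau = 0 returns the ancestral stationary
    distribution exactly; tau >= 10 (scaled) returns the current-epoch
    stationary distribution, the chain having mixed.
    """
    if grid is None:
        grid = FrequencyGrid()
    if p.tau == 0.0:
        return stationary_sample_probs(p, n, epoch="ancestral")
    if p.tau >= TAU_ERGODIC:
        return stationary_sample_probs(p, n, epoch="current")
    gens = int(round(p.tau * 2 * grid.n_grid))
    # initial state: ancestral stationary density discretized by binomial
    # sampling onto the 2*n_grid+1 count states
    w = stationary_sample_probs(p, grid.n_states - 1, epoch="ancestral")
    if gens > 0:
        T = wf_transition_matrix(p, grid)
        w = _evolve(w, T, gens)
    x = np.arange(grid.n_states) / (grid.n_states - 1)
    sampling = stats.binom.pmf(np.arange(n + 1)[None, :], n, x[:, None])
    out = w @ sampling
    out = np.clip(out, 0.0, None)
    return out / out.sum()


def zc_param_count(variant: str) -> int:
    return {"ZC1": 5, "ZC0": 4, "ZC1c": 3, "ZC0c": 2}[variant]


def zc_loglik(p: ZcParams, s: SpectrumSet, grid: FrequencyGrid | None = None) -> float:
    """Multinomial log-likelihood (constants dropped) of the S-allele count
    spectrum, classes 0..n including the fixed classes."""
    counts = s.s_allele_counts()
    probs = transient_sample_probs(p, s.n, grid=grid)
    probs = np.maximum(probs, 1e-300)
    return float(np.sum(counts * np.log(probs)))


def _unpack(z: np.ndarray, variant: str) -> ZcParams:
    free_gamma = variant.startswith("ZC1")
    const_size = variant.endswith("c")
    idx = 0
    gamma = 0.0
    if free_gamma:
        gamma = float(z[idx]); idx += 1
    theta = math.exp(float(z[idx])); idx += 1
    kappa = math.exp(float(z[idx])); idx += 1
    g, tau = 1.0, 0.0
    if not const_size:
        g = math.exp(float(z[idx])); idx += 1
        tau = float(z[idx]); idx += 1
    return ZcParams(gamma=gamma, theta=theta, kappa=kappa, g=g, tau=tau,
                    variant=variant)


def _bounds(variant: str) -> list[tuple[float, float]]:
    free_gamma = variant.startswith("ZC1")
    const_size = not variant.endswith("c")
    b = []
    if free_gamma:
        b.append((-20.0, 20.0))
    b.append((math.log(1e-5), math.log(0.5)))   # log theta
    b.append((-4.0, 4.0))                        # log kappa
    if const_size:
        b.append((-3.0, 3.0))                    # log g
        b.append((0.0, TAU_ERGODIC + 2.0))       # tau
    return b


def _moment_start(s: SpectrumSet, variant: str) -> np.ndarray:
    """Crude start: GC content fixes kappa at gamma=0; the segregating
    fraction fixes theta; demography starts near neutrality of the change."""
    counts = s.s_allele_counts()
    total = counts.sum()
    n = s.n
    q = float(np.sum(np.arange(n + 1) * counts) / (n * total))
    q = min(max(q, 0.01), 0.99)
    kappa0 = (1.0 - q) / q
    seg = float(counts[1:n].sum() / total)
    harm = np.sum(1.0 / np.arange(1, n))
    theta0 = min(max(seg / (harm * (1.0 + kappa0) * q + 1e-9), 1e-4), 0.4)
    z = []
    if variant.startswith("ZC1"):
        z.append(0.0)
    z += [math.log(theta0), math.log(kappa0)]
    if not variant.endswith("c"):
        z += [0.0, 1.0]
    return np.asarray(z)


def fit_zc(
    s: SpectrumSet,
    variant: str = "ZC1",
    restarts: int = 50,
    seed: int = 0,
    grid: FrequencyGrid | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model variant.

    Multi-start bounded quasi-Newton in transformed coordinates (log theta,
    log kappa, log g; gamma and tau untransformed).  The first start is a
    moment-based point; the rest are seeded random draws within the bounds.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if grid is None:
        grid = FrequencyGrid()
    if s.s_allele_counts().sum() <= 0:
        raise ValueError("empty spectrum")
    rng = np.random.default_rng(seed)
    bounds = np.asarray(_bounds(variant))

    def neg(z: np.ndarray) -> float:
        try:
            p = _unpack(z, variant)
        except ValueError:
            return 1e12
        ll = zc_loglik(p, s, grid=grid)
        return -ll if np.isfinite(ll) else 1e12

    starts = [_moment_start(s, variant)]
    if not variant.endswith("c"):
        # warm start at the constant-size solution (g=1, tau=0): those fits
        # only touch the closed-form stationary path, so they are cheap, and
        # the step-change model is guaranteed to do at least as well
        cfit = fit_zc(s, variant + "c", restarts=max(restarts // 2, 2),
                      seed=seed, grid=grid)
        z = ([cfit.params["gamma"]] if variant.startswith("ZC1") else [])
        z += [math.log(cfit.params["theta"]), math.log(cfit.params["kappa"]),
              0.0, 0.0]
        starts.insert(0, np.asarray(z))
    for _ in range(max(restarts - 1, 0)):
        starts.append(rng.uniform(bounds[:, 0], bounds[:, 1]))

    best = None
    trace = []
    for z0 in starts:
        res = optimize.minimize(neg, z0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 200, "ftol": 1e-12})
        trace.append((-float(res.fun), bool(res.success)))
        if best is None or res.fun < best.fun:
            best = res

    p = _unpack(best.x, variant)
    params = {"gamma": p.gamma, "theta": p.theta, "kappa": p.kappa,
              "g": p.g, "tau": p.tau}
    return ModelFit(
        model=variant,
        params=params,
        loglik=-float(best.fun),
        n_params=zc_param_count(variant),
        converged=any(ok for _, ok in trace),
        restarts=trace,
        meta={"n": s.n, "n_grid": grid.n_grid,
              "total_sites": float(s.s_allele_counts().sum())},
    )


def zc_model_tests(fits: dict[str, ModelFit]) -> dict:
    """Chi-squared LRTs between nested variants on the same data.

    Reported pairs (when present): ZC1 vs ZC0 (selection, df 1), ZC1 vs ZC1c
    and ZC0 vs ZC0c (size change, df 2).
    """
    tots = {round(f.meta.get("total_sites", -1), 6) for f in fits.values()}
    if len(tots) > 1:
        raise ValueError("fits were not computed on identical data")
    out = {}
    pairs = [("ZC1", "ZC0"), ("ZC1c", "ZC0c"), ("ZC1", "ZC1c"),
             ("ZC0", "ZC0c")]
    for alt, null in pairs:
        if alt in fits and null in fits:
            chi2 = max(2.0 * (fits[alt].loglik - fits[null].loglik), 0.0)
            df = fits[alt].n_params - fits[null].n_params
            out[f"{alt} vs {null}"] = {
                "chi2": chi2,
                "df": df,
                "p": float(stats.chi2.sf(chi2, df)),
            }
    return out
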