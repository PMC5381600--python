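"""Short-timescale selection inference from three polarized SFS categories.

The observed data are the unfolded site-frequency spectra of W->S, S->W and
neutral (A<->T, G<->C) segregating sites in a sample of n haploid sequences.
Under an infinite-sites Poisson-field model with genic selection of scaled
intensity gamma favoring S, the expected count in derived-copy class i is

    E[xi_i^cat] = theta_cat * r_i * Integral_0^1 C(n,i) x^i (1-x)^(n-i)
                                     * H(gamma_cat, x) dx,

    H(gamma, x) = (1 - exp(-gamma(1-x))) / ((1 - exp(-gamma)) x (1-x)),

with gamma_cat = +gamma for W->S, -gamma for S->W and 0 for the neutral
class.  The r_i (r_1 = 1) are per-class demographic distortion factors shared
across categories; they absorb departures of the neutral spectrum shape from
the equilibrium theta/i without an explicit demographic model.

Model variants: M0 (gamma = 0), M1 (gamma free), and the starred variants
M0*/M1* which additionally mix each spectrum with the reverse-complemented
class of its opposite category to model ancestral-state (polarization)
errors: one error rate shared by the two selected categories and one for the
neutral category.

The binomial-weighted integral has the closed form

    I_i(gamma) = C(n,i) B(i, n-i) * (1 - e^-gamma 1F1(i; n; gamma))
                 / (1 - e^-gamma),

which reduces to 1/i at gamma = 0; it is evaluated via Kummer's function.
The likelihood is an independent-Poisson quasi-likelihood over classes and
categories (fractional counts from probabilistic polarization are allowed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from basecomp.containers import ModelFit, SpectrumSet

__all__ = [
    "GleminParams",
    "sfs_integral",
    "expected_sfs_glemin",
    "glemin_loglik",
    "fit_glemin",
    "glemin_model_selection",
    "estimate_kappa_glemin",
    "glemin_param_count",
]

_GAMMA_EPS = 1e-8
VARIANTS = ("M0", "M1", "M0*", "M1*")


@dataclass
class GleminParams:
    """Parameter set for one model variant.

    ``r`` holds the distortion factors for classes 2..n-1 (r_1 is fixed to 1
    for identifiability).  ``e_sel``/``e_neu`` are polarization error rates in
    [0, 0.5]; they are only active in the starred variants.
    """

    gamma: float
    theta_ws: float
    theta_sw: float
    theta_neu: float
    r: np.ndarray
    e_sel: float = 0.0
    e_neu: float = 0.0
    variant: str = "M1"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r <= 0):
            raise ValueError("distortion factors must be positive")
        for th in (self.theta_ws, self.theta_sw, self.theta_neu):
            if th <= 0:
                raise ValueError("theta parameters must be positive")
        for e in (self.e_sel, self.e_neu):
            if not (0.0 <= e <= 0.5):
                raise ValueError("error rates must lie in [0, 0.5]")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n(self) -> int:
        return len(self.r) + 2

    def r_full(self) -> np.ndarray:
        """Distortion factors for classes 1..n-1 including the fixed r_1."""
        return np.concatenate([[1.0], self.r])


def glemin_param_count(variant: str, n: int) -> int:
    """Free-parameter count: M0 = 3 + (n-2), M1 adds gamma, starred add the
    two polarization-error rates."""
    base = 3 + (n - 2)
    if variant in ("M1", "M1*"):
        base += 1
    if variant.endswith("*"):
        base += 2
    return base


def sfs_integral(gamma: float, n: int) -> np.ndarray:
    """I_i(gamma) for i = 1..n-1 (closed form via Kummer's 1F1).

    This is the binomial-sampling integral of the Poisson-field frequency
    density; I_i(0) = 1/i.
    """
    i = np.arange(1, n)
    if abs(gamma) < _GAMMA_EPS:
        return 1.0 / i
    # C(n,i) * B(i, n-i) = n / (i * (n - i))
    prefactor = n / (i * (n - i))
    kummer = special.hyp1f1(i, n, gamma)
    num = 1.0 - math.exp(-gamma) * kummer
    den = -math.expm1(-gamma)
    return prefactor * num / den


def _unmixed_means(p: GleminParams) -> dict[str, np.ndarray]:
    n = p.n
    r = p.r_full()
    return {
        "WS": p.theta_ws * r * sfs_integral(p.gamma, n),
        "SW": p.theta_sw * r * sfs_integral(-p.gamma, n),
        "neu": p.theta_neu * r * sfs_integral(0.0, n),
    }


def _mix(means: dict[str, np.ndarray], e_sel: float, e_neu: float) -> dict[str, np.ndarray]:
    ws, sw, neu = means["WS"], means["SW"], means["neu"]
    return {
        "WS": (1 - e_sel) * ws + e_sel * sw[::-1],
        "SW": (1 - e_sel) * sw + e_sel * ws[::-1],
        "neu": (1 - e_neu) * neu + e_neu * neu[::-1],
    }


def expected_sfs_glemin(p: GleminParams, n: int | None = None) -> dict[str, np.ndarray]:
    """Expected spectra for the three categories under ``p``.

    Starred variants apply the polarization-error mixing; for M0/M1 the error
    rates are ignored.
    """
    if n is not None and n != p.n:
        raise ValueError(f"params imply n={p.n}, got n={n}")
    means = _unmixed_means(p)
    if p.variant.endswith("*"):
        means = _mix(means, p.e_sel, p.e_neu)
    return means


def glemin_loglik(p: GleminParams, s: SpectrumSet) -> float:
    """Independent-Poisson quasi-log-likelihood (x log mu - mu, constants
    dropped so that fractional counts are handled consistently)."""
    if s.n != p.n:
        raise ValueError(f"spectra have n={s.n}, params imply n={p.n}")
    means = expected_sfs_glemin(p)
    total = 0.0
    for cat in ("WS", "SW", "neu"):
        x = s.spectrum(cat)
        mu = means[cat]
        if np.any(mu <= 0):
            return -np.inf
        total += float(np.sum(x * np.log(mu) - mu))
    return total


# ---------------------------------------------------------------------------
# fitting


def _newton_scale(x: np.ndarray, off: np.ndarray, coef: np.ndarray, init: float) -> float:
    """Maximize sum x log(off + coef*t) - (off + coef*t) over t > 0.

    The objective is concave in t; with all offsets zero the maximizer is
    sum(x)/sum(coef).  Otherwise a few safeguarded Newton steps suffice.
    """
    mask = coef > 0
    if not np.any(mask):
        return init
    x, off, coef = x[mask], off[mask], coef[mask]
    if np.all(off == 0):
        tot = coef.sum()
        return float(x.sum() / tot) if tot > 0 else init
    t = max(init, 1e-12)
    for _ in range(30):
        denom = off + coef * t
        g = float(np.sum(x * coef / denom) - coef.sum())
        h = float(-np.sum(x * coef**2 / denom**2))
        if h >= 0:
            break
        step = -g / h
        t_new = t + step
        if t_new <= 0:
            t_new = t / 2.0
        if abs(t_new - t) < 1e-12 * (1.0 + t):
            t = t_new
            break
        t = t_new
    return float(max(t, 1e-12))


def _profile_nuisance(
    s: SpectrumSet,
    gamma: float,
    e_sel: float,
    e_neu: float,
    starred: bool,
    n_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[float, dict]:
    """Maximize the Poisson quasi-likelihood over (theta_WS, theta_SW,
    theta_neu, r_2..r_{n-1}) at fixed gamma and error rates.

    Coordinate ascent; every mean is linear in each coordinate, so each
    update is a 1-D concave Poisson-scale problem with a closed form or a
    short Newton iteration.
    """
    n = s.n
    i_ws = sfs_integral(gamma, n)
    i_sw = sfs_integral(-gamma, n)
    i_neu = sfs_integral(0.0, n)
    x = {c: s.spectrum(c) for c in ("WS", "SW", "neu")}

    theta = {
        "WS": max(x["WS"].sum(), 0.5) / i_ws.sum(),
        "SW": max(x["SW"].sum(), 0.5) / i_sw.sum(),
        "neu": max(x["neu"].sum(), 0.5) / i_neu.sum(),
    }
    r = np.ones(n - 1)
    es = e_sel if starred else 0.0
    en = e_neu if starred else 0.0

    def base():
        return {
            "WS": theta["WS"] * r * i_ws,
            "SW": theta["SW"] * r * i_sw,
            "neu": theta["neu"] * r * i_neu,
        }

    def loglik() -> float:
        m = _mix(base(), es, en) if starred else base()
        tot = 0.0
        for c in ("WS", "SW", "neu"):
            mu = np.maximum(m[c], 1e-300)
            tot += float(np.sum(x[c] * np.log(mu) - mu))
        return tot

    prev = -np.inf
    for _ in range(n_iter):
        # --- theta updates
        if not starred:
            for cat, integ in (("WS", i_ws), ("SW", i_sw), ("neu", i_neu)):
                tot = float(np.sum(r * integ))
                theta[cat] = max(x[cat].sum(), 1e-9) / tot
        else:
            # theta_WS appears in WS (weight 1-es) and SW (weight es, reversed)
            sw_mean = theta["SW"] * r * i_sw
            coef = np.concatenate([(1 - es) * r * i_ws, es * (r * i_ws)[::-1]])
            off = np.concatenate([es * sw_mean[::-1], (1 - es) * sw_mean])
            xx = np.concatenate([x["WS"], x["SW"]])
            theta["WS"] = _newton_scale(xx, off, coef, theta["WS"])
            ws_mean = theta["WS"] * r * i_ws
            coef = np.concatenate([(1 - es) * r * i_sw, es * (r * i_sw)[::-1]])
            off = np.concatenate([es * ws_mean[::-1], (1 - es) * ws_mean])
            xx = np.concatenate([x["SW"], x["WS"]])
            theta["SW"] = _newton_scale(xx, off, coef, theta["SW"])
            # neutral mixes with itself but stays proportional to theta_neu
            shape = (1 - en) * r * i_neu + en * (r * i_neu)[::-1]
            theta["neu"] = max(x["neu"].sum(), 1e-9) / float(shape.sum())

        # --- r updates (0-based position cls holds class cls+1; r_1 stays 1)
        b = base()
        spec = {"WS": (theta["WS"], i_ws), "SW": (theta["SW"], i_sw),
                "neu": (theta["neu"], i_neu)}
        partner = {"WS": "SW", "SW": "WS", "neu": "neu"}
        for cls in range(1, n - 1):
            mirror = n - 2 - cls
            coefs, offs, xs = [], [], []
            for cat in ("WS", "SW", "neu"):
                th, integ = spec[cat]
                th_p, integ_p = spec[partner[cat]]
                e = (en if cat == "neu" else es) if starred else 0.0
                if starred and mirror == cls:
                    # middle class: both the direct and the reversed term of
                    # the mixed mean are proportional to r_cls
                    coefs.append((1 - e) * th * integ[cls] + e * th_p * integ_p[cls])
                    offs.append(0.0)
                    xs.append(x[cat][cls])
                    continue
                # observed category `cat` at class cls: direct term carries r_cls
                coefs.append(((1 - e) if starred else 1.0) * th * integ[cls])
                offs.append(e * b[partner[cat]][mirror] if starred else 0.0)
                xs.append(x[cat][cls])
                if starred:
                    # observed `cat` at the mirror class picks up r_cls via the
                    # reversed partner term
                    coefs.append(e * th_p * integ_p[cls])
                    offs.append((1 - e) * b[cat][mirror])
                    xs.append(x[cat][mirror])
            r[cls] = _newton_scale(np.asarray(xs), np.asarray(offs),
                                   np.asarray(coefs), r[cls])
            b = base()
            spec = {"WS": (theta["WS"], i_ws), "SW": (theta["SW"], i_sw),
                    "neu": (theta["neu"], i_neu)}

        cur = loglik()
        if cur - prev < tol * (1.0 + abs(cur)):
            prev = cur
            break
        prev = cur

    params = {"theta_ws": theta["WS"], "theta_sw": theta["SW"],
              "theta_neu": theta["neu"], "r": r[1:].copy()}
    return prev, params


def fit_glemin(
    s: SpectrumSet,
    variant: str = "M1",
    restarts: int = 25,
    seed: int = 0,
    gamma_bound: float = 25.0,
) -> ModelFit:
    """Fit one model variant by maximum likelihood.

    gamma (M1/M1*) and the error rates (starred) are optimized in an outer
    low-dimensional search; the mutational and distortion parameters are
    profiled out by coordinate ascent at every outer evaluation.  ``restarts``
    controls the number of random outer starting points for the starred
    variants (the 1-D gamma profile for M1 uses a deterministic grid bracket
    and is insensitive to restarts).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    nonempty = sum(s.spectrum(c).sum() > 0 for c in ("WS", "SW", "neu"))
    if nonempty < 2:
        raise ValueError("need non-empty spectra for at least two categories")
    rng = np.random.default_rng(seed)
    starred = variant.endswith("*")
    free_gamma = variant in ("M1", "M1*")
    n = s.n

    def profile(gamma: float, es: float = 0.0, en: float = 0.0) -> tuple[float, dict]:
        return _profile_nuisance(s, gamma, es, en, starred)

    trace = []
    if not starred:
        if not free_gamma:
            ll, pars = profile(0.0)
            best = (ll, 0.0, 0.0, 0.0, pars)
        else:
            grid = np.linspace(-gamma_bound * 0.6, gamma_bound * 0.6, 25)
            vals = [profile(g)[0] for g in grid]
            g0 = grid[int(np.argmax(vals))]
            span = grid[1] - grid[0]
            res = optimize.minimize_scalar(
                lambda g: -profile(g)[0],
                bounds=(max(g0 - 2 * span, -gamma_bound),
                        min(g0 + 2 * span, gamma_bound)),
                method="bounded",
                options={"xatol": 1e-6},
            )
            ll, pars = profile(res.x)
            best = (ll, float(res.x), 0.0, 0.0, pars)
            trace.append((ll, True))
    else:
        def neg(z: np.ndarray) -> float:
            g = z[0] if free_gamma else 0.0
            es = 0.5 / (1.0 + math.exp(-z[-2]))
            en = 0.5 / (1.0 + math.exp(-z[-1]))
            return -profile(g, es, en)[0]

        ndim = 3 if free_gamma else 2
        starts = []
        if free_gamma:
            m1 = fit_glemin(s, "M1", restarts=1, seed=seed)
            starts.append(np.array([m1.params["gamma"], -3.0, -3.0]))
        else:
            starts.append(np.array([-3.0, -3.0]))
        for _ in range(max(restarts - 1, 0)):
            z = rng.normal(scale=2.0, size=ndim)
            if free_gamma:
                z[0] = rng.uniform(-8.0, 8.0)
            starts.append(z)

        best = None
        for z0 in starts:
            res = optimize.minimize(neg, z0, method="Nelder-Mead",
                                    options={"xatol": 1e-5, "fatol": 1e-8,
                                             "maxiter": 400})
            g = float(res.x[0]) if free_gamma else 0.0
            es = 0.5 / (1.0 + math.exp(-res.x[-2]))
            en = 0.5 / (1.0 + math.exp(-res.x[-1]))
            ll, pars = profile(g, es, en)
            trace.append((ll, bool(res.success)))
            if best is None or ll > best[0]:
                best = (ll, g, es, en, pars)

    ll, gamma, es, en, pars = best
    params = {"gamma": gamma, **pars, "e_sel": es, "e_neu": en}
    return ModelFit(
        model=variant,
        params=params,
        loglik=ll,
        n_params=glemin_param_count(variant, n),
        converged=bool(np.isfinite(ll)),
        restarts=trace,
        meta={"n": n},
    )


def glemin_model_selection(fits: dict[str, ModelFit]) -> dict:
    """LRTs for the nested pairs (M1 vs M0, M1* vs M0*) and AIC ranking."""
    ns = {f.meta.get("n") for f in fits.values()}
    if len(ns) > 1:
        raise ValueError("fits were not computed on identical data")
    out = {"lrt": {}, "aic_ranking": None}
    for alt, null in (("M1", "M0"), ("M1*", "M0*")):
        if alt in fits and null in fits:
            chi2 = 2.0 * (fits[alt].loglik - fits[null].loglik)
            chi2 = max(chi2, 0.0)
            out["lrt"][f"{alt} vs {null}"] = {
                "chi2": chi2,
                "df": 1,
                "p": float(stats.chi2.sf(chi2, 1)),
            }
    ranked = sorted(fits.values(), key=lambda f: f.aic)
    out["aic_ranking"] = [(f.model, float(f.aic)) for f in ranked]
    return out


def estimate_kappa_glemin(fit: ModelFit, LW: float, LS: float) -> float:
    """Mutational bias kappa = (theta_SW / L_S) / (theta_WS / L_W).

    theta_SW counts mutational input per S site and theta_WS per W site, so
    the per-site rate ratio u/v requires normalizing by the numbers of
    ancestral S and W sites.
    """
    if LW <= 0 or LS <= 0:
        raise ValueError("site totals LW and LS must be positive")
    th_ws = fit.params["theta_ws"]
    th_sw = fit.params["theta_sw"]
    if th_ws <= 0 or th_sw <= 0:
        raise ValueError("theta estimates must be positive")
    return (th_sw / LS) / (th_ws / LW)
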