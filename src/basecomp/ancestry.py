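"""Ancestral base inference at the mel-sim (*ms*) node of ((mel,sim),yak).

When base composition is drifting (e.g. a genome-wide loss of GC), both
parsimony and stationary maximum likelihood systematically over-call
common->rare changes.  The remedy used here is a branch-nonstationary GTR
model: each of the four branches of the rooted tree

    root --- ms --- mel
      \        \--- sim
       \--- yak

carries its own exchangeabilities and base frequencies, plus free root
frequencies, for 3 + 4*(5+3) + 4 = 39 free parameters.  The stationary
comparator is a single GTR on an unrooted star (5 + 3 + 3 = 11 parameters);
the two are nested, giving a 28-df likelihood-ratio test of nonstationarity.

Data enter as counts over the 64 (mel, sim, yak) site patterns.  Ancestral
states at the *ms* node are reported three ways: parsimony (majority base,
fully ambiguous patterns flagged), SBR (argmax of the model posterior) and
AWP (the full posterior vector, used downstream as fractional weights).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from basecomp.containers import ModelFit

__all__ = [
    "BASES",
    "TripletPatternCounts",
    "StationaryGtrModel",
    "NonStationaryGtrModel",
    "AncestralPosterior",
    "gtr_rate_matrix",
    "transition_probs",
    "fit_stationary_gtr",
    "fit_nh_gtr",
    "lrt_nonstationarity",
    "ancestral_posteriors",
    "parsimony_ancestor",
]

BASES = "ACGT"
BRANCHES = ("root_ms", "ms_mel", "ms_sim", "root_yak")
#: unordered base pairs in the order the 6 exchangeabilities are stored
PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

N_PARAMS_NH = 39
N_PARAMS_STATIONARY = 11


@dataclass
class TripletPatternCounts:
    """Counts over the 64 (mel, sim, yak) base patterns for one bin."""

    counts: np.ndarray  # shape (4, 4, 4), indexed [mel, sim, yak]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (4, 4, 4):
            raise ValueError("pattern counts must have shape (4, 4, 4)")
        if np.any(self.counts < 0):
            raise ValueError("negative pattern counts")

    @classmethod
    def from_site_bases(cls, mel, sim, yak) -> "TripletPatternCounts":
        """Tally patterns from three equal-length base strings/arrays;
        sites with non-ACGT characters in any species are skipped."""
        lut = np.full(256, -1, dtype=np.int8)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
            lut[ord(b.lower())] = i
        arrs = []
        for seq in (mel, sim, yak):
            if isinstance(seq, str):
                a = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
            else:
                a = np.asarray(seq, dtype=np.int8)
            arrs.append(a)
        m, s, y = arrs
        if not (len(m) == len(s) == len(y)):
            raise ValueError("sequences differ in length")
        ok = (m >= 0) & (s >= 0) & (y >= 0)
        flat = (m[ok].astype(int) * 16 + s[ok].astype(int) * 4 + y[ok].astype(int))
        counts = np.bincount(flat, minlength=64).reshape(4, 4, 4).astype(float)
        return cls(counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class StationaryGtrModel:
    """Time-reversible GTR on an unrooted 3-taxon star (11 free parameters)."""

    exch: np.ndarray          # 6 exchangeabilities, s_GT = 1 reference
    freqs: np.ndarray         # stationary base frequencies
    lengths: np.ndarray       # branch lengths to (mel, sim, yak)


@dataclass
class NonStationaryGtrModel:
    """Branch-nonstationary GTR on rooted ((mel,sim)ms, yak) (39 parameters)."""

    root_freqs: np.ndarray
    exch: dict = field(default_factory=dict)     # branch -> 6 exchangeabilities
    freqs: dict = field(default_factory=dict)    # branch -> 4 frequencies
    lengths: dict = field(default_factory=dict)  # branch -> length


@dataclass
class AncestralPosterior:
    """Per-pattern probability vectors over {A,C,G,T} at the *ms* node.

    ``probs[m, s, y]`` is the length-4 posterior for pattern (mel=m, sim=s,
    yak=y).  For parsimony/SBR the vector is a unit indicator; parsimony
    flags fully ambiguous patterns (three distinct bases) in ``ambiguous``
    with a zero vector.
    """

    probs: np.ndarray   # shape (4, 4, 4, 4)
    method: str
    ambiguous: np.ndarray | None = None  # shape (4, 4, 4) bool


def gtr_rate_matrix(exch: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Rate matrix Q_ij = s_ij * pi_j, normalized to one expected
    substitution per unit branch length at frequencies ``freqs``."""
    Q = np.zeros((4, 4))
    for s, (i, j) in zip(exch, PAIRS):
        Q[i, j] = s * freqs[j]
        Q[j, i] = s * freqs[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(freqs, np.diag(Q)))
    return Q / mu


def transition_probs(exch: np.ndarray, freqs: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) via symmetrization (Q is reversible w.r.t. freqs)."""
    Q = gtr_rate_matrix(exch, freqs)
    d = np.sqrt(np.maximum(freqs, 1e-12))
    S = Q * d[:, None] / d[None, :]
    S = (S + S.T) / 2.0
    lam, U = np.linalg.eigh(S)
    P = (U * np.exp(lam * t)) @ U.T
    P = P / d[:, None] * d[None, :]
    P = np.clip(P, 1e-300, None)
    return P / P.sum(axis=1, keepdims=True)


def _pattern_probs_nh(model: NonStationaryGtrModel) -> np.ndarray:
    P = {b: transition_probs(model.exch[b], model.freqs[b], model.lengths[b])
         for b in BRANCHES}
    return np.einsum(
        "r,ra,am,as,ry->msy",
        model.root_freqs, P["root_ms"], P["ms_mel"], P["ms_sim"], P["root_yak"],
    )


def _pattern_probs_stationary(model: StationaryGtrModel) -> np.ndarray:
    Ps = [transition_probs(model.exch, model.freqs, t) for t in model.lengths]
    return np.einsum("a,am,as,ay->msy", model.freqs, *Ps)


def _loglik(pattern_probs: np.ndarray, counts: np.ndarray) -> float:
    p = np.clip(pattern_probs, 1e-300, None)
    return float(np.sum(counts * np.log(p)))


# --- parameter packing -----------------------------------------------------

def _softmax4(z3: np.ndarray) -> np.ndarray:
    z = np.concatenate([z3, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _pack_freqs(freqs: np.ndarray) -> np.ndarray:
    logf = np.log(np.maximum(freqs, 1e-12))
    return logf[:3] - logf[3]


def _unpack_stationary(z: np.ndarray) -> StationaryGtrModel:
    exch = np.concatenate([np.exp(z[0:5]), [1.0]])
    freqs = _softmax4(z[5:8])
    lengths = np.exp(z[8:11])
    return StationaryGtrModel(exch=exch, freqs=freqs, lengths=lengths)


def _unpack_nh(z: np.ndarray) -> NonStationaryGtrModel:
    root = _softmax4(z[0:3])
    model = NonStationaryGtrModel(root_freqs=root)
    k = 3
    for b in BRANCHES:
        model.exch[b] = np.concatenate([np.exp(z[k:k + 5]), [1.0]])
        model.freqs[b] = _softmax4(z[k + 5:k + 8])
        k += 8
    for b in BRANCHES:
        model.lengths[b] = float(np.exp(z[k]))
        k += 1
    return model


def _empirical_start(c: TripletPatternCounts) -> np.ndarray:
    """Stationary-model start from empirical base frequencies and a rough
    divergence level."""
    counts = c.counts
    freq = np.zeros(4)
    for axis in range(3):
        freq += counts.sum(axis=tuple(a for a in range(3) if a != axis))
    freq /= freq.sum()
    freq = np.maximum(freq, 1e-4)
    total = counts.sum()
    mismatch = 1.0 - sum(counts[i, i, i] for i in range(4)) / max(total, 1.0)
    t0 = max(mismatch / 3.0, 1e-3)
    z = np.zeros(11)
    z[5:8] = _pack_freqs(freq)
    z[8:11] = np.log(t0)
    return z


def fit_stationary_gtr(
    c: TripletPatternCounts,
    restarts: int = 10,
    seed: int = 0,
    min_sites: int = 1000,
) -> ModelFit:
    """ML fit of the stationary star-tree GTR (11 parameters)."""
    if c.total < min_sites:
        raise ValueError(f"need at least {min_sites} sites (got {c.total:g})")
    rng = np.random.default_rng(seed)

    def neg(z):
        return -_loglik(_pattern_probs_stationary(_unpack_stationary(z)), c.counts)

    starts = [_empirical_start(c)]
    for _ in range(max(restarts - 1, 0)):
        starts.append(starts[0] + rng.normal(scale=0.5, size=11))
    best, trace = None, []
    for z0 in starts:
        res = optimize.minimize(neg, z0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12})
        trace.append((-float(res.fun), bool(res.success)))
        if best is None or res.fun < best.fun:
            best = res
    model = _unpack_stationary(best.x)
    return ModelFit(
        model="GTR-stationary",
        params={"exch": model.exch, "freqs": model.freqs, "lengths": model.lengths},
        loglik=-float(best.fun),
        n_params=N_PARAMS_STATIONARY,
        converged=any(ok for _, ok in trace),
        restarts=trace,
        meta={"total_sites": c.total, "x": best.x.tolist()},
    )


def _nh_start_from_stationary(fit: ModelFit) -> np.ndarray:
    """Embed a stationary solution in the nonstationary parameter space
    (same GTR on every branch; the yak branch split in half at the root)."""
    exch, freqs, lengths = fit.params["exch"], fit.params["freqs"], fit.params["lengths"]
    z = np.zeros(N_PARAMS_NH)
    z[0:3] = _pack_freqs(freqs)
    k = 3
    for _ in BRANCHES:
        z[k:k + 5] = np.log(np.maximum(exch[:5], 1e-8))
        z[k + 5:k + 8] = _pack_freqs(freqs)
        k += 8
    half_yak = max(lengths[2] / 2.0, 1e-4)
    z[k:k + 4] = np.log(np.maximum(
        [half_yak, lengths[0], lengths[1], half_yak], 1e-6))
    return z


def fit_nh_gtr(
    c: TripletPatternCounts,
    restarts: int = 10,
    seed: int = 0,
    min_sites: int = 1000,
    stationary_fit: ModelFit | None = None,
) -> ModelFit:
    """ML fit of the branch-nonstationary GTR (39 parameters).

    The first start embeds the stationary solution, which guarantees the
    nonstationary maximized likelihood is at least the stationary one.
    """
    if c.total < min_sites:
        raise ValueError(f"need at least {min_sites} sites (got {c.total:g})")
    rng = np.random.default_rng(seed)
    if stationary_fit is None:
        stationary_fit = fit_stationary_gtr(c, restarts=max(restarts // 2, 1),
                                            seed=seed, min_sites=min_sites)

    def neg(z):
        return -_loglik(_pattern_probs_nh(_unpack_nh(z)), c.counts)

    z_st = _nh_start_from_stationary(stationary_fit)
    starts = [z_st]
    for _ in range(max(restarts - 1, 0)):
        starts.append(z_st + rng.normal(scale=0.4, size=N_PARAMS_NH))
    best, trace = None, []
    for z0 in starts:
        res = optimize.minimize(neg, z0, method="L-BFGS-B",
                                options={"maxiter": 800, "ftol": 1e-12})
        trace.append((-float(res.fun), bool(res.success)))
        if best is None or res.fun < best.fun:
            best = res
    model = _unpack_nh(best.x)
    return ModelFit(
        model="GTR-NHb",
        params={
            "root_freqs": model.root_freqs,
            **{f"exch_{b}": model.exch[b] for b in BRANCHES},
            **{f"freqs_{b}": model.freqs[b] for b in BRANCHES},
            **{f"length_{b}": model.lengths[b] for b in BRANCHES},
        },
        loglik=-float(best.fun),
        n_params=N_PARAMS_NH,
        converged=any(ok for _, ok in trace),
        restarts=trace,
        meta={"total_sites": c.total, "x": best.x.tolist(),
              "stationary_loglik": stationary_fit.loglik},
    )


def nh_model_from_fit(fit: ModelFit) -> NonStationaryGtrModel:
    return _unpack_nh(np.asarray(fit.meta["x"]))


def lrt_nonstationarity(fit_nh: ModelFit, fit_st: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the nonstationary against the stationary
    model: chi2 = 2*delta(logLik), df = 39 - 11 = 28."""
    if fit_nh.meta.get("total_sites") != fit_st.meta.get("total_sites"):
        raise ValueError("fits do not appear to share the same data")
    chi2 = 2.0 * (fit_nh.loglik - fit_st.loglik)
    if chi2 < -1e-6:
        raise RuntimeError(
            "nonstationary fit has lower likelihood than its nested "
            "stationary fit; refit with more restarts")
    chi2 = max(chi2, 0.0)
    df = N_PARAMS_NH - N_PARAMS_STATIONARY
    return chi2, df, float(stats.chi2.sf(chi2, df))


def ancestral_posteriors(
    model: NonStationaryGtrModel | ModelFit,
    method: str = "AWP",
) -> AncestralPosterior:
    """Posterior P(state at ms | pattern) for each of the 64 patterns.

    AWP returns the full vector; SBR the argmax indicator (ties broken in
    A<C<G<T order, which is how numpy's argmax resolves them).
    """
    if isinstance(model, ModelFit):
        model = nh_model_from_fit(model)
    if method not in ("AWP", "SBR"):
        raise ValueError("method must be 'AWP' or 'SBR'")
    P = {b: transition_probs(model.exch[b], model.freqs[b], model.lengths[b])
         for b in BRANCHES}
    # joint[a, m, s, y] = sum_r rho_r P1[r,a] P4[r,y] * P2[a,m] P3[a,s]
    root_part = np.einsum("r,ra,ry->ay", model.root_freqs,
                          P["root_ms"], P["root_yak"])
    joint = np.einsum("ay,am,as->amsy", root_part, P["ms_mel"], P["ms_sim"])
    post = joint / joint.sum(axis=0, keepdims=True)
    post = np.moveaxis(post, 0, -1)  # -> [m, s, y, ancestor]
    if method == "SBR":
        idx = post.argmax(axis=-1)
        post = np.eye(4)[idx]
    return AncestralPosterior(probs=post, method=method)


def parsimony_ancestor(c: TripletPatternCounts | None = None) -> AncestralPosterior:
    """Majority-rule ancestor: the base shared by at least two of
    (mel, sim, yak); patterns with three distinct bases are flagged
    ambiguous and carry a zero vector."""
    probs = np.zeros((4, 4, 4, 4))
    ambiguous = np.zeros((4, 4, 4), dtype=bool)
    for m, s, y in itertools.product(range(4), repeat=3):
        votes = np.bincount([m, s, y], minlength=4)
        if votes.max() >= 2:
            probs[m, s, y, int(np.argmax(votes))] = 1.0
        else:
            ambiguous[m, s, y] = True
    return AncestralPosterior(probs=probs, method="parsimony", ambiguous=ambiguous)
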