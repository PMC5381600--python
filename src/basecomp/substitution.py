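"""W<->S substitution counts, rates, ratios and the chi-squared test battery.

Substitutions along the mel or sim lineage are counted by comparing the
(possibly probabilistic) ancestral state at the *ms* node with the extant
reference base at each site: W->S (ancestral A/T, extant G/C), S->W, and
"neutral" changes within a class (A<->T, G<->C).  Under a posterior-weighted
ancestor (AWP) the counts are expectations; totals are rounded to the
nearest integer once, at the aggregate level.

Test conventions: 2x2 contingency comparisons use Pearson chi-squared with
the Yates continuity correction; 1:1 goodness-of-fit tests use the
uncorrected (n1-n2)^2/(n1+n2); 2xk heterogeneity tests use uncorrected
Pearson with k-1 df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from basecomp.ancestry import AncestralPosterior, TripletPatternCounts

__all__ = [
    "W_INDICES",
    "S_INDICES",
    "SubstitutionCounts",
    "count_substitutions",
    "count_substitutions_patterns",
    "substitution_rates",
    "gof_1to1_chi2",
    "contingency_chi2_yates",
    "heterogeneity_chi2",
    "rpd_ratios",
]

#: base indices (A,C,G,T) in the weak and strong classes
W_INDICES = (0, 3)
S_INDICES = (1, 2)
_CLASS = np.array([0, 1, 1, 0])  # 0 = W, 1 = S, indexed by base


@dataclass
class SubstitutionCounts:
    """Directional substitution counts and ancestral site totals for one
    bin and lineage."""

    nws: float          # W->S substitutions
    nsw: float          # S->W substitutions
    nneu: float         # within-class (S->S, W->W) changes
    lw: float           # ancestral W sites
    ls: float           # ancestral S sites
    lineage: str = ""
    method: str = ""

    @property
    def ratio(self) -> float:
        """N_{W->S} / N_{S->W}."""
        if self.nsw == 0:
            return np.inf if self.nws > 0 else np.nan
        return self.nws / self.nsw


def count_substitutions(
    anc_probs: np.ndarray,
    extant: np.ndarray,
    lineage: str = "",
    method: str = "AWP",
    round_totals: bool | None = None,
) -> SubstitutionCounts:
    """Expected substitution counts from per-site ancestral posteriors.

    Parameters
    ----------
    anc_probs : (n_sites, 4) array
        Posterior probability of each base at the *ms* node.  Rows that sum
        to zero (e.g. parsimony-ambiguous sites) are excluded from both the
        counts and the L totals.
    extant : (n_sites,) integer array
        Extant reference base (0..3) on the lineage of interest.
    round_totals : bool, optional
        Round aggregate counts to the nearest integer.  Defaults to True for
        the AWP method (fractional expectations), False otherwise.
    """
    anc_probs = np.asarray(anc_probs, dtype=float)
    extant = np.asarray(extant)
    if anc_probs.ndim != 2 or anc_probs.shape[1] != 4:
        raise ValueError("anc_probs must have shape (n_sites, 4)")
    if len(extant) != len(anc_probs):
        raise ValueError("length mismatch between ancestors and extant bases")
    if round_totals is None:
        round_totals = method == "AWP"

    keep = anc_probs.sum(axis=1) > 0
    probs = anc_probs[keep]
    ext = extant[keep].astype(int)

    p_w = probs[:, list(W_INDICES)].sum(axis=1)
    p_s = probs[:, list(S_INDICES)].sum(axis=1)
    ext_is_s = _CLASS[ext] == 1
    nws = float(p_w[ext_is_s].sum())
    nsw = float(p_s[~ext_is_s].sum())
    # within-class changes: ancestral base differs from extant but same class
    p_same_class = np.where(ext_is_s, p_s, p_w)
    p_identical = probs[np.arange(len(ext)), ext]
    nneu = float((p_same_class - p_identical).sum())
    lw = float(p_w.sum())
    ls = float(p_s.sum())
    if round_totals:
        nws, nsw, nneu = round(nws), round(nsw), round(nneu)
        lw, ls = round(lw), round(ls)
    return SubstitutionCounts(nws=nws, nsw=nsw, nneu=nneu, lw=lw, ls=ls,
                              lineage=lineage, method=method)


def count_substitutions_patterns(
    anc: AncestralPosterior,
    c: TripletPatternCounts,
    lineage: str,
    round_totals: bool | None = None,
) -> SubstitutionCounts:
    """Aggregate counts from pattern counts instead of per-site arrays.

    ``lineage`` selects which extant reference ("mel" or "sim") the
    ancestral state is compared against.
    """
    if lineage not in ("mel", "sim"):
        raise ValueError("lineage must be 'mel' or 'sim'")
    axis = 0 if lineage == "mel" else 1
    probs = anc.probs.reshape(64, 4)
    weights = c.counts.reshape(64)
    extant = np.indices((4, 4, 4))[axis].reshape(64)
    keep = probs.sum(axis=1) > 0
    p = probs[keep] * weights[keep, None]
    ext = extant[keep]
    p_w = p[:, list(W_INDICES)].sum(axis=1)
    p_s = p[:, list(S_INDICES)].sum(axis=1)
    ext_is_s = _CLASS[ext] == 1
    nws = float(p_w[ext_is_s].sum())
    nsw = float(p_s[~ext_is_s].sum())
    p_same = np.where(ext_is_s, p_s, p_w)
    p_id = p[np.arange(len(ext)), ext]
    nneu = float((p_same - p_id).sum())
    lw, ls = float(p_w.sum()), float(p_s.sum())
    if round_totals is None:
        round_totals = anc.method == "AWP"
    if round_totals:
        nws, nsw, nneu = round(nws), round(nsw), round(nneu)
        lw, ls = round(lw), round(ls)
    return SubstitutionCounts(nws=nws, nsw=nsw, nneu=nneu, lw=lw, ls=ls,
                              lineage=lineage, method=anc.method)


def substitution_rates(s: SubstitutionCounts) -> tuple[float, float]:
    """Per-site rates (r_{W->S}, r_{S->W}) = (N_{W->S}/L_W, N_{S->W}/L_S)."""
    if s.lw <= 0 or s.ls <= 0:
        raise ValueError("ancestral site totals must be positive")
    return s.nws / s.lw, s.nsw / s.ls


def gof_1to1_chi2(n1: float, n2: float) -> tuple[float, float]:
    """Goodness-of-fit of two counts against a 1:1 ratio, without
    continuity correction: chi2 = (n1-n2)^2/(n1+n2), df = 1."""
    if n1 + n2 <= 0:
        raise ValueError("need a positive total count")
    chi2 = (n1 - n2) ** 2 / (n1 + n2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def contingency_chi2_yates(table) -> tuple[float, float]:
    """Yates-corrected Pearson chi-squared on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def heterogeneity_chi2(table) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-squared on a 2xk table (df = k-1).

    All-zero columns are dropped with a warning rather than raising."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2xk table with k >= 2")
    zero = table.sum(axis=0) == 0
    if np.any(zero):
        warnings.warn(f"dropping {int(zero.sum())} all-zero column(s)")
        table = table[:, ~zero]
        if table.shape[1] < 2:
            raise ValueError("fewer than 2 usable columns")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def rpd_ratios(
    poly: dict[str, float],
    div: dict[str, float],
    test: str = "yates",
) -> dict[str, dict]:
    """Polymorphism-to-divergence ratios relative to the neutral class.

    For each selected category (WS, SW) with polymorphism count P and
    divergence count D, reports rpd_neu / rpd_cat together with the p-value
    of the 2x2 (P vs D) x (cat vs neutral) association test (Yates-corrected
    chi-squared by default; ``test="fisher"`` for Fisher's exact test).
    """
    if test not in ("yates", "fisher"):
        raise ValueError("test must be 'yates' or 'fisher'")
    out = {}
    p_neu, d_neu = poly["neu"], div["neu"]
    if d_neu == 0:
        raise ValueError("neutral divergence count is zero")
    rpd_neu = p_neu / d_neu
    for cat in ("WS", "SW"):
        p_cat, d_cat = poly[cat], div[cat]
        if d_cat == 0:
            out[f"neu_vs_{cat}"] = {"ratio": np.nan, "p": np.nan,
                                    "flag": "zero divergence count"}
            continue
        ratio = rpd_neu / (p_cat / d_cat)
        table = np.asarray([[p_neu, d_neu], [p_cat, d_cat]], dtype=float)
        if test == "fisher":
            _, pval = stats.fisher_exact(np.round(table).astype(int))
        else:
            _, pval = contingency_chi2_yates(table)
        out[f"neu_vs_{cat}"] = {"ratio": float(ratio), "p": float(pval)}
    return out
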