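"""Building categorized unfolded SFSs and per-bin frequency summaries.

Segregating sites are polarized against the posterior distribution of the
ancestral base at the *ms* node, restricted to the two observed alleles and
renormalized; each SNP therefore contributes fractionally to a (category,
derived-copy-number) cell.  Categories: W->S (ancestral A/T, derived G/C),
S->W, and neutral (A<->T or G<->C, which leave base composition unchanged).
Monomorphic sites are tallied into the fixed-W / fixed-S classes used by
the reversible-mutation model.

Sites with missing calls are projected down to a common sample size with
the hypergeometric expectation (or dropped, by option), since both
downstream estimators require a single frequency-class dimension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from basecomp.ancestry import AncestralPosterior, BASES
from basecomp.containers import SpectrumSet
from basecomp.popgen import harmonic_number

__all__ = ["build_spectra", "mean_daf", "tajima_d", "tajima_d_per_gene",
           "delta_pi_per_gene"]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_IS_S = {"A": False, "T": False, "C": True, "G": True}


def _site_posterior(anc: AncestralPosterior, row) -> np.ndarray | None:
    try:
        m = _BASE_INDEX[row.ref_focal]
        s = _BASE_INDEX[row.ref_second]
        y = _BASE_INDEX[row.ref_outgroup]
    except KeyError:
        return None
    return anc.probs[m, s, y]


def _category(anc_base: str, derived_base: str) -> str:
    a_s, d_s = _IS_S[anc_base], _IS_S[derived_base]
    if not a_s and d_s:
        return "WS"
    if a_s and not d_s:
        return "SW"
    return "neu"


def build_spectra(
    t: pd.DataFrame,
    anc: AncestralPosterior,
    bins: list | None = None,
    n_target: int | None = None,
    hard_polarity: bool = False,
    drop_missing: bool = False,
) -> dict:
    """Per-bin SpectrumSets from a site table and an ancestral posterior.

    Parameters
    ----------
    t : site table (one row per site with A/C/G/T/N sample allele counts)
    anc : ancestral posterior over the 64 reference patterns
    bins : optional list of GcBin; None builds one spectrum over all sites
    n_target : common sample size; defaults to the minimum number of non-N
        calls over rows (sites with more calls are hypergeometrically
        projected down)
    hard_polarity : assign each SNP entirely to the maximum-posterior
        ancestral allele instead of splitting it fractionally
    drop_missing : drop rows with any N call instead of projecting
    """
    t = t.copy()
    t["n_called"] = t[["A", "C", "G", "T"]].sum(axis=1)
    if drop_missing:
        full = int(t["n_called"].max())
        t = t[t["n_called"] == full]
    if n_target is None:
        n_target = int(t["n_called"].min())
    if n_target < 2:
        raise ValueError("common sample size must be >= 2")
    n = n_target

    groups: dict[str, pd.DataFrame]
    if bins is None:
        groups = {"all": t}
    else:
        groups = {}
        for gcbin in bins:
            members = set(gcbin.gene_ids)
            groups[gcbin.bin_id] = t[t["gene_id"].isin(members)]

    out = {}
    for bin_id, sub in groups.items():
        ws = np.zeros(n - 1)
        sw = np.zeros(n - 1)
        neu = np.zeros(n - 1)
        fixed_w = fixed_s = 0.0
        n_unpolarizable = 0
        for row in sub.itertuples():
            counts = {b: getattr(row, b) for b in "ACGT"}
            alleles = [b for b in "ACGT" if counts[b] > 0]
            m = sum(counts.values())
            if m < n:
                continue
            if len(alleles) == 1:
                base = alleles[0]
                if _IS_S[base]:
                    fixed_s += 1.0
                else:
                    fixed_w += 1.0
                continue
            b1, b2 = alleles
            post = _site_posterior(anc, row)
            if post is None:
                n_unpolarizable += 1
                continue
            p1, p2 = post[_BASE_INDEX[b1]], post[_BASE_INDEX[b2]]
            if p1 + p2 <= 0:
                n_unpolarizable += 1
                continue
            q1 = p1 / (p1 + p2)
            if hard_polarity:
                q1 = 1.0 if q1 >= 0.5 else 0.0
            # orientation 1: ancestral b1, derived b2 (weight q1)
            for anc_b, der_b, der_count, w in (
                (b1, b2, counts[b2], q1),
                (b2, b1, counts[b1], 1.0 - q1),
            ):
                if w == 0.0:
                    continue
                cat = _category(anc_b, der_b)
                vec = {"WS": ws, "SW": sw, "neu": neu}[cat]
                if m == n:
                    proj = {der_count: 1.0}
                else:
                    j = np.arange(0, n + 1)
                    pmf = stats.hypergeom.pmf(j, m, der_count, n)
                    proj = {int(jj): float(p) for jj, p in zip(j, pmf) if p > 0}
                for j, pw in proj.items():
                    if j == 0:
                        if _IS_S[anc_b]:
                            fixed_s += w * pw
                        else:
                            fixed_w += w * pw
                    elif j == n:
                        if _IS_S[der_b]:
                            fixed_s += w * pw
                        else:
                            fixed_w += w * pw
                    else:
                        vec[j - 1] += w * pw
        spec = SpectrumSet(n=n, ws=ws, sw=sw, neu=neu,
                           fixed_w=fixed_w, fixed_s=fixed_s)
        spec.meta = {"n_unpolarizable": n_unpolarizable}
        out[bin_id] = spec
    return out


def mean_daf(s: SpectrumSet, category: str) -> float:
    """Mean derived-allele frequency sum_i (i/n) xi_i / sum_i xi_i."""
    vec = s.spectrum(category)
    total = vec.sum()
    if total <= 0:
        raise ValueError(f"category {category!r} is empty")
    i = np.arange(1, s.n)
    return float(np.sum((i / s.n) * vec) / total)


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = harmonic_number(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajima_d(k: float, S: int, n: int) -> float:
    """Tajima's D from mean pairwise differences k, segregating sites S and
    sample size n (the 1989 variance normalization)."""
    if n < 2:
        raise ValueError("need at least two sequences")
    if S == 0:
        raise ValueError("Tajima's D undefined when S = 0")
    a1 = harmonic_number(n - 1)
    e1, e2 = _tajima_constants(n)
    return float((k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1)))


def _per_gene_summaries(t: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for gid, sub in t.groupby("gene_id"):
        counts = sub[["A", "C", "G", "T"]].to_numpy(dtype=float)
        tot = counts.sum(axis=1)
        ok = tot >= 2
        counts, tot = counts[ok], tot[ok]
        poly = (counts > 0).sum(axis=1) >= 2
        S = int(poly.sum())
        with np.errstate(invalid="ignore"):
            # mean pairwise differences summed over sites
            het = 1.0 - (counts * (counts - 1)).sum(axis=1) / (tot * (tot - 1))
        k = float(het[poly].sum()) if S else 0.0
        n = int(np.round(tot.mean())) if len(tot) else 0
        rows.append({"gene_id": gid, "k": k, "S": S, "n": n})
    return pd.DataFrame(rows)


def tajima_d_per_gene(t: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Tajima's D (NaN where undefined); statistics are computed
    per gene and means over genes are what per-bin reports present."""
    out = _per_gene_summaries(t)
    ds = []
    for row in out.itertuples():
        if row.S == 0 or row.n < 2:
            ds.append(np.nan)
        else:
            ds.append(tajima_d(row.k, row.S, row.n))
    out["tajima_d"] = ds
    return out


def delta_pi_per_gene(t: pd.DataFrame) -> pd.DataFrame:
    """Per-gene diversity-normalized skew (k * a_{n-1} / S) - 1."""
    out = _per_gene_summaries(t)
    vals = []
    for row in out.itertuples():
        if row.S == 0 or row.n < 2:
            vals.append(np.nan)
        else:
            vals.append(row.k * harmonic_number(row.n - 1) / row.S - 1.0)
    out["delta_pi"] = vals
    return out
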