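"""Shared in-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectrumSet", "ModelFit"]

CATEGORIES = ("WS", "SW", "neu")


@dataclass
class SpectrumSet:
    """Three unfolded site-frequency spectra plus optional fixed classes.

    Attributes
    ----------
    n : int
        Haploid sample size; frequency classes are indexed by derived-allele
        copy number 1..n-1.
    ws, sw, neu : ndarray, shape (n-1,)
        Spectra for W->S (ancestral A/T, derived G/C), S->W, and neutral
        (A<->T or G<->C) segregating sites.  Entries may be fractional when
        polarization is probabilistic.
    fixed_w, fixed_s : float
        Monomorphic site counts carrying the W resp. S allele (the "0" and
        "n" classes of the S-allele count spectrum), used by the
        reversible-mutation (long-timescale) model.
    """

    n: int
    ws: np.ndarray
    sw: np.ndarray
    neu: np.ndarray
    fixed_w: float = 0.0
    fixed_s: float = 0.0

    def __post_init__(self) -> None:
        self.ws = np.asarray(self.ws, dtype=float)
        self.sw = np.asarray(self.sw, dtype=float)
        self.neu = np.asarray(self.neu, dtype=float)
        for name in ("ws", "sw", "neu"):
            vec = getattr(self, name)
            if vec.shape != (self.n - 1,):
                raise ValueError(
                    f"{name} spectrum must have length n-1={self.n - 1}, "
                    f"got {vec.shape}"
                )
            if np.any(vec < 0):
                raise ValueError(f"{name} spectrum has negative entries")
        if self.fixed_w < 0 or self.fixed_s < 0:
            raise ValueError("fixed-class counts must be non-negative")

    def spectrum(self, category: str) -> np.ndarray:
        try:
            return {"WS": self.ws, "SW": self.sw, "neu": self.neu}[category]
        except KeyError:
            raise ValueError(f"unknown category {category!r}") from None

    def s_allele_counts(self) -> np.ndarray:
        """Unpolarized spectrum of S-allele counts over classes 0..n.

        A W->S site with i derived copies carries i S alleles; an S->W site
        with i derived copies carries n-i.  Neutral (W<->W, S<->S) sites do
        not alter the W/S composition and are excluded.  Class 0 and n are
        the fixed-W and fixed-S counts.
        """
        out = np.zeros(self.n + 1)
        out[0] = self.fixed_w
        out[self.n] = self.fixed_s
        out[1:self.n] += self.ws
        out[1:self.n] += self.sw[::-1]
        return out

    def total_segregating(self) -> float:
        return float(self.ws.sum() + self.sw.sum() + self.neu.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: category, derived_count, weight (fixed classes
        as derived_count 0 and n under categories fixed_W / fixed_S)."""
        rows = []
        for cat in CATEGORIES:
            vec = self.spectrum(cat)
            for i, w in enumerate(vec, start=1):
                rows.append((cat, i, w))
        rows.append(("fixed_W", 0, self.fixed_w))
        rows.append(("fixed_S", self.n, self.fixed_s))
        return pd.DataFrame(rows, columns=["category", "derived_count", "weight"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n: int | None = None) -> "SpectrumSet":
        if n is None:
            n = int(frame.loc[frame["category"] == "fixed_S", "derived_count"].max())
            if not np.isfinite(n) or n < 2:
                n = int(frame["derived_count"].max()) + 1
        vecs = {cat: np.zeros(n - 1) for cat in CATEGORIES}
        fixed = {"fixed_W": 0.0, "fixed_S": 0.0}
        for _, row in frame.iterrows():
            cat = row["category"]
            if cat in fixed:
                fixed[cat] += float(row["weight"])
            else:
                i = int(row["derived_count"])
                if 1 <= i <= n - 1:
                    vecs[cat][i - 1] += float(row["weight"])
        return cls(n=n, ws=vecs["WS"], sw=vecs["SW"], neu=vecs["neu"],
                   fixed_w=fixed["fixed_W"], fixed_s=fixed["fixed_S"])

    @classmethod
    def from_tsv(cls, path: str | Path, n: int | None = None) -> "SpectrumSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"), n=n)


@dataclass
class ModelFit:
    """Result of a maximum-likelihood model fit.

    ``params`` holds named point estimates, ``loglik`` the maximized
    log-likelihood, ``n_params`` the free-parameter count used for AIC/LRTs,
    ``converged`` whether any restart reported clean convergence, and
    ``restarts`` per-restart (loglik, success) traces.
    """

    model: str
    params: dict
    loglik: float
    n_params: int
    converged: bool = True
    restarts: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: (float(v) if np.isscalar(v) else np.asarray(v).tolist())
                       for k, v in self.params.items()},
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "aic": float(self.aic),
            "converged": bool(self.converged),
        }
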