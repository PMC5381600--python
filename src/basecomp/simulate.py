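"""Synthetic data generators for every pipeline stage.

Everything here is seeded and emits a machine-readable truth record so that
extraction, reconstruction and estimation can be tested against planted
ground truth without any external data:

* toy genomes (FASTA + GFF3) with 4-fold-rich genes and short introns at
  known coordinates;
* three-species site patterns evolved under a (possibly branch-
  nonstationary) GTR model with the true *ms*-node ancestor retained;
* population samples of biallelic W/S sites from a discrete forward
  Wright-Fisher model with reversible mutation, selection and a one-step
  size change;
* Poisson-sampled categorized SFSs around the infinite-sites expectation,
  including polarization-error scenarios;
* origination-fixation substitution histories along a lineage whose
  GC-favoring force was reduced to a fraction p of its ancestral value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from basecomp.ancestry import BASES, NonStationaryGtrModel, BRANCHES, transition_probs
from basecomp.containers import SpectrumSet
from basecomp.glemin import GleminParams, expected_sfs_glemin
from basecomp.popgen import MutationScheme, equilibrium_gc, fixation_rate_pair
from basecomp.zc import ZcParams

__all__ = [
    "SimulationRecipe",
    "make_toy_genome",
    "make_nonstationary_model",
    "simulate_triplet_alignment",
    "simulate_wf_sites",
    "simulate_prf_spectra",
    "simulate_lineage_substitutions",
    "simulate_admixture_spectra",
]

SCENARIOS = (
    "stationary", "gc-shift", "equilibrium-selection", "reduced-selection",
    "expansion", "polarization-error", "admixture-bottleneck",
)


@dataclass
class SimulationRecipe:
    """Named, fully seeded description of one synthetic dataset."""

    seed: int
    scenario: str
    params: dict = field(default_factory=dict)
    sites: int = 10_000
    n: int = 20

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


# ---------------------------------------------------------------------------
# toy genomes

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def make_toy_genome(
    out_dir: str | Path,
    n_genes: int = 10,
    n_samples: int = 6,
    seed: int = 0,
    codons_per_gene: int = 15,
    intron_len: int = 60,
    include_minus: bool = True,
    reference_names: tuple = ("mel", "sim", "yak"),
) -> dict:
    """Write a toy three-species genome bundle and its truth sidecar.

    Each gene is ATG + 4-fold codons + a short intron + 4-fold codons + TAA
    on alternating strands; one gene per bundle gets a long (>= 66 bp)
    intron and one gets a doubly-segregating codon, to exercise the
    exclusion rules.  Returns paths plus a truth record with the planted
    per-gene 4-fold and SI site counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    prefixes = ["GG", "GC", "CC", "CG", "AC", "GT", "CT", "TC"]

    contigs: dict[str, list] = {"2L": [], "X": []}
    offsets = {"2L": 0, "X": 0}
    gff_lines = ["##gff-version 3"]
    sample_names = [f"s{k}" for k in range(n_samples)]
    # per-row contig strings built in parallel
    rows = {name: {"2L": [], "X": []} for name in
            list(reference_names) + sample_names}
    truth = {"genes": {}}

    for gi in range(n_genes):
        chrom = "X" if gi % 4 == 3 else "2L"
        strand = "-" if (include_minus and gi % 3 == 2) else "+"
        this_intron = 70 if gi == 1 else intron_len  # gene 1: intron too long
        k1 = codons_per_gene // 2
        k2 = codons_per_gene - k1

        codons = []
        for _ in range(codons_per_gene):
            codons.append(rng.choice(prefixes) +
                          rng.choice(list("ACGT")))
        part1 = "ATG" + "".join(codons[:k1])
        part2 = "".join(codons[k1:]) + "TAA"
        intron = "".join(rng.choice(list("ACGT"), size=this_intron))
        cassette = part1 + intron + part2

        # species differences: a couple of third-position substitutions
        variants = {name: list(cassette) for name in rows}
        third_positions = [3 + 3 * c + 2 for c in range(k1)] + \
            [len(part1) + this_intron + 3 * c + 2 for c in range(k2)]
        for name in reference_names:
            for pos in rng.choice(third_positions, size=2, replace=False):
                cur = variants[name][pos]
                variants[name][pos] = rng.choice(
                    [b for b in "ACGT" if b != cur])
        # sample polymorphism: two segregating third positions per gene
        seg_sites = rng.choice(third_positions, size=2, replace=False)
        for pos in seg_sites:
            cur = cassette[pos]
            alt = rng.choice([b for b in "ACGT" if b != cur])
            carriers = rng.choice(n_samples, size=max(1, n_samples // 3),
                                  replace=False)
            for ci in carriers:
                variants[sample_names[ci]][pos] = alt
        dropped_fourfold = 0
        if gi == 2 and codons_per_gene >= 2:
            # plant a codon segregating at two positions: excluded downstream
            pos3 = third_positions[0]
            pos1 = pos3 - 2
            alt = "A" if cassette[pos1] != "A" else "G"
            # keep the prefix a 4-fold family for every carrier
            alt = {"G": "C", "C": "G", "A": "G", "T": "C"}[cassette[pos1]]
            variants[sample_names[0]][pos1] = alt
            if pos3 not in seg_sites:
                alt3 = rng.choice([b for b in "ACGT" if b != cassette[pos3]])
                variants[sample_names[0]][pos3] = alt3
            dropped_fourfold = 1

        start = offsets[chrom] + 11  # 10-bp spacer, GFF3 coordinates 1-based
        glen = len(cassette)
        for name in rows:
            piece = "".join(variants[name])
            if strand == "-":
                piece = _revcomp(piece)
            rows[name][chrom].append("T" * 10 + piece)
        offsets[chrom] += 10 + glen

        gid = f"g{gi}"
        end = start + glen - 1
        if strand == "+":
            cds1 = (start, start + len(part1) - 1)
            intr = (start + len(part1), start + len(part1) + this_intron - 1)
            cds2 = (intr[1] + 1, end)
        else:
            # genomic coordinates mirror the coding-strand layout
            cds2 = (start, start + len(part2) - 1)
            intr = (cds2[1] + 1, cds2[1] + this_intron)
            cds1 = (intr[1] + 1, end)
        gff_lines.append(
            f"{chrom}\ttoy\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}")
        for s, e in (cds1, cds2):
            gff_lines.append(
                f"{chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{strand}\t0\tParent={gid}")
        gff_lines.append(
            f"{chrom}\ttoy\tintron\t{intr[0]}\t{intr[1]}\t.\t{strand}\t.\t"
            f"Parent={gid}")

        expected_4fold = codons_per_gene - dropped_fourfold
        truth["genes"][gid] = {
            "chrom": chrom,
            "strand": strand,
            "fourfold_sites": expected_4fold if expected_4fold >= 10 else 0,
            "si_sites": (0 if this_intron >= 66
                         else max(0, min(this_intron, 30) - 8 + 1)),
            "intron_len": this_intron,
        }

    paths = {"annotation": out_dir / "annotation.gff3"}
    paths["annotation"].write_text("\n".join(gff_lines) + "\n")
    genome_paths, sample_paths = {}, {}
    for name in rows:
        fasta = []
        for chrom in ("2L", "X"):
            seq = "".join(rows[name][chrom]) + "T" * 10
            fasta.append(f">{chrom}\n{seq}")
        path = out_dir / f"{name}.fa"
        path.write_text("\n".join(fasta) + "\n")
        if name in reference_names:
            genome_paths[name] = path
        else:
            sample_paths[name] = path
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return {"genomes": genome_paths, "samples": sample_paths,
            "annotation": paths["annotation"], "truth": truth,
            "truth_path": truth_path}


# ---------------------------------------------------------------------------
# three-species patterns

def make_nonstationary_model(
    scenario: str = "stationary",
    branch_length: float = 0.15,
    root_gc: float = 0.6,
    shifted_gc: float = 0.3,
    seed: int = 0,
) -> NonStationaryGtrModel:
    """A simple parameterized model: shared exchangeabilities, GC-symmetric
    frequencies, and (for "gc-shift") AT-shifted target frequencies on both
    post-*ms* branches — the regime in which parallel common->rare changes
    mislead parsimony."""
    rng = np.random.default_rng(seed)
    exch = np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0]) * (1 + 0.1 * rng.random(6))
    exch = exch / exch[-1]

    def freqs(gc):
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    model = NonStationaryGtrModel(root_freqs=freqs(root_gc))
    for b in BRANCHES:
        gc = root_gc
        if scenario == "gc-shift" and b in ("ms_mel", "ms_sim"):
            gc = shifted_gc
        model.exch[b] = exch.copy()
        model.freqs[b] = freqs(gc)
        model.lengths[b] = branch_length
    return model


def simulate_triplet_alignment(
    model: NonStationaryGtrModel, sites: int, seed: int = 0
) -> dict:
    """Evolve ``sites`` independent sites down the rooted tree.

    Returns pattern counts plus the truth: the joint (ancestor, pattern)
    tally ``joint[a, m, s, y]`` and the raw per-site arrays.
    """
    rng = np.random.default_rng(seed)
    P = {b: transition_probs(model.exch[b], model.freqs[b], model.lengths[b])
         for b in BRANCHES}

    def descend(parent: np.ndarray, mat: np.ndarray) -> np.ndarray:
        child = np.empty_like(parent)
        for v in range(4):
            idx = np.nonzero(parent == v)[0]
            if len(idx):
                child[idx] = rng.choice(4, size=len(idx), p=mat[v])
        return child

    root = rng.choice(4, size=sites, p=model.root_freqs)
    ms = descend(root, P["root_ms"])
    mel = descend(ms, P["ms_mel"])
    sim = descend(ms, P["ms_sim"])
    yak = descend(root, P["root_yak"])

    flat = ((ms * 64) + mel * 16 + sim * 4 + yak).astype(int)
    joint = np.bincount(flat, minlength=256).reshape(4, 4, 4, 4)
    counts = joint.sum(axis=0)
    from basecomp.ancestry import TripletPatternCounts
    return {
        "pattern_counts": TripletPatternCounts(counts.astype(float)),
        "joint": joint.astype(float),  # [ancestor, mel, sim, yak]
        "ms_states": ms, "mel": mel, "sim": sim, "yak": yak,
    }


# ---------------------------------------------------------------------------
# forward Wright-Fisher population samples

def simulate_wf_sites(
    p: ZcParams,
    sites: int,
    n: int,
    seed: int = 0,
    N0: int = 500,
    burnin_factor: float = 10.0,
) -> tuple[SpectrumSet, dict]:
    """Forward simulation of independent W/S sites through the size change.

    Discrete Wright-Fisher with 2*N haploid copies: burn-in of
    ``burnin_factor * 2 * N1`` generations at the ancestral size
    N1 = round(g*N0), an instantaneous change to N0, then
    ``round(tau * 2 * N0)`` further generations, and binomial sampling of n
    copies per site.  The returned SpectrumSet stores the S-allele count
    spectrum in its W->S slot (no polarity is defined here) and the fixed
    classes; its ``s_allele_counts`` is the ZC-model input.
    """
    rng = np.random.default_rng(seed)
    N1 = max(int(round(p.g * N0)), 2)

    def step(counts: np.ndarray, M: int, scale: float) -> np.ndarray:
        # per-generation rates at population size M/2 diploid-equivalents,
        # scaled so that theta/gamma retain their N0-based definitions
        x = counts / M
        s_gen = p.gamma / (2.0 * M) * scale
        v_gen = p.theta / (2.0 * M) * scale
        u_gen = p.kappa * p.theta / (2.0 * M) * scale
        psi = x + s_gen * x * (1 - x) + v_gen * (1 - x) - u_gen * x
        np.clip(psi, 0.0, 1.0, out=psi)
        return rng.binomial(M, psi)

    # ancestral epoch: size N1, locally scaled parameters are g*(gamma, theta)
    M1 = 2 * N1
    # start every site fixed, at the Li-Bulmer boundary composition for the
    # locally scaled force g*gamma: the burn-in then only has to establish
    # the polymorphic interior (a fast, O(N)-generation process), not the
    # W/S composition itself, which relaxes on the much slower
    # substitution timescale
    q0 = equilibrium_gc(MutationScheme(u=p.kappa, v=1.0), p.g * p.gamma)
    counts = M1 * rng.binomial(1, q0, size=sites)
    scale1 = N1 / N0  # converts 4*N0-scaled params to the local size
    for _ in range(int(round(burnin_factor * 2 * N1))):
        counts = step(counts, M1, scale1)
    # instantaneous change to N0
    M0 = 2 * N0
    counts = rng.binomial(M0, counts / M1)
    for _ in range(int(round(p.tau * 2 * N0))):
        counts = step(counts, M0, 1.0)

    sample = rng.binomial(n, counts / M0)
    hist = np.bincount(sample, minlength=n + 1).astype(float)
    spec = SpectrumSet(n=n, ws=hist[1:n], sw=np.zeros(n - 1),
                       neu=np.zeros(n - 1), fixed_w=hist[0], fixed_s=hist[n])
    truth = {
        "params": {"gamma": p.gamma, "theta": p.theta, "kappa": p.kappa,
                   "g": p.g, "tau": p.tau},
        "N0": N0, "N1": N1, "sites": sites, "n": n, "seed": seed,
        "final_gc": float(np.mean(counts / M0)),
    }
    return spec, truth


# ---------------------------------------------------------------------------
# Poisson-field spectra

def simulate_prf_spectra(
    p: GleminParams, seed: int = 0
) -> tuple[SpectrumSet, dict]:
    """Independent Poisson draws around the infinite-sites expectations
    (including any polarization-error mixing encoded in ``p``)."""
    rng = np.random.default_rng(seed)
    means = expected_sfs_glemin(p)
    draws = {cat: rng.poisson(mu).astype(float) for cat, mu in means.items()}
    spec = SpectrumSet(n=p.n, ws=draws["WS"], sw=draws["SW"], neu=draws["neu"])
    truth = {"params": {"gamma": p.gamma, "theta_ws": p.theta_ws,
                        "theta_sw": p.theta_sw, "theta_neu": p.theta_neu,
                        "e_sel": p.e_sel, "e_neu": p.e_neu,
                        "variant": p.variant},
             "seed": seed}
    return spec, truth


# ---------------------------------------------------------------------------
# lineage substitution histories

def simulate_lineage_substitutions(
    m: MutationScheme,
    gamma: float,
    p_retained: float,
    sites: int,
    time: float,
    seed: int = 0,
) -> dict:
    """Origination-fixation history under a reduced GC-favoring force.

    Ancestral states are drawn at the equilibrium GC content for
    (kappa, gamma); the lineage then evolves as a two-state Markov chain
    whose transition rates are the fixation rates under the reduced force
    p_retained * gamma.  Returns W->S / S->W counts from comparing ancestor
    to the extant state, mirroring how the pipeline counts substitutions.
    """
    rng = np.random.default_rng(seed)
    q = equilibrium_gc(m, gamma)
    anc_is_s = rng.random(sites) < q
    r_sw, r_ws = fixation_rate_pair(m, p_retained * gamma)
    lam = r_sw + r_ws
    # exact 2-state CTMC transition probabilities over `time`
    p_ws = (r_ws / lam) * (1.0 - np.exp(-lam * time))  # W -> S
    p_sw = (r_sw / lam) * (1.0 - np.exp(-lam * time))  # S -> W
    u = rng.random(sites)
    ext_is_s = np.where(anc_is_s, u >= p_sw, u < p_ws)
    nws = int(np.sum(~anc_is_s & ext_is_s))
    nsw = int(np.sum(anc_is_s & ~ext_is_s))
    return {
        "nws": nws, "nsw": nsw,
        "lw": int(np.sum(~anc_is_s)), "ls": int(np.sum(anc_is_s)),
        "anc_is_s": anc_is_s, "ext_is_s": ext_is_s,
        "truth": {"gamma": gamma, "p": p_retained, "kappa": m.kappa,
                  "q": q, "time": time, "seed": seed},
    }


# ---------------------------------------------------------------------------
# admixture-bottleneck testbed (qualitative)

def simulate_admixture_spectra(
    p_low: ZcParams,
    p_high: ZcParams,
    n: int,
    sites: int,
    admixture: float = 0.2,
    growth_skew: float = 1.5,
    seed: int = 0,
) -> tuple[SpectrumSet, dict]:
    """Qualitative testbed: a two-deme mixture of equilibrium spectra with a
    growth-like excess of singletons.

    This is *not* a calibrated demographic model — it exists to reproduce,
    qualitatively, the artifacts expected when a bottlenecked population
    receives migrants and then grows (distorted low-frequency classes).
    """
    from basecomp.zc import stationary_sample_probs
    rng = np.random.default_rng(seed)
    probs = ((1 - admixture) * stationary_sample_probs(p_low, n)
             + admixture * stationary_sample_probs(p_high, n))
    skew = np.ones(n + 1)
    skew[1:n] *= growth_skew ** (1.0 - np.arange(1, n) / n)
    probs = probs * skew
    probs /= probs.sum()
    hist = rng.multinomial(sites, probs).astype(float)
    spec = SpectrumSet(n=n, ws=hist[1:n], sw=np.zeros(n - 1),
                       neu=np.zeros(n - 1), fixed_w=hist[0], fixed_s=hist[n])
    return spec, {"qualitative": True, "admixture": admixture,
                  "growth_skew": growth_skew, "seed": seed}
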