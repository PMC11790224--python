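"""Premating-isolation and genetic-differentiation statistics.

Two summary statistics quantify progress toward allochronic speciation:

rMF — the Pearson correlation of chronotype (expressed adult timing)
    between the partners of all realised matings of a census generation.
    Strong assortative mating by timing drives rMF toward one.

FST — differentiation at the 20 neutral marker loci between the early and
    late chronotype sub-populations, obtained by 2-means clustering of
    juvenile timing.  The default estimator is Hudson's, computed as a
    ratio of averages over loci (numerator and denominator summed across
    loci before dividing), with Weir & Cockerham's theta available as an
    alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "CensusRecord",
    "mate_correlation",
    "classify_chronotypes",
    "fst_neutral",
    "summarize_phenotypes",
    "census",
]

N_HIST_BINS = 50


@dataclass
class CensusRecord:
    """Per-generation summary of the metapopulation."""

    generation: int
    n: int
    n_matings: int
    r_mf: float  # NaN when undefined (<2 matings or zero variance)
    f_st: float  # NaN when undefined (single cluster or monomorphic panel)
    cluster_centers: tuple  # (early, late) mean juvenile timing
    cluster_sizes: tuple
    mean_tau_juv: float
    var_tau_juv: float
    mean_tau_f: float
    mean_tau_m: float
    extras: dict = field(default_factory=dict)


def mate_correlation(pairs) -> float:
    """Pearson correlation rMF of chronotype across mating pairs.

    ``pairs`` is a sequence of (female_tau, male_tau).  Returns NaN when
    fewer than two pairs exist or either sex shows zero variance.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        return float("nan")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def classify_chronotypes(values, seed: int = 0):
    """Split individuals into early/late chronotypes by 1-D 2-means.

    Returns ``(labels, centers)`` with label 0 = early (smaller center) and
    centers sorted ascending.  If all values coincide, every individual is
    labelled 0 and both centers equal that value (the single-cluster case;
    FST is undefined downstream).
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 individuals to classify")
    if np.ptp(x) == 0.0:
        return np.zeros(x.shape[0], dtype=int), (float(x[0, 0]), float(x[0, 0]))
    km = KMeans(n_clusters=2, n_init=10, max_iter=100, random_state=seed)
    raw = km.fit_predict(x)
    centers = km.cluster_centers_.ravel()
    early = int(np.argmin(centers))
    labels = (raw != early).astype(int)
    return labels, (float(centers.min()), float(centers.max()))


def _allele_freqs(neutral_stack: np.ndarray) -> tuple[np.ndarray, int]:
    """Frequency of allele 1 per locus, and the allele sample size."""
    n = 2 * neutral_stack.shape[0]
    return neutral_stack.sum(axis=(0, 2)) / n, n


def fst_neutral(population, labels, estimator: str = "hudson") -> float:
    """Multi-locus FST at the neutral panel between two labelled groups.

    ``population`` is a sequence of individuals (or genomes) and ``labels``
    a 0/1 array.  Hudson's estimator (default) is the ratio of the
    locus-summed between-minus-within heterozygosity to the locus-summed
    between-group heterozygosity; ``estimator="wc"`` gives Weir &
    Cockerham's theta.  Returns NaN if either group is empty or the panel
    is monomorphic across both groups; the estimate is clipped to [0, 1].
    """
    labels = np.asarray(labels)
    genomes = [getattr(i, "genome", i) for i in population]
    stack = np.stack([g.neutral for g in genomes])
    g1, g2 = stack[labels == 0], stack[labels == 1]
    if g1.shape[0] == 0 or g2.shape[0] == 0:
        return float("nan")
    p1, n1 = _allele_freqs(g1)
    p2, n2 = _allele_freqs(g2)
    pooled = (n1 * p1 + n2 * p2) / (n1 + n2)
    if np.all((pooled == 0.0) | (pooled == 1.0)):
        return float("nan")  # panel monomorphic across both groups
    if estimator == "hudson":
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if den.sum() <= 0.0:
            return float("nan")
        return float(np.clip(num.sum() / den.sum(), 0.0, 1.0))
    if estimator == "wc":
        return _fst_weir_cockerham(p1, n1 // 2, p2, n2 // 2)
    raise ValueError(f"unknown FST estimator {estimator!r}")


def _fst_weir_cockerham(p1, n1, p2, n2) -> float:
    """Weir & Cockerham theta for two populations, haplotype-level variant.

    Computed from allele frequencies only (no inbreeding/heterozygote
    bookkeeping), summing variance components across loci.
    """
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2) / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (p_bar * (1 - p_bar) - (r - 1.0) / r * s2)
    den = (a + b).sum()
    if den <= 0.0:
        return float("nan")
    return float(np.clip(a.sum() / den, 0.0, 1.0))


def summarize_phenotypes(population, labels=None) -> dict:
    """Histograms (50 bins on [0, 1]) and moments of the timing phenotypes.

    Returns a dict with pooled (and, when ``labels`` is given, per-cluster)
    histograms/means/variances of juvenile, female-adult, and male-adult
    timing.  Adult histograms are restricted to individuals of that sex.
    """
    pop = list(population)
    if not pop:
        raise ValueError("population must be nonempty")
    edges = np.linspace(0.0, 1.0, N_HIST_BINS + 1)
    tau_juv = np.array([i.tau_juv for i in pop])
    sex = np.array([i.sex for i in pop])
    tau_ad = np.array([i.tau_adult for i in pop])

    def block(mask):
        tj = tau_juv[mask]
        tf = tau_ad[mask & (sex == 0)]
        tm = tau_ad[mask & (sex == 1)]
        return {
            "hist_tau_juv": np.histogram(tj, bins=edges)[0],
            "hist_tau_f": np.histogram(tf, bins=edges)[0],
            "hist_tau_m": np.histogram(tm, bins=edges)[0],
            "mean_tau_juv": float(tj.mean()) if tj.size else float("nan"),
            "var_tau_juv": float(tj.var()) if tj.size else float("nan"),
            "mean_tau_f": float(tf.mean()) if tf.size else float("nan"),
            "mean_tau_m": float(tm.mean()) if tm.size else float("nan"),
        }

    out = {"pooled": block(np.ones(len(pop), dtype=bool)), "bin_edges": edges}
    if labels is not None:
        labels = np.asarray(labels)
        out["early"] = block(labels == 0)
        out["late"] = block(labels == 1)
    return out


def census(generation: int, population, mating_records, seed: int = 0,
           rmf_chronotype: str = "expressed",
           cluster_chronotype: str = "juvenile") -> CensusRecord:
    """Full per-generation census: phenotypes, rMF, chronotype clusters, FST.

    By default rMF uses the expressed adult timing of this generation's
    mating partners and clustering uses juvenile timing (the sex-free
    population trait); either statistic can instead be computed on the
    other chronotype (``"expressed"`` or ``"juvenile"``).  FST compares
    the neutral panels of the two chronotype clusters.
    """
    if rmf_chronotype not in ("expressed", "juvenile") \
            or cluster_chronotype not in ("expressed", "juvenile"):
        raise ValueError("chronotype options must be 'expressed' or 'juvenile'")
    pop = list(population)
    att = "tau_adult" if rmf_chronotype == "expressed" else "tau_juv"
    pairs = [(getattr(r.female, att), getattr(r.sire, att))
             for r in mating_records if r.sire is not None]
    r_mf = mate_correlation(pairs) if pairs else float("nan")
    tau_juv = np.array([i.tau_juv for i in pop])
    cluster_values = (tau_juv if cluster_chronotype == "juvenile"
                      else np.array([i.tau_adult for i in pop]))
    labels, centers = classify_chronotypes(cluster_values, seed=seed)
    sizes = (int(np.sum(labels == 0)), int(np.sum(labels == 1)))
    f_st = fst_neutral(pop, labels) if min(sizes) > 0 else float("nan")
    summ = summarize_phenotypes(pop, labels)
    return CensusRecord(
        generation=generation,
        n=len(pop),
        n_matings=len(pairs),
        r_mf=r_mf,
        f_st=f_st,
        cluster_centers=centers,
        cluster_sizes=sizes,
        mean_tau_juv=float(tau_juv.mean()),
        var_tau_juv=float(tau_juv.var()),
        mean_tau_f=summ["pooled"]["mean_tau_f"],
        mean_tau_m=summ["pooled"]["mean_tau_m"],
        extras={"late_mean_tau_f": summ["late"]["mean_tau_f"],
                "late_mean_tau_m": summ["late"]["mean_tau_m"],
                "early_mean_tau_f": summ["early"]["mean_tau_f"],
                "early_mean_tau_m": summ["early"]["mean_tau_m"]},
    )
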