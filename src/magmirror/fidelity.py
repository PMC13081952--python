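"""Simulation-fidelity metrics and MinHash machinery for context selection.

How closely does a simulated sample mirror its original? Shannon alpha
diversity per profile, Bray-Curtis beta diversity between profiles, and an
ordinary least-squares regression of simulated-pair beta diversity on
original-pair beta diversity (slope near 1 and R^2 near 1 indicate that
population-level community structure is preserved).

The MinHash bottom-sketch / Mash-distance machinery here supports the
partial multi-sample binning mode, which bins a target sample in the
context of its D nearest samples by Mash distance (D = 20 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from scipy.spatial.distance import braycurtis

from ._kmers import canonical_kmers, hash_kmer


def _as_vectors(p: Mapping[str, float], q: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    taxa = sorted(set(p) | set(q))
    return (
        np.array([p.get(t, 0.0) for t in taxa]),
        np.array([q.get(t, 0.0) for t in taxa]),
    )


def shannon_alpha(profile: Mapping[str, float]) -> float:
    """Shannon diversity -sum p_i ln p_i over nonzero taxa, renormalized."""
    vals = np.array([v for v in profile.values() if v > 0], dtype=float)
    if vals.size == 0:
        raise ValueError("empty profile")
    p = vals / vals.sum()
    return float(-(p * np.log(p)).sum())


def bray_curtis(p: Mapping[str, float], q: Mapping[str, float]) -> float:
    """Bray-Curtis dissimilarity sum|p_i - q_i| / sum(p_i + q_i) over the
    shared taxon universe (missing taxa count as zero)."""
    u, v = _as_vectors(p, q)
    if u.sum() == 0 and v.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return float(braycurtis(u, v))


def paired_beta_regression(
    orig_pairwise: Iterable[float], sim_pairwise: Iterable[float]
) -> tuple[float, float, float]:
    """OLS of simulated-pair distances on original-pair distances.

    Returns (slope, intercept, r_squared). Pairs must be aligned
    pair-for-pair; requires >= 3 pairs and nonzero variance in the
    originals."""
    x = np.asarray(list(orig_pairwise), dtype=float)
    y = np.asarray(list(sim_pairwise), dtype=float)
    if x.size != y.size:
        raise ValueError("pairwise vectors must be aligned")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0:
        raise ValueError("zero variance in original distances")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


@dataclass(frozen=True)
class MinHashSketch:
    """Bottom-s sketch: the s smallest 64-bit canonical k-mer hashes."""

    k: int
    s: int
    hash_seed: int
    hashes: tuple[int, ...]  # sorted ascending


def minhash_sketch(
    sequences: Iterable[str], k: int = 21, s: int = 1000, hash_seed: int = 0
) -> MinHashSketch:
    """Sketch a sequence set (e.g. all reads of a sample) into its bottom-s
    canonical k-mer hashes."""
    hashes: set[int] = set()
    for seq in sequences:
        for kmer in canonical_kmers(seq, k):
            hashes.add(hash_kmer(kmer, hash_seed))
    bottom = sorted(hashes)[:s]
    return MinHashSketch(k=k, s=s, hash_seed=hash_seed, hashes=tuple(bottom))


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> float:
    """Mash distance from the merged bottom-sketch Jaccard estimate.

    j = |X ∩ A ∩ B| / |X| with X the bottom-s of the hash union;
    d = -ln(2j/(1+j)) / k; j = 0 reports the sentinel distance 1."""
    if a.k != b.k or a.hash_seed != b.hash_seed:
        raise ValueError("sketches built with different k or hash seed")
    s = min(a.s, b.s)
    sa, sb = set(a.hashes), set(b.hashes)
    merged = sorted(sa | sb)[:s]
    if not merged:
        return 1.0
    shared = sum(1 for h in merged if h in sa and h in sb)
    j = shared / len(merged)
    if j == 0.0:
        return 1.0
    return max(0.0, -math.log(2.0 * j / (1.0 + j)) / a.k)


@dataclass
class ContextSelection:
    sample_ids: list[str]
    warning: str | None = None


def select_partial_context(
    target_sample: str,
    sketches: Mapping[str, MinHashSketch],
    D: int = 20,
) -> ContextSelection:
    """The D non-target samples nearest to the target by Mash distance
    (ties by sample_id). If fewer than D others exist, all are returned
    with a warning."""
    if target_sample not in sketches:
        raise KeyError(f"no sketch for target sample {target_sample!r}")
    others = [s for s in sketches if s != target_sample]
    ranked = sorted(
        others, key=lambda s: (mash_distance(sketches[target_sample], sketches[s]), s)
    )
    if len(others) < D:
        return ContextSelection(
            sample_ids=ranked,
            warning=f"only {len(others)} context samples available (D={D})",
        )
    return ContextSelection(sample_ids=ranked[:D])
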