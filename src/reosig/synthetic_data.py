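"""Synthetic two-class expression data with controllable ordering structure.

The generator emulates the statistical skeleton the ordering pipeline feeds
on, without modelling microarray physics:

* per-gene baseline means on a log-like scale, shared by both classes, so
  most gene pairs have stable within-sample orderings in both classes;
* a planted set of disjoint reversed pairs whose two genes' means are
  swapped between the classes, separated by a margin large enough that the
  within-class ordering holds in at least a target fraction of samples; each
  planted pair owns an exclusive mean window that no background gene enters,
  so swapping the pair's means reverses exactly that pair and nothing else
  (a background gene with a mean between the swapped values would otherwise
  reverse against both planted genes as a side effect);
* iid additive Gaussian noise per entry and an optional additive per-dataset
  batch shift (which, being monotone, never changes orderings);
* "metastasis-like" samples drawn from the class-1 model in which a tunable
  fraction of the planted pairs is flipped toward the class-2 ordering by
  swapping the two genes' values.

The ordering margin for a planted pair is max(m_stab, m_gap) where
``m_stab = sqrt(2) * noise_sd * Phi^-1(stability)`` makes the per-sample
ordering hold with probability ``stability`` under Gaussian noise (the
difference of the two genes' values is N(margin, 2*noise_sd^2)), and
``m_gap`` converts ``rank_gap`` (a target rank separation) into mean units
through the baseline density ``n_genes / (base_high - base_low)``.

Everything is a deterministic function of the config, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "generate_two_class",
    "generate_metastasis",
    "apply_monotone_distortion",
]

DISTORTION_KINDS = ("exp", "affine_positive", "rank_preserving_spline")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-class ordering simulation.

    Defaults describe a desk-scale study: 500 genes, 50 samples per class,
    20 metastasis-like samples, 5 planted reversed pairs whose mean
    separation (rank_gap of 60 baseline-density rank units, i.e. ~1 unit on
    the log2-like scale against noise_sd 0.2) makes their orderings
    essentially deterministic within each class, and one of the five planted
    orderings flipped per metastasis sample (admixture 0.2).
    """

    n_genes: int = 500
    n_class1: int = 50
    n_class2: int = 50
    n_metastasis: int = 20
    n_reversed: int = 5
    stability: float = 0.97
    rank_gap: float = 60.0
    noise_sd: float = 0.2
    batch_shift: float = 0.0
    metastasis_admixture: float = 0.2
    seed: int = 0
    base_low: float = 4.0
    base_high: float = 12.0

    def __post_init__(self):
        if self.n_genes < 2 or self.n_reversed < 0:
            raise ValueError("need n_genes >= 2 and n_reversed >= 0")
        if 2 * self.n_reversed > self.n_genes:
            raise ValueError("planted pairs need 2*n_reversed <= n_genes distinct genes")
        if not (0.5 < self.stability <= 1.0):
            raise ValueError("stability must lie in (0.5, 1.0]")
        if not (0.0 <= self.metastasis_admixture <= 1.0):
            raise ValueError("metastasis_admixture must lie in [0, 1]")
        for name in ("n_class1", "n_class2", "n_metastasis"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0 or self.rank_gap < 0:
            raise ValueError("noise_sd and rank_gap must be non-negative")
        if not self.base_high > self.base_low:
            raise ValueError("base_high must exceed base_low")


def _planted_margin(cfg: SimulationConfig) -> float:
    span = cfg.base_high - cfg.base_low
    m_stab = 0.0
    if cfg.noise_sd > 0 and cfg.stability < 1.0:
        m_stab = float(np.sqrt(2.0) * cfg.noise_sd * stats.norm.ppf(cfg.stability))
    # target separation in rank units, converted through the baseline density;
    # capped so the exclusive windows always pack into the baseline range
    m_gap = cfg.rank_gap * span / cfg.n_genes
    if cfg.n_reversed:
        m_gap = min(m_gap, 0.9 * span / cfg.n_reversed)
    # a strictly positive margin keeps the noiseless limit unambiguous
    return max(m_stab, m_gap, 1e-6 * span)


def _sample_outside_windows(rng, n, low, high, windows):
    """Draw n points uniformly from [low, high] minus the given intervals."""
    edges = [low]
    for a, b in sorted(windows):
        edges.extend((a, b))
    edges.append(high)
    segments = [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)]
    lengths = np.array([b - a for a, b in segments])
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    u = rng.uniform(0.0, cum[-1], size=n)
    seg = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(segments) - 1)
    return np.array([segments[s][0] + (u_ - cum[s]) for s, u_ in zip(seg, u)])


def _class_means(cfg: SimulationConfig):
    """Baseline means, planted pairs, and the two class mean vectors.

    Planted pair p sits in an exclusive window of width ``margin`` centred at
    evenly spaced positions; background means are drawn uniformly from the
    complement, so swapping a pair's means between the classes reverses that
    pair's ordering and no other.  Drawn from a dedicated seeded stream so
    the metastasis generator can reconstruct the identical class-1 model
    without replaying the class noise draws.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    genes = np.array([f"g{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    idx = rng.choice(cfg.n_genes, size=2 * cfg.n_reversed, replace=False)

    span = cfg.base_high - cfg.base_low
    margin = _planted_margin(cfg)
    windows = []
    if cfg.n_reversed:
        if margin >= span / cfg.n_reversed:
            raise ValueError(
                "planted mean windows do not fit: reduce rank_gap/noise_sd or n_reversed, "
                "or widen the baseline range"
            )
        centers = cfg.base_low + (np.arange(cfg.n_reversed) + 0.5) * span / cfg.n_reversed
        windows = [(c - margin / 2.0, c + margin / 2.0) for c in centers]

    means1 = np.empty(cfg.n_genes)
    background = np.setdiff1d(np.arange(cfg.n_genes), idx)
    means1[background] = _sample_outside_windows(
        rng, background.size, cfg.base_low, cfg.base_high, windows
    )
    means2 = means1.copy()
    planted = []
    for p, (wlo, whi) in enumerate(windows):
        hi, lo = idx[2 * p], idx[2 * p + 1]
        means1[hi], means1[lo] = whi, wlo
        means2[hi], means2[lo] = wlo, whi
        planted.append((genes[hi], genes[lo]))
    return genes, means1, means2, frozenset(planted)


def generate_two_class(cfg: SimulationConfig):
    """Draw the two class matrices and return the planted reversed pairs.

    Returns ``(class1, class2, planted)`` with ``planted`` in the class-1
    direction (high, low).  The class-2 matrix carries the additive
    ``batch_shift``.  Two calls with equal configs produce identical output.
    """
    genes, means1, means2, planted = _class_means(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    x1 = means1[:, None] + cfg.noise_sd * rng.standard_normal((cfg.n_genes, cfg.n_class1))
    x2 = (
        means2[:, None]
        + cfg.noise_sd * rng.standard_normal((cfg.n_genes, cfg.n_class2))
        + cfg.batch_shift
    )
    m1 = ExpressionMatrix(
        pd.DataFrame(x1, index=genes, columns=[f"c1_s{i:03d}" for i in range(cfg.n_class1)])
    )
    m2 = ExpressionMatrix(
        pd.DataFrame(x2, index=genes, columns=[f"c2_s{i:03d}" for i in range(cfg.n_class2)])
    )
    return m1, m2, planted


def generate_metastasis(cfg: SimulationConfig, planted) -> ExpressionMatrix:
    """Class-1-like samples with a fraction of planted orderings flipped.

    Each sample starts from the class-1 model; then
    ``round(metastasis_admixture * n_planted)`` randomly chosen planted pairs
    have their two genes' values swapped, cleanly reversing those orderings
    toward class 2 while leaving every other pair untouched.
    """
    planted = sorted(tuple(p) for p in planted)
    if not planted:
        raise ValueError("planted pair set is empty")
    genes, means1, _, _ = _class_means(cfg)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng([cfg.seed, 2])
    x = means1[:, None] + cfg.noise_sd * rng.standard_normal((cfg.n_genes, cfg.n_metastasis))
    n_flip = int(round(cfg.metastasis_admixture * len(planted)))
    for s in range(cfg.n_metastasis):
        which = rng.choice(len(planted), size=n_flip, replace=False)
        for w in which:
            hi, lo = planted[w]
            i, j = gene_pos[hi], gene_pos[lo]
            x[i, s], x[j, s] = x[j, s], x[i, s]
    return ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=[f"met_s{i:03d}" for i in range(cfg.n_metastasis)])
    )


def apply_monotone_distortion(m: ExpressionMatrix, kind: str, seed: int = 0) -> ExpressionMatrix:
    """Apply a per-sample strictly increasing transform.

    ``exp`` exponentiates (log → linear scale); ``affine_positive`` applies a
    random positive-slope affine map per sample (a gain/offset batch effect);
    ``rank_preserving_spline`` pushes each sample through a random strictly
    increasing piecewise-linear curve.  Within-sample orderings are preserved
    exactly in every case.
    """
    if kind not in DISTORTION_KINDS:
        raise ValueError(f"unknown or non-monotone distortion kind {kind!r}; choose from {DISTORTION_KINDS}")
    rng = np.random.default_rng([seed, 3])
    x = m.values.copy()
    if kind == "exp":
        out = np.exp(x / 4.0)
    elif kind == "affine_positive":
        slope = rng.uniform(0.5, 3.0, x.shape[1])
        offset = rng.uniform(-10.0, 10.0, x.shape[1])
        out = x * slope[None, :] + offset[None, :]
    else:
        out = np.empty_like(x)
        for s in range(x.shape[1]):
            col = x[:, s]
            lo, hi = col.min(), col.max()
            span = hi - lo if hi > lo else 1.0
            knots = np.linspace(lo - 0.01 * span, hi + 0.01 * span, 9)
            ys = np.cumsum(rng.uniform(0.1, 1.0, knots.size))
            out[:, s] = np.interp(col, knots, ys)
    return ExpressionMatrix(pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids))
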