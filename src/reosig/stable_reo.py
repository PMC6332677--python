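"""Detection of stable within-sample gene-pair orderings.

A gene pair (A, B) is a *stable* ordered pair in a dataset when A's value
strictly exceeds B's in more than a threshold fraction of samples (default
0.95, strict "more than": support exactly equal to the threshold fails).
Expression ties count as "not higher" for both directions, so a tie can never
create reciprocal stability.

Pair sets that agree, direction included, across every dataset of a tumour
class are that class's *characteristic* stable pairs.

For G genes there are G(G-1)/2 unordered pairs; the scan is blocked over gene
chunks under a memory ceiling so large matrices never materialize the full
pair tensor, and the blocked result is bit-identical to the naive all-pairs
double loop.
"""

from __future__ import annotations

from collections.abc import Sequence
from functools import reduce

import numpy as np

from .core_io import DirectedPairSet, ExpressionMatrix

__all__ = ["detect_stable_pairs", "characteristic_pairs"]


def detect_stable_pairs(
    m: ExpressionMatrix,
    threshold: float = 0.95,
    *,
    max_block_bytes: int = 64_000_000,
    keep_support: bool = False,
) -> DirectedPairSet:
    """Find all ordered pairs (A, B) with support(A > B) strictly above ``threshold``.

    Parameters
    ----------
    m
        Expression matrix (any monotone scale).
    threshold
        Stability cutoff in (0.5, 1.0]; the comparison is strict, so with 20
        samples a pair holding in exactly 19 (support 0.95) is *not* stable at
        the default 0.95.
    max_block_bytes
        Approximate ceiling on the boolean comparison workspace; the gene
        axis is chunked so a block never exceeds it.
    keep_support
        Attach the per-pair support fraction to the result (costs memory for
        large outputs).
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1.0]")
    X = m.values
    genes = np.asarray(m.gene_ids, dtype=object)
    n_genes, n_samples = X.shape

    block = max(1, int(np.sqrt(max(1, max_block_bytes) / max(1, n_samples))))
    pairs: list = []
    support: dict = {}

    for i0 in range(0, n_genes, block):
        Xi = X[i0 : i0 + block]
        for j0 in range(i0, n_genes, block):
            Xj = X[j0 : j0 + block]
            gt = (Xi[:, None, :] > Xj[None, :, :]).sum(axis=2)
            lt = (Xi[:, None, :] < Xj[None, :, :]).sum(axis=2)
            if i0 == j0:
                ii, jj = np.triu_indices(Xi.shape[0], k=1)
                if Xi.shape[0] != Xj.shape[0]:  # pragma: no cover - same block
                    raise AssertionError
            else:
                ii, jj = np.indices((Xi.shape[0], Xj.shape[0]))
                ii, jj = ii.ravel(), jj.ravel()
            cg = gt[ii, jj]
            cl = lt[ii, jj]
            hi = cg / n_samples > threshold
            lo = cl / n_samples > threshold
            for a, b, c in zip(ii[hi], jj[hi], cg[hi]):
                pair = (genes[i0 + a], genes[j0 + b])
                pairs.append(pair)
                if keep_support:
                    support[pair] = c / n_samples
            for a, b, c in zip(ii[lo], jj[lo], cl[lo]):
                pair = (genes[j0 + b], genes[i0 + a])
                pairs.append(pair)
                if keep_support:
                    support[pair] = c / n_samples

    return DirectedPairSet(
        frozenset(pairs),
        threshold=threshold,
        n_samples=n_samples,
        support=support if keep_support else None,
    )


def characteristic_pairs(sets: Sequence[DirectedPairSet]) -> DirectedPairSet:
    """Ordered pairs present with the *same* direction in every input set.

    Because pairs are stored as directed tuples, plain set intersection
    already enforces direction agreement: a pair stable one way in one
    dataset and the other way in another contributes nothing.
    """
    if len(sets) < 2:
        raise ValueError("need at least two pair sets")
    common = reduce(frozenset.intersection, (s.pairs for s in sets))
    thresholds = {s.threshold for s in sets}
    return DirectedPairSet(
        common,
        threshold=thresholds.pop() if len(thresholds) == 1 else None,
        n_samples=None,
    )
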