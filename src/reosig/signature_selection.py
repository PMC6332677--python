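"""Reversed-pair signature selection between two tumour classes.

Given each class's characteristic stable-pair set, a *reversed* pair is one
stable in class 1 and stable with the opposite direction in class 2 — the raw
material for a batch-effect-invariant voting signature.  Candidate pairs are
ranked by (a) how often each gene appears among the reversed pairs and (b)
the pair's mean absolute within-sample rank difference

    dAvgR(i, j) = [ sum_n |R_{n,i} - R_{n,j}| + sum_m |R_{m,i} - R_{m,j}| ] / (N1 + N2)

over all training profiles of both classes, where R are within-sample ranks
(1..G ascending, average ties).  Genes are visited in order of decreasing
appearance frequency and each contributes its maximum-dAvgR reversed pair;
the final signature size is picked by scanning odd pair counts with the
majority-vote classifier on the pooled training samples.

All tie-breaks are lexicographic on gene identifiers: the selection must be
deterministic to be reproducible, and identifiers are the only canonical
order available.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import classify_matrix
from .core_io import DirectedPairSet, ExpressionMatrix, Signature, intersect_gene_universe
from .stable_reo import characteristic_pairs, detect_stable_pairs

__all__ = [
    "SizeScanResult",
    "find_reversed_pairs",
    "within_sample_ranks",
    "delta_avg_rank",
    "gene_frequencies",
    "reversed_pair_table",
    "build_candidate_list",
    "scan_odd_sizes",
    "select_signature",
]


@dataclass(frozen=True)
class SizeScanResult:
    """Training accuracy at each scanned odd signature size.

    ``chosen_n`` is the smallest odd n whose pooled accuracy equals the
    maximum over the scan.
    """

    sizes: tuple
    accuracy: tuple
    accuracy_class1: tuple
    accuracy_class2: tuple
    chosen_n: int

    @property
    def chosen_accuracy(self) -> float:
        return self.accuracy[self.sizes.index(self.chosen_n)]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_pairs": self.sizes,
                "accuracy_pct": self.accuracy,
                "accuracy_class1_pct": self.accuracy_class1,
                "accuracy_class2_pct": self.accuracy_class2,
            }
        )


def find_reversed_pairs(char1: DirectedPairSet, char2: DirectedPairSet) -> frozenset:
    """Pairs stable in class 1 whose direction is reversed in class 2.

    Returned in the class-1 direction: {(a, b) : (a, b) in char1 and
    (b, a) in char2}.  Swapping the two arguments returns the same unordered
    pairs with every direction flipped.
    """
    if len(char1) == 0 or len(char2) == 0:
        raise ValueError("both characteristic sets must be non-empty")
    c2 = char2.pairs
    return frozenset((a, b) for a, b in char1.pairs if (b, a) in c2)


def within_sample_ranks(m: ExpressionMatrix) -> pd.DataFrame:
    """Rank each sample's values 1..G ascending, ties getting the average rank."""
    ranks = stats.rankdata(m.values, axis=0, method="average")
    return pd.DataFrame(ranks, index=m.gene_ids, columns=m.sample_ids)


def delta_avg_rank(pair, ranks1: pd.DataFrame, ranks2: pd.DataFrame) -> float:
    """Mean absolute within-sample rank gap of a pair over both classes."""
    i, j = pair
    for r in (ranks1, ranks2):
        for g in (i, j):
            if g not in r.index:
                raise KeyError(f"gene {g!r} missing from rank matrix")
    d1 = np.abs(ranks1.loc[i].to_numpy() - ranks1.loc[j].to_numpy())
    d2 = np.abs(ranks2.loc[i].to_numpy() - ranks2.loc[j].to_numpy())
    return float((d1.sum() + d2.sum()) / (d1.size + d2.size))


def gene_frequencies(pairs) -> dict:
    """Appearance count of each gene across a collection of pairs."""
    counts: Counter = Counter()
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
    return dict(counts)


def reversed_pair_table(pairs, ranks1: pd.DataFrame, ranks2: pd.DataFrame) -> pd.DataFrame:
    """Tabulate reversed pairs (class-1 direction) with their dAvgR scores."""
    rows = [
        {"gene_high": a, "gene_low": b, "delta_avg_rank": delta_avg_rank((a, b), ranks1, ranks2)}
        for a, b in sorted(pairs)
    ]
    return pd.DataFrame(rows).sort_values(
        ["delta_avg_rank", "gene_high", "gene_low"], ascending=[False, True, True]
    ).reset_index(drop=True)


def build_candidate_list(
    reversed_pairs,
    freq: Mapping | None = None,
    delta: Mapping | None = None,
    *,
    ranks1: pd.DataFrame | None = None,
    ranks2: pd.DataFrame | None = None,
) -> list:
    """Order reversed pairs into the candidate signature list.

    Genes are sorted by appearance frequency, descending (ties broken
    lexicographically); each gene in turn contributes its reversed pair with
    maximal dAvgR (ties: partner with the larger frequency, then
    lexicographically smaller partner).  A pair already contributed by an
    earlier gene is skipped, so the list holds no duplicates.  ``delta`` may
    be given directly as a pair→score mapping, or computed from the two rank
    matrices.
    """
    reversed_pairs = set(tuple(p) for p in reversed_pairs)
    if not reversed_pairs:
        raise ValueError("reversed pair set is empty")
    if freq is None:
        freq = gene_frequencies(reversed_pairs)
    if delta is None:
        if ranks1 is None or ranks2 is None:
            raise ValueError("provide delta or both rank matrices")
        delta = {p: delta_avg_rank(p, ranks1, ranks2) for p in reversed_pairs}

    by_gene: dict = {}
    for a, b in reversed_pairs:
        by_gene.setdefault(a, []).append((a, b))
        by_gene.setdefault(b, []).append((a, b))

    genes = sorted(by_gene, key=lambda g: (-freq.get(g, 0), g))
    candidates: list = []
    chosen: set = set()
    for g in genes:
        def sort_key(pair):
            partner = pair[1] if pair[0] == g else pair[0]
            return (-delta[pair], -freq.get(partner, 0), partner)

        best = min(by_gene[g], key=sort_key)
        if best in chosen:
            continue
        candidates.append(best)
        chosen.add(best)
    return candidates


def scan_odd_sizes(
    candidates: Sequence,
    train1: ExpressionMatrix,
    train2: ExpressionMatrix,
    max_n: int = 43,
) -> SizeScanResult:
    """Scan odd signature sizes 1, 3, ..., max_n on the pooled training samples.

    At each size n the first n candidate pairs classify every training sample
    by strict majority vote; accuracy pools both classes (per-class values are
    kept alongside).  The chosen size is the smallest n reaching the scan's
    maximum pooled accuracy.
    """
    if len(candidates) < 1:
        raise ValueError("candidate list is empty")
    if max_n % 2 == 0:
        raise ValueError("max_n must be odd")
    if max_n > len(candidates):
        raise ValueError(f"max_n={max_n} exceeds candidate list length {len(candidates)}")

    sizes, acc, acc1, acc2 = [], [], [], []
    n1, n2 = train1.n_samples, train2.n_samples
    for n in range(1, max_n + 1, 2):
        sig = Signature(tuple(candidates[:n]), class1_label="class1", class2_label="class2")
        res1, _ = classify_matrix(train1, sig)
        res2, _ = classify_matrix(train2, sig)
        c1 = sum(r.predicted == "class1" for r in res1)
        c2 = sum(r.predicted == "class2" for r in res2)
        sizes.append(n)
        acc.append(100.0 * (c1 + c2) / (n1 + n2))
        acc1.append(100.0 * c1 / n1)
        acc2.append(100.0 * c2 / n2)

    best = max(acc)
    chosen = next(n for n, a in zip(sizes, acc) if a >= best - 1e-9)
    return SizeScanResult(
        sizes=tuple(sizes),
        accuracy=tuple(acc),
        accuracy_class1=tuple(acc1),
        accuracy_class2=tuple(acc2),
        chosen_n=chosen,
    )


def select_signature(
    class1_mats: Sequence[ExpressionMatrix],
    class2_mats: Sequence[ExpressionMatrix],
    *,
    threshold: float = 0.95,
    max_n: int = 43,
    class1_label: str = "class1",
    class2_label: str = "class2",
):
    """Run the full selection pipeline on training expression matrices.

    Steps: harmonize gene universes, detect each dataset's stable pairs,
    intersect per class into characteristic sets, find reversed pairs, score
    them (gene frequency + dAvgR over the pooled per-class rank matrices),
    order candidates, and scan odd sizes.  ``max_n`` is clamped to the
    largest odd number not exceeding the candidate count.

    Returns ``(signature, scan_result, reversed_table)``.
    """
    mats = intersect_gene_universe(list(class1_mats) + list(class2_mats))
    c1 = mats[: len(class1_mats)]
    c2 = mats[len(class1_mats) :]

    def _characteristic(ms):
        sets = [detect_stable_pairs(m, threshold) for m in ms]
        return sets[0] if len(sets) == 1 else characteristic_pairs(sets)

    char1, char2 = _characteristic(c1), _characteristic(c2)
    reversed_pairs = find_reversed_pairs(char1, char2)
    if not reversed_pairs:
        raise ValueError("no reversed pairs between the two classes")

    train1 = _pool_samples(c1)
    train2 = _pool_samples(c2)
    ranks1 = within_sample_ranks(train1)
    ranks2 = within_sample_ranks(train2)
    table = reversed_pair_table(reversed_pairs, ranks1, ranks2)
    delta = dict(zip(zip(table["gene_high"], table["gene_low"]), table["delta_avg_rank"]))
    candidates = build_candidate_list(reversed_pairs, delta=delta)

    max_n = min(max_n, len(candidates))
    if max_n % 2 == 0:
        max_n -= 1
    scan = scan_odd_sizes(candidates, train1, train2, max_n=max_n)
    sig = Signature(
        tuple(candidates[: scan.chosen_n]),
        class1_label=class1_label,
        class2_label=class2_label,
    )
    return sig, scan, table


def _pool_samples(mats: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    if len(mats) == 1:
        return mats[0]
    frames = [m.data for m in mats]
    seen: set = set()
    renamed = []
    for d, df in enumerate(frames):
        if any(c in seen for c in df.columns):
            df = df.rename(columns={c: f"{c}__d{d}" for c in df.columns})
        seen.update(df.columns)
        renamed.append(df)
    return ExpressionMatrix(pd.concat(renamed, axis=1))
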