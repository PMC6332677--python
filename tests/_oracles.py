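"""Independent brute-force reference implementations.

Everything here is deliberately naive — double loops, comparison counting,
exhaustive bitmask enumeration — and shares no code path with the package,
so agreement between the two is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def stable_pairs_oracle(df, threshold):
    """All-pairs double loop over unordered gene pairs."""
    genes = list(df.index)
    n = df.shape[1]
    out = set()
    X = df.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            gt = int((X[i] > X[j]).sum())
            lt = int((X[i] < X[j]).sum())
            if gt / n > threshold:
                out.add((genes[i], genes[j]))
            elif lt / n > threshold:
                out.add((genes[j], genes[i]))
    return frozenset(out)


def characteristic_oracle(list_of_pair_sets):
    first, *rest = [set(s) for s in list_of_pair_sets]
    return frozenset(p for p in first if all(p in s for s in rest))


def concordance_oracle(a_pairs, b_pairs):
    """Return (k, s): overlapping unordered pairs and direction agreements."""
    b = set(b_pairs)
    k = s = 0
    for x, y in a_pairs:
        if (x, y) in b:
            k += 1
            s += 1
        elif (y, x) in b:
            k += 1
    return k, s


def sample_concordance_oracle(values, pairs):
    """values: gene -> expression for one sample.  Returns (percent, n_eval)."""
    n_eval = n_conc = 0
    for hi, lo in pairs:
        if hi in values and lo in values:
            n_eval += 1
            if values[hi] > values[lo]:
                n_conc += 1
    return 100.0 * n_conc / n_eval, n_eval


def ranks_oracle(values):
    """Average ranks by comparison counting: 1 + #smaller + (#equal - 1)/2."""
    return {
        g: 1.0
        + sum(1 for h in values if values[h] < values[g])
        + (sum(1 for h in values if values[h] == values[g]) - 1) / 2.0
        for g in values
    }


def delta_avg_rank_oracle(pair, df1, df2):
    """Eq.-style arithmetic from raw expression via the counting ranks."""
    i, j = pair
    total = 0.0
    count = 0
    for df in (df1, df2):
        for col in df.columns:
            r = ranks_oracle(df[col].to_dict())
            total += abs(r[i] - r[j])
            count += 1
    return total / count


def vote_oracle(values, sig_pairs):
    """Class-1 votes of one sample under a directed-pair signature."""
    votes = n_eval = 0
    for hi, lo in sig_pairs:
        if hi in values and lo in values:
            n_eval += 1
            if values[hi] > values[lo]:
                votes += 1
    return votes, n_eval


def binomial_tail_enumeration(k, p):
    """Upper-tail probabilities for every s by enumerating all 2^k outcomes.

    Each integer in [0, 2^k) is one outcome; its population count is the
    number of successes.  Returns an array t with t[s] = P(X >= s).
    """
    outcomes = np.arange(2 ** k, dtype=np.uint64)
    successes = np.bitwise_count(outcomes).astype(np.int64)
    counts = np.bincount(successes, minlength=k + 1).astype(float)
    i = np.arange(k + 1)
    mass = counts * (p ** i) * ((1.0 - p) ** (k - i))
    tail = np.cumsum(mass[::-1])[::-1]
    return np.append(tail, 0.0)[: k + 1 + 1]
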