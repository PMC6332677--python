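"""Concordance between stable-pair sets and per-sample ordering agreement.

Two stable-pair lists that overlap in k unordered pairs, s of which point the
same way, get a concordance score of s/k x 100%.  The probability of seeing
at least s agreements by chance is the upper cumulative binomial tail

    P(X >= s),  X ~ Binomial(k, p_e),  p_e = 0.5 by default,

evaluated through the regularized incomplete beta function so it stays
accurate for k in the 10^8 range typical of all-pairs scans.

A single sample can likewise be scored against a reference direction set:
the percentage of evaluable reference pairs whose ordering the sample
realizes (ties count as discordant, pairs with genes absent from the sample
are excluded from the denominator and counted separately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DirectedPairSet, ExpressionMatrix

__all__ = [
    "ConcordanceResult",
    "SampleConcordance",
    "binomial_tail",
    "concordance_score",
    "per_sample_concordance",
    "per_sample_concordance_table",
]

_P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between two directed pair sets.

    ``score`` is None when the sets share no unordered pair (k = 0); the
    p-value is then 1 and ``applicable`` is False.  ``log10_p_value`` carries
    the tail probability in log space even when the linear value underflows.
    """

    k: int
    s: int
    p_e: float
    p_value: float
    log10_p_value: float

    @property
    def score(self) -> float | None:
        if self.k == 0:
            return None
        return 100.0 * self.s / self.k

    @property
    def applicable(self) -> bool:
        return self.k > 0

    def format_p(self) -> str:
        """Display form; values below double precision print as a floor."""
        if self.p_value < _P_FLOOR:
            return "< 2.2e-16"
        return f"{self.p_value:.4g}"


@dataclass(frozen=True)
class SampleConcordance:
    percent: float
    n_evaluated: int
    n_missing: int


def binomial_tail(s: int, k: int, p_e: float = 0.5) -> float:
    """Upper cumulative binomial probability P(X >= s) for X ~ Bin(k, p_e).

    Equals 1 - sum_{i=0}^{s-1} C(k,i) p_e^i (1-p_e)^(k-i); s = 0 gives exactly
    1.0 (empty sum).  Evaluated via the survival function (incomplete beta),
    which is numerically stable for very large k.
    """
    if int(s) != s or int(k) != k:
        raise ValueError("s and k must be integers")
    s, k = int(s), int(k)
    if k < 0 or not (0 <= s <= k):
        raise ValueError(f"need 0 <= s <= k, got s={s}, k={k}")
    if not (0.0 < p_e < 1.0):
        raise ValueError(f"p_e must lie strictly in (0, 1), got {p_e}")
    if s == 0:
        return 1.0
    return float(stats.binom.sf(s - 1, k, p_e))


def _log10_binomial_tail(s: int, k: int, p_e: float) -> float:
    if s == 0:
        return 0.0
    return float(stats.binom.logsf(s - 1, k, p_e) / np.log(10.0))


def concordance_score(a: DirectedPairSet, b: DirectedPairSet, p_e: float = 0.5) -> ConcordanceResult:
    """Score the agreement of two stable-pair sets.

    k counts unordered pairs present in both sets (either direction); s
    counts those whose directions agree.  Symmetric in its arguments.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both pair sets must be non-empty")
    k = s = 0
    b_pairs = b.pairs
    for pair in a.pairs:
        if pair in b_pairs:
            k += 1
            s += 1
        elif (pair[1], pair[0]) in b_pairs:
            k += 1
    if k == 0:
        return ConcordanceResult(k=0, s=0, p_e=p_e, p_value=1.0, log10_p_value=0.0)
    return ConcordanceResult(
        k=k,
        s=s,
        p_e=p_e,
        p_value=binomial_tail(s, k, p_e),
        log10_p_value=_log10_binomial_tail(s, k, p_e),
    )


def per_sample_concordance(sample: pd.Series, reference: DirectedPairSet) -> SampleConcordance:
    """Percentage of reference pairs (high, low) realized in one sample.

    A pair is concordant when the sample's high-gene value strictly exceeds
    the low-gene value; ties are discordant.  Pairs with either gene missing
    from the sample are excluded from the denominator and reported in
    ``n_missing``.
    """
    if len(reference) == 0:
        raise ValueError("reference pair set is empty")
    index = sample.index
    n_eval = n_conc = n_missing = 0
    for hi, lo in reference.pairs:
        if hi not in index or lo not in index:
            n_missing += 1
            continue
        n_eval += 1
        if sample[hi] > sample[lo]:
            n_conc += 1
    if n_eval == 0:
        raise ValueError("no reference pair is evaluable in this sample")
    return SampleConcordance(
        percent=100.0 * n_conc / n_eval,
        n_evaluated=n_eval,
        n_missing=n_missing,
    )


def per_sample_concordance_table(m: ExpressionMatrix, reference: DirectedPairSet) -> pd.DataFrame:
    """Per-sample concordance against a reference direction set.

    One row per sample with the percentage of reference pairs in the
    reference (class-1) direction and its complement — the tabular form of a
    stacked per-sample concordance bar chart.
    """
    rows = []
    for sid in m.sample_ids:
        sc = per_sample_concordance(m.sample(sid), reference)
        rows.append(
            {
                "sample_id": sid,
                "concordance_pct": sc.percent,
                "discordance_pct": 100.0 - sc.percent,
                "n_evaluated": sc.n_evaluated,
                "n_missing": sc.n_missing,
            }
        )
    return pd.DataFrame(rows)
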