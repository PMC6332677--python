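"""Majority-vote classification from a directed-pair signature.

Each signature pair (high, low) is stored in the class-1 direction; in a
given sample the pair votes for class 1 exactly when the high gene's value
strictly exceeds the low gene's (a tie or a reversal is not a class-1 vote).
The sample is predicted class 1 iff strictly more than half of the evaluable
pairs vote that way, otherwise class 2.  Because only within-sample
orderings are consulted, the prediction is invariant to any strictly
increasing per-sample transform — in particular to additive batch shifts and
linear/log scale changes.

Signature genes missing from a sample's platform are skipped by default and
the vote denominator shrinks (the result records how many were skipped); a
strict mode refuses to classify instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import ExpressionMatrix, Signature

__all__ = [
    "ClassificationResult",
    "classify_sample",
    "classify_matrix",
    "results_frame",
    "published_signature",
]


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    votes_class1: int
    n_evaluated: int
    n_missing: int
    predicted: str

    def __post_init__(self):
        if not (0 <= self.votes_class1 <= self.n_evaluated):
            raise ValueError("votes_class1 must lie in [0, n_evaluated]")


def classify_sample(
    sample: pd.Series,
    sig: Signature,
    *,
    sample_id: str | None = None,
    strict: bool = False,
) -> ClassificationResult:
    """Classify one expression profile by strict majority vote.

    With ``strict=True`` any signature gene missing from the sample is a hard
    error; otherwise such pairs are skipped and counted in ``n_missing``.
    """
    index = sample.index
    votes = n_eval = 0
    missing_genes: list = []
    for hi, lo in sig.pairs:
        absent = [g for g in (hi, lo) if g not in index]
        if absent:
            missing_genes.extend(absent)
            continue
        n_eval += 1
        if sample[hi] > sample[lo]:
            votes += 1
    sid = sample_id if sample_id is not None else str(sample.name)
    if strict and missing_genes:
        raise ValueError(f"sample {sid!r}: signature genes missing: {sorted(set(missing_genes))}")
    if n_eval == 0:
        raise ValueError(
            f"sample {sid!r}: no signature pair evaluable; missing genes: "
            f"{sorted(set(missing_genes))}"
        )
    predicted = sig.class1_label if votes > n_eval / 2 else sig.class2_label
    return ClassificationResult(
        sample_id=sid,
        votes_class1=votes,
        n_evaluated=n_eval,
        n_missing=len(sig.pairs) - n_eval,
        predicted=predicted,
    )


def classify_matrix(
    m: ExpressionMatrix,
    sig: Signature,
    labels: pd.Series | dict | None = None,
    *,
    strict: bool = False,
):
    """Classify every sample of a matrix; columns are independent.

    Returns ``(results, summary)`` where ``results`` is a list of per-sample
    :class:`ClassificationResult` and ``summary`` (None without labels) holds
    per-class and pooled accuracy percentages over the labelled samples.
    """
    results = []
    for sid in m.sample_ids:
        try:
            results.append(classify_sample(m.sample(sid), sig, sample_id=sid, strict=strict))
        except ValueError as exc:
            raise ValueError(f"sample {sid!r}: {exc}") from exc

    summary = None
    if labels is not None:
        labels = dict(labels)
        per_class: dict = {}
        for r in results:
            truth = labels.get(r.sample_id)
            if truth is None:
                continue
            n_ok, n_tot = per_class.get(truth, (0, 0))
            per_class[truth] = (n_ok + (r.predicted == truth), n_tot + 1)
        total_ok = sum(ok for ok, _ in per_class.values())
        total = sum(n for _, n in per_class.values())
        if total == 0:
            raise ValueError("labels were supplied but match no sample id")
        summary = {
            "accuracy_pct": 100.0 * total_ok / total,
            "n_labelled": total,
            "per_class_accuracy_pct": {
                cls: 100.0 * ok / n for cls, (ok, n) in sorted(per_class.items())
            },
        }
    return results, summary


def results_frame(results) -> pd.DataFrame:
    """Per-sample predictions as a DataFrame (the predictions.tsv layout)."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "votes_class1": r.votes_class1,
                "n_evaluated": r.n_evaluated,
                "n_missing": r.n_missing,
                "predicted": r.predicted,
            }
            for r in results
        ]
    )


def published_signature() -> Signature:
    """The published five-pair colorectal-vs-lung-cancer signature.

    Each pair's former gene has the higher expression in colorectal tumours;
    SLC34A2 — a gene with documented roles in non-small-cell lung cancer —
    is the low gene of all five pairs, so a sample in which SLC34A2 tops all
    five partners casts zero CRC votes and is called lung-like.
    """
    return Signature(
        pairs=(
            ("GUCY2C", "SLC34A2"),
            ("CDH17", "SLC34A2"),
            ("FABP1", "SLC34A2"),
            ("KRT20", "SLC34A2"),
            ("USH1C", "SLC34A2"),
        ),
        class1_label="CRC",
        class2_label="lung",
    )
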