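"""Core data containers and file I/O.

The pipeline's universal input is a gene-by-sample expression matrix on an
arbitrary monotone scale (linear or log): every downstream statistic depends
only on the within-sample ordering of values, so no rescaling is ever applied
here.  This module also reads/writes directed gene-pair sets and voting
signatures, collapses probe-level matrices to gene level, and harmonizes gene
universes across datasets.
"""

from __future__ import annotations

import gzip
import io
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DirectedPairSet",
    "Signature",
    "read_expression",
    "write_expression",
    "read_annotation",
    "clean_annotation",
    "collapse_probes",
    "intersect_gene_universe",
    "read_pairs",
    "write_pairs",
    "read_signature",
    "write_signature",
]


class ExpressionMatrix:
    """A validated gene-by-sample numeric matrix.

    Rows are genes (unique identifiers, treated as opaque case-sensitive
    strings), columns are samples.  Values may be on any strictly monotone
    scale; the container never rescales.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  All values must be numeric and finite.
    drop_missing
        If True, genes with any missing value are dropped; otherwise missing
        values are a hard error.  Ordering counts have no natural NA
        semantics, so rejection is the default.
    """

    __slots__ = ("_data",)

    def __init__(self, data: pd.DataFrame, *, drop_missing: bool = False):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("ExpressionMatrix expects a pandas DataFrame")
        data = data.copy()
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)

        dup_samples = data.columns[data.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample identifiers: {dup_samples}")
        dup_genes = data.index[data.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene identifiers: {dup_genes}")

        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError):
            _raise_non_numeric(data)
            raise  # pragma: no cover
        data = pd.DataFrame(values, index=data.index, columns=data.columns)

        if np.isnan(values).any():
            if drop_missing:
                data = data.dropna(axis=0, how="any")
            else:
                r, c = np.argwhere(np.isnan(values))[0]
                raise ValueError(
                    f"missing value at gene {data.index[r]!r}, "
                    f"sample {data.columns[c]!r} (pass drop_missing=True to drop)"
                )
        if not np.isfinite(data.to_numpy()).all():
            raise ValueError("non-finite values in expression matrix")
        if data.shape[0] < 2:
            raise ValueError("expression matrix needs at least 2 genes")
        if data.shape[1] < 1:
            raise ValueError("expression matrix needs at least 1 sample")
        self._data = data

    # -- accessors ---------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self._data.shape[0]

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's expression profile as a gene-indexed Series."""
        return self._data[sample_id]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self._data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._data.loc[list(genes)])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


def _raise_non_numeric(data: pd.DataFrame) -> None:
    for j, col in enumerate(data.columns):
        coerced = pd.to_numeric(data[col], errors="coerce")
        bad = coerced.isna() & data[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-numeric cell at gene {data.index[i]!r} (row {i}), "
                f"sample {col!r} (column {j}): {data[col].iloc[i]!r}"
            )


@dataclass(frozen=True)
class DirectedPairSet:
    """Ordered gene pairs (high, low): "high > low in more than a threshold
    fraction of samples" in the source dataset.

    At most one direction per unordered pair may be present; thresholds above
    0.5 guarantee this at detection time and the invariant is re-checked here.
    """

    pairs: frozenset
    threshold: float | None = None
    n_samples: int | None = None
    support: Mapping | None = None

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a!r}, {a!r}) not allowed")
            if (b, a) in self.pairs:
                raise ValueError(f"both directions present for pair ({a!r}, {b!r})")
        if self.threshold is not None and not (0.5 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0.5, 1.0]")
        if self.support is not None:
            object.__setattr__(self, "support", dict(self.support))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple]:
        return iter(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    def genes(self) -> frozenset:
        return frozenset(g for p in self.pairs for g in p)


@dataclass(frozen=True)
class Signature:
    """An ordered list of directed gene pairs in the class-1 direction.

    Each pair (high, low) votes for class 1 in a sample when the high gene's
    value strictly exceeds the low gene's; the sample is called class 1 iff
    strictly more than half of the evaluable pairs vote that way.
    """

    pairs: tuple
    class1_label: str = "class1"
    class2_label: str = "class2"

    def __post_init__(self):
        pairs = tuple(tuple(p) for p in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if not pairs:
            raise ValueError("signature must contain at least one pair")
        seen = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-pair ({a!r}, {a!r}) in signature")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate pair on genes {sorted(key)}")
            seen.add(key)
        if self.class1_label == self.class2_label:
            raise ValueError("class labels must differ")

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> frozenset:
        return frozenset(g for p in self.pairs for g in p)


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------

def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _series_matrix_body(lines: Iterable[str]) -> list[str]:
    """Strip a GEO series-matrix file down to its data table.

    Lines starting with "!" are metadata; if explicit
    ``!series_matrix_table_begin``/``_end`` markers are present, only the
    lines between them are the table.
    """
    lines = list(lines)
    begin = end = None
    for i, line in enumerate(lines):
        if line.startswith("!series_matrix_table_begin"):
            begin = i
        elif line.startswith("!series_matrix_table_end"):
            end = i
    if begin is not None:
        body = lines[begin + 1 : end if end is not None else None]
    else:
        body = [ln for ln in lines if not ln.startswith("!")]
    return [ln for ln in body if ln.strip()]


def read_expression(path, layout: str = "plain_tsv", *, drop_missing: bool = False) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    ``layout="plain_tsv"``: header row ``gene<TAB>sample1<TAB>...``, one gene
    per row.  ``layout="series_matrix"``: GEO series-matrix dialect — metadata
    lines beginning with "!" are ignored and the table may be delimited by
    ``!series_matrix_table_begin``/``end`` markers; quoted identifiers are
    unquoted.
    """
    if layout not in ("plain_tsv", "series_matrix"):
        raise ValueError(f"unknown layout {layout!r}")
    with _open_text(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    if layout == "series_matrix":
        lines = _series_matrix_body(lines)
    if not lines:
        raise ValueError(f"{path}: no table content found")
    df = pd.read_csv(
        io.StringIO("\n".join(lines)),
        sep="\t",
        index_col=0,
        quotechar='"',
        header=0,
    )
    # pandas mangles duplicate header names; detect them from the raw header
    header = next(csv_line for csv_line in lines if csv_line.strip())
    raw_cols = [c.strip('"') for c in header.rstrip("\n").split("\t")][1:]
    dupes = pd.Index(raw_cols)[pd.Index(raw_cols).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate sample identifiers in {path}: {dupes}")
    df.columns = raw_cols
    df.index = [str(i).strip('"') for i in df.index]
    return ExpressionMatrix(df, drop_missing=drop_missing)


def write_expression(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# annotation and probe collapsing
# ---------------------------------------------------------------------------

def clean_annotation(rows: Iterable[tuple]) -> dict:
    """Reduce raw (probe, gene) rows to a clean one-to-one probe map.

    Rows with an empty/NA gene are dropped; probes mapped to more than one
    distinct gene are ambiguous and dropped entirely.  Many probes per gene
    are fine (resolved later by :func:`collapse_probes`).
    """
    seen: dict = {}
    ambiguous: set = set()
    for probe, gene in rows:
        probe = str(probe).strip()
        gene = "" if gene is None or (isinstance(gene, float) and np.isnan(gene)) else str(gene).strip()
        if not probe or not gene or gene.lower() in ("nan", "na", "---"):
            continue
        if probe in seen and seen[probe] != gene:
            ambiguous.add(probe)
        seen[probe] = gene
    return {p: g for p, g in seen.items() if p not in ambiguous}


def read_annotation(path) -> dict:
    """Read a two-column probe→gene TSV (header required) and clean it."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs at least two columns")
    return clean_annotation(zip(df.iloc[:, 0], df.iloc[:, 1]))


def collapse_probes(m: ExpressionMatrix, ann: Mapping, rule: str = "max_mean") -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    ``max_mean`` keeps, per gene, the probe with the largest mean across
    samples (tie → lexicographically smallest probe id); ``mean`` averages
    the probe rows.  Unmapped probes are dropped.  Keeping a single
    highest-mean probe preserves within-sample orderings, which averaging of
    log-scale probes does not, hence the default.
    """
    if rule not in ("max_mean", "mean"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    mapped = [p for p in m.gene_ids if p in ann]
    if not mapped:
        raise ValueError("no probe in the matrix has a gene annotation")
    df = m.data.loc[mapped]
    genes = pd.Series([ann[p] for p in mapped], index=df.index, name="gene")
    if rule == "mean":
        out = df.groupby(genes, sort=True).mean()
    else:
        means = df.mean(axis=1)
        keep = []
        for _, probes in sorted(genes.groupby(genes).groups.items()):
            probes = sorted(probes, key=lambda p: (-means[p], p))
            keep.append(probes[0])
        out = df.loc[keep]
        out.index = [genes[p] for p in keep]
        out = out.sort_index()
    return ExpressionMatrix(out)


def intersect_gene_universe(ms: Sequence[ExpressionMatrix]) -> list:
    """Restrict every matrix to the sorted common gene set.

    Cross-dataset pair comparison is only meaningful on a shared gene
    universe; this is an explicit pipeline step, never implicit.
    """
    if len(ms) < 2:
        raise ValueError("need at least two matrices to intersect")
    common: set = set(ms[0].gene_ids)
    for m in ms[1:]:
        common &= set(m.gene_ids)
    genes = sorted(common)
    if len(genes) < 2:
        raise ValueError(
            f"common gene universe has {len(genes)} genes; pair analysis needs at least 2"
        )
    return [m.subset_genes(genes) for m in ms]


# ---------------------------------------------------------------------------
# pair-set and signature I/O
# ---------------------------------------------------------------------------

def write_pairs(ps: DirectedPairSet, path) -> None:
    """Write a pair set as TSV: gene_high, gene_low [, support_fraction]."""
    rows = sorted(ps.pairs)
    df = pd.DataFrame(rows, columns=["gene_high", "gene_low"])
    if ps.support is not None:
        df["support_fraction"] = [ps.support.get(p, np.nan) for p in rows]
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path, threshold: float | None = None, n_samples: int | None = None) -> DirectedPairSet:
    df = pd.read_csv(path, sep="\t", dtype={"gene_high": str, "gene_low": str})
    if not {"gene_high", "gene_low"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns gene_high, gene_low")
    pairs = [tuple(r) for r in df[["gene_high", "gene_low"]].itertuples(index=False)]
    support = None
    if "support_fraction" in df.columns:
        support = {p: float(s) for p, s in zip(pairs, df["support_fraction"])}
    return DirectedPairSet(frozenset(pairs), threshold=threshold, n_samples=n_samples, support=support)


def write_signature(sig: Signature, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#class1={sig.class1_label}\n")
        fh.write(f"#class2={sig.class2_label}\n")
        fh.write("gene_high\tgene_low\n")
        for a, b in sig.pairs:
            fh.write(f"{a}\t{b}\n")


def read_signature(path) -> Signature:
    class1, class2 = "class1", "class2"
    rows: list = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#class1="):
                class1 = line.split("=", 1)[1]
            elif line.startswith("#class2="):
                class2 = line.split("=", 1)[1]
            elif line.startswith("#"):
                continue
            else:
                rows.append(line.split("\t"))
    if not rows or rows[0][:2] != ["gene_high", "gene_low"]:
        raise ValueError(f"{path}: expected a 'gene_high<TAB>gene_low' header")
    pairs = tuple((a, b) for a, b, *_ in rows[1:])
    return Signature(pairs, class1_label=class1, class2_label=class2)
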