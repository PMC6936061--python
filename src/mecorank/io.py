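"""Readers and writers for the external file formats the pipeline touches.

All computation lives elsewhere; this module only parses, validates and
serializes. Gene identity is the bare symbol string, case-sensitive, after
trimming whitespace — no alias resolution is attempted.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "ExpressionMatrix",
    "MutationRecord",
    "MutationTable",
    "read_ppi",
    "write_ppi",
    "read_expression",
    "read_expression_pair",
    "read_mutations",
    "write_mutations",
    "read_gene_list",
    "write_gene_list",
    "write_ranking",
    "read_ranking",
]


# ---------------------------------------------------------------------------
# protein-protein interaction network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PPINetwork:
    """Undirected simple graph over gene symbols.

    Edges are stored as lexicographically sorted 2-tuples, so symmetry and
    de-duplication hold by construction; self-loops are excluded by the
    constructor of :func:`read_ppi` / :meth:`from_edges`.
    """

    genes: frozenset
    edges: frozenset  # of sorted (a, b) tuples, a < b or a != b

    def __post_init__(self):
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop edge ({a}, {b}) in PPINetwork")
            if a not in self.genes or b not in self.genes:
                raise ValueError(f"edge endpoint missing from gene set: ({a}, {b})")

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple], extra_genes: Iterable[str] = ()) -> "PPINetwork":
        """Build a network from an iterable of (possibly messy) gene pairs.

        Duplicates (in either orientation) are collapsed and self-loops are
        dropped; counts of both are logged.
        """
        genes = set(extra_genes)
        edges = set()
        n_self = 0
        n_dup = 0
        for a, b in pairs:
            a, b = a.strip(), b.strip()
            genes.add(a)
            genes.add(b)
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in edges:
                n_dup += 1
            else:
                edges.add(key)
        if n_self:
            logger.info("PPI load: dropped %d self-loop edge(s)", n_self)
        if n_dup:
            logger.info("PPI load: collapsed %d duplicate edge(s)", n_dup)
        return cls(genes=frozenset(genes), edges=frozenset(edges))

    def adjacency(self) -> dict:
        """Gene -> set of interacting genes."""
        adj: dict = {g: set() for g in self.genes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def neighbors(self, gene: str) -> set:
        out = set()
        for a, b in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def degree(self) -> dict:
        deg = {g: 0 for g in self.genes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.edges)
        return g


_PPI_HEADER_TOKENS = re.compile(
    r"gene|symbol|protein|interactor|node", re.IGNORECASE
)


def read_ppi(path) -> PPINetwork:
    """Read a two-column (tab- or whitespace-separated) undirected edge list.

    An optional header line is detected heuristically (tokens that look like
    column names rather than gene symbols). Lines starting with '#' are
    skipped. A data line with fewer than two columns is a fatal parse error.
    """
    path = Path(path)
    pairs = []
    with open(path) as fh:
        first_data_line = True
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 2 columns, got {len(fields)}"
                )
            a, b = fields[0], fields[1]
            if first_data_line:
                first_data_line = False
                if _PPI_HEADER_TOKENS.search(a) and _PPI_HEADER_TOKENS.search(b):
                    continue  # header
            pairs.append((a, b))
    return PPINetwork.from_edges(pairs)


def write_ppi(ppi: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(ppi.edges):
            fh.write(f"{a}\t{b}\n")
        # isolated genes cannot be represented in an edge list; warn if any
        seen = {g for e in ppi.edges for g in e}
        lost = ppi.genes - seen
        if lost:
            logger.warning(
                "write_ppi: %d isolated gene(s) not representable in edge list", len(lost)
            )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

CONDITIONS = ("tumor", "normal")


@dataclass
class ExpressionMatrix:
    """Gene x sample real matrix with a tumor/normal label per sample.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample IDs
    as columns; ``conditions`` maps each sample ID to "tumor" or "normal".
    """

    values: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self):
        self.values.index.name = "gene"
        self.values.columns.name = None
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        if not isinstance(self.conditions, pd.Series):
            self.conditions = pd.Series(self.conditions)
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without a condition label: {missing[:5]}")
        self.conditions = self.conditions.reindex(self.values.columns)
        bad = set(self.conditions.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def tumor_samples(self) -> list:
        return [s for s in self.values.columns if self.conditions[s] == "tumor"]

    @property
    def normal_samples(self) -> list:
        return [s for s in self.values.columns if self.conditions[s] == "normal"]

    @property
    def tumor(self) -> pd.DataFrame:
        return self.values[self.tumor_samples]

    @property
    def normal(self) -> pd.DataFrame:
        return self.values[self.normal_samples]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples].copy(), self.conditions[samples].copy())


def read_expression(path, condition_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV matrix (genes in first column, sample IDs in the header).

    Every sample in the file must appear in ``condition_map``; a non-numeric
    or missing cell is fatal and is reported with its coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    missing = [s for s in df.columns if s not in condition_map]
    if missing:
        raise ValueError(f"{path}: samples absent from condition map: {missing[:5]}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            gene = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise ValueError(f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}")
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"{path}: missing (NA) cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    cond = pd.Series({s: condition_map[s] for s in df.columns})
    return ExpressionMatrix(df.astype(float), cond)


def read_expression_pair(tumor_path, normal_path) -> ExpressionMatrix:
    """Read separate tumor and normal matrices sharing a gene universe."""
    tdf = read_expression(tumor_path, _uniform_map(tumor_path, "tumor"))
    ndf = read_expression(normal_path, _uniform_map(normal_path, "normal"))
    if list(tdf.values.index) != list(ndf.values.index):
        common = tdf.values.index.intersection(ndf.values.index)
        if len(common) == 0:
            raise ValueError("tumor and normal matrices share no genes")
        logger.warning(
            "expression pair: restricting to %d genes common to both matrices", len(common)
        )
        tdf_v = tdf.values.loc[common]
        ndf_v = ndf.values.loc[common]
    else:
        tdf_v, ndf_v = tdf.values, ndf.values
    overlap = set(tdf_v.columns) & set(ndf_v.columns)
    if overlap:
        raise ValueError(f"sample IDs present in both tumor and normal files: {sorted(overlap)[:5]}")
    values = pd.concat([tdf_v, ndf_v], axis=1)
    cond = pd.Series(
        {**{s: "tumor" for s in tdf_v.columns}, **{s: "normal" for s in ndf_v.columns}}
    )
    return ExpressionMatrix(values, cond)


def _uniform_map(path, label):
    header = pd.read_csv(path, sep="\t", index_col=0, nrows=0)
    return {str(s).strip(): label for s in header.columns}


def write_expression(expr_values: pd.DataFrame, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    expr_values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


# ---------------------------------------------------------------------------
# somatic mutation tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRecord:
    sample: str
    gene: str
    polyphen_label: str | None = None
    polyphen_score: float | None = None
    sift_label: str | None = None
    sift_score: float | None = None

    def __post_init__(self):
        if self.polyphen_label is None and self.sift_label is None:
            raise ValueError(
                f"mutation record for ({self.sample}, {self.gene}) carries no annotation"
            )
        for name, score in (("PolyPhen", self.polyphen_score), ("SIFT", self.sift_score)):
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValueError(
                    f"{name} score {score} outside [0, 1] for ({self.sample}, {self.gene})"
                )


@dataclass
class MutationTable:
    records: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def samples(self) -> list:
        return sorted({r.sample for r in self.records})

    def genes(self) -> list:
        return sorted({r.gene for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.sample, r.gene, r.polyphen_label, r.polyphen_score, r.sift_label, r.sift_score)
                for r in self.records
            ],
            columns=[
                "sample", "gene", "polyphen_label", "polyphen_score", "sift_label", "sift_score",
            ],
        )


_COMBINED = re.compile(r"^\s*([A-Za-z_][\w\- ]*?)\s*\(\s*([^)]*)\s*\)\s*$")

_SAMPLE_COLS = ("tumor_sample_barcode", "sample", "sample_id", "patient")
_GENE_COLS = ("hugo_symbol", "gene", "gene_symbol", "symbol")
_PP_LABEL_COLS = ("polyphen", "polyphen_label", "polyphen_prediction")
_PP_SCORE_COLS = ("polyphen_score",)
_SIFT_LABEL_COLS = ("sift", "sift_label", "sift_prediction")
_SIFT_SCORE_COLS = ("sift_score",)


def _find_col(columns, candidates):
    lowered = {c.lower(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def _parse_annotation(label_val, score_val, where: str):
    """Split a possibly combined "label(score)" string into (label, score).

    A separate numeric score column wins over a score embedded in the label.
    An unparseable score leaves the score missing with a warning.
    """
    label = None
    score = None
    if label_val is not None and not (isinstance(label_val, float) and math.isnan(label_val)):
        text = str(label_val).strip()
        if text and text not in (".", "NA", "nan"):
            m = _COMBINED.match(text)
            if m:
                label = m.group(1).strip()
                try:
                    score = float(m.group(2))
                except ValueError:
                    logger.warning("unparseable score in %r at %s; kept with score missing", text, where)
            else:
                label = text
    if score_val is not None and not (isinstance(score_val, float) and math.isnan(score_val)):
        try:
            score = float(score_val)
        except (TypeError, ValueError):
            logger.warning("unparseable score %r at %s; kept with score missing", score_val, where)
    return label, score


def read_mutations(path) -> MutationTable:
    """Read a MAF-style TSV of per-sample somatic SNVs.

    Requires sample-ID, gene-symbol, PolyPhen and SIFT columns (common MAF
    header spellings are auto-detected). PolyPhen/SIFT cells may be either
    bare labels with separate ``*_score`` columns or combined
    ``label(score)`` strings; the dialect is detected per column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    sample_col = _find_col(df.columns, _SAMPLE_COLS)
    gene_col = _find_col(df.columns, _GENE_COLS)
    if sample_col is None or gene_col is None:
        raise ValueError(f"{path}: could not locate sample and gene columns (got {list(df.columns)})")
    pp_col = _find_col(df.columns, _PP_LABEL_COLS)
    pp_score_col = _find_col(df.columns, _PP_SCORE_COLS)
    sift_col = _find_col(df.columns, _SIFT_LABEL_COLS)
    sift_score_col = _find_col(df.columns, _SIFT_SCORE_COLS)
    if pp_col is None and sift_col is None:
        raise ValueError(f"{path}: neither a PolyPhen nor a SIFT column was found")

    records = []
    n_dropped = 0
    for i, row in df.iterrows():
        where = f"{path}:row {i + 2}"
        pl, ps = _parse_annotation(
            row[pp_col] if pp_col else None,
            row[pp_score_col] if pp_score_col else None,
            where,
        )
        sl, ss = _parse_annotation(
            row[sift_col] if sift_col else None,
            row[sift_score_col] if sift_score_col else None,
            where,
        )
        if pl is None and sl is None:
            n_dropped += 1
            continue
        records.append(
            MutationRecord(
                sample=str(row[sample_col]).strip(),
                gene=str(row[gene_col]).strip(),
                polyphen_label=pl,
                polyphen_score=ps,
                sift_label=sl,
                sift_score=ss,
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with no PolyPhen/SIFT annotation", path, n_dropped)
    return MutationTable(records)


def write_mutations(table: MutationTable, path) -> None:
    """Write a MAF-style TSV using combined ``label(score)`` cells."""

    def combined(label, score):
        if label is None:
            return ""
        if score is None:
            return label
        return f"{label}({score!r})"

    with open(path, "w") as fh:
        fh.write("Tumor_Sample_Barcode\tHugo_Symbol\tPolyPhen\tSIFT\n")
        for r in table.records:
            fh.write(
                f"{r.sample}\t{r.gene}\t"
                f"{combined(r.polyphen_label, r.polyphen_score)}\t"
                f"{combined(r.sift_label, r.sift_score)}\n"
            )


# ---------------------------------------------------------------------------
# gene lists and rankings
# ---------------------------------------------------------------------------

def read_gene_list(path) -> set:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def write_ranking(ranking, path, known_drivers: set | None = None) -> None:
    """Write a ranking as TSV with columns rank, gene, score, flag.

    ``ranking`` may be any object exposing ``to_frame()`` that yields
    columns (rank, gene, score, flag) — both per-patient and aggregate
    rankings do — or a DataFrame of that shape. Rank 1 is best. When a
    known-driver set is supplied an extra ``known_driver`` column is added.
    """
    df = ranking.to_frame() if hasattr(ranking, "to_frame") else ranking.copy()
    if known_drivers is not None:
        df = df.copy()
        df["known_driver"] = df["gene"].isin(known_drivers).map({True: "YES", False: "NO"})
    df.to_csv(path, sep="\t", index=False)


def read_ranking(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
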