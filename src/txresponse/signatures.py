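"""Gene sets (GMT), single-sample enrichment scores, marker abundance, overlap tests.

Single-sample scores stratify samples by the coordinate activity of a gene
set (e.g. the hallmark interferon-gamma response set, or the two tertiary
lymphoid structure signatures).  Scores are rank-based and comparable across
samples within one set, never across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .deg import bh_adjust
from .expression import NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: ``name TAB description TAB gene TAB gene ...`` per line."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=frozenset(genes), source=desc))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source or "na", *sorted(s.genes)]) + "\n")


def tls_signatures() -> list[GeneSet]:
    """The two bundled tertiary-lymphoid-structure signatures (9 and 7 genes)."""
    ref = resources.files("txresponse.data").joinpath("tls_signatures.gmt")
    with resources.as_file(ref) as path:
        return read_gmt(path)


def _ssgsea_sample(expr: np.ndarray, member: np.ndarray, alpha: float) -> float:
    """Weighted Kolmogorov–Smirnov running-sum score for one sample.

    Genes are ranked by expression (ties get the average rank); walking the
    list from the top-ranked gene down, member genes step the running sum up
    proportionally to rank**alpha, non-members step it down uniformly; the
    score is the sum of the running-sum deviations over all positions.
    """
    n = expr.size
    ranks = rankdata(expr)  # 1 = lowest expression
    order = np.argsort(-ranks, kind="mergesort")  # descending expression
    is_member = member[order]
    weights = ranks[order] ** alpha
    hit = np.where(is_member, weights, 0.0)
    hit_total = hit.sum()
    n_member = int(is_member.sum())
    miss = np.where(is_member, 0.0, 1.0 / (n - n_member))
    running = np.cumsum(hit / hit_total - miss)
    return float(running.sum())


def single_sample_score(
    matrix: NormalizedMatrix,
    gene_set: GeneSet,
    method: str = "ssgsea",
    alpha: float = 0.25,
    min_overlap: int = 3,
) -> pd.Series | None:
    """Per-sample enrichment score of one gene set.

    ``ssgsea``: rank-based weighted KS running-sum score (see
    :func:`_ssgsea_sample`).  ``mean_z``: per-gene z score across samples,
    averaged over member genes.  Sets overlapping the matrix by fewer than
    ``min_overlap`` genes are skipped (returns None with a warning).
    """
    present = matrix.gene_ids.intersection(sorted(gene_set.genes))
    if len(present) < min_overlap:
        logger.warning(
            "gene set %s: only %d/%d genes in matrix (< %d); skipped",
            gene_set.name, len(present), len(gene_set.genes), min_overlap,
        )
        return None
    values = matrix.values.to_numpy()
    member = np.asarray(matrix.gene_ids.isin(present))
    if method == "ssgsea":
        scores = np.array(
            [_ssgsea_sample(values[:, j], member, alpha) for j in range(values.shape[1])]
        )
    elif method == "mean_z":
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (values - mu) / sd
        scores = z[member].mean(axis=0)
    else:
        raise ValidationError(f"unknown scoring method {method!r}")
    return pd.Series(scores, index=matrix.sample_ids, name=gene_set.name)


def score_gene_sets(
    matrix: NormalizedMatrix,
    sets: list[GeneSet],
    method: str = "ssgsea",
    alpha: float = 0.25,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Score matrix (gene set x sample); sets failing the overlap filter are dropped."""
    rows = {}
    for s in sets:
        scores = single_sample_score(matrix, s, method=method, alpha=alpha,
                                     min_overlap=min_overlap)
        if scores is not None:
            rows[s.name] = scores
    return pd.DataFrame(rows).T


def marker_abundance(matrix: NormalizedMatrix, populations: list[GeneSet]) -> pd.DataFrame:
    """Marker-mean abundance of cell populations (population x sample).

    ``abundance[pop, s]`` is the arithmetic mean of the log2-CPM values of the
    population's marker genes present in the matrix; populations with no
    present marker are dropped with a warning.
    """
    rows = {}
    for pop in populations:
        present = matrix.gene_ids.intersection(sorted(pop.genes))
        if len(present) == 0:
            logger.warning("population %s: no marker present in matrix; dropped", pop.name)
            continue
        if pop.name in rows:
            raise ValidationError(f"duplicate population name {pop.name!r}")
        rows[pop.name] = matrix.values.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def overlap_enrichment(
    query,
    collection: list[GeneSet],
    universe,
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of a query gene list.

    Each collection set is intersected with the universe; the 2x2 table
    counts in-query x in-set membership over the universe, the p value is the
    one-sided (enrichment) Fisher exact probability, and q values are BH
    across the collection.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty query")
    stray = query - universe
    if stray:
        raise ValidationError(f"query genes outside universe: {sorted(stray)[:10]}")
    records = []
    for s in collection:
        members = s.genes & universe
        overlap = len(query & members)
        table = np.array(
            [
                [overlap, len(query) - overlap],
                [len(members) - overlap, len(universe) - len(query) - len(members) + overlap],
            ]
        )
        odds, p = stats.fisher_exact(table, alternative="greater")
        records.append((s.name, overlap, len(members), odds, p))
    out = pd.DataFrame(records, columns=["set", "overlap", "set_size", "odds_ratio", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.set_index("set")
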