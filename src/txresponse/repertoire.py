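"""Immune-receptor clonotype statistics: diversity, clonality, SHM lineages.

Clonotype tables are AIRR-style records (one row per CDR3 nucleotide sequence
per sample and chain, with V/J gene calls, an abundance count and a
productive flag).  B-cell heavy-chain (IGH) repertoires additionally carry
somatic-hypermutation (SHM) structure: sequences descending from one V(D)J
recombination event ("germline clone") differ by a few substitutions, so
lineages are recovered by single-linkage clustering of CDR3 nucleotide
sequences under normalized Hamming distance within each
(V gene, J gene, junction length) partition, cut at a threshold read off the
bimodal nearest-neighbor distance distribution.

The SHM occurrence frequency of a repertoire is the fraction of germline
clones carrying more than one distinct mature (post-SHM) sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde

from .expression import ValidationError

logger = logging.getLogger(__name__)

CHAINS = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRD", "TRG")
CLONOTYPE_COLUMNS = (
    "sample_id", "chain", "cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "count", "productive",
)

FALLBACK_THRESHOLD = 0.1


def read_clonotypes(path) -> pd.DataFrame:
    """Read an AIRR-style clonotype TSV with the required columns."""
    table = pd.read_csv(path, sep="\t", dtype={"cdr3_nt": str, "cdr3_aa": str})
    missing = [c for c in CLONOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"clonotype table missing columns: {missing}")
    bad_chain = sorted(set(table["chain"]) - set(CHAINS))
    if bad_chain:
        raise ValidationError(f"unknown chain labels: {bad_chain}")
    if (table["count"] < 1).any():
        raise ValidationError("clonotype counts must be >= 1")
    if (table["cdr3_nt"].str.len() == 0).any():
        raise ValidationError("empty cdr3_nt sequences")
    if table["productive"].dtype != bool:
        table["productive"] = table["productive"].astype(str).str.lower().isin(
            ("true", "t", "1", "yes")
        )
    return table


def write_clonotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def filter_productive(records: pd.DataFrame) -> pd.DataFrame:
    """Keep productive records whose CDR3aa has no stop (*) or frameshift (_) symbol."""
    keep = (
        records["productive"]
        & ~records["cdr3_aa"].fillna("").str.contains(r"[*_]", regex=True)
    )
    return records[keep].reset_index(drop=True)


def merge_convergent(records: pd.DataFrame) -> pd.DataFrame:
    """Merge convergent clonotypes (same CDR3aa, different CDR3nt) per sample/chain.

    Counts are summed; the representative nucleotide sequence is the
    highest-count member (ties broken lexicographically).
    """
    if records.empty:
        return records.copy()

    def _collapse(group: pd.DataFrame) -> pd.Series:
        best = group.sort_values(["count", "cdr3_nt"], ascending=[False, True]).iloc[0]
        out = best.copy()
        out["count"] = group["count"].sum()
        return out

    merged = (
        records.groupby(["sample_id", "chain", "cdr3_aa"], sort=False, group_keys=False)
        .apply(_collapse, include_groups=False)
        .reset_index()
    )
    return merged[list(records.columns)]


def diversity_metrics(counts, weight: str = "count") -> dict[str, float]:
    """Shannon diversity and clonality of a clone-size distribution.

    ``p_i = count_i / total``; ``H = -sum p_i ln p_i`` (nats);
    ``normalized_diversity = H / ln(richness)`` (Pielou evenness) for richness
    > 1, else 0; ``clonality = 1 - normalized_diversity`` (monoclonal
    convention: 1).  ``weight='clone'`` gives every clone equal weight.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValidationError("empty repertoire")
    if (counts <= 0).any():
        raise ValidationError("clone counts must be positive")
    if weight == "clone":
        counts = np.ones_like(counts)
    elif weight != "count":
        raise ValidationError(f"unknown weighting {weight!r}")
    richness = counts.size
    p = counts / counts.sum()
    shannon = float(-np.sum(p * np.log(p)))
    if richness > 1:
        normalized = shannon / np.log(richness)
    else:
        normalized = 0.0
    return {
        "richness": richness,
        "shannon": shannon,
        "normalized_diversity": normalized,
        "clonality": 1.0 - normalized,
    }


def _seq_matrix(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def _pairwise_hamming(seqs: list[str]) -> np.ndarray:
    arr = _seq_matrix(seqs)
    return (arr[:, None, :] != arr[None, :, :]).mean(axis=2)


@dataclass
class CloneLineage:
    """An inferred germline clone and its mature (SHM-derived) sequence set."""

    germline_clone_id: str
    v_gene: str
    j_gene: str
    junction_length: int
    mature_clones: frozenset[str]
    total_count: int
    record_indices: tuple[int, ...]

    @property
    def n_mature(self) -> int:
        return len(self.mature_clones)


def nearest_neighbor_distances(records: pd.DataFrame) -> np.ndarray:
    """Each sequence's nearest-neighbor normalized Hamming distance.

    Distances are computed within (V gene, J gene, junction length)
    partitions; singleton partitions contribute nothing.
    """
    out = []
    lengths = records["cdr3_nt"].str.len()
    for _, sub in records.groupby([records["v_gene"], records["j_gene"], lengths]):
        seqs = sub["cdr3_nt"].tolist()
        if len(seqs) < 2:
            continue
        d = _pairwise_hamming(seqs)
        np.fill_diagonal(d, np.inf)
        out.append(d.min(axis=1))
    if not out:
        return np.array([])
    return np.concatenate(out)


def detect_bimodal_threshold(
    distances: np.ndarray,
    fallback: float = FALLBACK_THRESHOLD,
    grid_size: int = 512,
) -> float:
    """Threshold at the density valley of a bimodal distance distribution.

    A Gaussian kernel density estimate (Silverman bandwidth) is evaluated on
    the pooled distances; the threshold is the local minimum of the density
    between its two highest local maxima.  If fewer than 20 observations are
    available or the density is unimodal, the conventional fallback (0.1
    normalized Hamming) is returned and the branch is logged.
    """
    distances = np.asarray(distances, dtype=float)
    distances = distances[np.isfinite(distances)]
    if distances.size < 20:
        logger.info("threshold: only %d distances (< 20); fallback %.3f",
                    distances.size, fallback)
        return fallback
    if np.ptp(distances) < 1e-12:
        logger.info("threshold: degenerate distance distribution; fallback %.3f", fallback)
        return fallback
    kde = gaussian_kde(distances, bw_method="silverman")
    lo = max(0.0, distances.min() - kde.factor * distances.std(ddof=1))
    hi = min(1.0, distances.max() + kde.factor * distances.std(ddof=1))
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    maxima = interior[is_max]
    if maxima.size < 2:
        logger.info("threshold: unimodal density; fallback %.3f", fallback)
        return fallback
    top_two = maxima[np.argsort(dens[maxima])[-2:]]
    left, right = int(top_two.min()), int(top_two.max())
    valley = left + int(np.argmin(dens[left:right + 1]))
    threshold = float(grid[valley])
    logger.info("threshold: bimodal valley at %.4f", threshold)
    return threshold


def find_threshold(records: pd.DataFrame, fallback: float = FALLBACK_THRESHOLD) -> float:
    """Automatic lineage-clustering threshold from a repertoire's distances."""
    return detect_bimodal_threshold(nearest_neighbor_distances(records), fallback=fallback)


def infer_lineages(records: pd.DataFrame, threshold="auto") -> list[CloneLineage]:
    """Group IGH records into germline clones by single-linkage clustering.

    Records are partitioned by (V gene, J gene, junction nucleotide length);
    within each partition, CDR3 nucleotide sequences are clustered by
    single linkage under normalized Hamming distance and the dendrogram is
    cut at ``threshold`` (or the automatic bimodal threshold).  Each cluster
    is one germline clone; its distinct nucleotide sequences are the mature
    clones.
    """
    if records.empty:
        return []
    non_igh = set(records["chain"]) - {"IGH"}
    if non_igh:
        raise ValidationError(f"lineage inference expects IGH records only, got {non_igh}")
    if threshold == "auto":
        threshold = find_threshold(records)
    threshold = float(threshold)
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    records = records.reset_index(drop=True)
    lineages: list[CloneLineage] = []
    lengths = records["cdr3_nt"].str.len()
    for (v, j, length), sub in records.groupby(
        [records["v_gene"], records["j_gene"], lengths], sort=True
    ):
        idx = sub.index.to_numpy()
        seqs = sub["cdr3_nt"].tolist()
        if len(seqs) == 1:
            labels = np.array([1])
        else:
            d = _pairwise_hamming(seqs)
            z = linkage(squareform(d, checks=False), method="single")
            labels = fcluster(z, t=threshold, criterion="distance")
        for k in np.unique(labels):
            members = idx[labels == k]
            member_rows = records.loc[members]
            lineages.append(
                CloneLineage(
                    germline_clone_id=f"{v}|{j}|{length}|{k}",
                    v_gene=v,
                    j_gene=j,
                    junction_length=int(length),
                    mature_clones=frozenset(member_rows["cdr3_nt"]),
                    total_count=int(member_rows["count"].sum()),
                    record_indices=tuple(int(i) for i in members),
                )
            )
    return lineages


def lineage_labels(lineages: list[CloneLineage], n_records: int) -> np.ndarray:
    """Per-record germline clone assignment (integer labels), for comparisons."""
    labels = np.full(n_records, -1)
    for k, lin in enumerate(lineages):
        labels[list(lin.record_indices)] = k
    if (labels < 0).any():
        raise ValidationError("lineages do not cover all records")
    return labels


def shm_frequency(lineages: list[CloneLineage]) -> float:
    """Fraction of germline clones with more than one mature clone."""
    if not lineages:
        raise ValidationError("no lineages")
    return sum(1 for lin in lineages if lin.n_mature >= 2) / len(lineages)


def novel_clone_fraction(pre: pd.DataFrame, post: pd.DataFrame) -> float:
    """Fraction of post-treatment clones (by CDR3aa) absent pre-treatment."""
    post_clones = set(post["cdr3_aa"])
    if not post_clones:
        raise ValidationError("empty post-treatment repertoire")
    pre_clones = set(pre["cdr3_aa"])
    return len(post_clones - pre_clones) / len(post_clones)


def repertoire_metrics(
    records: pd.DataFrame,
    lineage_threshold="auto",
    weight: str = "count",
) -> pd.DataFrame:
    """Per (sample, chain) richness, Shannon, evenness, clonality; SHM for IGH.

    Records are productive-filtered and convergent-merged first.  The SHM
    frequency column is filled for IGH repertoires only.
    """
    records = merge_convergent(filter_productive(records))
    rows = []
    for (sample, chain), sub in records.groupby(["sample_id", "chain"], sort=True):
        if sub.empty:
            continue
        metrics = diversity_metrics(sub["count"].to_numpy(), weight=weight)
        shm = np.nan
        if chain == "IGH":
            lineages = infer_lineages(sub.reset_index(drop=True), threshold=lineage_threshold)
            if lineages:
                shm = shm_frequency(lineages)
        rows.append({"sample_id": sample, "chain": chain, **metrics, "shm_frequency": shm})
    return pd.DataFrame(rows)
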