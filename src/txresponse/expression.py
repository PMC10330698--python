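"""Count-matrix handling: TMM normalization, log-CPM, batch centering, paired fold changes.

The cohorts analysed here are paired tumor biopsies: each patient contributes a
pre-treatment (PT) sample and one or more on-treatment (OT) samples, under one
of two therapies (immune checkpoint inhibition, ``ICI``, or MAPK-pathway
inhibition, ``MAPKi``), with a clinical response label on the OT biopsy
(responder ``R`` = CR/PR/SD, non-responder ``NR`` = PD).

The unit of all downstream differential statistics is the per-patient paired
log2 fold change between an OT sample and the patient's (averaged) PT
baseline, computed on TMM-normalized log2 counts-per-million.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

THERAPIES = ("ICI", "MAPKi")
TIMEPOINTS = ("PT", "OT")
RESPONSES = ("R", "NR", "unknown")

ANNOTATION_COLUMNS = ("patient_id", "therapy", "timepoint", "response", "batch")


class ValidationError(ValueError):
    """Raised when an input table violates the documented contract."""


@dataclass
class AnnotatedCounts:
    """Gene x sample raw counts with per-sample clinical annotation.

    ``counts`` is genes x samples (non-negative integers); ``annotation`` is
    indexed by sample id with columns patient_id, therapy, timepoint,
    response, batch.  Column order of ``counts`` matches the annotation index.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def validate(self) -> None:
        dup_genes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValidationError(f"duplicate gene ids: {dup_genes}")
        dup_samples = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValidationError(f"duplicate sample ids: {dup_samples}")
        missing = [s for s in self.counts.columns if s not in self.annotation.index]
        if missing:
            raise ValidationError(f"samples missing annotation: {missing}")
        for col in ANNOTATION_COLUMNS:
            if col not in self.annotation.columns:
                raise ValidationError(f"annotation missing required column {col!r}")
        bad_therapy = sorted(set(self.annotation["therapy"]) - set(THERAPIES))
        if bad_therapy:
            raise ValidationError(f"unknown therapy labels: {bad_therapy}")
        bad_tp = sorted(set(self.annotation["timepoint"]) - set(TIMEPOINTS))
        if bad_tp:
            raise ValidationError(f"unknown timepoint labels: {bad_tp}")
        bad_resp = sorted(set(self.annotation["response"]) - set(RESPONSES))
        if bad_resp:
            raise ValidationError(f"unknown response labels: {bad_resp}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if not np.all(np.isfinite(values)):
            raise ValidationError("counts contain non-finite values")
        if (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            offenders = [
                (self.counts.index[r], self.counts.columns[c])
                for r, c in zip(rows[:10], cols[:10])
            ]
            raise ValidationError(f"negative counts at (gene, sample): {offenders}")
        # keep annotation restricted to and ordered like the count columns
        self.annotation = self.annotation.loc[self.counts.columns]


@dataclass
class NormalizedMatrix:
    """log2 counts-per-million, genes x samples, with the TMM scaling factors."""

    values: pd.DataFrame
    tmm_factors: pd.Series
    effective_lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("normalized values contain non-finite entries")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class FoldChangeTable:
    """Per-(patient, OT sample) paired log2 fold changes.

    One column per retained OT sample; ``pairs`` is indexed by the OT sample
    id with columns patient_id, therapy, response (response in {R, NR}).
    """

    log2fc: pd.DataFrame
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.log2fc.columns) != list(self.pairs.index):
            raise ValidationError("fold-change columns and pair annotation disagree")
        bad = sorted(set(self.pairs["response"]) - {"R", "NR"})
        if bad:
            raise ValidationError(f"pair response labels must be R/NR, got {bad}")
        if not np.all(np.isfinite(self.log2fc.to_numpy())):
            raise ValidationError("fold changes contain non-finite entries")


def read_counts(counts_path, annotation_path) -> AnnotatedCounts:
    """Read a gene x sample counts TSV plus a sample annotation TSV.

    The counts file's first column holds gene ids; the annotation file is
    keyed by ``sample_id`` and must cover every count column.  Sample order is
    taken from the annotation file.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    annotation = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if "sample_id" not in annotation.columns:
        raise ValidationError("annotation TSV must have a sample_id column")
    annotation = annotation.set_index("sample_id")
    dup = annotation.index[annotation.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate sample ids in annotation: {dup}")
    missing = [s for s in counts.columns if s not in annotation.index]
    if missing:
        raise ValidationError(f"samples missing annotation: {missing}")
    extra = [s for s in annotation.index if s not in counts.columns]
    if extra:
        raise ValidationError(f"annotated samples absent from counts: {extra}")
    non_numeric = [c for c in counts.columns if not np.issubdtype(counts[c].dtype, np.number)]
    if non_numeric:
        raise ValidationError(f"non-numeric count columns: {non_numeric}")
    counts = counts[annotation.index.tolist()]
    return AnnotatedCounts(counts=counts, annotation=annotation)


def write_counts(data: AnnotatedCounts, counts_path, annotation_path) -> None:
    out = data.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    ann = data.annotation.copy()
    ann.index.name = "sample_id"
    ann.to_csv(annotation_path, sep="\t")


def _choose_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    # sample whose upper-quartile count fraction is closest to the mean one
    f75 = np.array(
        [np.quantile(counts[:, j], 0.75) / lib_sizes[j] for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
    weighted: bool,
) -> float:
    """Trimmed (weighted) mean of M-values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic binomial variance of M (delta method)
    var = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, var = m[finite], a[finite], var[finite]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not kept.any():
        return 1.0
    if weighted:
        f = np.sum(m[kept] / var[kept]) / np.sum(1.0 / var[kept])
    else:
        f = np.mean(m[kept])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_normalize(
    data: AnnotatedCounts,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    prior: float = 1.0,
    weighted: bool = True,
    reference: str | None = None,
) -> NormalizedMatrix:
    """TMM-normalize a count matrix and return log2 counts-per-million.

    Scaling factors are the trimmed weighted mean of per-gene M-values of each
    sample against a reference sample (chosen by upper-quartile closeness to
    the cohort mean unless ``reference`` names one), re-centered to geometric
    mean 1.  Genes with a zero count in either the reference or the test
    sample are excluded from that pair's trimmed mean.

    ``values[g, s] = log2(1e6 * count / (lib_size * factor) + prior)``.
    """
    counts = data.counts.to_numpy(dtype=float)
    n_genes, n_samples = counts.shape
    if n_samples < 2:
        raise ValidationError("TMM normalization needs at least 2 samples")
    lib_sizes = counts.sum(axis=0)
    zero_samples = data.sample_ids[lib_sizes == 0].tolist()
    if zero_samples:
        raise ValidationError(f"all-zero samples: {zero_samples}")
    if reference is None:
        ref_idx = _choose_reference(counts, lib_sizes)
    else:
        ref_idx = int(data.sample_ids.get_loc(reference))
    ref = counts[:, ref_idx]
    factors = np.array(
        [
            _pair_factor(
                counts[:, j], ref, lib_sizes[j], lib_sizes[ref_idx], trim_m, trim_a, weighted
            )
            for j in range(n_samples)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    effective = lib_sizes * factors
    values = np.log2(1e6 * counts / effective[np.newaxis, :] + prior)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=data.gene_ids, columns=data.sample_ids),
        tmm_factors=pd.Series(factors, index=data.sample_ids, name="tmm_factor"),
        effective_lib_sizes=pd.Series(effective, index=data.sample_ids, name="effective_lib_size"),
    )


def remove_batch(
    matrix: NormalizedMatrix,
    batch: pd.Series | list,
    preserve: pd.Series | list,
) -> NormalizedMatrix:
    """Subtract additive per-gene batch effects, preserving group differences.

    Per gene, expression is regressed on preserved-group indicators plus
    sum-to-zero-coded batch indicators; only the fitted batch component is
    subtracted, so the removed term has zero mean per gene over a balanced
    design and group contrasts are untouched.
    """
    samples = matrix.sample_ids
    batch = pd.Series(np.asarray(batch, dtype=object), index=samples)
    preserve = pd.Series(np.asarray(preserve, dtype=object), index=samples)
    batches = sorted(set(batch))
    if len(batches) < 2:
        return NormalizedMatrix(
            values=matrix.values.copy(),
            tmm_factors=matrix.tmm_factors.copy(),
            effective_lib_sizes=matrix.effective_lib_sizes.copy(),
        )
    groups = sorted(set(preserve))
    # group one-hot spans the intercept
    x_group = np.stack([(preserve == g).to_numpy(dtype=float) for g in groups], axis=1)
    # sum-to-zero contrasts: last batch = -1 in every column
    x_batch = np.zeros((len(samples), len(batches) - 1))
    for k, b in enumerate(batches[:-1]):
        x_batch[:, k] = np.where(batch == b, 1.0, np.where(batch == batches[-1], -1.0, 0.0))
    design = np.hstack([x_group, x_batch])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        tab = pd.crosstab(batch, preserve)
        raise ValidationError(
            "batch is confounded with the preserved groups; cannot separate "
            f"batch from group effects.\n{tab}"
        )
    y = matrix.values.to_numpy().T  # samples x genes
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    batch_component = x_batch @ coef[len(groups):, :]
    corrected = (y - batch_component).T
    return NormalizedMatrix(
        values=pd.DataFrame(corrected, index=matrix.gene_ids, columns=samples),
        tmm_factors=matrix.tmm_factors.copy(),
        effective_lib_sizes=matrix.effective_lib_sizes.copy(),
    )


def paired_log2fc(matrix: NormalizedMatrix, data: AnnotatedCounts) -> FoldChangeTable:
    """Per-patient paired log2 fold change of each OT sample against the PT mean.

    For each on-treatment sample ``o`` of patient ``p``,
    ``log2fc[g, o] = value[g, o] - mean over p's PT samples of value[g, .]``.
    Patients with several PT biopsies are collapsed by averaging their PT
    profiles; each OT sample yields its own fold-change column, inheriting
    the therapy and response labels of that OT biopsy.  OT samples whose
    patient lacks a PT baseline, or whose response is unknown, are skipped
    with a warning.
    """
    ann = data.annotation
    values = matrix.values
    pt_mean: dict[str, np.ndarray] = {}
    for patient, sub in ann[ann["timepoint"] == "PT"].groupby("patient_id"):
        pt_mean[patient] = values[sub.index.tolist()].mean(axis=1).to_numpy()
    cols: dict[str, np.ndarray] = {}
    meta = []
    for sample_id, row in ann[ann["timepoint"] == "OT"].iterrows():
        patient = row["patient_id"]
        if patient not in pt_mean:
            logger.warning(
                "skipping OT sample %s: patient %s has no PT sample", sample_id, patient
            )
            continue
        if row["response"] not in ("R", "NR"):
            logger.warning(
                "skipping OT sample %s: response %r is not R/NR", sample_id, row["response"]
            )
            continue
        cols[sample_id] = values[sample_id].to_numpy() - pt_mean[patient]
        meta.append(
            {
                "pair_id": sample_id,
                "patient_id": patient,
                "therapy": row["therapy"],
                "response": row["response"],
            }
        )
    if not cols:
        raise ValidationError("no valid (patient, OT sample) pairs found")
    log2fc = pd.DataFrame(cols, index=values.index)
    pairs = pd.DataFrame(meta).set_index("pair_id")
    return FoldChangeTable(log2fc=log2fc, pairs=pairs)
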