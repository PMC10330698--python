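"""Synthetic cohorts with the statistical structure the analysis assumes.

Three generators produce desk-scale stand-ins for the study's data arms,
each with stored ground truth for parameter-recovery testing:

* a two-therapy paired-biopsy expression cohort (negative-binomial counts,
  planted responder-specific fold changes, multiplicative batch offsets,
  patient-level baseline effects);
* a heavy-chain receptor repertoire with power-law clone sizes and somatic
  hypermutation lineages (per-base substitutions on a shared germline
  junction, stored lineage labels);
* exponential proportional-hazards survival with uniform censoring linked to
  supplied covariates.

All generators are pure functions of their config: the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import AnnotatedCounts, ValidationError

# the 61 sense codons (stop codons TAA, TAG, TGA excluded) keep junctions in frame
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


def _translate(nt: str) -> str:
    return "".join(_CODON_TABLE[nt[i:i + 3]] for i in range(0, len(nt), 3))


@dataclass
class PlantedEffect:
    """A block of genes with a responder-specific on-treatment fold change."""

    n_genes: int = 50
    delta: float = 2.0  # asymptotic responder-vs-non-responder log2 fold-change gap
    therapy: str = "ICI"
    direction: str = "up"  # "down" mirrors the sign


@dataclass
class CohortConfig:
    """Two-therapy paired-biopsy expression cohort parameters.

    ``n_per_arm`` patients per response arm (R / NR) per therapy, each with
    one pre-treatment and one on-treatment biopsy.  Negative-binomial counts
    with variance = mean + dispersion * mean^2.
    """

    n_per_arm: int = 20
    n_genes: int = 2000
    planted: tuple[PlantedEffect, ...] = (PlantedEffect(),)
    dispersion: float = 0.2
    batches: tuple[str, ...] = ("b1", "b2")
    batch_offsets: tuple[float, ...] = (0.0, 0.0)  # log2, per batch
    gene_batch_sd: float = 0.0  # log2 sd of gene-level batch wobble
    patient_effect_sd: float = 0.5  # log2 sd of per-(patient, gene) baseline shifts
    baseline_log_sd: float = 1.0  # log sd of gene baseline abundances
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    therapies: tuple[str, ...] = ("ICI", "MAPKi")
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm < 1 or self.n_genes < 1:
            raise ValidationError("cohort sizes must be >= 1")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if len(self.batch_offsets) != len(self.batches):
            raise ValidationError("one batch offset per batch required")
        total_planted = sum(p.n_genes for p in self.planted)
        if total_planted > self.n_genes:
            raise ValidationError("more planted genes than genes")
        for p in self.planted:
            if p.therapy not in self.therapies:
                raise ValidationError(f"planted therapy {p.therapy!r} not in cohort")
            if p.direction not in ("up", "down"):
                raise ValidationError(f"bad direction {p.direction!r}")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    n = 1.0 / phi
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_expression_cohort(config: CohortConfig) -> tuple[AnnotatedCounts, pd.DataFrame]:
    """Simulate the paired cohort; returns counts plus the planted-gene truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    baseline = np.exp(rng.normal(0.0, config.baseline_log_sd, size=config.n_genes))
    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])

    # assign disjoint gene blocks to the planted effects
    perm = rng.permutation(config.n_genes)
    truth_rows = []
    effect_of_gene: dict[int, tuple[str, float]] = {}
    cursor = 0
    for eff in config.planted:
        block = perm[cursor:cursor + eff.n_genes]
        cursor += eff.n_genes
        signed = eff.delta if eff.direction == "up" else -eff.delta
        for g in block:
            effect_of_gene[int(g)] = (eff.therapy, signed)
            truth_rows.append({"gene": gene_ids[g], "therapy": eff.therapy, "delta": signed})
    truth = pd.DataFrame(truth_rows, columns=["gene", "therapy", "delta"])

    gene_batch = {
        b: config.batch_offsets[k]
        + (rng.normal(0.0, config.gene_batch_sd, size=config.n_genes)
           if config.gene_batch_sd > 0 else 0.0)
        for k, b in enumerate(config.batches)
    }

    columns: dict[str, np.ndarray] = {}
    ann_rows = []
    batch_cycle = itertools.cycle(config.batches)
    for therapy in config.therapies:
        for response in ("R", "NR"):
            for i in range(config.n_per_arm):
                patient = f"{therapy}_{response}_{i:03d}"
                batch = next(batch_cycle)
                patient_shift = rng.normal(0.0, config.patient_effect_sd,
                                           size=config.n_genes)
                for timepoint in ("PT", "OT"):
                    sample = f"{patient}_{timepoint}"
                    log2_effect = patient_shift + gene_batch[batch]
                    if timepoint == "OT" and response == "R":
                        for g, (eff_therapy, delta) in effect_of_gene.items():
                            if eff_therapy == therapy:
                                log2_effect = log2_effect.copy()
                                log2_effect[g] += delta
                    rel = baseline * np.exp2(log2_effect)
                    lib = rng.uniform(*config.library_size_range)
                    mean = lib * rel / rel.sum()
                    columns[sample] = _nb_sample(rng, mean, config.dispersion)
                    ann_rows.append(
                        {
                            "sample_id": sample,
                            "patient_id": patient,
                            "therapy": therapy,
                            "timepoint": timepoint,
                            "response": response,
                            "batch": batch,
                        }
                    )
    counts = pd.DataFrame(columns, index=gene_ids)
    annotation = pd.DataFrame(ann_rows).set_index("sample_id")
    return AnnotatedCounts(counts=counts, annotation=annotation), truth


@dataclass
class RepertoireConfig:
    """Heavy-chain repertoire with power-law clone sizes and SHM lineages."""

    n_germline_clones: int = 200
    zipf_exponent: float = 2.0
    shm_probability: float = 0.3  # chance a germline clone carries SHM descendants
    shm_per_base_rate: float = 0.02  # per-base substitution probability
    descendants_range: tuple[int, int] = (2, 4)  # inclusive
    junction_length_range: tuple[int, int] = (36, 60)  # nt, multiples of 3
    v_pool: int = 10
    j_pool: int = 4
    sample_id: str = "S1"
    chain: str = "IGH"
    max_clone_size: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.shm_probability <= 1.0:
            raise ValidationError("shm_probability must lie in [0, 1]")
        if not 0.0 <= self.shm_per_base_rate <= 1.0:
            raise ValidationError("shm_per_base_rate must lie in [0, 1]")
        lo, hi = self.junction_length_range
        if lo % 3 or hi % 3 or lo < 3 or hi < lo:
            raise ValidationError("junction lengths must be positive multiples of 3")
        if self.n_germline_clones < 1 or self.v_pool < 1 or self.j_pool < 1:
            raise ValidationError("pool sizes must be >= 1")
        if self.zipf_exponent <= 1.0:
            raise ValidationError("zipf_exponent must exceed 1")


def _random_junction(rng: np.random.Generator, length: int) -> str:
    codons = rng.choice(len(_SENSE_CODONS), size=length // 3)
    return "".join(_SENSE_CODONS[c] for c in codons)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-base substitution at the given rate; stop-creating variants are resampled
    (nonproductive SHM variants are purged in vivo and would be productive-filtered)."""
    for _ in range(100):
        chars = list(seq)
        hits = np.nonzero(rng.random(len(chars)) < rate)[0]
        for i in hits:
            alternatives = [b for b in _BASES if b != chars[i]]
            chars[i] = alternatives[rng.integers(3)]
        mutated = "".join(chars)
        if "*" not in _translate(mutated):
            return mutated
    return seq


def simulate_repertoire(
    config: RepertoireConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a repertoire; returns (clonotype table, truth labels, metadata).

    The truth table has one row per clonotype record, in the same order as
    the clonotype table, with the germline clone each sequence descends
    from.  Metadata reports the realized and the analytic expected fraction
    of germline clones carrying more than one distinct mature sequence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.junction_length_range
    lengths_allowed = np.arange(lo, hi + 1, 3)
    records = []
    truth = []
    seen: set[str] = set()
    n_multi_expected = 0.0
    for clone_idx in range(config.n_germline_clones):
        v = f"IGHV{1 + rng.integers(config.v_pool)}"
        j = f"IGHJ{1 + rng.integers(config.j_pool)}"
        length = int(lengths_allowed[rng.integers(lengths_allowed.size)])
        junction = _random_junction(rng, length)
        while junction in seen:  # germline junctions unique by construction
            junction = _random_junction(rng, length)
        seen.add(junction)
        germline_id = f"GC{clone_idx:04d}"
        variants = {junction}

        def _emit(seq: str, origin: str) -> None:
            count = int(min(rng.zipf(config.zipf_exponent), config.max_clone_size))
            records.append(
                {
                    "sample_id": config.sample_id,
                    "chain": config.chain,
                    "cdr3_nt": seq,
                    "cdr3_aa": _translate(seq),
                    "v_gene": v,
                    "j_gene": j,
                    "count": count,
                    "productive": True,
                }
            )
            truth.append({"germline_clone": germline_id, "origin": origin})

        _emit(junction, "germline")
        has_shm = rng.random() < config.shm_probability
        k = 0
        if has_shm:
            k = int(rng.integers(config.descendants_range[0],
                                 config.descendants_range[1] + 1))
            for _ in range(k):
                descendant = _mutate(rng, junction, config.shm_per_base_rate)
                if descendant not in variants:
                    variants.add(descendant)
                    _emit(descendant, "descendant")
        n_multi_expected += config.shm_probability * (
            1.0 - (1.0 - config.shm_per_base_rate)
            ** (length * np.mean(config.descendants_range))
        )
    table = pd.DataFrame(records)
    truth = pd.DataFrame(truth)
    realized = (
        truth.assign(nt=table["cdr3_nt"])
        .groupby("germline_clone")["nt"].nunique()
    )
    metadata = {
        "true_multi_clone_fraction": float((realized >= 2).mean()),
        "expected_multi_clone_fraction": n_multi_expected / config.n_germline_clones,
        "n_records": len(table),
    }
    return table, truth, metadata


@dataclass
class SurvivalConfig:
    """Exponential proportional-hazards times with uniform censoring."""

    baseline_rate: float = 0.05  # events per month
    betas: dict = field(default_factory=lambda: {"x": 0.7})  # log hazard ratios
    censoring_window: float | None = 60.0  # months; None = no censoring
    n_subjects: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be positive")
        if self.censoring_window is not None and self.censoring_window <= 0:
            raise ValidationError("censoring window must be positive")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")


def simulate_survival(
    config: SurvivalConfig,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate survival records; returns (records, truth betas).

    Event times are exponential with rate ``baseline_rate * exp(x @ beta)``;
    censoring times are uniform over the window; the observed time is the
    minimum.  Standard-normal covariates are drawn when none are supplied.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = list(config.betas)
    if covariates is None:
        covariates = pd.DataFrame(
            rng.standard_normal((config.n_subjects, len(names))), columns=names
        )
    missing = [c for c in names if c not in covariates.columns]
    if missing:
        raise ValidationError(f"covariates missing columns: {missing}")
    n = len(covariates)
    beta = np.array([config.betas[c] for c in names])
    rate = config.baseline_rate * np.exp(covariates[names].to_numpy() @ beta)
    event_time = rng.exponential(1.0 / rate)
    if config.censoring_window is None:
        time, event = event_time, np.ones(n, dtype=int)
    else:
        censor = rng.uniform(0.0, config.censoring_window, size=n)
        time = np.minimum(event_time, censor)
        event = (event_time <= censor).astype(int)
    records = pd.DataFrame(
        {
            "subject_id": [f"P{i:04d}" for i in range(n)],
            "time": np.maximum(time, 1e-9),
            "event": event,
        }
    )
    records = pd.concat([records, covariates[names].reset_index(drop=True)], axis=1)
    return records, dict(config.betas)


def make_fixtures(out_dir, seed: int = 0, n_per_arm: int = 4, n_genes: int = 300) -> dict:
    """Write a complete miniature cohort (expression, repertoire, survival, gene sets).

    Emits the exact TSV/CSV dialects the analysis modules consume and returns
    the paths.  Intended for smoke tests and worked examples.
    """
    from pathlib import Path

    from .expression import write_counts
    from .repertoire import write_clonotypes
    from .signatures import GeneSet, tls_signatures, write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = CohortConfig(
        n_per_arm=n_per_arm,
        n_genes=n_genes,
        planted=(PlantedEffect(n_genes=10, delta=2.0, therapy="ICI"),),
        seed=seed,
    )
    data, truth = simulate_expression_cohort(cohort_cfg)
    write_counts(data, out / "counts.tsv", out / "annotation.tsv")
    truth.to_csv(out / "expression_truth.tsv", sep="\t", index=False)

    rep_cfg = RepertoireConfig(n_germline_clones=40, seed=seed + 1)
    table, rep_truth, _ = simulate_repertoire(rep_cfg)
    write_clonotypes(table, out / "clonotypes.tsv")
    rep_truth.to_csv(out / "repertoire_truth.tsv", sep="\t", index=False)

    surv_cfg = SurvivalConfig(
        n_subjects=40,
        betas={"feature1": -0.5, "feature2": -0.5},
        seed=seed + 2,
    )
    records, _ = simulate_survival(surv_cfg)
    records.to_csv(out / "survival.csv", index=False)

    planted = truth["gene"].tolist()
    sets = tls_signatures() + [
        GeneSet(name="planted_response_block", genes=frozenset(planted),
                source="synthetic planted responder genes"),
        GeneSet(name="random_markers",
                genes=frozenset(data.gene_ids[:5]), source="synthetic markers"),
    ]
    write_gmt(sets, out / "gene_sets.gmt")
    return {
        "counts": str(out / "counts.tsv"),
        "annotation": str(out / "annotation.tsv"),
        "clonotypes": str(out / "clonotypes.tsv"),
        "survival": str(out / "survival.csv"),
        "gene_sets": str(out / "gene_sets.gmt"),
    }
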