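"""End-to-end orchestration: normalize -> paired FC -> DEG/contrast -> scores ->
repertoire -> survival, with a JSON run manifest.

Every stage reads files, writes new files into the output directory and never
mutates its inputs; re-running with an identical config and inputs reproduces
byte-identical outputs.  Optional inputs (gene sets, clonotypes, survival)
skip their stage with a recorded reason instead of failing the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, deg, expression, repertoire, signatures, survival

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str = ""
    annotation: str = ""
    gene_sets: str | None = None
    marker_sets: str | None = None
    clonotypes: str | None = None
    survival: str | None = None
    out_dir: str = "txresponse_out"
    fc_threshold: float = 1.0
    q_threshold: float = 0.05
    ddfc_threshold: float = 1.0
    within_threshold: float = 1.0
    clone_threshold: str | float = "auto"
    score_method: str = "ssgsea"
    min_overlap: int = 3
    stratify_features: tuple[str, str] = ("feature1", "feature2")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - known
        if stray:
            raise expression.ValidationError(f"unknown config keys: {sorted(stray)}")
        if "stratify_features" in raw:
            raw["stratify_features"] = tuple(raw["stratify_features"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stratify_features"] = list(self.stratify_features)
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.data = {
            "package": "txresponse",
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "stages": [],
        }

    def record(self, name: str, status: str, outputs=(), n_rows=None, reason=None):
        self.data["stages"].append(
            {
                "stage": name,
                "status": status,
                "outputs": [str(p) for p in outputs],
                "n_rows": n_rows,
                "reason": reason,
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    A failing mandatory stage halts the run after recording the failure; the
    manifest is always written to ``<out_dir>/manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    manifest_path = out / "manifest.json"
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:
        manifest.record("pipeline", "failed", reason=f"{type(exc).__name__}: {exc}")
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest.data


def _run_stages(config: PipelineConfig, out: Path, manifest: _Manifest) -> None:
    # 1. normalize
    data = expression.read_counts(config.counts, config.annotation)
    norm = expression.tmm_normalize(data)
    if data.annotation["batch"].nunique() > 1:
        norm = expression.remove_batch(
            norm,
            batch=data.annotation["batch"],
            preserve=data.annotation["therapy"] + ":" + data.annotation["timepoint"]
            + ":" + data.annotation["response"],
        )
    norm_path = out / "normalized_log2cpm.tsv"
    norm.to_tsv(norm_path)
    manifest.record("normalize", "completed", [norm_path], n_rows=len(norm.values))

    # 2. paired fold changes
    fc = expression.paired_log2fc(norm, data)
    fc_path = out / "paired_log2fc.tsv"
    pairs_path = out / "pairs.tsv"
    fc.log2fc.rename_axis("gene").to_csv(fc_path, sep="\t")
    fc.pairs.rename_axis("pair_id").to_csv(pairs_path, sep="\t")
    manifest.record("paired_fc", "completed", [fc_path, pairs_path],
                    n_rows=fc.log2fc.shape[1])

    # 3. per-therapy responder contrast
    results = {}
    deg_paths = []
    for therapy in sorted(fc.pairs["therapy"].unique()):
        res = deg.delta_fc_test(fc, therapy, fc_threshold=config.fc_threshold,
                                q_threshold=config.q_threshold)
        results[therapy] = res
        path = out / f"deg_{therapy}.tsv"
        res.to_tsv(path)
        deg_paths.append(path)
    manifest.record("deg", "completed", deg_paths,
                    n_rows=sum(len(r.table) for r in results.values()))

    # 4. cross-therapy contrast + classification
    if len(results) == 2:
        (ta, ra), (tb, rb) = sorted(results.items())
        contrast = deg.cross_therapy_contrast(
            ra, rb, ddfc_threshold=config.ddfc_threshold,
            within_threshold=config.within_threshold,
        )
        contrast_path = out / "cross_therapy_contrast.tsv"
        contrast.table.rename_axis("gene").to_csv(contrast_path, sep="\t")
        classes = deg.classify_degs(ra.up_genes, rb.up_genes)
        class_path = out / "deg_classification.tsv"
        classes.to_frame().to_csv(class_path, sep="\t", index=False)
        manifest.record("contrast", "completed", [contrast_path, class_path],
                        n_rows=len(contrast.table))
    else:
        manifest.record("contrast", "skipped", reason="fewer than two therapies")

    # 5. gene-set scores and marker abundance
    if config.gene_sets:
        sets = signatures.read_gmt(config.gene_sets)
        scores = signatures.score_gene_sets(norm, sets, method=config.score_method,
                                            min_overlap=config.min_overlap)
        score_path = out / "gene_set_scores.tsv"
        scores.rename_axis("gene_set").to_csv(score_path, sep="\t")
        outputs = [score_path]
        if config.marker_sets:
            markers = signatures.read_gmt(config.marker_sets)
            abundance = signatures.marker_abundance(norm, markers)
            ab_path = out / "population_abundance.tsv"
            abundance.rename_axis("population").to_csv(ab_path, sep="\t")
            outputs.append(ab_path)
        manifest.record("score", "completed", outputs, n_rows=len(scores))
    else:
        manifest.record("score", "skipped", reason="no gene sets supplied")

    # 6. repertoire metrics
    if config.clonotypes:
        table = repertoire.read_clonotypes(config.clonotypes)
        metrics = repertoire.repertoire_metrics(table,
                                                lineage_threshold=config.clone_threshold)
        rep_path = out / "repertoire_metrics.tsv"
        metrics.to_csv(rep_path, sep="\t", index=False)
        manifest.record("repertoire", "completed", [rep_path], n_rows=len(metrics))
    else:
        manifest.record("repertoire", "skipped", reason="no clonotype table supplied")

    # 7. survival stratification
    if config.survival:
        records = survival.read_survival(config.survival)
        f1, f2 = config.stratify_features
        missing = [c for c in (f1, f2) if c not in records.columns]
        if missing:
            manifest.record("survival", "skipped",
                            reason=f"missing stratification features: {missing}")
        else:
            res = survival.joint_strata_analysis(
                records, records[f1], records[f2], feature_names=(f1, f2)
            )
            strata_path = out / "survival_strata.tsv"
            pd.DataFrame(
                {"subject_id": records["subject_id"], "stratum": res.labels}
            ).to_csv(strata_path, sep="\t", index=False)
            outputs = [strata_path]
            summary = {
                "n_groups": res.n_groups,
                "logrank_statistic": res.logrank_statistic,
                "logrank_p": res.logrank_p,
            }
            if res.interaction_fit is not None:
                cox_path = out / "survival_interaction_cox.tsv"
                res.interaction_fit.to_tsv(cox_path)
                outputs.append(cox_path)
            summary_path = out / "survival_summary.json"
            summary_path.write_text(json.dumps(summary, indent=2) + "\n")
            outputs.append(summary_path)
            manifest.record("survival", "completed", outputs, n_rows=len(records))
    else:
        manifest.record("survival", "skipped", reason="no survival table supplied")
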