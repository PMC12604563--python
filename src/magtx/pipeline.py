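"""End-to-end orchestration from a single YAML config.

One run executes: (optional) dereplication -> activity profiling and
active-MAG selection -> marker normalization -> per-MAG consensus DE
for each configured contrast -> (optional) KO-level MAG-vs-MAG
comparison -> pathway-panel report, and writes a manifest recording
inputs, the config hash, and the row count of every emitted table so
a re-run can be checked byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .detest import de_pipeline, make_contrast
from .kopath import aggregate_ko, compare_mags_ko, panel_summary
from .mags import dereplicate, mag_activity, mean_proportions_by_day, select_active_mags
from .normalize import NormalizationConfig, normalize_pipeline
from .types import CountMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    counts: str
    annotations: str
    markers: str
    sheet: str
    outdir: str
    quality: str | None = None
    ani: str | None = None
    panels: str | None = None
    ani_threshold: float = 97.0
    min_proportion: float = 0.05
    min_breadth: float = 0.5
    selection_rule: str = "all_samples"
    contrasts: list[dict] = field(
        default_factory=lambda: [
            {"condition_a": "low_p", "condition_b": "high_p", "phase": "feeding"},
            {"condition_a": "low_p", "condition_b": "high_p", "phase": "aerobic"},
        ]
    )
    alpha: float = 0.01
    min_methods: int = 2
    compare_mags: list[list[str]] = field(default_factory=list)
    normalization: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> int:
    df.to_csv(path, sep="\t", index=index)
    return len(df)


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.__dict__.copy(), "tables": {}}
    cfg_bytes = json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    manifest["config_sha256"] = hashlib.sha256(cfg_bytes).hexdigest()

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = outdir / f"{name}.tsv"
        manifest["tables"][name] = {"path": str(path), "rows": _write(df, path, index=index)}

    try:
        catalog, counts, sheet = mio.load_dataset(
            config.counts, config.annotations, config.markers, config.sheet,
            quality_path=config.quality,
        )
    except (ValidationError, FileNotFoundError) as err:
        raise ValidationError(f"[load] {err}") from err

    if config.ani is not None:
        ani = mio.load_ani_matrix(config.ani)
        derep = dereplicate(ani, catalog.mags, threshold=config.ani_threshold)
        emit(
            "dereplication_clusters",
            pd.DataFrame(
                [
                    {"cluster": i, "genome_id": g, "representative": derep.representatives[i]}
                    for i, cluster in enumerate(derep.clusters)
                    for g in sorted(cluster)
                ]
            ),
            index=False,
        )

    activity = mag_activity(counts, catalog)
    emit("mag_activity", activity.table.reset_index(), index=False)
    emit("mag_day_means", mean_proportions_by_day(activity, sheet))
    selected = select_active_mags(
        activity, config.min_proportion, config.min_breadth, config.selection_rule
    )
    if not selected:
        raise ValidationError("[select] no MAGs selected at the configured thresholds")
    manifest["selected_mags"] = sorted(selected)

    keep_genes = [g.gene_id for g in catalog.genes if g.mag_id in selected]
    sub_counts = CountMatrix(
        values=counts.values.loc[[g for g in counts.gene_ids if g in set(keep_genes)]],
        stage="raw",
    )
    norm_cfg = NormalizationConfig(**config.normalization)
    try:
        rescaled = normalize_pipeline(sub_counts, catalog, sheet, norm_cfg)
    except ValidationError as err:
        raise ValidationError(f"[normalize] {err}") from err
    emit("rescaled", rescaled.values.rename_axis("gene_id"))

    gt = catalog.gene_table()
    de_tables: dict[str, pd.DataFrame] = {}
    for spec in config.contrasts:
        phase = spec["phase"]
        contrast = make_contrast(
            sheet, phase, spec.get("condition_a", "low_p"), spec.get("condition_b", "high_p")
        )
        for mag in sorted(selected):
            genes = [g for g in rescaled.gene_ids if gt.loc[g, "mag_id"] == mag]
            if not genes:
                continue
            sub = rescaled.values.loc[genes]
            table = de_pipeline(sub, sheet, contrast, config.alpha, config.min_methods)
            table.insert(0, "ko", gt.loc[table.index, "ko"])
            label = f"de_{mag}_{phase}"
            emit(label, table.rename_axis("gene_id"))
            de_tables[f"{mag}:{phase}"] = table

    if config.compare_mags:
        profile = aggregate_ko(rescaled, catalog)
        for mag_a, mag_b in config.compare_mags:
            for phase in sorted({c["phase"] for c in config.contrasts}):
                for cond in sheet.table["condition"].unique():
                    samples = sheet.samples_in(condition=cond, phase=phase)
                    res, private = compare_mags_ko(
                        profile, mag_a, mag_b, samples, alpha=config.alpha
                    )
                    tag = f"{mag_a}_vs_{mag_b}_{cond}_{phase}"
                    emit(f"ko_compare_{tag}", res.rename_axis("ko"))
                    emit(f"ko_private_{mag_a}_vs_{mag_b}", private, index=False)

    if config.panels is not None:
        panels = mio.load_pathway_panels(config.panels)
        phase_tables = {
            phase: pd.concat(
                [t for key, t in de_tables.items() if key.endswith(f":{phase}")]
            )
            for phase in sorted({c["phase"] for c in config.contrasts})
            if any(key.endswith(f":{phase}") for key in de_tables)
        }
        summary = panel_summary(rescaled, phase_tables, panels, catalog, sheet)
        emit("panel_summary", summary, index=False)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("run complete: %d tables in %s", len(manifest["tables"]), outdir)
    return manifest
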