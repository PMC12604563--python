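"""Readers and writers for the pipeline's tabular formats.

All inputs are plain TSV. The count table follows the featureCounts
dialect (``Geneid``, a MAG column, ``Length``, then one column per
sample; ``#`` comment lines skipped). Identifiers are case-sensitive
and never trimmed beyond line ends. All cross-references between the
count table, annotations, marker table and sample sheet are validated
on load; a gene present in the counts but missing from the annotations
is an error, as is a count column not named in the sample sheet.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    KO_PATTERN,
    AniMatrix,
    CountMatrix,
    GeneRecord,
    MagCatalog,
    MagRecord,
    PathwayPanel,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str}, **kwargs)


def _opt(value) -> str | None:
    """NaN/empty -> None for optional string columns."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return str(value)


def load_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_tsv(path)
    required = ["sample_id", "condition", "phase", "cycle", "day"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["cycle"] = df["cycle"].astype(int)
    df["day"] = df["day"].astype(int)
    return SampleSheet(df[required].copy())


def load_annotations(path: str | Path, markers_path: str | Path) -> list[GeneRecord]:
    ann = _read_tsv(path)
    required = ["gene_id", "mag_id", "length_bp"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotations missing columns: {missing}")
    mk = _read_tsv(markers_path)
    for col in ("gene_id", "mag_id", "cog_id"):
        if col not in mk.columns:
            raise ValidationError(f"markers table missing column: {col}")
    marker_of = dict(zip(mk["gene_id"].astype(str), mk["cog_id"].astype(str)))

    genes = []
    for row in ann.itertuples(index=False):
        gid = str(row.gene_id)
        genes.append(
            GeneRecord(
                gene_id=gid,
                mag_id=str(row.mag_id),
                length_bp=int(row.length_bp),
                ko=_opt(getattr(row, "ko", None)),
                product=_opt(getattr(row, "product", None)),
                marker_cog=marker_of.get(gid),
            )
        )
    unknown_markers = set(marker_of) - {g.gene_id for g in genes}
    if unknown_markers:
        raise ValidationError(
            f"marker table references unannotated genes: {sorted(unknown_markers)[:5]}"
        )
    return genes


def load_mag_quality(path: str | Path) -> list[MagRecord]:
    """CheckM-style quality table: mag_id, taxon_label, completeness,
    contamination, n_contigs, n_markers_present."""
    df = _read_tsv(path)
    if "mag_id" not in df.columns:
        raise ValidationError("quality table missing column: mag_id")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MagRecord(
                mag_id=str(row.mag_id),
                taxon_label=str(getattr(row, "taxon_label", "") or ""),
                completeness=float(getattr(row, "completeness", 100.0)),
                contamination=float(getattr(row, "contamination", 0.0)),
                n_contigs=int(getattr(row, "n_contigs", 1)),
                n_markers_present=int(getattr(row, "n_markers_present", 0)),
            )
        )
    return records


def load_counts(path: str | Path, sheet: SampleSheet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a featureCounts-style TSV.

    Returns (counts gene x sample, meta with MAG and Length columns).
    """
    df = _read_tsv(path)
    if "Geneid" not in df.columns or "Length" not in df.columns:
        raise ValidationError("count table must have Geneid and Length columns")
    mag_col = df.columns[1]  # featureCounts puts the Chr-like column second
    meta_cols = ["Geneid", mag_col, "Length"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    unknown = set(sample_cols) - set(sheet.sample_ids)
    if unknown:
        raise ValidationError(f"unknown sample in counts: {sorted(unknown)}")
    absent = set(sheet.sample_ids) - set(sample_cols)
    if absent:
        raise ValidationError(f"samples in sheet missing from counts: {sorted(absent)}")
    if df["Geneid"].duplicated().any():
        dups = df.loc[df["Geneid"].duplicated(), "Geneid"].tolist()
        raise ValidationError(f"duplicate gene ids in counts: {dups[:5]}")
    counts = df.set_index("Geneid")[sheet.sample_ids]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.allclose(arr, np.round(arr)):
        raise ValidationError("count column not integer")
    meta = df.set_index("Geneid")[[mag_col, "Length"]]
    meta.columns = ["mag_id", "length_bp"]
    counts = counts.astype(np.int64)
    counts.index.name = "gene_id"
    meta.index.name = "gene_id"
    return counts, meta


def load_dataset(
    counts_path: str | Path,
    annotations_path: str | Path,
    markers_path: str | Path,
    sheet_path: str | Path,
    quality_path: str | Path | None = None,
) -> tuple[MagCatalog, CountMatrix, SampleSheet]:
    """Load and cross-validate a full dataset.

    Genes appearing in the count table but absent from the annotations
    are a hard error; so are samples absent from the sheet. When no
    quality table is given, MAG records carry neutral quality values
    (dereplication takes its own quality input).
    """
    sheet = load_sample_sheet(sheet_path)
    genes = load_annotations(annotations_path, markers_path)
    counts, meta = load_counts(counts_path, sheet)

    known = {g.gene_id for g in genes}
    orphans = [g for g in counts.index if g not in known]
    if orphans:
        raise ValidationError(f"genes in counts missing from annotations: {orphans[:5]}")

    mag_ids = sorted({g.mag_id for g in genes})
    n_markers = {m: 0 for m in mag_ids}
    for g in genes:
        if g.is_marker:
            n_markers[g.mag_id] += 1
    if quality_path is not None:
        mags = load_mag_quality(quality_path)
        covered = {m.mag_id for m in mags}
        if set(mag_ids) - covered:
            raise ValidationError(f"quality table missing MAGs: {sorted(set(mag_ids) - covered)}")
    else:
        mags = [
            MagRecord(mag_id=m, taxon_label=m, n_markers_present=n_markers[m]) for m in mag_ids
        ]
    catalog = MagCatalog(mags=mags, genes=genes)
    # keep count rows in annotation order for determinism
    order = [g.gene_id for g in genes if g.gene_id in set(counts.index)]
    matrix = CountMatrix(values=counts.loc[order], stage="raw")
    return catalog, matrix, sheet


def load_ani_matrix(path: str | Path) -> AniMatrix:
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"ANI table not square: {df.shape}")
    if set(df.index) != set(df.columns):
        raise ValidationError("ANI row/column label sets differ")
    df = df.loc[df.index, df.index]  # align column order to rows
    diag = np.diag(df.to_numpy(dtype=float))
    if not np.allclose(diag, 100.0):
        logger.warning("ANI diagonal not 100 (min %.3f); coercing to 100", diag.min())
    return AniMatrix(values=df)


def load_pathway_panels(path: str | Path) -> list[PathwayPanel]:
    """Panels from YAML (``panel: [{ko, symbol}, ...]`` or ``panel: {ko: symbol}``)
    or TSV (panel_name, ko, symbol). Duplicate KOs within a panel are
    kept once, order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw: list[tuple[str, str, str]] = []
    if path.suffix in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError("panel YAML must map panel names to KO entries")
        for panel, entries in data.items():
            if isinstance(entries, dict):
                for ko, sym in entries.items():
                    raw.append((str(panel), str(ko), str(sym)))
            else:
                for e in entries:
                    if isinstance(e, dict):
                        raw.append((str(panel), str(e["ko"]), str(e.get("symbol", ""))))
                    else:
                        raw.append((str(panel), str(e), ""))
    else:
        df = _read_tsv(path)
        for col in ("panel_name", "ko"):
            if col not in df.columns:
                raise ValidationError(f"panel TSV missing column: {col}")
        for row in df.itertuples(index=False):
            raw.append((str(row.panel_name), str(row.ko), str(getattr(row, "symbol", "") or "")))

    panels: dict[str, list[tuple[str, str]]] = {}
    seen: dict[str, set[str]] = {}
    for panel, ko, sym in raw:
        if not KO_PATTERN.match(ko):
            raise ValidationError(f"panel {panel!r}: malformed KO id {ko!r}")
        if ko in seen.setdefault(panel, set()):
            logger.warning("panel %s: duplicate KO %s kept once", panel, ko)
            continue
        seen[panel].add(ko)
        panels.setdefault(panel, []).append((ko, sym))
    return [PathwayPanel(panel_name=name, entries=entries) for name, entries in panels.items()]


# ---------------------------------------------------------------- writers


def write_counts(matrix: CountMatrix, catalog: MagCatalog, path: str | Path) -> None:
    """Write a featureCounts-style table (raw stage) or a plain value TSV."""
    gt = catalog.gene_table()
    df = matrix.values.copy()
    out = pd.DataFrame(
        {
            "Geneid": df.index,
            "MAG": gt.loc[df.index, "mag_id"].to_numpy(),
            "Length": gt.loc[df.index, "length_bp"].to_numpy(),
        }
    )
    for col in df.columns:
        out[col] = df[col].to_numpy()
    with open(path, "w") as fh:
        fh.write("# magtx count table\n")
        out.to_csv(fh, sep="\t", index=False)


def write_annotations(catalog: MagCatalog, path: str | Path) -> None:
    gt = catalog.gene_table().reset_index()
    gt[["gene_id", "mag_id", "length_bp", "ko", "product"]].to_csv(path, sep="\t", index=False)


def write_markers(catalog: MagCatalog, path: str | Path) -> None:
    rows = [
        {"gene_id": g.gene_id, "mag_id": g.mag_id, "cog_id": g.marker_cog}
        for g in catalog.genes
        if g.is_marker
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def write_quality(catalog: MagCatalog, path: str | Path) -> None:
    rows = [
        {
            "mag_id": m.mag_id,
            "taxon_label": m.taxon_label,
            "completeness": m.completeness,
            "contamination": m.contamination,
            "n_contigs": m.n_contigs,
            "n_markers_present": m.n_markers_present,
        }
        for m in catalog.mags
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dataset(
    catalog: MagCatalog, matrix: CountMatrix, sheet: SampleSheet, outdir: str | Path
) -> dict[str, Path]:
    """Write the four dataset files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "annotations": outdir / "annotations.tsv",
        "markers": outdir / "markers.tsv",
        "sheet": outdir / "samples.tsv",
        "quality": outdir / "mag_quality.tsv",
    }
    write_counts(matrix, catalog, paths["counts"])
    write_annotations(catalog, paths["annotations"])
    write_markers(catalog, paths["markers"])
    write_sample_sheet(sheet, paths["sheet"])
    write_quality(catalog, paths["quality"])
    return paths
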