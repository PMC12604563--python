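"""Universal-marker-gene normalization to relative copies per cell.

The chain, applied per MAG independently:

1. filter: drop genes whose raw count reaches ``min_count`` in fewer
   than k samples, k being the size of the smallest (condition, phase)
   group — marker genes are always kept so the divisor below exists;
2. impute: replace remaining zeros by 0.5;
3. length-normalize: counts / (length / 1000)  (reads per kilobase);
4. marker-normalize: divide every gene's RPK by the per-sample median
   RPK of that MAG's 10 single-copy universal marker genes. Because a
   single-copy constitutive gene is transcribed at ~1 copy per cell,
   the ratio estimates the relative transcript copies per cell, which
   cancels both sequencing depth and the MAG's abundance in the
   community;
5. rescale: divide by the MAG's global maximum and multiply by 1e9,
   yielding integer-sized pseudo-counts for count-based tests.

Marker medians are computed on length-normalized values: dividing raw
counts by raw marker counts would leave a gene-length bias in place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .simulate import DEFAULT_MARKER_COGS
from .types import CountMatrix, MagCatalog, SampleSheet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormalizationConfig:
    min_count: int = 15
    impute_value: float = 0.5
    rescale_factor: float = 1e9
    min_markers: int = 6
    marker_cogs: tuple[str, ...] = field(default=DEFAULT_MARKER_COGS)

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValidationError("min_count must be >= 0")
        if self.impute_value <= 0:
            raise ValidationError("impute_value must be > 0")
        if self.min_markers > len(self.marker_cogs):
            raise ValidationError("min_markers exceeds the marker set size")


def _reorder(vals: pd.DataFrame, original_index) -> pd.DataFrame:
    kept = set(vals.index)
    return vals.loc[[g for g in original_index if g in kept]]


def filter_low_counts(
    counts: CountMatrix,
    sheet: SampleSheet,
    config: NormalizationConfig | None = None,
    catalog: MagCatalog | None = None,
) -> CountMatrix:
    """Keep genes with raw count >= min_count in at least k samples,
    k = size of the smallest (condition, phase) group.

    When a catalog is given, its marker genes are exempt from the
    filter (they must survive to serve as the normalization divisor).
    """
    config = config or NormalizationConfig()
    if counts.stage != "raw":
        raise ValidationError(f"filter expects raw counts, got {counts.stage!r}")
    sizes = sheet.group_sizes()
    if not sizes:
        raise ValidationError("sample sheet defines no groups")
    k = min(sizes.values())
    keep = (counts.values >= config.min_count).sum(axis=1) >= k
    if catalog is not None:
        gt = catalog.gene_table()
        keep = keep | gt.loc[counts.values.index, "marker_cog"].notna()
    kept = counts.values.loc[keep]
    if kept.empty:
        raise ValidationError("all genes removed by the low-count filter")
    return counts.with_stage(kept.astype(float), "filtered")


def impute_zeros(counts: CountMatrix, config: NormalizationConfig | None = None) -> CountMatrix:
    """Replace zeros by impute_value (0.5); other cells untouched."""
    config = config or NormalizationConfig()
    if counts.stage != "filtered":
        raise ValidationError(f"impute expects filtered counts, got {counts.stage!r}")
    vals = counts.values.astype(float)
    vals = vals.mask(vals == 0, config.impute_value)
    return counts.with_stage(vals, "imputed")


def length_normalize(counts: CountMatrix, catalog: MagCatalog) -> CountMatrix:
    """Reads per kilobase: value / (length_bp / 1000)."""
    if counts.stage != "imputed":
        raise ValidationError(f"length_normalize expects imputed counts, got {counts.stage!r}")
    gt = catalog.gene_table()
    missing = set(counts.values.index) - set(gt.index)
    if missing:
        raise ValidationError(f"missing length for genes: {sorted(missing)[:5]}")
    len_kb = gt.loc[counts.values.index, "length_bp"].to_numpy(dtype=float) / 1000.0
    vals = counts.values.div(len_kb, axis=0)
    return counts.with_stage(vals, "rpk")


def marker_normalize(
    rpk: CountMatrix,
    catalog: MagCatalog,
    config: NormalizationConfig | None = None,
) -> CountMatrix:
    """Divide each gene's RPK by the per-sample median marker RPK of
    its MAG.

    MAGs with fewer than ``min_markers`` marker genes present in the
    matrix cannot be anchored to a per-cell scale; they are dropped
    with a warning rather than silently mis-normalized.
    """
    config = config or NormalizationConfig()
    if rpk.stage != "rpk":
        raise ValidationError(f"marker_normalize expects rpk stage, got {rpk.stage!r}")
    gt = catalog.gene_table()
    mag_of = gt.loc[rpk.values.index, "mag_id"]
    is_marker = gt.loc[rpk.values.index, "marker_cog"].notna()

    blocks = []
    for mag, idx in rpk.values.groupby(mag_of).groups.items():
        sub = rpk.values.loc[idx]
        markers = sub.loc[is_marker.loc[idx]]
        if len(markers) < config.min_markers:
            logger.warning(
                "MAG %s: only %d marker genes with data (< %d); excluded as unquantifiable",
                mag, len(markers), config.min_markers,
            )
            continue
        med = markers.median(axis=0)
        if (med <= 0).any():
            raise ValidationError(f"MAG {mag}: non-positive marker median")
        blocks.append(sub.div(med, axis=1))
    if not blocks:
        raise ValidationError("no MAG passed the marker-count requirement")
    return rpk.with_stage(_reorder(pd.concat(blocks), rpk.values.index), "marker_norm")


def rescale_per_mag(
    marker_norm: CountMatrix,
    catalog: MagCatalog,
    config: NormalizationConfig | None = None,
) -> CountMatrix:
    """Scale each MAG block so its global maximum (over all genes and
    samples of that MAG) equals rescale_factor; within-MAG ratios are
    preserved exactly."""
    config = config or NormalizationConfig()
    if marker_norm.stage != "marker_norm":
        raise ValidationError(f"rescale expects marker_norm stage, got {marker_norm.stage!r}")
    gt = catalog.gene_table()
    mag_of = gt.loc[marker_norm.values.index, "mag_id"]
    blocks = []
    for mag, idx in marker_norm.values.groupby(mag_of).groups.items():
        sub = marker_norm.values.loc[idx]
        mx = sub.to_numpy().max()
        if mx <= 0:
            raise ValidationError(f"MAG {mag}: maximum normalized value is 0")
        blocks.append(sub / mx * config.rescale_factor)
    return marker_norm.with_stage(
        _reorder(pd.concat(blocks), marker_norm.values.index), "rescaled"
    )


def normalize_pipeline(
    counts: CountMatrix,
    catalog: MagCatalog,
    sheet: SampleSheet,
    config: NormalizationConfig | None = None,
    return_stages: bool = False,
):
    """filter -> impute -> length -> marker -> rescale.

    Returns the rescaled matrix, or the dict of all stages when
    ``return_stages`` is true.
    """
    config = config or NormalizationConfig()
    filtered = filter_low_counts(counts, sheet, config, catalog=catalog)
    imputed = impute_zeros(filtered, config)
    rpk = length_normalize(imputed, catalog)
    mnorm = marker_normalize(rpk, catalog, config)
    rescaled = rescale_per_mag(mnorm, catalog, config)
    if return_stages:
        return {
            "raw": counts,
            "filtered": filtered,
            "imputed": imputed,
            "rpk": rpk,
            "marker_norm": mnorm,
            "rescaled": rescaled,
        }
    return rescaled
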