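"""KEGG-Ortholog aggregation, cross-MAG comparison, and pathway panels.

Comparing transcription *between* genomes needs a unit shared by both:
gene ids are genome-specific, so counts are summed to the KEGG
Ortholog (KO) level per MAG and sample, and only KOs present in both
genomes are tested (KOs private to one genome are listed separately —
absence of the gene, not silence of it). The comparison runs on the
marker-normalized per-cell scale so a more abundant genome does not
masquerade as a more transcribed one; the replication unit is the
reactor cycle, and because both MAGs are measured in the same physical
samples the report carries a paired-sample caveat.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detest import bh_adjust, estimate_dispersions, exact_test_nb
from .types import Contrast, CountMatrix, MagCatalog, PathwayPanel, SampleSheet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class KoProfile:
    """(mag_id, ko) x sample sums of a gene-level matrix."""

    values: pd.DataFrame  # MultiIndex (mag_id, ko) rows
    source_stage: str
    n_dropped_genes: int  # genes without KO annotation

    def mags(self) -> list[str]:
        return sorted(self.values.index.get_level_values("mag_id").unique())

    def of_mag(self, mag_id: str) -> pd.DataFrame:
        sub = self.values.loc[mag_id]
        sub.index.name = "ko"
        return sub


def aggregate_ko(values: CountMatrix, catalog: MagCatalog) -> KoProfile:
    """Sum gene rows to (MAG, KO) rows; unannotated genes are dropped
    and tallied."""
    gt = catalog.gene_table()
    meta = gt.loc[values.values.index]
    has_ko = meta["ko"].notna()
    n_dropped = int((~has_ko).sum())
    if n_dropped:
        logger.info("aggregate_ko: %d genes without KO dropped", n_dropped)
    sub = values.values.loc[has_ko]
    keys = pd.MultiIndex.from_arrays(
        [meta.loc[has_ko, "mag_id"], meta.loc[has_ko, "ko"]], names=["mag_id", "ko"]
    )
    summed = sub.groupby(keys).sum()
    summed.index = pd.MultiIndex.from_tuples(summed.index, names=["mag_id", "ko"])
    return KoProfile(values=summed, source_stage=values.stage, n_dropped_genes=n_dropped)


def compare_mags_ko(
    profile: KoProfile,
    mag_a: str,
    mag_b: str,
    samples: list[str],
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact NB test per shared KO between two MAGs over one set of
    samples (one time point / phase).

    Returns (de_table, private_kos). The test treats MAG A's values
    and MAG B's values in the given samples as the two groups; each KO
    is BH-adjusted, significant at padj < alpha, with direction
    "up_a"/"up_b". KOs present in only one MAG are excluded and listed
    in the private table.
    """
    if len(samples) < 2:
        raise ValidationError("need >= 2 samples for a MAG-vs-MAG comparison")
    a = profile.of_mag(mag_a)[samples]
    b = profile.of_mag(mag_b)[samples]
    shared = a.index.intersection(b.index)
    private = pd.DataFrame(
        [(ko, mag_a) for ko in a.index.difference(b.index)]
        + [(ko, mag_b) for ko in b.index.difference(a.index)],
        columns=["ko", "private_to"],
    ).sort_values(["private_to", "ko"]).reset_index(drop=True)
    if shared.empty:
        raise ValidationError(f"no shared KO between {mag_a} and {mag_b}")

    # stack the two MAGs side by side so the generic two-group test applies;
    # columns are tagged with the MAG so sample ids stay unique
    cols_a = [f"A::{s}" for s in samples]
    cols_b = [f"B::{s}" for s in samples]
    stacked = pd.DataFrame(
        np.hstack(
            [
                np.floor(a.loc[shared].to_numpy(dtype=float) + 0.5),
                np.floor(b.loc[shared].to_numpy(dtype=float) + 0.5),
            ]
        ),
        index=shared,
        columns=cols_a + cols_b,
    )
    contrast = Contrast(
        group_a=tuple(cols_a),
        group_b=tuple(cols_b),
        label=f"{mag_a} vs {mag_b} (paired-sample caveat)",
    )
    phi = estimate_dispersions(stacked, contrast)
    res = exact_test_nb(stacked, contrast, phi)
    res["padj"] = bh_adjust(res["p"])
    res["significant"] = res["padj"] < alpha
    res["direction"] = np.where(
        ~res["significant"], "ns", np.where(res["log2fc"] > 0, "up_a", "up_b")
    )
    res.attrs["mag_a"] = mag_a
    res.attrs["mag_b"] = mag_b
    res.attrs["caveat"] = "paired-sample caveat: both MAGs measured in the same samples"
    return res, private


def ko_set_overlap(sets: dict[str, set[str]]) -> pd.DataFrame:
    """All 2^k - 1 exclusive region sizes of k named KO sets (k <= 6).

    Each row is one membership pattern; region sizes sum to the size
    of the union (the tabular equivalent of a Venn diagram).
    """
    if len(sets) < 2:
        raise ValidationError("need >= 2 sets for an overlap report")
    if len(sets) > 6:
        raise ValidationError("overlap report limited to 6 sets")
    names = list(sets)
    rows = []
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in members))
            outside = set.union(set(), *(sets[n] for n in names if n not in members))
            region = inside - outside
            rows.append(
                {
                    "region": "&".join(members),
                    "n_sets": r,
                    "size": len(region),
                    "members": ";".join(sorted(region)),
                }
            )
    return pd.DataFrame(rows)


def panel_summary(
    rescaled: CountMatrix,
    de_tables: dict[str, pd.DataFrame],
    panels: list[PathwayPanel],
    catalog: MagCatalog,
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Per panel KO and MAG: log2 mean per-cell value per
    (condition, phase) group, the consensus call of each contrast, and
    a missing flag for pathway genes a genome lacks.

    ``de_tables`` maps a contrast label (e.g. a phase) to a gene-level
    consensus table from :func:`magtx.detest.de_pipeline`.
    """
    gt = catalog.gene_table()
    kept = gt.loc[rescaled.values.index]
    groups = {
        (cond, phase): sheet.samples_in(condition=cond, phase=phase)
        for cond in sheet.table["condition"].unique()
        for phase in sheet.table["phase"].unique()
    }
    rows = []
    for panel in panels:
        panel_hit = False
        for ko, symbol in panel.entries:
            for mag in catalog.mag_ids:
                genes = kept.index[(kept["mag_id"] == mag) & (kept["ko"] == ko)]
                row = {
                    "panel": panel.panel_name,
                    "ko": ko,
                    "symbol": symbol,
                    "mag_id": mag,
                    "missing": len(genes) == 0,
                }
                if len(genes):
                    panel_hit = True
                    vals = rescaled.values.loc[genes]
                    for (cond, phase), samp in groups.items():
                        if samp:
                            row[f"log2_mean_{cond}_{phase}"] = float(
                                np.log2(vals[samp].to_numpy().mean())
                            )
                    for label, de in de_tables.items():
                        hits = de.loc[de.index.intersection(genes)]
                        consensus = bool(hits["consensus"].any()) if len(hits) else False
                        row[f"consensus_{label}"] = consensus
                        if consensus:
                            direction = hits.loc[hits["consensus"], "direction"].iloc[0]
                        else:
                            direction = "ns"
                        row[f"direction_{label}"] = direction
                rows.append(row)
        if not panel_hit:
            logger.warning("panel %s: no KO present in any MAG", panel.panel_name)
    return pd.DataFrame(rows)
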