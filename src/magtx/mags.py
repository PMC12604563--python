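"""Genome dereplication and per-MAG transcriptional activity.

Dereplication clusters genomes by single linkage at a hard ANI
threshold (97% by default): two genomes are linked when either
direction of their pairwise average nucleotide identity reaches the
threshold, and clusters are the connected components of that graph.
The representative of each cluster is the genome with the best
MIMAG-style composite score (completeness - 5 x contamination), ties
broken by fewer contigs, then more universal markers, then id.

Activity profiling follows the read-proportion view of a
metatranscriptome: raw counts are summed per MAG and sample, turned
into per-sample proportions, and paired with the breadth of
transcription (fraction of a MAG's genes with at least one read).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .types import AniMatrix, CountMatrix, MagCatalog, MagRecord, SampleSheet, ValidationError


@dataclass
class DereplicationResult:
    clusters: list[set[str]]
    representatives: dict[int, str]  # cluster index -> genome id
    threshold: float

    def representative_ids(self) -> list[str]:
        return [self.representatives[i] for i in range(len(self.clusters))]

    def cluster_of(self, genome_id: str) -> int:
        for i, c in enumerate(self.clusters):
            if genome_id in c:
                return i
        raise KeyError(genome_id)


def dereplicate(
    ani: AniMatrix,
    quality: list[MagRecord],
    threshold: float = 97.0,
) -> DereplicationResult:
    """Single-linkage dereplication at an ANI threshold.

    Asymmetric ANI is resolved permissively: an edge exists when
    max(ANI(a,b), ANI(b,a)) >= threshold.
    """
    ids = ani.genome_ids
    by_id = {q.mag_id: q for q in quality}
    missing = set(ids) - set(by_id)
    if missing:
        raise ValidationError(f"quality records missing for genomes: {sorted(missing)}")

    arr = ani.values.to_numpy(dtype=float)
    sym = np.maximum(arr, arr.T)
    adj = csr_matrix(sym >= threshold)
    n_comp, labels = connected_components(adj, directed=False)

    clusters: list[set[str]] = [set() for _ in range(n_comp)]
    for gid, lab in zip(ids, labels):
        clusters[lab].add(gid)
    # stable order: by smallest member id
    order = sorted(range(n_comp), key=lambda i: min(clusters[i]))
    clusters = [clusters[i] for i in order]

    reps: dict[int, str] = {}
    for i, members in enumerate(clusters):
        reps[i] = min(
            members,
            key=lambda g: (
                -by_id[g].quality_score,
                by_id[g].n_contigs,
                -by_id[g].n_markers_present,
                g,
            ),
        )
    return DereplicationResult(clusters=clusters, representatives=reps, threshold=threshold)


@dataclass
class MagActivity:
    """Per-(MAG, sample) activity table.

    Columns: total_counts, n_transcribed, breadth, proportion; the
    proportions of each sample sum to 1 over MAGs (0 if the sample has
    no mapped reads at all).
    """

    table: pd.DataFrame  # index (mag_id, sample_id)

    def pivot(self, column: str) -> pd.DataFrame:
        return self.table[column].unstack("sample_id")


def mag_activity(counts: CountMatrix, catalog: MagCatalog) -> MagActivity:
    """Sum raw counts per MAG and sample; derive breadth and proportion."""
    if counts.stage != "raw":
        raise ValidationError(f"mag_activity expects raw counts, got {counts.stage!r}")
    gt = catalog.gene_table()
    mag_of = gt.loc[counts.gene_ids, "mag_id"]
    totals = counts.values.groupby(mag_of).sum()
    transcribed = (counts.values >= 1).groupby(mag_of).sum()
    genes_per_mag = mag_of.value_counts()
    totals = totals.reindex(catalog.mag_ids, fill_value=0)
    transcribed = transcribed.reindex(catalog.mag_ids, fill_value=0)

    sample_sums = totals.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportion = totals.div(sample_sums, axis=1).fillna(0.0)
    breadth = transcribed.div(genes_per_mag.reindex(catalog.mag_ids), axis=0).fillna(0.0)

    rows = []
    for mag in catalog.mag_ids:
        for s in counts.sample_ids:
            rows.append(
                {
                    "mag_id": mag,
                    "sample_id": s,
                    "total_counts": int(totals.loc[mag, s]),
                    "n_transcribed": int(transcribed.loc[mag, s]),
                    "breadth": float(breadth.loc[mag, s]),
                    "proportion": float(proportion.loc[mag, s]),
                }
            )
    table = pd.DataFrame(rows).set_index(["mag_id", "sample_id"])
    return MagActivity(table=table)


def mean_proportions_by_day(activity: MagActivity, sheet: SampleSheet) -> pd.DataFrame:
    """Mean per-sample read proportion per MAG and day (cycles and
    phases pooled), the stacked-bar summary of community shifts."""
    prop = activity.pivot("proportion")
    day_of = dict(zip(sheet.table["sample_id"], sheet.table["day"]))
    missing = set(prop.columns) - set(day_of)
    if missing:
        raise ValidationError(f"samples missing from sheet: {sorted(missing)}")
    days = pd.Series({s: day_of[s] for s in prop.columns})
    out = prop.T.groupby(days).mean().T
    out.columns.name = "day"
    return out


def select_active_mags(
    activity: MagActivity,
    min_proportion: float = 0.05,
    min_breadth: float = 0.5,
    rule: str = "all_samples",
) -> set[str]:
    """MAGs with a high transcription level across samples.

    rule="all_samples": both thresholds met in every sample;
    rule="majority": met in at least half of the samples.
    """
    if not (0 <= min_proportion <= 1 and 0 <= min_breadth <= 1):
        raise ValidationError("thresholds must be in [0, 1]")
    if rule not in {"all_samples", "majority"}:
        raise ValidationError(f"unknown rule {rule!r}")
    prop = activity.pivot("proportion")
    breadth = activity.pivot("breadth")
    ok = (prop >= min_proportion) & (breadth >= min_breadth)
    n = ok.shape[1]
    if rule == "all_samples":
        keep = ok.all(axis=1)
    else:
        keep = ok.sum(axis=1) >= (n / 2.0)
    return set(keep.index[keep])
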