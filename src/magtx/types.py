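"""Domain containers for genome-resolved metatranscriptomics.

The unit of analysis is the MAG (metagenome-assembled genome): a genome
binned from a metagenomic assembly whose genes are profiled together.
Counts flow through a tagged pipeline of stages (raw -> filtered ->
imputed -> rpk -> marker_norm -> rescaled); each stage is a plain
pandas DataFrame (gene x sample) wrapped with its stage label so that
downstream operations can refuse inputs at the wrong stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KO_PATTERN = re.compile(r"^K\d{5}$")

#: stages a count matrix can be in, in pipeline order
STAGES = ("raw", "filtered", "imputed", "rpk", "marker_norm", "rescaled")

CONDITIONS = ("high_p", "low_p")
PHASES = ("feeding", "aerobic")


class ValidationError(ValueError):
    """Raised when an input file or cross-reference fails validation."""


@dataclass(frozen=True)
class GeneRecord:
    """One predicted gene: its MAG, length, and functional labels.

    ``marker_cog`` is set only for the universal single-copy marker
    genes (fetchMGs-style COG ids); ``ko`` is the KEGG Ortholog label
    (K#####) and may be absent — such genes take part in gene-level
    differential tests but not in KO aggregation.
    """

    gene_id: str
    mag_id: str
    length_bp: int
    ko: str | None = None
    product: str | None = None
    marker_cog: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValidationError(f"gene {self.gene_id}: length_bp must be >= 1")
        if self.ko is not None and not KO_PATTERN.match(self.ko):
            raise ValidationError(f"gene {self.gene_id}: malformed KO id {self.ko!r}")

    @property
    def is_marker(self) -> bool:
        return self.marker_cog is not None


@dataclass(frozen=True)
class MagRecord:
    """Quality and identity of one MAG (CheckM-style metrics)."""

    mag_id: str
    taxon_label: str = ""
    completeness: float = 100.0
    contamination: float = 0.0
    n_contigs: int = 1
    n_markers_present: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise ValidationError(f"MAG {self.mag_id}: completeness outside [0, 100]")
        if self.contamination < 0:
            raise ValidationError(f"MAG {self.mag_id}: negative contamination")
        if self.n_contigs < 1:
            raise ValidationError(f"MAG {self.mag_id}: n_contigs must be >= 1")

    @property
    def quality_score(self) -> float:
        """MIMAG-style composite: completeness - 5 * contamination."""
        return self.completeness - 5.0 * self.contamination


@dataclass
class MagCatalog:
    """MAGs plus their genes; the reference the counts map onto."""

    mags: list[MagRecord]
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        mag_ids = [m.mag_id for m in self.mags]
        if len(set(mag_ids)) != len(mag_ids):
            raise ValidationError("duplicate mag_id in catalog")
        gene_ids = [g.gene_id for g in self.genes]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValidationError("duplicate gene_id in catalog")
        known = set(mag_ids)
        genes_per_mag: dict[str, int] = {m: 0 for m in known}
        seen_cogs: set[tuple[str, str]] = set()
        for g in self.genes:
            if g.mag_id not in known:
                raise ValidationError(f"gene {g.gene_id}: unknown mag_id {g.mag_id!r}")
            genes_per_mag[g.mag_id] += 1
            if g.marker_cog is not None:
                key = (g.mag_id, g.marker_cog)
                if key in seen_cogs:
                    raise ValidationError(
                        f"MAG {g.mag_id}: marker {g.marker_cog} occurs twice "
                        "(violates single-copy assumption)"
                    )
                seen_cogs.add(key)
        empty = [m for m, n in genes_per_mag.items() if n == 0]
        if empty:
            raise ValidationError(f"MAGs without genes: {sorted(empty)}")

    @property
    def mag_ids(self) -> list[str]:
        return [m.mag_id for m in self.mags]

    def genes_of(self, mag_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.mag_id == mag_id]

    def markers_of(self, mag_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.mag_id == mag_id and g.is_marker]

    def gene_table(self) -> pd.DataFrame:
        """Genes as a DataFrame indexed by gene_id."""
        df = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "mag_id": [g.mag_id for g in self.genes],
                "length_bp": [g.length_bp for g in self.genes],
                "ko": [g.ko for g in self.genes],
                "product": [g.product for g in self.genes],
                "marker_cog": [g.marker_cog for g in self.genes],
            }
        )
        return df.set_index("gene_id")


@dataclass
class SampleSheet:
    """Experimental design: condition x phase x cycle per sample.

    Mirrors an alternating anaerobic-feed / aerobic EBPR reactor sampled
    in both phases over consecutive cycles, before (high_p) and after
    (low_p) the influent phosphate drop.
    """

    table: pd.DataFrame  # columns: sample_id, condition, phase, cycle, day

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "phase", "cycle", "day"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sheet")
        bad_cond = set(self.table["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition values: {sorted(bad_cond)}")
        bad_phase = set(self.table["phase"]) - set(PHASES)
        if bad_phase:
            raise ValidationError(f"unknown phase values: {sorted(bad_phase)}")
        if (self.table["cycle"] < 1).any():
            raise ValidationError("cycle must be >= 1")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_in(self, condition: str | None = None, phase: str | None = None) -> list[str]:
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        if phase is not None:
            t = t[t["phase"] == phase]
        return list(t["sample_id"])

    def group_sizes(self) -> dict[tuple[str, str], int]:
        """Sample count per (condition, phase) group."""
        out: dict[tuple[str, str], int] = {}
        for (cond, phase), sub in self.table.groupby(["condition", "phase"]):
            out[(cond, phase)] = len(sub)
        return out

    def condition_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["condition"].iloc[0]


@dataclass
class CountMatrix:
    """Gene x sample count grid with a pipeline stage tag.

    The raw stage holds integers (uniquely-mapped primary-alignment
    counts); later stages hold non-negative reals.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if (self.values.values < 0).any():
            raise ValidationError("negative count values")
        if self.stage == "raw":
            arr = self.values.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("raw stage must be integer-valued")
            self.values = self.values.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_stage(self, values: pd.DataFrame, stage: str) -> "CountMatrix":
        return CountMatrix(values=values, stage=stage)


@dataclass
class AniMatrix:
    """Square pairwise average-nucleotide-identity grid (percent).

    FastANI output is directional, so the matrix may be asymmetric;
    the diagonal is coerced to 100.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.values.columns):
            raise ValidationError("ANI matrix row/column labels differ")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("ANI matrix contains missing values")
        if (arr < 0).any() or (arr > 100).any():
            raise ValidationError("ANI values outside [0, 100]")
        np.fill_diagonal(arr, 100.0)
        self.values = pd.DataFrame(arr, index=self.values.index, columns=self.values.columns)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class PathwayPanel:
    """A named panel of KEGG Orthologs (pathway gene set of interest)."""

    panel_name: str
    entries: list[tuple[str, str]] = field(default_factory=list)  # (ko, symbol)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(f"panel {self.panel_name!r} has no entries")
        for ko, _sym in self.entries:
            if not KO_PATTERN.match(ko):
                raise ValidationError(f"panel {self.panel_name!r}: malformed KO id {ko!r}")

    @property
    def kos(self) -> list[str]:
        return [ko for ko, _ in self.entries]


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison within one reactor phase."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValidationError("contrast groups overlap")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValidationError("each contrast group needs >= 2 samples")
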