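"""Synthetic metatranscriptomes with known per-cell transcription.

The generator emulates the downstream structure of an EBPR
metatranscriptomics experiment: a 12-sample design (2 phosphate
conditions x 2 reactor phases x 3 cycles), a handful of MAGs sharing
~80% of their KEGG-Ortholog content, 10 single-copy universal marker
genes per MAG held at exactly one transcript copy per cell, and
negative-binomial read counts whose mean is

    mu(g, s) = depth_s * abundance(mag(g), s) * lambda(g, cond, phase)
               * length_kb(g) / Z_s,

with Z_s chosen so the expected total per sample equals depth_s.
Because every quantity in that product is recorded in a TruthTable,
each downstream stage (normalization, differential tests, KO-level
comparison) can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    CountMatrix,
    GeneRecord,
    MagCatalog,
    MagRecord,
    SampleSheet,
    ValidationError,
)

#: canonical single-copy universal marker COGs (fetchMGs-style set)
DEFAULT_MARKER_COGS = (
    "COG0012",
    "COG0016",
    "COG0018",
    "COG0172",
    "COG0215",
    "COG0495",
    "COG0525",
    "COG0533",
    "COG0541",
    "COG0552",
)

#: sampling days mirroring the before/after phosphate-shift time points
CONDITION_DAY = {"high_p": 103, "low_p": 182}


@dataclass
class SimParams:
    """Knobs of the generator; defaults are the study-like conditions."""

    n_mags: int = 4
    genes_per_mag: int = 500
    ko_pool_size: int = 4000
    ko_share_frac: float = 0.8
    length_log_mean: float = 6.8  # ln-bp; exp(6.8) ~ 900 bp median gene
    length_log_sd: float = 0.45
    n_cycles: int = 3
    depth_per_sample: float = 1e6
    dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    ko_missing_frac: float = 0.05  # genes with no KO annotation
    abundance_shift_max: float = 10.0  # max Dirichlet concentration ratio
    seed: int = 0
    marker_cogs: tuple[str, ...] = field(default=DEFAULT_MARKER_COGS)

    def __post_init__(self) -> None:
        # coerce numerics so YAML-sourced values ("5e4" parses as str) work
        import dataclasses

        for f in dataclasses.fields(self):
            if f.type in ("int", "float"):
                setattr(self, f.name, {"int": int, "float": float}[f.type](
                    float(getattr(self, f.name))
                ))
        for name in ("n_mags", "genes_per_mag", "ko_pool_size", "n_cycles"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("ko_share_frac", "de_fraction", "ko_missing_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.genes_per_mag < len(self.marker_cogs):
            raise ValidationError("genes_per_mag smaller than the marker set")


@dataclass
class TruthTable:
    """Ground truth behind a simulated count table.

    lam        per-cell transcript rate, gene x "condition:phase"
    abundance  cell fraction of each MAG per sample (columns sum to 1)
    depth      expected total reads per sample
    de         per gene: de_flag (bool) and signed log2fc (low_p vs high_p)
    dispersion per-gene NB dispersion phi (variance = mu + phi*mu^2)
    """

    lam: pd.DataFrame
    abundance: pd.DataFrame
    depth: pd.Series
    de: pd.DataFrame
    dispersion: pd.Series

    def __post_init__(self) -> None:
        sums = self.abundance.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("abundances per sample must sum to 1")
        if (self.lam.to_numpy() <= 0).any():
            raise ValidationError("lambda must be > 0")


def _taxon_label(i: int) -> str:
    return f"Ca. Simulibacter sp{i + 1:02d} (synthetic)"


def simulate_catalog(params: SimParams, rng: np.random.Generator | None = None) -> MagCatalog:
    """Build a MAG catalog with shared KO content and 10 markers per MAG.

    Non-marker genes draw KOs from a core set common to all MAGs (a
    ``ko_share_frac`` fraction of each MAG's annotated genes) plus a
    MAG-private remainder, so the fraction of a MAG's KOs shared with
    any other MAG is ~ko_share_frac. A small fraction of genes carries
    no KO at all, as in real annotations.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n_marker = len(params.marker_cogs)
    n_free = params.genes_per_mag - n_marker
    n_with_ko = int(round(n_free * (1.0 - params.ko_missing_frac)))
    n_core = int(round(params.ko_share_frac * n_with_ko))
    n_private = n_with_ko - n_core
    need = n_core + params.n_mags * n_private
    if need > params.ko_pool_size:
        raise ValidationError(
            f"ko_pool_size={params.ko_pool_size} too small; need >= {need}"
        )
    pool = [f"K{j:05d}" for j in rng.choice(99999, size=params.ko_pool_size, replace=False) + 1]
    core = pool[:n_core]
    private_pool = pool[n_core:]

    mags, genes = [], []
    for i in range(params.n_mags):
        mag_id = f"MAG{i + 1:02d}"
        mags.append(
            MagRecord(
                mag_id=mag_id,
                taxon_label=_taxon_label(i),
                completeness=float(rng.uniform(85, 99.5)),
                contamination=float(rng.uniform(0, 5)),
                n_contigs=int(rng.integers(40, 400)),
                n_markers_present=n_marker,
            )
        )
        lengths = np.exp(
            rng.normal(params.length_log_mean, params.length_log_sd, params.genes_per_mag)
        )
        lengths = np.clip(np.round(lengths), 150, 30000).astype(int)
        kos: list[str | None] = list(core)
        kos += private_pool[i * n_private : (i + 1) * n_private]
        kos += [None] * (n_free - n_with_ko)
        perm = rng.permutation(n_free)
        kos = [kos[j] for j in perm]
        for j in range(params.genes_per_mag):
            is_marker = j < n_marker
            genes.append(
                GeneRecord(
                    gene_id=f"{mag_id}_g{j + 1:04d}",
                    mag_id=mag_id,
                    length_bp=int(lengths[j]),
                    ko=None if is_marker else kos[j - n_marker],
                    product="universal marker" if is_marker else None,
                    marker_cog=params.marker_cogs[j] if is_marker else None,
                )
            )
    return MagCatalog(mags=mags, genes=genes)


def simulate_design(n_cycles: int = 3) -> SampleSheet:
    """2 conditions x 2 phases x n_cycles samples (12 at the default)."""
    if n_cycles < 2:
        raise ValidationError("n_cycles must be >= 2 for any tested contrast")
    rows = []
    for cond, short in (("high_p", "HP"), ("low_p", "LP")):
        for phase, pshort in (("feeding", "F"), ("aerobic", "A")):
            for cycle in range(1, n_cycles + 1):
                rows.append(
                    {
                        "sample_id": f"{short}_{pshort}_c{cycle}",
                        "condition": cond,
                        "phase": phase,
                        "cycle": cycle,
                        "day": CONDITION_DAY[cond],
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def simulate_truth(
    catalog: MagCatalog,
    sheet: SampleSheet,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Draw per-cell rates, MAG abundances, and depths.

    Marker genes are pinned at lambda = 1 in every condition and phase
    (the constitutive single-copy baseline the normalization assumes).
    A deterministic count of ``de_fraction`` of the non-marker genes
    gets a signed log2 fold change of magnitude ``de_log2fc`` between
    conditions (shared by both phases). MAG abundances follow a
    Dirichlet whose concentrations shift between conditions by ratios
    up to ``abundance_shift_max``, floored so no MAG drops below 5% of
    the total concentration.
    """
    rng = np.random.default_rng(params.seed + 1) if rng is None else rng
    gene_ids = [g.gene_id for g in catalog.genes]
    eligible = [g.gene_id for g in catalog.genes if not g.is_marker]

    base = pd.Series(np.exp(rng.normal(0.0, 1.0, len(gene_ids))), index=gene_ids)
    for g in catalog.genes:
        if g.is_marker:
            base[g.gene_id] = 1.0

    n_de = int(round(params.de_fraction * len(eligible)))
    de_genes = list(rng.choice(eligible, size=n_de, replace=False)) if n_de else []
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = pd.Series(0.0, index=gene_ids)
    for g, s in zip(de_genes, signs):
        lfc[g] = s * params.de_log2fc
    de = pd.DataFrame({"de_flag": lfc != 0.0, "log2fc": lfc})

    lam = pd.DataFrame(index=gene_ids, dtype=float)
    for cond in ("high_p", "low_p"):
        fold = np.power(2.0, lfc.to_numpy()) if cond == "low_p" else 1.0
        for phase in ("feeding", "aerobic"):
            lam[f"{cond}:{phase}"] = base.to_numpy() * fold

    mag_ids = catalog.mag_ids
    alpha_high = rng.uniform(2.0, 8.0, len(mag_ids))
    log_max = np.log(params.abundance_shift_max)
    shift = np.exp(rng.uniform(-log_max, log_max, len(mag_ids)))
    alpha_low = alpha_high * shift
    abund = {}
    for row in sheet.table.itertuples(index=False):
        alpha = alpha_high if row.condition == "high_p" else alpha_low
        alpha = np.maximum(alpha, 0.05 * alpha.sum())
        draw = rng.dirichlet(alpha * 20.0)  # x20: within-condition replicate stability
        abund[row.sample_id] = draw
    abundance = pd.DataFrame(abund, index=mag_ids)

    depth = pd.Series(
        params.depth_per_sample * np.exp(rng.normal(0.0, 0.1, len(sheet.sample_ids))),
        index=sheet.sample_ids,
    )
    dispersion = pd.Series(params.dispersion, index=gene_ids)
    return TruthTable(lam=lam, abundance=abundance, depth=depth, de=de, dispersion=dispersion)


def expected_means(catalog: MagCatalog, sheet: SampleSheet, truth: TruthTable) -> pd.DataFrame:
    """Generative mean mu(g, s); expected column sums equal truth.depth."""
    gt = catalog.gene_table()
    len_kb = gt["length_bp"].to_numpy() / 1000.0
    mag_of = gt["mag_id"].to_numpy()
    mu = pd.DataFrame(index=gt.index, dtype=float)
    for row in sheet.table.itertuples(index=False):
        lam = truth.lam[f"{row.condition}:{row.phase}"].loc[gt.index].to_numpy()
        ab = truth.abundance.loc[mag_of, row.sample_id].to_numpy()
        w = ab * lam * len_kb
        mu[row.sample_id] = truth.depth[row.sample_id] * w / w.sum()
    return mu


def simulate_counts(
    catalog: MagCatalog,
    sheet: SampleSheet,
    truth: TruthTable,
    seed: int = 0,
) -> CountMatrix:
    """Draw NB counts (variance = mu + phi*mu^2) around the generative mean.

    phi = 0 degenerates to Poisson; phi > 0 is sampled as a
    gamma-Poisson mixture.
    """
    rng = np.random.default_rng(seed)
    mu = expected_means(catalog, sheet, truth)
    phi = truth.dispersion.loc[mu.index].to_numpy()
    out = np.empty(mu.shape, dtype=np.int64)
    for j, s in enumerate(mu.columns):
        m = mu[s].to_numpy()
        lam = m.copy()
        over = phi > 0
        if over.any():
            shape = 1.0 / phi[over]
            lam[over] = rng.gamma(shape, phi[over] * m[over])
        out[:, j] = rng.poisson(lam)
    return CountMatrix(values=pd.DataFrame(out, index=mu.index, columns=mu.columns), stage="raw")


def simulate_dataset(
    params: SimParams,
) -> tuple[MagCatalog, SampleSheet, TruthTable, CountMatrix]:
    """One-call generator: catalog, design, truth, and counts.

    All randomness flows from ``params.seed`` through named substreams,
    so two calls with equal params are identical.
    """
    ss = np.random.SeedSequence(params.seed)
    kc, kt, kn = ss.spawn(3)
    catalog = simulate_catalog(params, rng=np.random.default_rng(kc))
    sheet = simulate_design(params.n_cycles)
    truth = simulate_truth(catalog, sheet, params, rng=np.random.default_rng(kt))
    counts = simulate_counts(catalog, sheet, truth, seed=int(kn.generate_state(1)[0] % 2**31))
    return catalog, sheet, truth, counts


def write_truth(truth: TruthTable, outdir) -> None:
    """Dump the truth tables as TSVs next to the dataset files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.lam.rename_axis("gene_id").to_csv(outdir / "truth_lambda.tsv", sep="\t")
    truth.abundance.rename_axis("mag_id").to_csv(outdir / "truth_abundance.tsv", sep="\t")
    truth.depth.rename("depth").rename_axis("sample_id").to_csv(
        outdir / "truth_depth.tsv", sep="\t"
    )
    truth.de.rename_axis("gene_id").to_csv(outdir / "truth_de.tsv", sep="\t")
    truth.dispersion.rename("dispersion").rename_axis("gene_id").to_csv(
        outdir / "truth_dispersion.tsv", sep="\t"
    )
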