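"""Synthetic case-control exome cohorts with planted disease genes.

The generator emulates the statistical structure the pipeline assumes
without claiming biological realism: diploid genotypes drawn per-locus from
Hardy-Weinberg proportions, a handful of *causal* genes whose
high-effect-score variants are carried more often by cases (the
``case_enrichment`` excess carrier probability), consequence classes and
effect scores matching what a variant annotator would emit, a couple of
relative pairs sharing part of their genotypes, and optional inter-batch
score displacement realised as systematically inflated genotype calls —
the kind of artefact differing capture kits and calling settings produce.
No linkage disequilibrium, population structure or sequencing-error model
is attempted.

Cohorts serialise to plain-text VCF v4.2 plus annotation and phenotype TSVs
and round-trip losslessly through :mod:`avadx.cohort`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import HET, HOM_ALT, HOM_REF, MISSING, Panel
from .scoring import DEFAULT_VSCORE, VScoreParams

logger = logging.getLogger(__name__)

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort generator.

    Defaults describe a mid-size exome panel: 60 cases and 60 controls over
    2000 variant-bearing genes of which 10 are causal, with cases carrying
    each causal gene's effect variant with a 0.5 excess probability over
    the Hardy-Weinberg baseline.  Background nonsynonymous effect scores
    centre below zero (most exome variants are predicted neutral) while
    causal variants draw from the high-effect range.
    """

    n_cases: int = 60
    n_controls: int = 60
    n_genes: int = 2000
    n_causal: int = 10
    variants_per_gene: float = 12.0       # Poisson mean, at least 1 per gene
    allele_freq: tuple[float, float] = (0.05, 0.40)
    causal_allele_freq: tuple[float, float] = (0.005, 0.05)
    case_enrichment: float = 0.5
    frac_synonymous: float = 0.30
    frac_indel: float = 0.05
    causal_effect_range: tuple[float, float] = (40.0, 100.0)
    background_effect_mean: float = -20.0
    background_effect_sd: float = 30.0
    n_families: int = 2
    family_share: float = 0.5
    frac_nonpass: float = 0.02
    frac_chrx: float = 0.01
    frac_missing: float = 0.01
    batch_id: str = "B1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal cannot exceed n_genes")
        if self.n_cases < 1 or self.n_controls < 1 or self.n_genes < 1:
            raise ValueError("cohort must have cases, controls and genes")
        if self.variants_per_gene <= 0:
            raise ValueError("variants_per_gene must be positive")
        for name in ("case_enrichment", "frac_synonymous", "frac_indel",
                     "family_share", "frac_nonpass", "frac_chrx", "frac_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("allele_freq", "causal_allele_freq"):
            lo, hi = getattr(self, name)
            if not 0.0 < lo <= hi <= 0.5:
                raise ValueError(f"{name} range must lie in (0, 0.5]")
        if 2 * self.n_families > self.n_cases:
            raise ValueError("not enough cases to form the requested families")


@dataclass(frozen=True)
class CohortFiles:
    vcf: Path
    annotations: Path
    phenotypes: Path


@dataclass
class SyntheticCohort:
    """A generated cohort held in memory; serialisable to VCF/TSV."""

    config: CohortConfig
    individuals: pd.DataFrame        # index individual_id: status, family_id, batch_id
    variants: pd.DataFrame           # chrom pos ref alt filter_status gene consequence effect_score
    genotypes: np.ndarray            # (n_variants, n_individuals) int8
    causal_genes: tuple[str, ...]

    def to_panel(self) -> Panel:
        """The cohort as an annotated :class:`~avadx.cohort.Panel`."""
        v = self.variants
        panel_variants = pd.DataFrame({
            "chrom": v["chrom"], "pos": v["pos"], "ref": v["ref"], "alt": v["alt"],
            "filter_status": v["filter_status"],
            "genes": [(g,) for g in v["gene"]],
            "consequence": v["consequence"],
            "effect_score": v["effect_score"],
        })
        return Panel(
            individuals=self.individuals.copy(),
            variants=panel_variants,
            genotypes=self.genotypes.copy(),
        )

    def split(self, n_test_cases: int, n_test_controls: int
              ) -> tuple["SyntheticCohort", "SyntheticCohort"]:
        """Deterministically split off a test cohort sharing the variant set.

        The last ``n_test_cases`` cases and ``n_test_controls`` controls
        become the test cohort (family pairs sit at the front of the case
        list and stay in the training half).
        """
        status = self.individuals["status"].to_numpy()
        case_idx = np.flatnonzero(status == "CD")
        ctrl_idx = np.flatnonzero(status == "HC")
        if n_test_cases > len(case_idx) or n_test_controls > len(ctrl_idx):
            raise ValueError("split larger than the cohort")
        test_idx = np.sort(np.concatenate([
            case_idx[len(case_idx) - n_test_cases:],
            ctrl_idx[len(ctrl_idx) - n_test_controls:],
        ]))
        train_idx = np.setdiff1d(np.arange(len(status)), test_idx)

        def take(idx: np.ndarray) -> "SyntheticCohort":
            return SyntheticCohort(
                config=self.config,
                individuals=self.individuals.iloc[idx].copy(),
                variants=self.variants.copy(),
                genotypes=self.genotypes[:, idx].copy(),
                causal_genes=self.causal_genes,
            )

        return take(train_idx), take(test_idx)

    def write(self, out_dir: str | Path) -> CohortFiles:
        """Write VCF v4.2, annotation TSV and phenotype TSV under ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vcf_path = out_dir / "cohort.vcf"
        anno_path = out_dir / "annotations.tsv"
        pheno_path = out_dir / "phenotypes.tsv"

        samples = list(self.individuals.index)
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FILTER=<ID=q10,Description="Low quality">\n')
            for c in [str(i) for i in range(1, 23)] + ["X"]:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            v = self.variants
            for i in range(len(v)):
                gts = "\t".join(_GT_STRING[g] for g in self.genotypes[i])
                fh.write(
                    f"{v['chrom'].iat[i]}\t{v['pos'].iat[i]}\t.\t{v['ref'].iat[i]}\t"
                    f"{v['alt'].iat[i]}\t.\t{v['filter_status'].iat[i]}\t.\tGT\t{gts}\n"
                )

        anno = self.variants[
            ["chrom", "pos", "ref", "alt", "gene", "consequence", "effect_score"]
        ]
        anno.to_csv(anno_path, sep="\t", index=False)
        self.individuals.reset_index(names="individual_id").to_csv(
            pheno_path, sep="\t", index=False
        )
        return CohortFiles(vcf=vcf_path, annotations=anno_path, phenotypes=pheno_path)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; byte-identical output under one seed."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    causal = tuple(sorted(rng.choice(genes, size=config.n_causal, replace=False)))
    causal_set = set(causal)

    # individuals ---------------------------------------------------------
    cases = [f"case{i + 1:04d}" for i in range(config.n_cases)]
    controls = [f"ctrl{i + 1:04d}" for i in range(config.n_controls)]
    ids = cases + controls
    family = {i: i for i in ids}
    for f in range(config.n_families):
        a, b = cases[2 * f], cases[2 * f + 1]
        family[a] = family[b] = f"FAM{f + 1}"
    individuals = pd.DataFrame(
        {
            "status": ["CD"] * len(cases) + ["HC"] * len(controls),
            "family_id": [family[i] for i in ids],
            "batch_id": config.batch_id,
        },
        index=pd.Index(ids, name="individual_id"),
    )
    n_ind = len(ids)
    is_case = np.array([s == "CD" for s in individuals["status"]])

    # variant layout ------------------------------------------------------
    counts = np.maximum(1, rng.poisson(config.variants_per_gene, size=config.n_genes))
    per_chrom = int(np.ceil(config.n_genes / 22))
    rows = []
    causal_variant_rows: list[int] = []
    for gi, gene in enumerate(genes):
        chrom = str(gi // per_chrom + 1)
        base = 1_000 + (gi % per_chrom) * 1_000
        u = rng.random(counts[gi])
        for j in range(counts[gi]):
            pos = base + j
            # In a causal gene every nonsynonymous SNV is a planted effect
            # variant (high effect score, case-enriched carriers); the first
            # slot is forced nonsynonymous so each causal gene has at least
            # one.  Synonymous/indel fractions apply as in background genes.
            if gene in causal_set and (
                j == 0 or u[j] >= config.frac_synonymous + config.frac_indel
            ):
                consequence = "nonsynonymous"
                effect = float(rng.uniform(*config.causal_effect_range))
                causal_variant_rows.append(len(rows))
            elif u[j] < config.frac_synonymous:
                consequence, effect = "synonymous", np.nan
            elif u[j] < config.frac_synonymous + config.frac_indel:
                consequence, effect = "indel", np.nan
            else:
                consequence = "nonsynonymous"
                effect = float(np.clip(
                    rng.normal(config.background_effect_mean, config.background_effect_sd),
                    -100.0, 100.0,
                ))
            ref, alt = ("TA", "T") if consequence == "indel" else ("A", "G")
            rows.append((chrom, pos, ref, alt, "PASS", gene, consequence, effect))
    variants = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "filter_status", "gene",
                 "consequence", "effect_score"],
    )
    n_var = len(variants)
    causal_mask = np.zeros(n_var, dtype=bool)
    causal_mask[causal_variant_rows] = True

    # genotypes under Hardy-Weinberg --------------------------------------
    # planted effect variants are rare; background variants span the common
    # range so gene burden scores are dense rather than carrier-sparse
    maf = rng.uniform(*config.allele_freq, size=n_var)
    maf[causal_mask] = rng.uniform(*config.causal_allele_freq,
                                   size=int(causal_mask.sum()))
    u = rng.random((n_var, n_ind))
    p_hom = maf[:, None] ** 2
    p_het = 2 * maf[:, None] * (1 - maf[:, None])
    genotypes = np.where(u < p_hom, HOM_ALT, np.where(u < p_hom + p_het, HET, HOM_REF))
    genotypes = genotypes.astype(np.int8)

    # excess causal-variant carriers among cases
    if config.n_causal and config.case_enrichment > 0:
        forced = rng.random((len(causal_variant_rows), n_ind)) < config.case_enrichment
        forced[:, ~is_case] = False
        rows_idx = np.asarray(causal_variant_rows)
        sub = genotypes[rows_idx]
        sub[forced] = np.maximum(sub[forced], HET)
        genotypes[rows_idx] = sub

    # relative pairs share a fraction of genotype rows
    for f in range(config.n_families):
        a, b = 2 * f, 2 * f + 1
        shared = rng.random(n_var) < config.family_share
        genotypes[shared, b] = genotypes[shared, a]

    # filter-exercising noise: never applied to causal variants ------------
    background = ~causal_mask
    nonpass = background & (rng.random(n_var) < config.frac_nonpass)
    variants.loc[nonpass, "filter_status"] = "q10"
    miss_locus = background & (rng.random(n_var) < config.frac_missing)
    for i in np.flatnonzero(miss_locus):
        k = int(rng.integers(1, 4))
        who = rng.choice(n_ind, size=min(k, n_ind), replace=False)
        genotypes[i, who] = MISSING

    # a few chrX variants to exercise the autosome filter
    n_x = int(round(config.frac_chrx * n_var))
    if n_x:
        x_rows = []
        for j in range(n_x):
            gene = genes[int(rng.integers(0, config.n_genes))]
            x_rows.append(("X", 5_000 + j, "A", "G", "PASS", gene, "synonymous", np.nan))
        x_var = pd.DataFrame(x_rows, columns=variants.columns)
        x_maf = rng.uniform(*config.allele_freq, size=n_x)
        xu = rng.random((n_x, n_ind))
        xg = np.where(
            xu < x_maf[:, None] ** 2, HOM_ALT,
            np.where(xu < x_maf[:, None] ** 2 + 2 * x_maf[:, None] * (1 - x_maf[:, None]),
                     HET, HOM_REF),
        ).astype(np.int8)
        variants = pd.concat([variants, x_var], ignore_index=True)
        genotypes = np.vstack([genotypes, xg])

    return SyntheticCohort(
        config=config,
        individuals=individuals,
        variants=variants,
        genotypes=genotypes,
        causal_genes=causal,
    )


def plant_batch_shift(
    cohort: SyntheticCohort,
    shift: float,
    affected_fraction: float = 0.3,
    seed: int | None = None,
    params: VScoreParams = DEFAULT_VSCORE,
) -> SyntheticCohort:
    """Displace a cohort's gene scores to emulate a second sequencing batch.

    All individuals are relabelled to a new batch and, on a random
    ``affected_fraction`` of genes, genotype calls at existing loci are
    probabilistically inflated (ref->het, het->hom) so that the expected
    per-gene score displacement is about ``shift``.  Working through
    genotypes at shared loci (rather than extra private variants) means the
    displacement survives restriction of a test panel to training loci —
    exactly the situation batch adjustment has to fix.  ``shift = 0``
    relabels only.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    out = SyntheticCohort(
        config=cohort.config,
        individuals=cohort.individuals.assign(batch_id=cohort.config.batch_id + "_shifted"),
        variants=cohort.variants.copy(),
        genotypes=cohort.genotypes.copy(),
        causal_genes=cohort.causal_genes,
    )
    if shift == 0:
        return out
    rng = np.random.default_rng(cohort.config.seed + 1 if seed is None else seed)
    genes = out.variants["gene"].to_numpy()
    unique_genes = pd.unique(genes)
    n_affected = max(1, int(round(affected_fraction * len(unique_genes))))
    affected = set(rng.choice(unique_genes, size=n_affected, replace=False))

    from .scoring import variant_scores_for_panel  # local to avoid cycle at import

    vscores = variant_scores_for_panel(out.to_panel(), params)
    for gene in affected:
        idx = np.flatnonzero(genes == gene)
        vbar = max(vscores[idx].mean(), 1e-6)
        p_up = min(1.0, shift / (len(idx) * params.het_weight * vbar))
        upgrade = rng.random((len(idx), out.genotypes.shape[1])) < p_up
        block = out.genotypes[idx]
        can_move = (block >= HOM_REF) & (block < HOM_ALT)
        block[upgrade & can_move] += 1
        out.genotypes[idx] = block
    return out
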