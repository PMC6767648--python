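"""Cohort ingestion: VCF genotypes, phenotype tables, variant annotations.

A :class:`Panel` is the unit of analysis: a set of individuals with
case/control status (``CD``/``HC``), family and batch labels, and the
variant loci observed in the cohort with one genotype call per individual
per locus.  Genotypes are held as a dense ``(n_variants, n_individuals)``
int8 matrix (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing) rather than
per-call objects; at exome scale this is the only practical layout.

Variant identity throughout the package is the exact
``(chrom, pos, ref, alt)`` tuple in VCF-native 1-based coordinates; no
left-normalisation is attempted.  Multi-allelic records are split into one
record per alternate allele on load, so every stored variant is biallelic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: genotype codes used in Panel.genotypes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

AUTOSOMES = {str(i) for i in range(1, 23)}

CONSEQUENCES = ("synonymous", "nonsynonymous", "indel", "unscorable")

STATUS_CASE = "CD"
STATUS_CONTROL = "HC"


class Zygosity(IntEnum):
    """Per-individual call state at one biallelic locus."""

    homozygous_ref = HOM_REF
    heterozygous = HET
    homozygous_alt = HOM_ALT
    missing = MISSING


@dataclass(frozen=True)
class GenotypeCall:
    """A single individual's call at one variant locus."""

    individual_id: str
    zygosity: Zygosity


@dataclass(frozen=True)
class AnnotatedVariant:
    """One biallelic variant with its annotation.

    ``effect_score`` is a precomputed functional-effect prediction in
    [-100, 100]; it must be present exactly when the consequence is
    ``nonsynonymous``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"
    calls: tuple[GenotypeCall, ...] = ()
    genes: tuple[str, ...] = ()
    consequence: str | None = None
    effect_score: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.consequence == "nonsynonymous" and self.effect_score is None:
            raise ValueError("nonsynonymous variant requires an effect_score")
        if self.consequence not in (None, "nonsynonymous") and self.effect_score is not None:
            raise ValueError("effect_score is only meaningful for nonsynonymous variants")

    @property
    def locus(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class Panel:
    """A cohort: individuals plus the variants observed across them.

    ``individuals`` is indexed by individual ID with columns
    ``status`` (CD|HC), ``family_id`` and ``batch_id``.  ``variants`` has
    one row per biallelic variant with columns ``chrom pos ref alt
    filter_status`` and, once annotated, ``genes`` (tuple of gene IDs),
    ``consequence`` and ``effect_score``.  Row *i* of ``genotypes``
    corresponds to row *i* of ``variants``; column *j* to the *j*-th
    individual.
    """

    individuals: pd.DataFrame
    variants: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.individuals.index.has_duplicates:
            raise ValueError("duplicate individual IDs in panel")
        if self.genotypes.shape != (len(self.variants), len(self.individuals)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.individuals)} individuals"
            )

    @property
    def individual_ids(self) -> list[str]:
        return list(self.individuals.index)

    @property
    def statuses(self) -> pd.Series:
        return self.individuals["status"]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def loci(self) -> set[tuple[str, int, str, str]]:
        """The set of (chrom, pos, ref, alt) tuples in this panel."""
        v = self.variants
        return set(zip(v["chrom"], v["pos"], v["ref"], v["alt"]))

    def is_annotated(self) -> bool:
        return "genes" in self.variants.columns

    def subset_variants(self, mask: np.ndarray) -> "Panel":
        """New panel keeping variants where ``mask`` is True; order preserved."""
        return Panel(
            individuals=self.individuals.copy(),
            variants=self.variants.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[np.asarray(mask)],
        )

    def save(self, out_dir: str | Path) -> None:
        """Persist the panel as plain TSVs (variants, genotypes, phenotypes)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        v = self.variants.copy()
        if "genes" in v.columns:
            v["genes"] = [";".join(g) for g in v["genes"]]
        v.to_csv(out_dir / "variants.tsv", sep="\t", index=False)
        pd.DataFrame(self.genotypes, columns=self.individuals.index).to_csv(
            out_dir / "genotypes.tsv", sep="\t", index=False
        )
        self.individuals.reset_index(names="individual_id").to_csv(
            out_dir / "phenotypes.tsv", sep="\t", index=False
        )

    @classmethod
    def load(cls, panel_dir: str | Path) -> "Panel":
        panel_dir = Path(panel_dir)
        v = pd.read_csv(panel_dir / "variants.tsv", sep="\t",
                        dtype={"chrom": str, "ref": str, "alt": str})
        if "genes" in v.columns:
            v["genes"] = [tuple(str(g).split(";")) for g in v["genes"]]
        genotypes = pd.read_csv(panel_dir / "genotypes.tsv", sep="\t").to_numpy(
            dtype=np.int8
        )
        individuals = load_phenotypes(panel_dir / "phenotypes.tsv")
        return cls(individuals=individuals, variants=v, genotypes=genotypes)

    def require_training_classes(self) -> None:
        s = self.statuses
        if (s == STATUS_CASE).sum() < 1 or (s == STATUS_CONTROL).sum() < 1:
            raise ValueError("training panel needs at least one CD and one HC individual")


def _normalise_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def load_phenotypes(phenotype_path: str | Path) -> pd.DataFrame:
    """Read the phenotype TSV (individual_id, status, family_id, batch_id)."""
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    required = {"individual_id", "status", "family_id", "batch_id"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    bad = set(pheno["status"]) - {STATUS_CASE, STATUS_CONTROL}
    if bad:
        raise ValueError(f"unknown status values: {sorted(bad)}")
    return pheno.set_index("individual_id")


def load_panel(vcf_path: str | Path, phenotype_path: str | Path) -> Panel:
    """Load a multi-sample VCF and its phenotype table into a Panel.

    Multi-allelic records are split into one variant per alternate allele.
    Every VCF sample must be present in the phenotype table; a missing
    sample is a hard error naming the sample.
    """
    from cyvcf2 import VCF

    pheno = load_phenotypes(phenotype_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pheno.index]
    if absent:
        raise ValueError(
            f"VCF sample(s) absent from phenotype table: {', '.join(absent)}"
        )

    rows: list[tuple] = []
    geno_rows: list[np.ndarray] = []
    for rec in vcf:
        gts = np.asarray(rec.genotypes, dtype=np.int64)  # (n_samples, ploidy+1)
        alleles = gts[:, :2]
        missing = (alleles < 0).any(axis=1)
        for k, alt in enumerate(rec.ALT, start=1):
            codes = (alleles == k).sum(axis=1).astype(np.int8)
            codes[missing] = MISSING
            rows.append((rec.CHROM, int(rec.POS), rec.REF, alt, rec.FILTER or "PASS"))
            geno_rows.append(codes)
    vcf.close()

    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "filter_status"]
    )
    genotypes = (
        np.vstack(geno_rows) if geno_rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    individuals = pheno.loc[samples]
    return Panel(individuals=individuals, variants=variants, genotypes=genotypes)


def filter_training_variants(panel: Panel) -> Panel:
    """Apply the training-panel variant filters.

    Keeps autosomal variants with FILTER = PASS that are fully called
    (no missing genotype in any panel individual).  Order is preserved.
    Idempotent by construction.
    """
    v = panel.variants
    autosomal = v["chrom"].map(_normalise_chrom).isin(AUTOSOMES).to_numpy()
    passed = (v["filter_status"] == "PASS").to_numpy()
    complete = (panel.genotypes != MISSING).all(axis=1)
    mask = autosomal & passed & complete
    out = panel.subset_variants(mask)
    n_dropped = int((~mask).sum())
    logger.info("filter_training_variants: dropped %d of %d variants", n_dropped, len(v))
    if out.n_variants == 0:
        warnings.warn("no variants survive training filters", stacklevel=2)
    return out


def restrict_test_variants(
    test_panel: Panel, train_loci: Iterable[tuple[str, int, str, str]]
) -> Panel:
    """Keep only test variants whose (chrom, pos, ref, alt) is a training locus."""
    train_loci = set(train_loci)
    v = test_panel.variants
    keys = list(zip(v["chrom"], v["pos"], v["ref"], v["alt"]))
    mask = np.fromiter((k in train_loci for k in keys), dtype=bool, count=len(keys))
    if len(keys) and not mask.any():
        raise ValueError("no test variant overlaps the training loci; cannot predict")
    logger.info(
        "restrict_test_variants: %d of %d test variants are training loci",
        int(mask.sum()), len(keys),
    )
    return test_panel.subset_variants(mask)


def overlap_fraction(
    test_panel: Panel, train_loci: Iterable[tuple[str, int, str, str]]
) -> float:
    """Fraction of training loci also observed in the test panel."""
    train_loci = set(train_loci)
    if not train_loci:
        raise ValueError("empty training locus set")
    return len(test_panel.loci() & train_loci) / len(train_loci)


def load_annotation_table(annotation_path: str | Path) -> pd.DataFrame:
    anno = pd.read_csv(
        annotation_path,
        sep="\t",
        dtype={"chrom": str, "pos": np.int64, "ref": str, "alt": str, "gene": str,
               "consequence": str},
    )
    required = {"chrom", "pos", "ref", "alt", "gene", "consequence", "effect_score"}
    missing = required - set(anno.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    bad = set(anno["consequence"]) - set(CONSEQUENCES)
    if bad:
        raise ValueError(f"unknown consequence values: {sorted(bad)}")
    return anno


def load_annotations(panel: Panel, annotation_path: str | Path) -> Panel:
    """Join an annotation table onto a panel's variants.

    A variant mapping to several genes is recorded with all of them (it
    will contribute to each gene's score).  Variants with no annotation
    row are dropped (count logged).  A nonsynonymous row lacking an
    effect score is demoted to ``unscorable`` (count logged).
    """
    anno = load_annotation_table(annotation_path)
    key_cols = ["chrom", "pos", "ref", "alt"]
    grouped: dict[tuple, tuple[tuple[str, ...], str, float]] = {}
    for key, grp in anno.groupby(key_cols, sort=False):
        genes = tuple(dict.fromkeys(grp["gene"]))  # de-duplicated, order kept
        consequence = grp["consequence"].iloc[0]
        score = grp["effect_score"].iloc[0]
        grouped[key] = (genes, consequence, float(score) if pd.notna(score) else np.nan)

    v = panel.variants
    keys = list(zip(v["chrom"], v["pos"], v["ref"], v["alt"]))
    mask = np.fromiter((k in grouped for k in keys), dtype=bool, count=len(keys))
    n_unannotated = int((~mask).sum())
    if n_unannotated:
        logger.info("load_annotations: dropping %d unannotated variants", n_unannotated)

    out = panel.subset_variants(mask)
    hits = [grouped[k] for k, m in zip(keys, mask) if m]
    genes_col = [h[0] for h in hits]
    cons_col = [h[1] for h in hits]
    score_col = [h[2] for h in hits]
    n_demoted = 0
    for i, (c, s) in enumerate(zip(cons_col, score_col)):
        if c == "nonsynonymous" and not np.isfinite(s):
            cons_col[i] = "unscorable"
            score_col[i] = np.nan
            n_demoted += 1
        elif c != "nonsynonymous":
            score_col[i] = np.nan
    if n_demoted:
        logger.info(
            "load_annotations: %d nonsynonymous variants without effect score "
            "treated as unscorable", n_demoted,
        )
    out.variants = out.variants.assign(
        genes=genes_col, consequence=cons_col, effect_score=score_col
    )
    return out
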