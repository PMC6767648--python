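"""Gene functional-deficit scoring.

Each variant receives a ``v_score`` in [0, 1] describing how much protein
function it is expected to remove: indels are treated as knockouts
(v_score 1), synonymous variants as near-neutral (0.05), nonsynonymous
variants are scaled from an external effect prediction in [-100, 100]
(predicted-effect variants map to 0.06 + 0.94 * score/100; predicted-neutral
ones get a fixed 0.055, as do variants the predictor cannot handle).

A gene's score for one individual is the zygosity-weighted sum of the
v_scores of that individual's variants in the gene::

    gene_score(g) = sum_i het_i * v_score_i,   het = 0.25 (het) or 1 (hom)

so a gene scores zero exactly when the individual carries no variant in it.
Scores are comparable between individuals for the same gene but not between
genes (longer, more tolerant genes score higher at baseline).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import HET, HOM_ALT, AnnotatedVariant, Panel, Zygosity

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VScoreParams:
    """Constants of the variant-scoring table.

    ``effect_base`` and ``effect_span`` define the affine map of a
    non-negative effect prediction s to ``effect_base + effect_span * s/100``;
    they must sum to 1 so that a full-effect prediction (s = 100) yields a
    knockout-equivalent v_score of 1.
    """

    effect_base: float = 0.06
    effect_span: float = 0.94
    neutral: float = 0.055
    synonymous: float = 0.05
    indel: float = 1.0
    unscorable: float = 0.055
    het_weight: float = 0.25

    def __post_init__(self) -> None:
        for name in ("effect_base", "effect_span", "neutral", "synonymous",
                     "indel", "unscorable", "het_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.effect_base + self.effect_span - 1.0) > 1e-12:
            raise ValueError("effect_base + effect_span must equal 1")


DEFAULT_VSCORE = VScoreParams()


def variant_score(
    variant: AnnotatedVariant | str,
    params: VScoreParams = DEFAULT_VSCORE,
    *,
    effect_score: float | None = None,
) -> float:
    """Raw v_score of one variant (zygosity weighting NOT applied).

    ``variant`` is either an :class:`AnnotatedVariant` or a consequence
    string, in which case ``effect_score`` supplies the prediction for
    nonsynonymous variants.  An effect prediction of exactly 0 falls on the
    effect side of the table (v_score = effect_base).
    """
    if isinstance(variant, AnnotatedVariant):
        consequence = variant.consequence
        effect_score = variant.effect_score
    else:
        consequence = variant
    if consequence == "synonymous":
        return params.synonymous
    if consequence == "indel":
        return params.indel
    if consequence == "unscorable":
        return params.unscorable
    if consequence == "nonsynonymous":
        if effect_score is None:
            raise ValueError("nonsynonymous variant requires an effect score")
        if not -100.0 <= effect_score <= 100.0:
            raise ValueError(f"effect score {effect_score} outside [-100, 100]")
        if effect_score < 0:
            return params.neutral
        return params.effect_base + (effect_score / 100.0) * params.effect_span
    raise ValueError(f"unknown consequence {consequence!r}")


def _zygosity_weight(zygosity, params: VScoreParams) -> float:
    if isinstance(zygosity, str):
        zygosity = {"heterozygous": Zygosity.heterozygous, "het": Zygosity.heterozygous,
                    "homozygous_alt": Zygosity.homozygous_alt, "hom": Zygosity.homozygous_alt,
                    }[zygosity]
    if zygosity == Zygosity.heterozygous:
        return params.het_weight
    if zygosity == Zygosity.homozygous_alt:
        return 1.0
    raise ValueError(f"gene_score only accepts het/hom calls, got {zygosity!r}")


def gene_score(
    variants_in_gene: Iterable[tuple[float, object]],
    params: VScoreParams = DEFAULT_VSCORE,
) -> float:
    """Zygosity-weighted sum of v_scores for one gene in one individual."""
    return float(sum(v * _zygosity_weight(z, params) for v, z in variants_in_gene))


@dataclass
class GeneScoreMatrix:
    """Individuals x genes matrix of gene functional-deficit scores.

    ``scores`` is indexed by individual ID with one column per gene.
    Scores are non-negative by construction; after batch adjustment they
    may go negative, which is recorded in ``provenance["adjusted"]``.
    """

    scores: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return list(self.scores.index)

    @property
    def genes(self) -> list[str]:
        return list(self.scores.columns)

    def restricted(self, genes: Sequence[str]) -> pd.DataFrame:
        missing = [g for g in genes if g not in self.scores.columns]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return self.scores[list(genes)]

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.scores.to_csv(path, sep="\t", index_label="individual_id")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, default=str))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneScoreMatrix":
        path = Path(path)
        scores = pd.read_csv(path, sep="\t", index_col="individual_id").rename_axis(None)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(scores=scores, provenance=provenance)


def variant_scores_for_panel(
    panel: Panel, params: VScoreParams = DEFAULT_VSCORE
) -> np.ndarray:
    """Vector of raw v_scores, one per panel variant."""
    if not panel.is_annotated():
        raise ValueError("panel must be annotated before scoring")
    v = panel.variants
    out = np.empty(len(v), dtype=float)
    cons = v["consequence"].to_numpy()
    eff = v["effect_score"].to_numpy(dtype=float)
    out[cons == "synonymous"] = params.synonymous
    out[cons == "indel"] = params.indel
    out[cons == "unscorable"] = params.unscorable
    ns = cons == "nonsynonymous"
    if ns.any():
        s = eff[ns]
        if np.isnan(s).any():
            raise ValueError("nonsynonymous variant without effect score")
        if (s < -100).any() or (s > 100).any():
            raise ValueError("effect score outside [-100, 100]")
        out[ns] = np.where(s < 0, params.neutral,
                           params.effect_base + (s / 100.0) * params.effect_span)
    return out


def build_gene_score_matrix(
    panel: Panel, params: VScoreParams = DEFAULT_VSCORE
) -> GeneScoreMatrix:
    """Aggregate a panel's variants into the individuals x genes score matrix.

    Covers every gene touched by at least one variant in at least one
    individual; an (individual, gene) cell with no scored variant is 0.
    A variant mapped to several genes contributes to each of them.
    """
    if len(panel.individuals) == 0:
        raise ValueError("empty panel")
    if panel.n_variants == 0:
        raise ValueError("panel has no variants to score")
    vscores = variant_scores_for_panel(panel, params)
    weights = np.zeros_like(panel.genotypes, dtype=float)
    weights[panel.genotypes == HET] = params.het_weight
    weights[panel.genotypes == HOM_ALT] = 1.0
    contrib = vscores[:, None] * weights  # (n_variants, n_individuals)

    gene_lists = panel.variants["genes"]
    all_genes = sorted({g for genes in gene_lists for g in genes})
    gene_index = {g: i for i, g in enumerate(all_genes)}
    var_idx = np.fromiter(
        (i for i, genes in enumerate(gene_lists) for _ in genes), dtype=np.int64
    )
    gidx = np.fromiter(
        (gene_index[g] for genes in gene_lists for g in genes), dtype=np.int64
    )
    out = np.zeros((len(all_genes), len(panel.individuals)), dtype=float)
    np.add.at(out, gidx, contrib[var_idx])

    scores = pd.DataFrame(out.T, index=panel.individuals.index, columns=all_genes)
    provenance = {
        "batch": panel.individuals["batch_id"].to_dict(),
        "adjusted": False,
    }
    return GeneScoreMatrix(scores=scores, provenance=provenance)


def prune_genes(matrix: GeneScoreMatrix) -> GeneScoreMatrix:
    """Drop uninformative genes from a score matrix.

    Removes (a) genes with all-zero scores, (b) genes with an identical
    non-zero score in every individual (constant, hence uninformative),
    and (c) genes non-zero in exactly one individual.  Idempotent.
    """
    x = matrix.scores.to_numpy()
    nonzero = x != 0
    n_nonzero = nonzero.sum(axis=0)
    all_zero = n_nonzero == 0
    constant_nonzero = (x == x[0]).all(axis=0) & (x[0] != 0)
    single_carrier = n_nonzero == 1
    keep = ~(all_zero | constant_nonzero | single_carrier)
    logger.info("prune_genes: kept %d of %d genes", int(keep.sum()), len(keep))
    return GeneScoreMatrix(
        scores=matrix.scores.loc[:, keep].copy(),
        provenance=dict(matrix.provenance),
    )
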