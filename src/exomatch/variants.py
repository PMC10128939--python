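"""Consequence classification, frequency filtering, and per-gene
aggregation of annotated variants from a case-only sample.

Inputs arrive downstream of alignment/calling/VQSR: a VCF annotated with a
SnpEff ``ANN=`` INFO field (the artifact expects tranche filtering already
applied), or a pre-aggregated per-gene count table.  Variants are grouped
into three consequence classes — loss-of-function (LOF), missense (MIS) and
synonymous (SYN) — filtered on a reference-population allele frequency, and
aggregated per gene as counts of distinct qualifying sites observed in at
least one case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constraints import ConstraintUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "LOF_TERMS",
    "MIS_TERMS",
    "SYN_TERMS",
    "CLASSES",
    "AnnotatedVariant",
    "GeneVariantCounts",
    "classify_consequence",
    "filter_variants",
    "aggregate_counts",
    "read_annotated_vcf",
]

#: High-confidence LOF annotation terms (LOFTEE-style).  start_lost and
#: stop_lost are deliberately excluded by default; the sets are overridable
#: because annotation pipelines differ in which terms they call LOF.
LOF_TERMS = frozenset(
    {"stop_gained", "frameshift_variant", "splice_acceptor_variant", "splice_donor_variant"}
)
MIS_TERMS = frozenset({"missense_variant"})
SYN_TERMS = frozenset({"synonymous_variant"})

#: Consequence classes in decreasing severity.
CLASSES = ("lof", "mis", "syn")
_SEVERITY = {"lof": 0, "mis": 1, "syn": 2, "other": 3}


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated alternate allele at a genomic site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_symbol: str
    transcript_id: str
    consequence: str
    ref_pop_af: float | None = None
    observed_in_cases: bool = True
    n_case_alleles: int = 1

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based VCF convention)")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def classify_consequence(
    term: str,
    lof_terms: frozenset[str] = LOF_TERMS,
    mis_terms: frozenset[str] = MIS_TERMS,
    syn_terms: frozenset[str] = SYN_TERMS,
) -> str:
    """Map a (possibly ``&``-joined) SnpEff term to lof/mis/syn/other.

    For joined terms the most severe class wins (lof > mis > syn > other);
    unknown terms are 'other', never an error.
    """
    best = "other"
    for t in str(term).split("&"):
        t = t.strip()
        if t in lof_terms:
            cls = "lof"
        elif t in mis_terms:
            cls = "mis"
        elif t in syn_terms:
            cls = "syn"
        else:
            cls = "other"
        if _SEVERITY[cls] < _SEVERITY[best]:
            best = cls
    return best


def filter_variants(variants, maf_threshold: float = 0.05):
    """Retain variants rare in the reference population.

    A variant is retained when its reference-population allele frequency is
    strictly below ``maf_threshold`` (the boundary is exclusionary) or
    missing — absence from the reference panel is itself evidence of rarity.
    """
    if not 0.0 < maf_threshold <= 1.0:
        raise ValueError("maf_threshold must be in (0, 1]")
    retained = [
        v for v in variants if v.ref_pop_af is None or v.ref_pop_af < maf_threshold
    ]
    n_excluded = len(variants) - len(retained)
    logger.info(
        "filter_variants: retained %d, excluded %d at reference AF >= %g",
        len(retained), n_excluded, maf_threshold,
    )
    return retained


@dataclass
class GeneVariantCounts:
    """Per-gene LOF/MIS/SYN qualifying-variant counts.

    Genes absent from the table have implicit (0, 0, 0).
    """

    frame: pd.DataFrame  # index gene_symbol, integer columns lof/mis/syn

    def __post_init__(self):
        missing = [c for c in CLASSES if c not in self.frame.columns]
        if missing:
            raise ValueError(f"counts frame lacks columns {missing}")
        f = self.frame[list(CLASSES)]
        if (f.to_numpy() < 0).any():
            raise ValueError("variant counts must be non-negative")
        self.frame = f.astype(np.int64)

    def get(self, gene: str) -> tuple[int, int, int]:
        if gene in self.frame.index:
            row = self.frame.loc[gene]
            return int(row["lof"]), int(row["mis"]), int(row["syn"])
        return (0, 0, 0)

    def matrix(self, genes) -> np.ndarray:
        """len(genes) x 3 count matrix with implicit zeros, class order lof/mis/syn."""
        out = self.frame.reindex(genes, fill_value=0)
        return out.to_numpy(dtype=np.float64)

    def totals(self) -> dict[str, int]:
        return {c: int(self.frame[c].sum()) for c in CLASSES}

    def to_tsv(self, path) -> None:
        self.frame.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GeneVariantCounts":
        frame = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(frame)

    @classmethod
    def from_matrix(cls, genes, values) -> "GeneVariantCounts":
        frame = pd.DataFrame(
            np.asarray(values), index=pd.Index(genes, name="gene"), columns=list(CLASSES)
        )
        return cls(frame)


def aggregate_counts(
    variants,
    universe: ConstraintUniverse,
    unit: str = "sites",
) -> GeneVariantCounts:
    """Aggregate classified variants into per-gene class counts.

    ``unit='sites'`` (default) counts distinct qualifying sites
    (chrom, pos, ref, alt) observed in >= 1 case — a site carried by many
    cases counts once; ``unit='alleles'`` sums alternate-allele carriers
    instead.  Genes outside the universe are dropped and reported.
    """
    if unit not in {"sites", "alleles"}:
        raise ValueError("unit must be 'sites' or 'alleles'")
    in_universe = set(universe.symbols)
    counts: dict[str, list[int]] = {}
    seen_sites: set[tuple] = set()
    dropped_genes: set[str] = set()
    for v in variants:
        cls = classify_consequence(v.consequence)
        if cls == "other" or not v.observed_in_cases:
            continue
        if v.gene_symbol not in in_universe:
            dropped_genes.add(v.gene_symbol)
            continue
        key = (v.gene_symbol, cls, *v.site)
        if unit == "sites":
            if key in seen_sites:
                continue
            seen_sites.add(key)
            increment = 1
        else:
            increment = v.n_case_alleles
        row = counts.setdefault(v.gene_symbol, [0, 0, 0])
        row[CLASSES.index(cls)] += increment
    if dropped_genes:
        logger.info(
            "aggregate_counts: %d gene(s) outside the constraint universe dropped: %s",
            len(dropped_genes),
            ", ".join(sorted(dropped_genes)[:20]),
        )
    frame = pd.DataFrame.from_dict(
        counts, orient="index", columns=list(CLASSES)
    ).rename_axis("gene").sort_index()
    return GeneVariantCounts(frame)


def read_annotated_vcf(
    path,
    universe: ConstraintUniverse | None = None,
    af_key: str = "gnomad_nfe_af",
    restrict_transcripts: bool = True,
) -> list[AnnotatedVariant]:
    """Read a SnpEff-annotated VCF into :class:`AnnotatedVariant` records.

    The ``ANN=`` INFO field is parsed per entry
    (``allele|annotation|impact|gene|gene_id|feature_type|feature_id|...``);
    when a universe is supplied and ``restrict_transcripts`` is set, only
    entries whose (version-stripped) transcript appears in the universe's
    transcript set are considered — mirroring annotation restricted to the
    constraint-release transcripts.  Among surviving entries per record the
    most severe consequence (and its gene) is kept.  Input is assumed
    normalized; only the first ALT allele of each record is used.
    """
    from cyvcf2 import VCF

    allowed = universe.transcripts if (universe and restrict_transcripts) else None
    out: list[AnnotatedVariant] = []
    vcf = VCF(str(path))
    has_samples = len(vcf.samples) > 0
    for record in vcf:
        ann = record.INFO.get("ANN")
        if ann is None or not record.ALT:
            continue
        best = None  # (severity, gene, transcript, annotation)
        for entry in str(ann).split(","):
            fields = entry.split("|")
            if len(fields) < 7:
                continue
            annotation, gene, feature_id = fields[1], fields[3], fields[6]
            transcript = feature_id.split(".")[0]
            if allowed is not None and transcript not in allowed:
                continue
            cls = classify_consequence(annotation)
            if best is None or _SEVERITY[cls] < best[0]:
                best = (_SEVERITY[cls], gene, transcript, annotation)
        if best is None:
            continue
        af = record.INFO.get(af_key)
        if has_samples:
            gt = record.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            n_alleles = int(np.sum(gt == 1) + 2 * np.sum(gt == 3))
            observed = n_alleles > 0
        else:
            n_alleles, observed = 1, True
        out.append(
            AnnotatedVariant(
                chrom=str(record.CHROM),
                pos=int(record.POS),
                ref=str(record.REF),
                alt=str(record.ALT[0]),
                gene_symbol=str(best[1]).upper(),
                transcript_id=best[2],
                consequence=best[3],
                ref_pop_af=None if af is None else float(af),
                observed_in_cases=observed,
                n_case_alleles=max(n_alleles, 0),
            )
        )
    logger.info("read_annotated_vcf: %d annotated variant(s) from %s", len(out), path)
    return out
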