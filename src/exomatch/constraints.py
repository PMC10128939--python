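"""Gene-level constraint tables: reading the gnomAD dialect and simulating
synthetic constraint universes with a realistic inter-metric correlation
structure.

The "universe" is the set of canonical genes carrying ten clustering
metrics: observed/expected (O/E) variant-count ratios for loss-of-function
(LOF), missense (MIS) and synonymous (SYN) classes; a z-score for each O/E
ratio; the probability of LOF intolerance (pLI); genomic length; transcript
(CDS) length; and number of exons.  Genes missing any metric are dropped at
load and reported — never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .norta import (
    LognormalMarginal,
    LogitNormalMarginal,
    Marginal,
    NormalMarginal,
    NortaGenerator,
    ScaledBetaMarginal,
)

logger = logging.getLogger(__name__)

__all__ = [
    "METRICS",
    "DEFAULT_COLUMN_MAP",
    "GNOMAD_METRIC_CORRELATIONS",
    "DEFAULT_METRIC_MARGINALS",
    "ConstraintUniverse",
    "ConfigurationError",
    "read_constraints",
    "write_constraints",
    "simulate_constraints",
]

#: The ten clustering metrics, in canonical order.
METRICS = (
    "oe_lof",
    "oe_mis",
    "oe_syn",
    "lof_z",
    "mis_z",
    "syn_z",
    "pli",
    "genomic_length",
    "transcript_length",
    "n_exons",
)

#: Internal field -> gnomAD v2.1.1 constraint-file column name.  The file
#: format does not pin down which columns supply the three size metrics, so
#: those defaults (gene_length / cds_length / num_coding_exons) are the ones
#: most users will want but remain overridable through ``column_map``.
DEFAULT_COLUMN_MAP = {
    "gene_symbol": "gene",
    "transcript_id": "transcript",
    "oe_lof": "oe_lof",
    "oe_mis": "oe_mis",
    "oe_syn": "oe_syn",
    "lof_z": "lof_z",
    "mis_z": "mis_z",
    "syn_z": "syn_z",
    "pli": "pLI",
    "genomic_length": "gene_length",
    "transcript_length": "cds_length",
    "n_exons": "num_coding_exons",
}

#: Published pairwise Pearson correlations among the ten gnomAD-derived
#: clustering metrics (order = METRICS); the default target for the
#: synthetic universe generator.
GNOMAD_METRIC_CORRELATIONS = np.array(
    [
        [1.000, 0.551, 0.207, -0.728, -0.548, -0.137, -0.619, -0.141, -0.156, -0.161],
        [0.551, 1.000, 0.416, -0.472, -0.874, -0.395, -0.495, -0.062, 0.002, -0.071],
        [0.207, 0.416, 1.000, -0.113, -0.326, -0.848, -0.031, -0.007, 0.008, -0.028],
        [-0.728, -0.472, -0.113, 1.000, 0.648, 0.069, 0.654, 0.335, 0.572, 0.590],
        [-0.548, -0.874, -0.326, 0.648, 1.000, 0.403, 0.564, 0.135, 0.149, 0.245],
        [-0.137, -0.395, -0.848, 0.069, 0.403, 1.000, 0.016, -0.032, -0.101, -0.030],
        [-0.619, -0.495, -0.031, 0.654, 0.564, 0.016, 1.000, 0.148, 0.158, 0.141],
        [-0.141, -0.062, -0.007, 0.335, 0.135, -0.032, 0.148, 1.000, 0.315, 0.378],
        [-0.156, 0.002, 0.008, 0.572, 0.149, -0.101, 0.158, 0.315, 1.000, 0.802],
        [-0.161, -0.071, -0.028, 0.590, 0.245, -0.030, 0.141, 0.378, 0.802, 1.000],
    ]
)

#: Default marginal shapes for the synthetic generator.  Only the
#: correlation structure of the universe is pinned by published data; the
#: marginals below are plausible stand-ins: scaled betas for the bounded
#: O/E ratios, normals for z-scores, a logit-normal for the U-shaped pLI,
#: and lognormals for the three (heavy-tailed) size metrics.
DEFAULT_METRIC_MARGINALS: dict[str, Marginal] = {
    "oe_lof": ScaledBetaMarginal(1.2, 2.2, 2.0),
    "oe_mis": ScaledBetaMarginal(8.0, 8.0, 2.0),
    "oe_syn": ScaledBetaMarginal(12.0, 12.0, 2.0),
    "lof_z": NormalMarginal(1.0, 2.2),
    "mis_z": NormalMarginal(0.8, 1.6),
    "syn_z": NormalMarginal(0.0, 1.3),
    "pli": LogitNormalMarginal(-2.0, 2.5),
    "genomic_length": LognormalMarginal(math.log(24_000.0), 1.2),
    "transcript_length": LognormalMarginal(math.log(1_600.0), 0.65),
    "n_exons": LognormalMarginal(math.log(9.0), 0.85, round_to_int=True, minimum=1),
}


class ConfigurationError(ValueError):
    """A constraint file whose columns cannot be resolved."""


@dataclass
class ConstraintUniverse:
    """An ordered collection of genes with complete clustering metrics.

    ``frame`` is indexed by unique gene symbol and carries ``transcript_id``
    plus the ten metric columns; ``dropped`` records symbols removed at load
    for incomplete or out-of-range metrics.
    """

    frame: pd.DataFrame
    dropped: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        missing = [c for c in METRICS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"universe frame lacks metric columns: {missing}")
        if "transcript_id" not in self.frame.columns:
            self.frame = self.frame.assign(transcript_id="")
        dup = self.frame.index[self.frame.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate gene symbols in universe: {sorted(dup)}")
        m = self.frame
        bad = (
            (m["pli"] < 0)
            | (m["pli"] > 1)
            | (m[["oe_lof", "oe_mis", "oe_syn"]] < 0).any(axis=1)
            | (m[["genomic_length", "transcript_length"]] <= 0).any(axis=1)
            | (m["n_exons"] < 1)
        )
        if bad.any():
            raise ValueError(
                f"metric values out of range for genes: {list(m.index[bad])[:10]}"
            )

    @property
    def size(self) -> int:
        return len(self.frame)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def transcripts(self) -> frozenset[str]:
        return frozenset(t for t in self.frame["transcript_id"] if t)

    def metrics(self) -> pd.DataFrame:
        """The p x 10 metric block, genes as rows in universe order."""
        return self.frame[list(METRICS)]

    def metric_correlations(self) -> pd.DataFrame:
        """Sample Pearson correlations among the ten metrics."""
        return self.metrics().corr()


def read_constraints(path, column_map: dict[str, str] | None = None) -> ConstraintUniverse:
    """Load a gnomAD-style constraint TSV into a :class:`ConstraintUniverse`.

    Rows with any missing or out-of-range metric are dropped and reported
    (mirroring the treatment of genes absent from the constraint release);
    duplicate gene symbols among the surviving rows are a load error.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_symbol", *METRICS]
    missing = [f for f in required if colmap[f] not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"constraint file {path} lacks columns for fields {missing} "
            f"(expected names: {[colmap[f] for f in missing]})"
        )
    frame = pd.DataFrame(index=raw.index)
    frame["gene_symbol"] = raw[colmap["gene_symbol"]].astype(str).str.strip()
    tcol = colmap["transcript_id"]
    frame["transcript_id"] = (
        raw[tcol].fillna("").astype(str).str.strip() if tcol in raw.columns else ""
    )
    for f in METRICS:
        frame[f] = pd.to_numeric(raw[colmap[f]], errors="coerce")

    complete = frame[list(METRICS)].notna().all(axis=1)
    in_range = (
        frame["pli"].fillna(-1).between(0, 1)
        & (frame[["oe_lof", "oe_mis", "oe_syn"]].fillna(-1) >= 0).all(axis=1)
        & (frame[["genomic_length", "transcript_length"]].fillna(0) > 0).all(axis=1)
        & (frame["n_exons"].fillna(0) >= 1)
    )
    keep = complete & in_range
    dropped = tuple(frame.loc[~keep, "gene_symbol"])
    if dropped:
        logger.info(
            "read_constraints: dropped %d gene(s) with incomplete or invalid "
            "metrics: %s",
            len(dropped),
            ", ".join(dropped[:20]) + ("..." if len(dropped) > 20 else ""),
        )
    kept = frame.loc[keep].set_index("gene_symbol")
    dup = kept.index[kept.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene symbols in {path}: {sorted(dup)}")
    logger.info("read_constraints: loaded %d genes from %s", len(kept), path)
    return ConstraintUniverse(kept, dropped=dropped)


def write_constraints(universe: ConstraintUniverse, path, column_map: dict[str, str] | None = None) -> None:
    """Write a universe back to the TSV dialect accepted by read_constraints."""
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    out = universe.frame.reset_index()
    out = out.rename(columns={f: colmap[f] for f in out.columns if f in colmap})
    out.to_csv(path, sep="\t", index=False)


def simulate_constraints(
    p: int,
    metric_correlations: np.ndarray | None = None,
    marginal_specs: dict[str, Marginal] | None = None,
    seed: int | np.random.Generator = 0,
) -> ConstraintUniverse:
    """Generate a synthetic universe of ``p`` genes.

    A correlated multivariate normal with the (nearest-PSD-adjusted,
    pairwise-calibrated) target correlation is transformed per metric to the
    configured marginal, so sample inter-metric Pearson correlations
    approach the targets as ``p`` grows.  Deterministic given ``seed``.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    target = (
        GNOMAD_METRIC_CORRELATIONS
        if metric_correlations is None
        else np.asarray(metric_correlations, float)
    )
    specs = dict(DEFAULT_METRIC_MARGINALS)
    if marginal_specs:
        specs.update(marginal_specs)
    gen = NortaGenerator([specs[m] for m in METRICS], target)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = gen.sample(p, rng)

    width = max(5, len(str(p)))
    frame = pd.DataFrame(values, columns=list(METRICS))
    frame["pli"] = frame["pli"].clip(0.0, 1.0)
    frame["n_exons"] = frame["n_exons"].clip(lower=1).round()
    frame.index = pd.Index(
        [f"G{i:0{width}d}" for i in range(1, p + 1)], name="gene_symbol"
    )
    frame.insert(0, "transcript_id", [f"T{i:0{width}d}" for i in range(1, p + 1)])
    return ConstraintUniverse(frame)
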