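"""Genes-of-interest (GOI) sets: loading, filtering against a constraint
universe, and cumulative unions with overlap accounting.

Hypothesis sets are typically nested unions (a primary human set, plus
model-organism sets mapped to human symbols), so every combination reports
|A|, |B|, |A∩B| and |A∪B| rather than assuming disjointness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .constraints import ConstraintUniverse

logger = logging.getLogger(__name__)

__all__ = ["GeneSet", "GeneSetError", "load_goi", "gene_set_from_symbols", "combine_sets", "overlap_report"]


class GeneSetError(ValueError):
    pass


@dataclass
class GeneSet:
    """A named set of gene symbols filtered against one universe.

    ``dropped`` lists requested symbols absent from the universe;
    ``universe_key`` identifies the universe the set was filtered against so
    sets from different universes cannot be silently combined.
    """

    name: str
    members: frozenset[str]
    provenance: str = ""
    dropped: tuple[str, ...] = ()
    universe_key: int = 0
    report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.members


def _universe_key(universe: ConstraintUniverse) -> int:
    return hash(frozenset(universe.symbols))


def gene_set_from_symbols(
    name: str,
    symbols,
    universe: ConstraintUniverse,
    provenance: str = "",
) -> GeneSet:
    """Build a GeneSet from an in-memory symbol collection.

    Symbols are uppercase-normalized (human nomenclature) and de-duplicated;
    symbols absent from the universe are dropped and reported.  An empty
    surviving set is an error: it carries no testable hypothesis.
    """
    seen: list[str] = []
    dups: list[str] = []
    for s in symbols:
        s = str(s).strip().upper()
        if not s:
            continue
        if s in seen:
            dups.append(s)
        else:
            seen.append(s)
    if dups:
        logger.warning("gene set %r: %d duplicated symbol(s) removed: %s", name, len(dups), sorted(set(dups)))
    in_universe = set(universe.symbols)
    members = frozenset(s for s in seen if s in in_universe)
    dropped = tuple(s for s in seen if s not in in_universe)
    if dropped:
        logger.info(
            "gene set %r: dropped %d symbol(s) absent from the universe: %s",
            name, len(dropped), ", ".join(dropped),
        )
    if not members:
        raise GeneSetError(f"gene set {name!r} has no members present in the universe")
    return GeneSet(
        name=name,
        members=members,
        provenance=provenance,
        dropped=dropped,
        universe_key=_universe_key(universe),
        report={"n_requested": len(seen), "n_members": len(members), "n_dropped": len(dropped)},
    )


def load_goi(path, universe: ConstraintUniverse, name: str | None = None, provenance: str = "") -> GeneSet:
    """Load a plain-text GOI list (one symbol per line; ``#`` comments)."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    return gene_set_from_symbols(
        name or str(path), symbols, universe, provenance=provenance or str(path)
    )


def overlap_report(a: GeneSet, b: GeneSet) -> dict:
    inter = a.members & b.members
    union = a.members | b.members
    report = {
        "n_a": len(a.members),
        "n_b": len(b.members),
        "n_overlap": len(inter),
        "n_union": len(union),
    }
    assert report["n_union"] == report["n_a"] + report["n_b"] - report["n_overlap"]
    return report


def combine_sets(a: GeneSet, b: GeneSet, name: str) -> GeneSet:
    """Union of two sets filtered against the same universe.

    The returned set's ``report`` carries the full overlap arithmetic,
    which is mandatory output because testing sets are cumulative unions.
    """
    if a.universe_key != b.universe_key:
        raise GeneSetError(
            f"cannot combine {a.name!r} and {b.name!r}: filtered against different universes"
        )
    report = overlap_report(a, b)
    logger.info(
        "combine_sets %r: |%s|=%d, |%s|=%d, overlap=%d, union=%d",
        name, a.name, report["n_a"], b.name, report["n_b"],
        report["n_overlap"], report["n_union"],
    )
    return GeneSet(
        name=name,
        members=a.members | b.members,
        provenance=f"{a.name} ∪ {b.name}",
        dropped=tuple(dict.fromkeys(a.dropped + b.dropped)),
        universe_key=a.universe_key,
        report=report,
    )
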