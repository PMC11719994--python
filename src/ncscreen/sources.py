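"""Food-source set analysis of predicted-hit compounds.

Maps compounds to the foods they occur in, ranks sources by how many
predicted hits they contribute, and computes exact Venn-region counts for up
to six sources. Source names are normalized (case-fold, trim) on entry
because real food–compound tables are dirty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chem import CompoundRecord


def _norm(name: str) -> str:
    return str(name).strip().casefold()


@dataclass
class SourceMap:
    """Bidirectional mapping between food sources and compound ids."""

    by_source: dict[str, set[str]] = field(default_factory=dict)
    by_compound: dict[str, set[str]] = field(default_factory=dict)

    def add(self, compound_id: str, source: str) -> None:
        source = _norm(source)
        if not source:
            return
        self.by_source.setdefault(source, set()).add(compound_id)
        self.by_compound.setdefault(compound_id, set()).add(source)

    @classmethod
    def from_records(cls, records: list[CompoundRecord]) -> "SourceMap":
        m = cls()
        for r in records:
            for s in r.sources:
                m.add(r.id, s)
        return m

    @classmethod
    def from_long_table(cls, df: pd.DataFrame) -> "SourceMap":
        """Build from a two-column (compound, source) long table."""
        for col in ("compound", "source"):
            if col not in df.columns:
                raise ValueError(f"long table is missing column {col!r}")
        m = cls()
        for _, row in df.iterrows():
            m.add(str(row["compound"]), str(row["source"]))
        return m

    def is_consistent(self) -> bool:
        """True when the forward and inverse mappings agree exactly."""
        rebuilt: dict[str, set[str]] = {}
        for cid, srcs in self.by_compound.items():
            for s in srcs:
                rebuilt.setdefault(s, set()).add(cid)
        return rebuilt == self.by_source


def top_sources(source_map: SourceMap, n: int) -> list[tuple[str, int]]:
    """Top-n sources by compound count, ties broken alphabetically."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not source_map.by_source:
        raise ValueError("empty source map")
    ranked = sorted(
        ((s, len(ids)) for s, ids in source_map.by_source.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:n]


def venn_intersections(
    source_map: SourceMap, sources: list[str]
) -> dict[str, int]:
    """Exact Venn-region counts for 2–6 named sources.

    Returns a dict keyed by membership bitmask (one character per source, in
    the given order; '1' = member). Regions are disjoint and their counts sum
    to the size of the union.
    """
    names = [_norm(s) for s in sources]
    if not 2 <= len(names) <= 6:
        raise ValueError(f"need 2 to 6 sources, got {len(names)}")
    for s in names:
        if s not in source_map.by_source:
            raise ValueError(f"unknown source {s!r}")
    sets = [source_map.by_source[s] for s in names]
    union = set().union(*sets)
    regions = {
        format(mask, f"0{len(names)}b"): 0 for mask in range(1, 2 ** len(names))
    }
    for cid in union:
        mask = "".join("1" if cid in s else "0" for s in sets)
        regions[mask] += 1
    return regions


def full_intersection_count(source_map: SourceMap, sources: list[str]) -> int:
    """Number of compounds present in every one of the named sources."""
    regions = venn_intersections(source_map, sources)
    return regions["1" * len(sources)]


def top_sources_table(source_map: SourceMap, n: int) -> pd.DataFrame:
    return pd.DataFrame(top_sources(source_map, n), columns=["source", "n_compounds"])
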