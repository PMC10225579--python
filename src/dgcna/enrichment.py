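"""Over-representation analysis (ORA) of gene lists against GMT collections.

The hypergeometric upper tail measures whether a query list overlaps a gene
set more than random draws from the analysis universe would; BH controls the
FDR across sets.  Any GMT file works — the collection's content is the
user's choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .containers import ParameterError
from .diffcoexp import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (the GMT payload)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated ``name, description, genes...`` per line.

    Duplicate members within a set are collapsed; case is preserved.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParameterError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            if name in collection.sets:
                raise ParameterError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {m for m in members if m}
            if not members:
                raise ParameterError(f"{path}:{lineno}: set {name!r} has no members")
            collection.sets[name] = members
            collection.descriptions[name] = desc
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def ora_hypergeom(
    query: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric ORA of ``query`` against every set, BH across sets.

    Per set S (intersected with the universe): with N = |universe|,
    K = |S ∩ universe|, n = |query| and k = |query ∩ S|, the p-value is
    ``P(X >= k)`` for X ~ Hypergeometric(N, K, n).  Query genes outside the
    universe are dropped with a warning.
    """
    query, universe = set(query), set(universe)
    if not universe or not query:
        raise ParameterError("query and universe must be non-empty")
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
        query &= universe
        if not query:
            raise ParameterError("no query genes remain inside the universe")
    n_universe, n_query = len(universe), len(query)
    rows = []
    for name, members in sets.sets.items():
        in_universe = members & universe
        overlap = query & in_universe
        k, big_k = len(overlap), len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append(
            {
                "set": name,
                "description": sets.descriptions.get(name, ""),
                "overlap": k,
                "set_size": big_k,
                "query_size": n_query,
                "universe_size": n_universe,
                "p": min(p, 1.0),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["q"] <= q_threshold
        result = result.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    else:
        result["q"] = []
        result["significant"] = []
    return result
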