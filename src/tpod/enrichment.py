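"""Over-representation analysis of gene lists against GMT gene-set collections.

A generic hypergeometric ORA: each gene set is intersected with the analysis
universe (by default all genes tested for differential expression), sets
larger than ``max_term_size`` are excluded, the one-sided hypergeometric
upper-tail p-value of the query/set overlap is computed, and p-values are
BH-adjusted across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "ora",
           "MAX_TERM_SIZE", "ORA_FDR"]

#: term-size cap: larger sets are not tested or reported
MAX_TERM_SIZE = 1000
#: BH FDR threshold for significance flags
ORA_FDR = 0.05


@dataclass
class GeneSetCollection:
    """Named, nonempty gene sets with descriptions, as parsed from GMT."""

    sets: dict          # name -> frozenset of gene ids
    descriptions: dict  # name -> str

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (name, description, members...).

    Duplicate members within a set are deduplicated; duplicate set names or
    lines with fewer than 3 fields raise with the offending line number.
    """
    sets, desc = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}")
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no "
                                 "members")
            sets[name] = members
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            fh.write("\t".join([name, collection.descriptions.get(name, "")]
                               + sorted(members)) + "\n")


def ora(query, universe, collection: GeneSetCollection,
        max_term_size: int = MAX_TERM_SIZE, fdr: float = ORA_FDR
        ) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within ``universe``.

    Returns one row per tested term (term intersected with the universe,
    size in [1, max_term_size]), sorted by adjusted p then term name, with a
    ``significant`` flag at the given BH FDR.
    """
    query = frozenset(query)
    universe = frozenset(universe)
    stray = query - universe
    if stray:
        raise ValueError("query genes missing from universe: "
                         + ", ".join(sorted(stray)[:10]))
    M, N = len(universe), len(query)
    rows = []
    for name, members in sorted(collection, key=lambda kv: kv[0]):
        term = members & universe
        n = len(term)
        if n == 0 or n > max_term_size:
            continue
        overlap = term & query
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, M, n, N))  # P(X >= k)
        rows.append({"term": name,
                     "name": collection.descriptions.get(name, ""),
                     "size": n, "overlap": k, "p": min(p, 1.0),
                     "genes": ",".join(sorted(overlap))})
    out = pd.DataFrame(rows, columns=["term", "name", "size", "overlap",
                                      "p", "genes"])
    if len(out):
        out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["padj"] < fdr
        out = out.sort_values(["padj", "p", "term"],
                              kind="mergesort").reset_index(drop=True)
    else:
        out["padj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out[["term", "name", "size", "overlap", "p", "padj",
                "significant", "genes"]]
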