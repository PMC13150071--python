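"""Minimal over-representation analysis against GMT-format annotation sets.

One-sided hypergeometric tail P(X >= k) for the overlap of a selected feature
set with each annotation set, BH-FDR across sets. The universe is the set of
features that survived preprocessing, and annotation sets are restricted to it.
Pathway topology / impact scoring is deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .differential import bh_fdr


@dataclass
class AnnotationSets:
    sets: dict  # set_id -> list of member ids (deduplicated)
    descriptions: dict  # set_id -> description
    universe: set

    def restrict(self, universe) -> "AnnotationSets":
        """Drop members outside ``universe``; empty sets are removed."""
        uni = set(universe)
        sets, desc = {}, {}
        for sid, members in self.sets.items():
            kept = [f for f in members if f in uni]
            if kept:
                sets[sid] = kept
                desc[sid] = self.descriptions.get(sid, "")
            else:
                warnings.warn(f"set {sid!r} empty after universe restriction; dropped")
        return AnnotationSets(sets=sets, descriptions=desc, universe=uni)


def read_gmt(path) -> AnnotationSets:
    """Parse a GMT file: tab-separated set id, description, members..."""
    sets, desc = {}, {}
    universe: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 columns")
            sid, description = parts[0], parts[1]
            members = list(dict.fromkeys(p for p in parts[2:] if p))
            if not members:
                warnings.warn(f"set {sid!r} has no members; dropped")
                continue
            sets[sid] = members
            desc[sid] = description
            universe.update(members)
    return AnnotationSets(sets=sets, descriptions=desc, universe=universe)


def write_gmt(sets: AnnotationSets, path) -> None:
    with open(path, "w") as fh:
        for sid, members in sets.sets.items():
            fh.write("\t".join([sid, sets.descriptions.get(sid, "")] + list(members)) + "\n")


def hypergeom_ora(selected, sets: AnnotationSets, universe=None) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each set.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|set|, n=|selected|);
    BH-FDR across sets.
    """
    selected = set(selected)
    if not selected:
        raise ValueError("empty selection")
    uni = set(universe) if universe is not None else set(sets.universe)
    if not selected.issubset(uni):
        raise ValueError("selected features must be a subset of the universe")
    restricted = sets.restrict(uni)
    N = len(uni)
    n = len(selected)
    rows = []
    for sid in sorted(restricted.sets):
        members = set(restricted.sets[sid])
        K = len(members)
        k = len(selected & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_id": sid, "description": restricted.descriptions.get(sid, ""),
                     "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["p", "set_id"]).reset_index(drop=True)
    return out
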