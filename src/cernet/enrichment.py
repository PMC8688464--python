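"""Over-representation analysis of a gene list against GMT gene sets.

The test is the one-sided upper-tail hypergeometric — equivalently a
one-sided Fisher exact test on the 2x2 overlap table — computed within an
explicit gene universe (the genes measured on the platform, not the
genome). Benjamini-Hochberg q-values are reported alongside raw p, but
results are ranked by raw p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "fisher_enrich", "bh_adjust"]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to an explicit universe.

    Members outside the universe are removed at construction; sets left
    empty by the restriction are dropped (with a log line).
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(
        cls,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str],
        names: Mapping[str, str] | None = None,
    ) -> "GeneSetCollection":
        uni = frozenset(universe)
        if not uni:
            raise ValueError("empty gene universe")
        restricted = {}
        dropped = []
        for sid, members in sets.items():
            m = frozenset(members) & uni
            if m:
                restricted[sid] = m
            else:
                dropped.append(sid)
        if dropped:
            logger.info(
                "GeneSetCollection: %d sets empty after universe restriction",
                len(dropped),
            )
        return cls(restricted, uni, dict(names or {}))

    @classmethod
    def from_gmt(
        cls, path: str | Path, universe: Iterable[str] | None = None
    ) -> "GeneSetCollection":
        """Read tab-separated GMT (id, description, members...).

        Without an explicit universe, the union of all set members is used.
        """
        sets: dict[str, list[str]] = {}
        names: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
            names[parts[0]] = parts[1]
        if universe is None:
            universe = {g for members in sets.values() for g in members}
        return cls.from_dict(sets, universe, names)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid in sorted(self.sets):
                members = "\t".join(sorted(self.sets[sid]))
                fh.write(f"{sid}\t{self.names.get(sid, sid)}\t{members}\n")


def bh_adjust(p_values) -> pd.Series:
    """Benjamini-Hochberg step-up q-values (monotone, in [p, 1])."""
    p = pd.Series(p_values, dtype=float)
    if p.empty:
        return p
    q = multipletests(p.to_numpy(), method="fdr_bh")[1]
    return pd.Series(q, index=p.index)


def fisher_enrich(
    query: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """One-sided over-representation test of ``query`` against each set.

    For a set of size K in a universe of size N, with a query of size n and
    overlap k, p = P(X >= k) under Hypergeom(N, K, n). Query genes outside
    the universe are dropped (their count is logged). Results are sorted by
    p ascending, then set id, with columns ``set_id, name, overlap,
    set_size, query_size, universe_size, p, q, enrichment_score`` where the
    enrichment score is the ratio of proportions (k/n) / (K/N).
    """
    n_universe = len(collection.universe)
    if n_universe == 0:
        raise ValueError("empty gene universe")
    query_all = set(query)
    query_in = query_all & collection.universe
    n_out = len(query_all) - len(query_in)
    if n_out:
        logger.info("fisher_enrich: %d query genes outside the universe", n_out)
    if not query_in:
        raise ValueError("query has no genes in the universe")
    n = len(query_in)

    rows = []
    for sid in sorted(collection.sets):
        members = collection.sets[sid]
        big_k = len(members)
        k = len(members & query_in)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n))
        score = (k / n) / (big_k / n_universe)
        rows.append(
            {
                "set_id": sid,
                "name": collection.names.get(sid, sid),
                "overlap": k,
                "set_size": big_k,
                "query_size": n,
                "universe_size": n_universe,
                "p": min(p, 1.0),
                "enrichment_score": score,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"]).to_numpy()
        out = out.sort_values(["p", "set_id"], ignore_index=True)
        out = out[
            [
                "set_id", "name", "overlap", "set_size", "query_size",
                "universe_size", "p", "q", "enrichment_score",
            ]
        ]
    return out
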