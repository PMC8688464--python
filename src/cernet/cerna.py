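"""Evidence filtering and sign-consistent ceRNA triple assembly.

A competing endogenous RNA (ceRNA) triple is a lncRNA-miRNA-mRNA trio in
which the lncRNA sponges the shared miRNA and thereby de-represses the
mRNA. Two constraints define a candidate triple here:

* evidence: the miRNA-mRNA pair must be supported by at least ``min_db``
  distinct target-prediction databases (default 3 of 5); the miRNA-lncRNA
  pair must be present in the single lncRNA-interaction table;
* sign consistency: all three members are differentially expressed, with
  the lncRNA and mRNA sharing a direction opposite to the miRNA's
  (lncRNA up / miRNA down / mRNA up, or the mirror pattern).

Triples — not merged star subgraphs — are the primitive; the network is
derived from them, which keeps the sign rule locally checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .diffexpr import DERecord

__all__ = [
    "CeRNATriple",
    "normalize_id",
    "normalize_ids",
    "filter_by_evidence",
    "assemble_triples",
    "build_network",
    "rank_hubs",
    "triples_to_frame",
]


@dataclass(frozen=True, order=True)
class CeRNATriple:
    """A sign-consistent (lncRNA, miRNA, mRNA) triple with its evidence."""

    lncrna: str
    mirna: str
    mrna: str
    lncrna_direction: str
    mirna_direction: str
    mrna_direction: str
    evidence: int  # distinct databases supporting the miRNA-mRNA pair

    @property
    def polarity(self) -> str:
        """``miRNA-down`` or ``miRNA-up`` — the two allowed sign patterns."""
        return f"miRNA-{self.mirna_direction}"


def normalize_id(identifier: str) -> str:
    """Case-fold an id and repair the common ``has-`` -> ``hsa-`` typo."""
    out = identifier.strip().casefold()
    if out.startswith("has-"):
        out = "hsa-" + out[4:]
    return out


def normalize_ids(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize the ``mirna`` and ``target`` columns; collapse duplicates.

    Rows identical after normalization (same regulator, target and source
    database) are collapsed to one.
    """
    out = records.copy()
    out["mirna"] = out["mirna"].map(normalize_id)
    out["target"] = out["target"].map(normalize_id)
    out = out.drop_duplicates(ignore_index=True)
    return out


def filter_by_evidence(
    records: pd.DataFrame, min_db: int = 3
) -> pd.DataFrame:
    """Retain (miRNA, target) pairs present in at least ``min_db`` databases.

    Duplicate rows within one database count once. Returns a table with
    columns ``mirna, target, evidence`` sorted by (mirna, target).
    """
    if min_db < 1:
        raise ValueError("min_db must be >= 1")
    counts = (
        records.groupby(["mirna", "target"])["database"]
        .nunique()
        .rename("evidence")
        .reset_index()
    )
    kept = counts[counts["evidence"] >= min_db]
    return kept.sort_values(["mirna", "target"], ignore_index=True)


def _pair_set(pairs: pd.DataFrame | Iterable[tuple[str, str]]):
    if isinstance(pairs, pd.DataFrame):
        return {
            (normalize_id(m), normalize_id(t))
            for m, t in zip(pairs["mirna"], pairs["target"])
        }
    return {(normalize_id(m), normalize_id(t)) for m, t in pairs}


def assemble_triples(
    de_lnc: list[DERecord],
    de_mir: list[DERecord],
    de_mrna: list[DERecord],
    lnc_mir_pairs: pd.DataFrame | Iterable[tuple[str, str]],
    mir_mrna_pairs: pd.DataFrame,
    evidence: Mapping[tuple[str, str], int] | None = None,
) -> list[CeRNATriple]:
    """Emit every sign-consistent, evidence-backed ceRNA triple.

    A triple (L, M, G) is emitted iff the (M, L) pair is in the
    lncRNA-interaction table, the (M, G) pair survived the evidence filter,
    all three members are differentially expressed, and
    dir(L) = dir(G) = -dir(M). Ids are matched after normalization but
    triples carry the DE lists' original spellings. Output is sorted by
    (lncRNA, miRNA, mRNA).

    ``mir_mrna_pairs`` may be the output of :func:`filter_by_evidence`
    (its ``evidence`` column is used); otherwise pass ``evidence`` counts
    explicitly or each pair defaults to evidence 1.
    """
    ev: dict[tuple[str, str], int] = {}
    if isinstance(mir_mrna_pairs, pd.DataFrame) and "evidence" in mir_mrna_pairs:
        for m, t, e in zip(
            mir_mrna_pairs["mirna"],
            mir_mrna_pairs["target"],
            mir_mrna_pairs["evidence"],
        ):
            ev[(normalize_id(m), normalize_id(t))] = int(e)
    else:
        for pair in _pair_set(mir_mrna_pairs):
            ev[pair] = 1
    if evidence is not None:
        for (m, t), e in evidence.items():
            ev[(normalize_id(m), normalize_id(t))] = int(e)
    ml_pairs = _pair_set(lnc_mir_pairs)

    lnc_by_mir: dict[str, list[DERecord]] = {}
    for m, l in ml_pairs:
        lnc_by_mir.setdefault(m, [])
    mrna_by_mir: dict[str, list[DERecord]] = {}
    for m, _ in ev:
        mrna_by_mir.setdefault(m, [])
    lnc_norm = {normalize_id(r.feature): r for r in de_lnc}
    mrna_norm = {normalize_id(r.feature): r for r in de_mrna}
    for m, l in ml_pairs:
        rec = lnc_norm.get(l)
        if rec is not None:
            lnc_by_mir[m].append(rec)
    for m, g in ev:
        rec = mrna_norm.get(g)
        if rec is not None:
            mrna_by_mir[m].append(rec)

    triples: list[CeRNATriple] = []
    for mrec in de_mir:
        m = normalize_id(mrec.feature)
        opposite = "down" if mrec.direction == "up" else "up"
        for lrec in lnc_by_mir.get(m, ()):
            if lrec.direction != opposite:
                continue
            for grec in mrna_by_mir.get(m, ()):
                if grec.direction != opposite:
                    continue
                triples.append(
                    CeRNATriple(
                        lncrna=lrec.feature,
                        mirna=mrec.feature,
                        mrna=grec.feature,
                        lncrna_direction=lrec.direction,
                        mirna_direction=mrec.direction,
                        mrna_direction=grec.direction,
                        evidence=ev[(m, normalize_id(grec.feature))],
                    )
                )
    triples.sort(key=lambda t: (t.lncrna, t.mirna, t.mrna))
    return triples


def build_network(triples: Iterable[CeRNATriple]) -> nx.Graph:
    """Materialize the (bipartite miRNA vs lncRNA/mRNA) ceRNA network.

    Nodes carry ``kind`` and ``direction`` attributes; edges carry ``kind``
    (``lncRNA-miRNA`` or ``miRNA-mRNA``). Nodes and edges are deduplicated
    across triples.
    """
    g = nx.Graph()
    for t in triples:
        g.add_node(t.lncrna, kind="lncRNA", direction=t.lncrna_direction)
        g.add_node(t.mirna, kind="miRNA", direction=t.mirna_direction)
        g.add_node(t.mrna, kind="mRNA", direction=t.mrna_direction)
        g.add_edge(t.lncrna, t.mirna, kind="lncRNA-miRNA")
        g.add_edge(t.mirna, t.mrna, kind="miRNA-mRNA")
    return g


def rank_hubs(network: nx.Graph, k: int = 10) -> list[tuple[str, int]]:
    """Top-k nodes by degree, ties at the k-th degree fully expanded.

    Sorted by degree descending, then node id ascending.
    """
    ranked = sorted(network.degree(), key=lambda nd: (-nd[1], nd[0]))
    if k <= 0 or not ranked:
        return []
    if len(ranked) <= k:
        return [(n, int(d)) for n, d in ranked]
    cutoff = ranked[k - 1][1]
    return [(n, int(d)) for n, d in ranked if d >= cutoff]


def triples_to_frame(triples: Iterable[CeRNATriple]) -> pd.DataFrame:
    """Tabular view of triples (one row each, with polarity)."""
    rows = [
        {
            "lncrna": t.lncrna,
            "mirna": t.mirna,
            "mrna": t.mrna,
            "lncrna_direction": t.lncrna_direction,
            "mirna_direction": t.mirna_direction,
            "mrna_direction": t.mrna_direction,
            "evidence": t.evidence,
            "polarity": t.polarity,
        }
        for t in triples
    ]
    cols = [
        "lncrna", "mirna", "mrna", "lncrna_direction", "mirna_direction",
        "mrna_direction", "evidence", "polarity",
    ]
    return pd.DataFrame(rows, columns=cols)
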