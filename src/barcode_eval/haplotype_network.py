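"""Haplotype collapsing and minimum-spanning networks.

Specimens sharing a sequence are collapsed into haplotypes; a
minimum-spanning network (MSN, the union of all minimum spanning trees of
the haplotype Hamming-distance graph) then shows the mutational steps
between them. Haplotypes carrying more than one species diagnose the
problem groups where barcoding fails — introgression, incomplete lineage
sorting or over-split taxonomy.

Missing data rule: sites with a gap or ambiguity code in either sequence
are ignored for the identity test, so an N never splits a haplotype. Each
haplotype keeps a fill-in consensus (missing sites completed from later
members) against which new specimens are compared; because
identical-modulo-missing is not transitive, the grouping follows input
order for the rare conflicting cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .distance import encode_sequence
from .io_metadata import BarcodeDataset


@dataclass
class Haplotype:
    haplotype_id: str
    sequence: str                      # fill-in consensus of members
    members: list[str]
    species_composition: dict[str, int]
    _consensus: np.ndarray = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_species(self) -> int:
        return len(self.species_composition)


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    both = (a >= 0) & (b >= 0)
    return bool(np.all(a[both] == b[both]))


def collapse_haplotypes(dataset: BarcodeDataset) -> list[Haplotype]:
    """Collapse specimens into haplotypes (missing-data tolerant).

    Exact duplicate strings are grouped first; the resulting unique
    sequences are then merged greedily whenever they agree at every
    mutually unambiguous site.
    """
    by_string: dict[str, list] = {}
    for r in dataset.records:
        by_string.setdefault(r.sequence, []).append(r)

    haps: list[Haplotype] = []
    for seq, recs in by_string.items():
        enc = encode_sequence(seq)
        target = None
        has_missing = (enc < 0).any()
        for h in haps:
            # distinct fully-resolved strings can never merge
            if (has_missing or (h._consensus < 0).any()) \
                    and _compatible(h._consensus, enc):
                target = h
                break
        if target is None:
            haps.append(Haplotype(
                haplotype_id=f"H{len(haps) + 1:04d}",
                sequence=seq,
                members=[r.specimen_id for r in recs],
                species_composition={},
                _consensus=enc.copy()))
            target = haps[-1]
        else:
            target.members.extend(r.specimen_id for r in recs)
            fill = (target._consensus < 0) & (enc >= 0)
            target._consensus[fill] = enc[fill]
            target.sequence = _decode(target._consensus, seq)
        for r in recs:
            comp = target.species_composition
            comp[r.species] = comp.get(r.species, 0) + 1
    return haps


_BASES = np.array(list("ACGT"))


def _decode(enc: np.ndarray, template: str) -> str:
    out = list(template)
    known = enc >= 0
    for i in np.nonzero(known)[0]:
        out[i] = _BASES[enc[i]]
    return "".join(out)


def shared_haplotypes(haplotypes: list[Haplotype]) -> list[Haplotype]:
    """Haplotypes carried by two or more species."""
    return [h for h in haplotypes if h.n_species >= 2]


def haplotype_distances(haplotypes: list[Haplotype]) -> np.ndarray:
    """Integer substitution counts (Hamming over pairwise-complete sites)."""
    k = len(haplotypes)
    enc = np.vstack([h._consensus for h in haplotypes])
    valid = enc >= 0
    d = np.zeros((k, k), dtype=np.int64)
    for i in range(k - 1):
        both = valid[i] & valid[i + 1:]
        d[i, i + 1:] = ((enc[i] != enc[i + 1:]) & both).sum(axis=1)
        d[i + 1:, i] = d[i, i + 1:]
    return d


@dataclass
class HaplotypeNetwork:
    nodes: list[Haplotype]
    # (hap_a, hap_b, mutations, in_all_msts)
    edges: list[tuple[str, str, int, bool]]

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"haplotype_id": h.haplotype_id, "size": h.size,
              "n_species": h.n_species,
              "species_composition": ";".join(
                  f"{s}:{c}" for s, c in sorted(h.species_composition.items()))}
             for h in self.nodes])

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["hap_a", "hap_b",
                                                 "mutations", "in_all_msts"])

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for h in self.nodes:
            g.add_node(h.haplotype_id, size=h.size,
                       species=";".join(sorted(h.species_composition)))
        for a, b, w, forced in self.edges:
            g.add_edge(a, b, mutations=int(w), in_all_msts=bool(forced))
        nx.write_graphml(g, str(path))


def minimum_spanning_network(haplotypes: list[Haplotype],
                             distances: np.ndarray | None = None,
                             epsilon: int = 0) -> HaplotypeNetwork:
    """Union of all minimum spanning trees of the haplotype graph.

    Kruskal by ascending weight level: an edge of weight w joins the
    network iff its endpoints lie in different components of the graph
    built from all strictly cheaper (by more than epsilon) retained edges —
    exactly the edges belonging to at least one MST when epsilon = 0.
    ``in_all_msts`` marks edges whose removal would disconnect their weight
    level (bridges of the component multigraph), i.e. edges present in
    every MST.
    """
    k = len(haplotypes)
    if k == 0:
        raise ValueError("no haplotypes")
    if distances is None:
        distances = haplotype_distances(haplotypes)
    ids = [h.haplotype_id for h in haplotypes]
    if k == 1:
        return HaplotypeNetwork(list(haplotypes), [])

    uf = nx.utils.UnionFind(range(k))
    iu = np.triu_indices(k, 1)
    order = np.lexsort((iu[1], iu[0], distances[iu]))
    pairs = list(zip(distances[iu][order], iu[0][order], iu[1][order]))

    edges: list[tuple[str, str, int, bool]] = []
    pos = 0
    while pos < len(pairs):
        w = pairs[pos][0]
        level = []
        while pos < len(pairs) and pairs[pos][0] <= w + epsilon:
            level.append(pairs[pos])
            pos += 1
        # candidate edges: endpoints in different components so far
        cand = [(int(wi), int(i), int(j)) for wi, i, j in level
                if uf[i] != uf[j]]
        if not cand:
            continue
        # forced edges are bridges of the component-level multigraph
        cg = nx.MultiGraph()
        for wi, i, j in cand:
            cg.add_edge(uf[i], uf[j], key=(i, j))
        simple = nx.Graph(cg)
        multi = {frozenset(e): cg.number_of_edges(*e) for e in simple.edges}
        bridges = {frozenset(e) for e in nx.bridges(simple)}
        for wi, i, j in cand:
            key = frozenset((uf[i], uf[j]))
            forced = key in bridges and multi[key] == 1
            edges.append((ids[i], ids[j], wi, forced))
        for wi, i, j in cand:
            uf.union(i, j)
    return HaplotypeNetwork(list(haplotypes), edges)


def haplotypes_per_species(haplotypes: list[Haplotype]) -> dict[str, int]:
    """Number of distinct haplotypes observed per species."""
    out: dict[str, int] = {}
    for h in haplotypes:
        for s in h.species_composition:
            out[s] = out.get(s, 0) + 1
    return out
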