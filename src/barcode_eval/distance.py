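"""Pairwise genetic distances and intra/interspecific decomposition.

Distances are Kimura two-parameter (K2P) or uncorrected p-distances with
pairwise deletion: for each pair, only sites where both sequences carry an
unambiguous A/C/G/T are compared. With P the proportion of compared sites
differing by a transition and Q by a transversion,

    d_K2P = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

The correction is undefined (saturated) when a log argument is <= 0; such
pairs are flagged and excluded from summaries rather than capped. All
distances are substitutions/site (fractions); reporting layers convert to
percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_metadata import BarcodeDataset

# encoding: A=0, C=1, G=2, T=3; gaps/ambiguity codes = -1 (missing).
# Transition partner is base XOR 2 (A<->G, C<->T).
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes; non-ACGT become -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class PairDistance(NamedTuple):
    distance: float          # nan when undefined
    p_transitions: float     # P
    q_transversions: float   # Q
    n_sites: int
    defined: bool


def _k2p_from_pq(p: float, q: float) -> tuple[float, bool]:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, False
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), True


def k2p_distance(seq_a: str, seq_b: str) -> PairDistance:
    """K2P distance between two aligned sequences (pairwise deletion).

    Returns the distance together with the transition (P) and transversion
    (Q) proportions and the number of compared sites. Zero comparable sites
    or a saturated correction yield a flagged undefined result.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"unequal lengths: {len(seq_a)} vs {len(seq_b)}")
    a, b = encode_sequence(seq_a), encode_sequence(seq_b)
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    if n == 0:
        return PairDistance(math.nan, math.nan, math.nan, 0, False)
    diff = both & (a != b)
    ts = int((diff & ((a ^ 2) == b)).sum())
    tv = int(diff.sum()) - ts
    p, q = ts / n, tv / n
    d, ok = _k2p_from_pq(p, q)
    return PairDistance(d, p, q, n, ok)


def p_distance(seq_a: str, seq_b: str) -> PairDistance:
    """Uncorrected proportion of differing sites (pairwise deletion)."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"unequal lengths: {len(seq_a)} vs {len(seq_b)}")
    a, b = encode_sequence(seq_a), encode_sequence(seq_b)
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    if n == 0:
        return PairDistance(math.nan, math.nan, math.nan, 0, False)
    diff = both & (a != b)
    ts = int((diff & ((a ^ 2) == b)).sum())
    tv = int(diff.sum()) - ts
    return PairDistance(int(diff.sum()) / n, ts / n, tv / n, n, True)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over specimens.

    ``d`` holds nan for undefined (saturated or zero-overlap) pairs;
    ``undefined_pairs`` lists them explicitly so they are never silently
    zeroed. ``n_sites`` counts compared sites per pair.
    """

    ids: list[str]
    d: np.ndarray
    model: str
    n_sites: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, k=1)
        bad = np.isnan(self.d[iu])
        return [(self.ids[i], self.ids[j])
                for i, j in zip(iu[0][bad], iu[1][bad])]

    def submatrix(self, keep: Sequence[int]) -> "DistanceMatrix":
        keep = list(keep)
        return DistanceMatrix([self.ids[i] for i in keep],
                              self.d[np.ix_(keep, keep)], self.model,
                              self.n_sites[np.ix_(keep, keep)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.ids,
                     columns=self.ids).to_csv(path, sep="\t")


def distance_matrix(dataset: BarcodeDataset,
                    model: str = "K2P") -> DistanceMatrix:
    """All-against-all distance matrix under K2P or p-distance.

    Vectorized row-at-a-time; equivalent to calling :func:`k2p_distance`
    on every pair.
    """
    if model not in ("K2P", "p"):
        raise ValueError(f"unknown model '{model}'")
    n = len(dataset)
    enc = np.vstack([encode_sequence(r.sequence) for r in dataset.records])
    valid = enc >= 0
    d = np.zeros((n, n))
    nsites = np.zeros((n, n), dtype=np.int64)
    nsites[np.diag_indices(n)] = valid.sum(axis=1)
    for i in range(n - 1):
        rest = slice(i + 1, n)
        both = valid[i] & valid[rest]
        diff = (enc[i] != enc[rest]) & both
        ts = (diff & ((enc[i] ^ 2) == enc[rest])).sum(axis=1)
        ndiff = diff.sum(axis=1)
        nn = both.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            if model == "p":
                row = np.where(nn > 0, ndiff / np.maximum(nn, 1), np.nan)
            else:
                p = ts / np.maximum(nn, 1)
                q = (ndiff - ts) / np.maximum(nn, 1)
                w1 = 1.0 - 2.0 * p - q
                w2 = 1.0 - 2.0 * q
                row = np.where((nn > 0) & (w1 > 0) & (w2 > 0),
                               -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                               - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                               np.nan)
        d[i, rest] = row
        d[rest, i] = row
        nsites[i, rest] = nn
        nsites[rest, i] = nn
    return DistanceMatrix(dataset.ids, d, model, nsites)


@dataclass
class DistanceDecomposition:
    """Defined pairwise distances split into intra- and interspecific sets."""

    intra: pd.DataFrame    # columns: species, id_a, id_b, distance
    inter: pd.DataFrame    # columns: species_a, species_b, id_a, id_b, distance
    n_undefined: int

    def summary(self) -> dict:
        out = {}
        for name, frame in (("intra", self.intra), ("inter", self.inter)):
            vals = frame["distance"].to_numpy()
            out[name] = (
                {"n": 0, "mean": None, "min": None, "max": None}
                if vals.size == 0 else
                {"n": int(vals.size), "mean": float(vals.mean()),
                 "min": float(vals.min()), "max": float(vals.max())}
            )
        out["n_undefined"] = self.n_undefined
        return out


def decompose(matrix: DistanceMatrix,
              dataset: BarcodeDataset) -> DistanceDecomposition:
    """Assign every defined pair to the intra- or interspecific set.

    Singleton species contribute no intraspecific pairs; undefined pairs
    are counted but excluded from both sets.
    """
    species = {r.specimen_id: r.species for r in dataset.records}
    sp = np.array([species[i] for i in matrix.ids])
    iu = np.triu_indices(matrix.n, k=1)
    vals = matrix.d[iu]
    defined = ~np.isnan(vals)
    same = sp[iu[0]] == sp[iu[1]]
    ids = np.array(matrix.ids)

    m_in = defined & same
    m_out = defined & ~same
    intra = pd.DataFrame({
        "species": sp[iu[0]][m_in],
        "id_a": ids[iu[0]][m_in], "id_b": ids[iu[1]][m_in],
        "distance": vals[m_in]})
    inter = pd.DataFrame({
        "species_a": sp[iu[0]][m_out], "species_b": sp[iu[1]][m_out],
        "id_a": ids[iu[0]][m_out], "id_b": ids[iu[1]][m_out],
        "distance": vals[m_out]})
    return DistanceDecomposition(intra, inter,
                                 n_undefined=int((~defined).sum()))


def pairs_long_format(matrix: DistanceMatrix,
                      dataset: BarcodeDataset) -> pd.DataFrame:
    """Long-format pair table (id_a, id_b, model, distance, n_sites, class)."""
    species = {r.specimen_id: r.species for r in dataset.records}
    iu = np.triu_indices(matrix.n, k=1)
    ids = np.array(matrix.ids)
    sp = np.array([species[i] for i in matrix.ids])
    return pd.DataFrame({
        "id_a": ids[iu[0]], "id_b": ids[iu[1]],
        "model": matrix.model,
        "distance": matrix.d[iu],
        "n_sites": matrix.n_sites[iu],
        "class": np.where(sp[iu[0]] == sp[iu[1]], "intra", "inter"),
    })
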