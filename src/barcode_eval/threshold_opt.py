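"""Optimal identification thresholds by cumulative-error minimization.

A candidate threshold t splits identification failures into false
positives — sequences whose nearest conspecific lies beyond t (the species
looks over-split) — and false negatives — sequences with a heterospecific
within t (lumping). The cumulative error CE(t) = FP(t) + FN(t) is scanned
over a grid and the optimal threshold (OT) is the argmin, smallest t on
ties. Counting is per sequence via minimum conspecific / minimum
heterospecific distance, the nearest-neighbour reading that matches
best-close-match logic and lets CE be reported in sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distance import DistanceMatrix, distance_matrix
from .io_metadata import BarcodeDataset, split_by_taxon


def default_grid(start: float = 0.001, stop: float = 0.10,
                 step: float = 0.001) -> np.ndarray:
    """Default threshold grid: 0.1%-resolution from 0.1% to 10%."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def _min_intra_inter(matrix: DistanceMatrix,
                     species_labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence minimum defined conspecific / heterospecific distance.

    nan where a sequence has no conspecific (singleton) or no defined
    distance in the respective class.
    """
    sp = np.asarray(species_labels)
    d = matrix.d.copy()
    np.fill_diagonal(d, np.nan)
    same = sp[:, None] == sp[None, :]
    with warnings.catch_warnings():
        # all-nan rows (singletons) legitimately yield nan
        warnings.simplefilter("ignore", RuntimeWarning)
        min_intra = np.nanmin(np.where(same, d, np.nan), axis=1)
        min_inter = np.nanmin(np.where(~same, d, np.nan), axis=1)
    return min_intra, min_inter


def classify_at_threshold(matrix: DistanceMatrix, species_labels: list[str],
                          t: float) -> tuple[list[str], list[str]]:
    """Sequences in error at threshold t: (fp_ids, fn_ids).

    FP: has a defined conspecific distance and the minimum exceeds t.
    FN: minimum defined heterospecific distance <= t. A sequence can be
    both; singletons can only be FN.
    """
    min_intra, min_inter = _min_intra_inter(matrix, species_labels)
    ids = np.asarray(matrix.ids)
    fp = ids[~np.isnan(min_intra) & (min_intra > t)]
    fn = ids[~np.isnan(min_inter) & (min_inter <= t)]
    return list(fp), list(fn)


@dataclass
class ThresholdScan:
    """Per-threshold FP/FN/CE counts and the selected optimal threshold."""

    ids: list[str]
    thresholds: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    ce: np.ndarray
    optimal: float
    optimal_index: int
    n_evaluable: int
    # per-sequence 0/1 indicator (FP or FN) at the optimal threshold:
    error_at_optimal: np.ndarray = field(repr=False)
    n_doubly_flagged_at_optimal: int = 0
    label: str = ""

    @property
    def ce_at_optimal(self) -> int:
        return int(self.ce[self.optimal_index])

    @property
    def fp_at_optimal(self) -> int:
        return int(self.fp[self.optimal_index])

    @property
    def fn_at_optimal(self) -> int:
        return int(self.fn[self.optimal_index])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"threshold": self.thresholds, "fp": self.fp,
                             "fn": self.fn, "ce": self.ce})


def threshold_scan(matrix: DistanceMatrix, species_labels: list[str],
                   grid: np.ndarray | list[float],
                   label: str = "") -> ThresholdScan:
    """Scan CE over a threshold grid and select the optimal threshold.

    The per-sequence minimum conspecific/heterospecific distances are
    computed once; each grid point is then a pair of comparisons, so the
    scan is exact (identical to re-classifying at every t) and cheap.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(np.diff(grid) < 0) or np.any(grid < 0):
        raise ValueError("grid must be sorted ascending and non-negative")
    min_intra, min_inter = _min_intra_inter(matrix, species_labels)
    has_intra = ~np.isnan(min_intra)
    has_inter = ~np.isnan(min_inter)
    # (n_seq, n_grid) boolean tables
    fp_tab = has_intra[:, None] & (min_intra[:, None] > grid[None, :])
    fn_tab = has_inter[:, None] & (min_inter[:, None] <= grid[None, :])
    fp = fp_tab.sum(axis=0)
    fn = fn_tab.sum(axis=0)
    ce = fp + fn
    k = int(np.argmin(ce))  # argmin returns the first = smallest t on ties
    err = fp_tab[:, k] | fn_tab[:, k]
    return ThresholdScan(
        ids=list(matrix.ids),
        thresholds=grid, fp=fp, fn=fn, ce=ce,
        optimal=float(grid[k]), optimal_index=k,
        n_evaluable=int((has_intra | has_inter).sum()),
        error_at_optimal=err.astype(np.int8),
        n_doubly_flagged_at_optimal=int((fp_tab[:, k] & fn_tab[:, k]).sum()),
        label=label,
    )


def partitioned_scan(dataset: BarcodeDataset, rank: str = "subfamily",
                     grid: np.ndarray | list[float] | None = None,
                     model: str = "K2P") -> list[tuple[str, ThresholdScan]]:
    """Independent threshold scan per taxon partition.

    Distances are recomputed within each partition (pairwise deletion makes
    a submatrix slice equivalent, but recomputation keeps partitions
    self-contained). Partitions with <2 species are dropped upstream.
    """
    if grid is None:
        grid = default_grid()
    out = []
    for part in split_by_taxon(dataset, rank=rank):
        m = distance_matrix(part, model=model)
        out.append((part.label,
                    threshold_scan(m, part.species_labels, grid,
                                   label=part.label)))
    return out


def cumulative_error_percent(fp: int, fn: int, n: int) -> float:
    """CE as a percentage of evaluated sequences."""
    return 100.0 * (fp + fn) / n


@dataclass
class PartitionComparison:
    """Family-level vs summed partition-level cumulative error."""

    family_ce: int
    family_ce_percent: float
    partition_ce_sum: int
    partition_ce_percent: float
    n_sequences: int
    t_statistic: float
    p_value: float
    note: str = ""


def compare_family_vs_partitions(
        family_scan: ThresholdScan,
        partition_scans: list[tuple[str, ThresholdScan]]) -> PartitionComparison:
    """Compare identification error under one family-wide OT vs per-taxon OTs.

    Per-sequence binary error indicators (1 = FP or FN at the relevant OT)
    are compared between the two schemes with a two-sample Student t test
    (equal variances). Only sequences present in both schemes (i.e. in a
    retained partition) enter the comparison, so percentages share a
    denominator.
    """
    part_err: dict[str, int] = {}
    for _, scan in partition_scans:
        for sid, e in zip(scan.ids, scan.error_at_optimal):
            part_err[sid] = int(e)
    fam = {sid: int(e) for sid, e in zip(family_scan.ids,
                                         family_scan.error_at_optimal)}
    common = [sid for sid in family_scan.ids if sid in part_err]
    a = np.array([fam[sid] for sid in common], dtype=float)
    b = np.array([part_err[sid] for sid in common], dtype=float)
    n = len(common)
    note = ""
    if n == 0 or (a.std() == 0 and b.std() == 0):
        t_stat, p_val = float("nan"), float("nan")
        note = "degenerate indicator vectors; t statistic undefined"
    else:
        res = stats.ttest_ind(b, a, equal_var=True)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return PartitionComparison(
        family_ce=int(a.sum()),
        family_ce_percent=100.0 * a.sum() / n if n else float("nan"),
        partition_ce_sum=int(b.sum()),
        partition_ce_percent=100.0 * b.sum() / n if n else float("nan"),
        n_sequences=n, t_statistic=t_stat, p_value=p_val, note=note)
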