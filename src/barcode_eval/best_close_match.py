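"""Best Close Match (BCM) species identification.

Each query sequence is compared against every other sequence in the
library; candidates are those within a distance threshold t. The set of
candidates at the minimal distance decides the status:

* correct    — all minimal-distance candidates are conspecific;
* incorrect  — none are;
* ambiguous  — the minimal-distance set spans several species;
* no_id      — no candidate within t.

Singleton species (one sequence in the library) can never match a
conspecific; under ``singleton_policy="correct"`` a singleton with no
match within t counts as correctly identified — no heterospecific lies
close enough to mislead — instead of no_id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

DISTANCE_TIE_TOL = 1e-12

STATUSES = ("correct", "incorrect", "ambiguous", "no_id")


@dataclass
class BCMRecord:
    specimen_id: str
    species: str
    best_match_ids: list[str]
    best_distance: float          # nan when no match within threshold
    status: str
    singleton_rule_applied: bool = False


@dataclass
class BCMReport:
    records: list[BCMRecord]
    threshold: float
    singleton_policy: str

    def counts(self) -> dict[str, int]:
        c = dict.fromkeys(STATUSES, 0)
        for r in self.records:
            c[r.status] += 1
        return c

    @property
    def efficiency(self) -> float:
        """Percentage of correct identifications."""
        return 100.0 * self.counts()["correct"] / len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"specimen_id": r.specimen_id, "species": r.species,
              "best_match": ",".join(r.best_match_ids),
              "best_distance": r.best_distance, "status": r.status,
              "singleton_rule_applied": r.singleton_rule_applied}
             for r in self.records])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def best_close_match(matrix: DistanceMatrix, species_labels: list[str],
                     t: float,
                     singleton_policy: str = "correct") -> BCMReport:
    """Classify every sequence by its nearest neighbours within t.

    Distances flagged undefined count as "no match" for that pair. Ties at
    the minimal distance are resolved as a set (tolerance 1e-12): a mixed
    set is ambiguous.
    """
    if singleton_policy not in ("correct", "no_id"):
        raise ValueError(f"unknown singleton_policy '{singleton_policy}'")
    sp = np.asarray(species_labels)
    ids = np.asarray(matrix.ids)
    counts = pd.Series(sp).value_counts()
    d = matrix.d.copy()
    np.fill_diagonal(d, np.nan)

    records: list[BCMRecord] = []
    for i in range(matrix.n):
        row = d[i]
        within = ~np.isnan(row) & (row <= t)
        singleton = counts[sp[i]] == 1
        if not within.any():
            if singleton and singleton_policy == "correct":
                records.append(BCMRecord(ids[i], sp[i], [], np.nan,
                                         "correct",
                                         singleton_rule_applied=True))
            else:
                records.append(BCMRecord(ids[i], sp[i], [], np.nan, "no_id"))
            continue
        best = np.nanmin(np.where(within, row, np.nan))
        tie = within & (row <= best + DISTANCE_TIE_TOL)
        match_species = set(sp[tie])
        if len(match_species) > 1:
            status = "ambiguous"
        elif sp[i] in match_species:
            status = "correct"
        else:
            status = "incorrect"
        records.append(BCMRecord(ids[i], sp[i], list(ids[tie]), float(best),
                                 status))
    return BCMReport(records, threshold=t, singleton_policy=singleton_policy)


def efficiency_summary(report: "BCMReport | dict[str, int]") -> dict:
    """Aggregate status percentages and overall identification efficiency.

    Accepts a BCMReport, or a plain mapping of status -> count so that
    published tallies can be summarized directly.
    """
    counts = report.counts() if isinstance(report, BCMReport) else dict(report)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty report")
    pct = {s: 100.0 * counts.get(s, 0) / total for s in STATUSES}
    return {
        "n": total,
        "counts": {s: counts.get(s, 0) for s in STATUSES},
        "percent": pct,
        "efficiency_percent": pct["correct"],
    }
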