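"""Reading, writing and partitioning barcode reference libraries.

A library is an aligned FASTA of COI barcodes plus a tab-separated specimen
metadata table (one row per specimen: id, species, genus, subfamily, family,
and optionally the record source and an accession). The layout mirrors a
trimmed BOLD specimen export. Sequences must arrive aligned: the reader
enforces equal lengths and leaves alignment to upstream tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

METADATA_COLUMNS = ("specimen_id", "species", "genus", "subfamily", "family",
                    "source", "accession")

_UNAMBIGUOUS = set("ACGT")


def _norm_name(name: str) -> str:
    """Normalization key for species-name matching: collapse whitespace,
    case-fold everything but the leading genus capital."""
    parts = name.split()
    return " ".join(p.lower() for p in parts).capitalize()


@dataclass
class SpecimenRecord:
    """One barcode sequence with its taxonomic assignment."""

    specimen_id: str
    sequence: str
    species: str
    genus: str
    subfamily: str
    family: str
    source: str | None = None      # "new" | "mined"
    accession: str | None = None


@dataclass
class BarcodeDataset:
    """A set of aligned specimen records forming one reference library."""

    records: list[SpecimenRecord]
    label: str = "dataset"
    alignment_length: int = 0

    def __post_init__(self) -> None:
        if self.records and not self.alignment_length:
            self.alignment_length = len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def species_labels(self) -> list[str]:
        return [r.species for r in self.records]

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.species] = counts.get(r.species, 0) + 1
        return counts

    def validate(self) -> None:
        seen: set[str] = set()
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(
                f"ragged alignment in dataset '{self.label}': "
                f"sequence lengths {sorted(lengths)}")
        for r in self.records:
            if r.specimen_id in seen:
                raise ValueError(f"duplicate specimen_id '{r.specimen_id}'")
            seen.add(r.specimen_id)


@dataclass
class SynonymMap:
    """Explicit mapping of species-name variants to accepted names.

    Stands in for the manual nomenclature check against a reference
    checklist; the map is made idempotent on construction (every accepted
    name maps to itself) and lookups are whitespace/case normalized.
    """

    pairs: dict[str, str] = field(default_factory=dict)
    _norm: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for variant, accepted in list(self.pairs.items()):
            self.pairs.setdefault(accepted, accepted)
        self._norm = {_norm_name(v): a for v, a in self.pairs.items()}

    def resolve(self, name: str) -> str:
        return self._norm.get(_norm_name(name), name)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymMap":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         comment="#").dropna()
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


# ---------------------------------------------------------------------------
# Read / write

def read_dataset(fasta_path: str | Path, metadata_path: str | Path,
                 label: str | None = None) -> BarcodeDataset:
    """Load an aligned FASTA plus its metadata TSV into a BarcodeDataset.

    FASTA record order is preserved. Every FASTA id must have a metadata
    row; sequences must share one alignment length.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing_cols = {"specimen_id", "species", "subfamily",
                    "family"} - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    rows = meta.set_index("specimen_id", drop=False)

    records: list[SpecimenRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in rows.index:
            raise ValueError(f"metadata missing for specimen '{rec.id}'")
        row = rows.loc[rec.id]
        records.append(SpecimenRecord(
            specimen_id=rec.id,
            sequence=str(rec.seq).upper(),
            species=row["species"],
            genus=row.get("genus", ""),
            subfamily=row["subfamily"],
            family=row["family"],
            source=row.get("source") or None,
            accession=row.get("accession") or None,
        ))
    ds = BarcodeDataset(records, label=label or Path(fasta_path).stem)
    ds.validate()
    return ds


def write_dataset(dataset: BarcodeDataset, fasta_path: str | Path,
                  metadata_path: str | Path) -> None:
    """Write the dataset back out as aligned FASTA + metadata TSV."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
            for r in dataset.records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    pd.DataFrame(
        [{"specimen_id": r.specimen_id, "species": r.species,
          "genus": r.genus, "subfamily": r.subfamily, "family": r.family,
          "source": r.source or "", "accession": r.accession or ""}
         for r in dataset.records],
        columns=list(METADATA_COLUMNS),
    ).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy handling

def standardize_taxonomy(dataset: BarcodeDataset,
                         synonyms: SynonymMap) -> BarcodeDataset:
    """Replace every species name by its accepted name.

    Names absent from the map pass through unchanged; the operation is
    idempotent because the map sends accepted names to themselves.
    """
    records = [replace(r, species=synonyms.resolve(r.species))
               for r in dataset.records]
    return BarcodeDataset(records, label=dataset.label,
                          alignment_length=dataset.alignment_length)


def split_by_taxon(dataset: BarcodeDataset,
                   rank: str = "subfamily") -> list[BarcodeDataset]:
    """Partition the dataset by subfamily (or genus).

    Partitions with fewer than two distinct species are dropped — a
    threshold or identification analysis on a single species is
    meaningless. Partitions preserve input record order.
    """
    if rank not in ("subfamily", "genus"):
        raise ValueError(f"unsupported rank '{rank}'")
    groups: dict[str, list[SpecimenRecord]] = {}
    for r in dataset.records:
        groups.setdefault(getattr(r, rank), []).append(r)
    out = []
    for taxon, recs in groups.items():
        if len({r.species for r in recs}) >= 2:
            out.append(BarcodeDataset(recs, label=taxon,
                                      alignment_length=dataset.alignment_length))
    return out


# ---------------------------------------------------------------------------
# Summary

def dataset_summary(dataset: BarcodeDataset) -> dict:
    """Sequence/species counts, ungapped length range and base composition.

    Base composition is computed over unambiguous bases (A/C/G/T) only and
    reported as percentages summing to 100 up to rounding.
    """
    counts = dataset.species_counts()
    base_counts = {b: 0 for b in "ACGT"}
    lengths = []
    for r in dataset.records:
        n_unamb = 0
        for b in r.sequence:
            if b in _UNAMBIGUOUS:
                base_counts[b] += 1
                n_unamb += 1
        lengths.append(sum(c not in "-." for c in r.sequence))
    total = sum(base_counts.values()) or 1
    return {
        "label": dataset.label,
        "n_sequences": len(dataset),
        "n_species": len(counts),
        "n_singleton_species": sum(1 for c in counts.values() if c == 1),
        "alignment_length": dataset.alignment_length,
        "length_min": min(lengths) if lengths else 0,
        "length_max": max(lengths) if lengths else 0,
        "length_mean": (sum(lengths) / len(lengths)) if lengths else 0.0,
        "base_composition_percent": {
            b: 100.0 * base_counts[b] / total for b in "ACGT"},
    }


def write_summary(summary: Mapping, json_path: str | Path | None = None,
                  tsv_path: str | Path | None = None) -> None:
    if json_path:
        Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")
    if tsv_path:
        flat = dict(summary)
        comp = flat.pop("base_composition_percent", {})
        for b, v in comp.items():
            flat[f"pct_{b}"] = v
        pd.DataFrame([flat]).to_csv(tsv_path, sep="\t", index=False)
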