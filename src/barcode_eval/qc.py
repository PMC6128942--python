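"""Pre-analysis sequence quality screens.

COI barcodes are protein-coding, so a genuine barcode must translate
without internal stop codons in at least one reading frame under the
invertebrate mitochondrial genetic code (NCBI table 5). This module
verifies the reading frame and applies length and ambiguity filters.
Filtering is advisory: reports flag records, the caller decides to drop.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io_metadata import BarcodeDataset

INVERTEBRATE_MITO_TABLE = 5

_GAPS = "-."
_UNAMBIGUOUS = set("ACGT")


@dataclass
class QCReport:
    specimen_id: str
    length_ungapped: int
    n_ambiguous: int
    frame: int | None
    has_internal_stop: bool
    passed: bool
    reasons: tuple[str, ...] = ()


def _has_internal_stop(ungapped: str, offset: int, table: int) -> bool:
    """Translate from `offset`, dropping the trailing partial codon.

    A stop in the final complete codon is treated as terminal and allowed;
    barcode fragments are mid-gene so any earlier stop marks a pseudogene,
    frameshift or contaminant. Ambiguous codons translate to X, never *.
    """
    sub = ungapped[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    aa = str(Seq(sub).translate(table=table))
    return "*" in aa[:-1]


def find_reading_frame(sequence: str, table: int = INVERTEBRATE_MITO_TABLE,
                       six_frame: bool = False) -> tuple[int | None, bool]:
    """Find the smallest offset in {0, 1, 2} with a stop-free translation.

    Gaps are stripped before translation. Returns ``(frame, has_internal_stop)``
    where frame is None and has_internal_stop True when every frame contains
    an internal stop. Reverse-strand frames are only searched when
    ``six_frame`` is set (inputs are assumed orientation-normalized); a
    clean frame found on the reverse strand is still reported in {0, 1, 2}.
    """
    ungapped = "".join(b for b in sequence.upper() if b not in _GAPS)
    if len(ungapped) < 3:
        raise ValueError("sequence shorter than one codon after degapping")
    strands = [ungapped]
    if six_frame:
        strands.append(str(Seq(ungapped).reverse_complement()))
    for strand in strands:
        for offset in range(3):
            if not _has_internal_stop(strand, offset, table):
                return offset, False
    return None, True


def qc_record(specimen_id: str, sequence: str, min_len: int = 400,
              max_len: int = 700, max_ambiguous_frac: float = 0.02,
              six_frame: bool = False,
              table: int = INVERTEBRATE_MITO_TABLE) -> QCReport:
    ungapped = "".join(b for b in sequence.upper() if b not in _GAPS)
    n_ambiguous = sum(1 for b in ungapped if b not in _UNAMBIGUOUS)
    frame, internal_stop = find_reading_frame(sequence, table=table,
                                              six_frame=six_frame)
    reasons = []
    if frame is None:
        reasons.append("no_open_reading_frame")
    if not (min_len <= len(ungapped) <= max_len):
        reasons.append("length")
    if ungapped and n_ambiguous / len(ungapped) > max_ambiguous_frac:
        reasons.append("ambiguity")
    return QCReport(
        specimen_id=specimen_id,
        length_ungapped=len(ungapped),
        n_ambiguous=n_ambiguous,
        frame=frame,
        has_internal_stop=internal_stop,
        passed=not reasons,
        reasons=tuple(reasons),
    )


def qc_dataset(dataset: BarcodeDataset, min_len: int = 400,
               max_len: int = 700, max_ambiguous_frac: float = 0.02,
               six_frame: bool = False) -> list[QCReport]:
    """One QCReport per record, in dataset order."""
    return [qc_record(r.specimen_id, r.sequence, min_len=min_len,
                      max_len=max_len,
                      max_ambiguous_frac=max_ambiguous_frac,
                      six_frame=six_frame)
            for r in dataset.records]
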