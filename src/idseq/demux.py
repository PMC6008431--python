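"""Streaming demultiplexing of triple-barcoded reads into UMI count matrices.

Each read is split at the fixed positions declared by a :class:`~idseq.readmodel.ReadLayout`
into UMI, antibody barcode (BC1) and well barcode (BC2).  After tolerant
barcode correction, PCR duplicates — reads sharing the same corrected
(well, antibody, UMI) triple — are removed and the number of distinct UMIs is
counted per antibody and well.  The distinct-UMI count is the assay signal:
each originally released DNA tag carries its own random UMI, so duplicates are
amplification copies, not signal.

Memory is constant in the number of reads except for the per-(antibody, well)
distinct-UMI sets.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .readmodel import AntibodyPanel, BarcodeIndex, PlateMap, ReadLayout, hamming

STATUSES = ("ok", "too_short", "no_anchor", "bad_bc1", "bad_bc2")


@dataclass(frozen=True)
class ParsedRead:
    """Outcome of splitting one read; ``status != "ok"`` records the first
    failing stage and leaves the un-parsed fields as None."""

    status: str
    umi: str | None = None
    bc1: str | None = None
    bc2: str | None = None
    antibody_id: str | None = None
    well_id: str | None = None


@dataclass
class UMICountMatrix:
    """Antibodies × wells distinct-UMI counts plus parsing statistics.

    Invariants: ``counts.sum() == reads_assigned - duplicates_removed`` and
    ``duplicate_rate`` in [0, 1].
    """

    counts: pd.DataFrame  # index antibody_id, columns well_id, int counts
    reads_total: int = 0
    reads_assigned: int = 0
    duplicates_removed: int = 0
    status_counts: dict[str, int] = field(default_factory=dict)

    @property
    def duplicate_rate(self) -> float:
        if self.reads_assigned == 0:
            return 0.0
        return self.duplicates_removed / self.reads_assigned

    @property
    def assignment_rate(self) -> float:
        if self.reads_total == 0:
            return 0.0
        return self.reads_assigned / self.reads_total

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("antibody_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "UMICountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.columns = counts.columns.astype(str)
        counts.index.name = None
        total = int(counts.to_numpy().sum())
        return cls(counts=counts, reads_total=total, reads_assigned=total)


class ReadParser:
    """Splits reads per layout and corrects both barcodes against their panels."""

    def __init__(
        self,
        layout: ReadLayout,
        panel: AntibodyPanel,
        plate: PlateMap,
        tolerance: int = 1,
    ):
        if panel.barcode_length != layout.bc1_len:
            raise ValueError(
                f"antibody barcodes are {panel.barcode_length} nt but layout "
                f"declares bc1_len={layout.bc1_len}"
            )
        if plate.barcode_length != layout.bc2_len:
            raise ValueError(
                f"well barcodes are {plate.barcode_length} nt but layout "
                f"declares bc2_len={layout.bc2_len}"
            )
        self.layout = layout
        self.bc1_index = BarcodeIndex(panel, tolerance)
        self.bc2_index = BarcodeIndex(plate, tolerance)
        self._segments = layout.segments

    def parse(self, sequence: str) -> ParsedRead:
        if not sequence:
            raise ValueError("empty sequence")
        seq = sequence.upper()
        if len(seq) < self.layout.total_length:
            return ParsedRead(status="too_short")
        umi = bc1 = bc2 = None
        for token, start, end in self._segments:
            segment = seq[start:end]
            if token == "ANCHOR":
                if hamming(segment, self.layout.anchor) > self.layout.anchor_max_mismatch:
                    return ParsedRead(status="no_anchor")
            elif token == "UMI":
                umi = segment
            elif token == "BC1":
                bc1 = segment
            else:
                bc2 = segment
        antibody = self.bc1_index.match(bc1)
        if antibody is None:
            return ParsedRead(status="bad_bc1", umi=umi, bc1=bc1, bc2=bc2)
        well = self.bc2_index.match(bc2)
        if well is None:
            return ParsedRead(status="bad_bc2", umi=umi, bc1=bc1, bc2=bc2)
        return ParsedRead(
            status="ok", umi=umi, bc1=bc1, bc2=bc2, antibody_id=antibody, well_id=well
        )


def parse_read(
    sequence: str,
    layout: ReadLayout,
    panel: AntibodyPanel,
    plate: PlateMap,
    tolerance: int = 1,
) -> ParsedRead:
    """Parse a single read (convenience wrapper; build a :class:`ReadParser`
    once when processing many reads)."""
    return ReadParser(layout, panel, plate, tolerance).parse(sequence)


def iter_fastq(source) -> Iterator[str]:
    """Yield read sequences from a FASTQ / FASTQ.gz path, open handle, or an
    iterable of raw sequence strings."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            yield from _fastq_records(handle)
    elif hasattr(source, "read"):
        yield from _fastq_records(source)
    else:  # pre-extracted sequences
        yield from source


def _fastq_records(handle) -> Iterator[str]:
    try:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            yield seq
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record: {exc}") from exc


def count_umis(
    reads: Iterable[str] | str | Path,
    layout: ReadLayout,
    panel: AntibodyPanel,
    plate: PlateMap,
    tolerance: int = 1,
) -> UMICountMatrix:
    """Stream reads, drop PCR duplicates and count distinct UMIs per
    (antibody, well).

    A duplicate is an exact repeat of the corrected (well, antibody, UMI)
    triple; UMIs themselves are not error-collapsed.  The result is
    independent of read order.
    """
    parser = ReadParser(layout, panel, plate, tolerance)
    ab_ids = panel.ids
    well_ids = plate.ids
    ab_pos = {a: i for i, a in enumerate(ab_ids)}
    well_pos = {w: j for j, w in enumerate(well_ids)}
    counts = np.zeros((len(ab_ids), len(well_ids)), dtype=np.int64)
    umi_sets: dict[tuple[int, int], set[str]] = {}
    status_counts = dict.fromkeys(STATUSES, 0)
    reads_total = assigned = duplicates = 0

    for seq in iter_fastq(reads):
        reads_total += 1
        parsed = parser.parse(seq)
        status_counts[parsed.status] += 1
        if parsed.status != "ok":
            continue
        assigned += 1
        key = (ab_pos[parsed.antibody_id], well_pos[parsed.well_id])
        seen = umi_sets.setdefault(key, set())
        if parsed.umi in seen:
            duplicates += 1
        else:
            seen.add(parsed.umi)
            counts[key] += 1

    matrix = pd.DataFrame(counts, index=ab_ids, columns=well_ids)
    return UMICountMatrix(
        counts=matrix,
        reads_total=reads_total,
        reads_assigned=assigned,
        duplicates_removed=duplicates,
        status_counts=status_counts,
    )


def demux_report(matrix: UMICountMatrix) -> dict:
    """QC summary of a demultiplexed run (JSON-serialisable)."""
    return {
        "reads_total": matrix.reads_total,
        "reads_assigned": matrix.reads_assigned,
        "duplicates_removed": matrix.duplicates_removed,
        "assignment_rate": matrix.assignment_rate,
        "duplicate_rate": matrix.duplicate_rate,
        "status_counts": dict(matrix.status_counts),
        "umi_total": int(matrix.counts.to_numpy().sum()),
        "per_well_umis": {str(k): int(v) for k, v in matrix.counts.sum(axis=0).items()},
        "per_antibody_umis": {
            str(k): int(v) for k, v in matrix.counts.sum(axis=1).items()
        },
    }


def write_report(matrix: UMICountMatrix, path) -> None:
    Path(path).write_text(json.dumps(demux_report(matrix), indent=2, sort_keys=True))
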