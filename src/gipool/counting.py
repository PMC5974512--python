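"""Demultiplexing and fused-barcode counting from paired amplicon reads.

Reads are fixed-structure amplicons: mate 1 carries the 20-nt donor barcode,
mate 2 the 20-nt recipient barcode (each followed by constant flank within
the 25 sequenced cycles), and a third 6-nt read carries the sample index.
Matching is a Hamming-distance scan of every offset window against the
expected-barcode library, accepting the unique best barcode at <= 3
mismatches (>= 85% identity over 20 nt); the sample index is matched
exactly. No indel alignment and no reverse-complement search: the amplicon
is primer-anchored, so orientation is fixed.
"""

from __future__ import annotations

import enum
import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from gipool.core import BarcodeLibrary, FusedCountTable

#: maximum Hamming distance accepted between read window and barcode
MAX_MISMATCHES = 3

BARCODE_LEN = 20


class NoMatch(enum.Enum):
    """Non-assignment outcomes of barcode matching."""

    UNMATCHED = "unmatched"
    AMBIGUOUS = "ambiguous"


_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i


class BarcodeMatcher:
    """Mismatch-tolerant matcher for one side's barcode library."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("empty barcode library side")
        self.ids = list(sequences)
        mat = np.array(
            [_BASE_TO_IDX[np.frombuffer(s.encode(), np.uint8)] for s in sequences.values()]
        )
        if mat.shape[1] != BARCODE_LEN:
            raise ValueError("barcodes must be 20 nt")
        self.matrix = mat
        self.exact = {seq: bid for bid, seq in sequences.items()}

    def match(self, read: str, max_mismatches: int = MAX_MISMATCHES):
        """Best-matching barcode_id, or a :class:`NoMatch` outcome.

        Scans all offset windows 0..len(read)-20; accepts the unique barcode
        minimising Hamming distance iff that distance <= ``max_mismatches``.
        Two distinct barcodes tied at the best distance -> AMBIGUOUS. An
        exact hit at offset 0 short-circuits the scan.
        """
        if len(read) < BARCODE_LEN:
            return NoMatch.UNMATCHED
        hit = self.exact.get(read[:BARCODE_LEN])
        if hit is not None:
            return hit
        enc = _BASE_TO_IDX[np.frombuffer(read.encode(), np.uint8)]
        n_off = len(read) - BARCODE_LEN + 1
        windows = np.lib.stride_tricks.sliding_window_view(enc, BARCODE_LEN)[:n_off]
        # (n_offsets, n_barcodes) mismatch counts
        dists = (windows[:, None, :] != self.matrix[None, :, :]).sum(axis=2)
        best = int(dists.min())
        if best > max_mismatches:
            return NoMatch.UNMATCHED
        best_barcodes = np.unique(np.where(dists == best)[1])
        if len(best_barcodes) > 1:
            return NoMatch.AMBIGUOUS
        return self.ids[int(best_barcodes[0])]


def match_barcode(read: str, side_library: dict[str, str] | BarcodeMatcher):
    """Match one read against one side's expected barcodes.

    ``side_library`` maps barcode_id -> 20-nt sequence (or is a prebuilt
    :class:`BarcodeMatcher`). Returns the barcode_id, or
    ``NoMatch.UNMATCHED`` / ``NoMatch.AMBIGUOUS``.
    """
    matcher = (
        side_library
        if isinstance(side_library, BarcodeMatcher)
        else BarcodeMatcher(side_library)
    )
    return matcher.match(read)


@dataclass
class MappingReport:
    """Per-sample and overall read-assignment tallies.

    Conservation holds by construction: ``matched + unmatched_index +
    unmatched_donor + unmatched_recipient + ambiguous_donor +
    ambiguous_recipient == total_reads`` (each read is tallied once, at the
    first failing step: index, then donor, then recipient).
    """

    total_reads: int
    matched: int
    unmatched_index: int
    unmatched_donor: int
    ambiguous_donor: int
    unmatched_recipient: int
    ambiguous_recipient: int
    per_sample: pd.DataFrame

    @property
    def matched_fraction(self) -> float:
        return self.matched / self.total_reads if self.total_reads else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_reads", self.total_reads),
            ("matched", self.matched),
            ("unmatched_index", self.unmatched_index),
            ("unmatched_donor", self.unmatched_donor),
            ("ambiguous_donor", self.ambiguous_donor),
            ("unmatched_recipient", self.unmatched_recipient),
            ("ambiguous_recipient", self.ambiguous_recipient),
            ("matched_fraction", self.matched_fraction),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(path, label: str):
    """Yield (title, seq) with malformed records reported by index."""
    i = 0
    with _open_text(path) as handle:
        try:
            for title, seq, _qual in FastqGeneralIterator(handle):
                yield title, seq
                i += 1
        except ValueError as exc:
            raise ValueError(f"truncated/malformed FASTQ record {i} in {label}: {exc}")


def count_fused_barcodes(
    r1_path,
    r2_path,
    index_path,
    library: BarcodeLibrary,
    sample_sheet: pd.DataFrame,
) -> tuple[FusedCountTable, MappingReport]:
    """Assign read triples to (donor barcode, recipient barcode, sample) cells.

    A read pair increments exactly one cell iff its index read matches a
    sample index exactly, mate 1 matches a donor barcode uniquely and mate 2
    matches a recipient barcode uniquely; otherwise it lands in exactly one
    rejection tally. ``sample_sheet`` must carry ``sample_id``, ``index_seq``
    and the usual sample metadata columns. The returned table spans the full
    donor x recipient grid (zero-filled), so an error-free round trip through
    :func:`gipool.simulate.simulate_reads` is exact.
    """
    if "index_seq" not in sample_sheet.columns:
        raise ValueError("sample sheet needs an index_seq column")
    idx_to_sample = dict(zip(sample_sheet["index_seq"], sample_sheet["sample_id"]))
    if len(idx_to_sample) != len(sample_sheet):
        raise ValueError("duplicate index sequences in sample sheet")
    sample_pos = {sid: k for k, sid in enumerate(sample_sheet["sample_id"])}

    donor_matcher = BarcodeMatcher(library.donors["sequence"].to_dict())
    recip_matcher = BarcodeMatcher(library.recipients["sequence"].to_dict())
    donor_pos = {bid: k for k, bid in enumerate(donor_matcher.ids)}
    recip_pos = {bid: k for k, bid in enumerate(recip_matcher.ids)}

    grid = np.zeros((len(donor_pos), len(recip_pos), len(sample_pos)), dtype=np.int64)
    per_sample_total = np.zeros(len(sample_pos), dtype=np.int64)
    per_sample_matched = np.zeros(len(sample_pos), dtype=np.int64)
    tallies = {
        "unmatched_index": 0,
        "unmatched_donor": 0,
        "ambiguous_donor": 0,
        "unmatched_recipient": 0,
        "ambiguous_recipient": 0,
    }
    total = 0
    matched = 0

    sentinel = object()
    it1 = _fastq_records(r1_path, "R1")
    it2 = _fastq_records(r2_path, "R2")
    it3 = _fastq_records(index_path, "index")
    while True:
        rec1 = next(it1, sentinel)
        rec2 = next(it2, sentinel)
        rec3 = next(it3, sentinel)
        ended = [rec is sentinel for rec in (rec1, rec2, rec3)]
        if all(ended):
            break
        if any(ended):
            raise ValueError(
                f"R1/R2/index record counts differ (desynchronised at record {total})"
            )
        total += 1
        sid = idx_to_sample.get(rec3[1])
        if sid is None:
            tallies["unmatched_index"] += 1
            continue
        sk = sample_pos[sid]
        per_sample_total[sk] += 1
        d = donor_matcher.match(rec1[1])
        if d is NoMatch.UNMATCHED:
            tallies["unmatched_donor"] += 1
            continue
        if d is NoMatch.AMBIGUOUS:
            tallies["ambiguous_donor"] += 1
            continue
        r = recip_matcher.match(rec2[1])
        if r is NoMatch.UNMATCHED:
            tallies["unmatched_recipient"] += 1
            continue
        if r is NoMatch.AMBIGUOUS:
            tallies["ambiguous_recipient"] += 1
            continue
        grid[donor_pos[d], recip_pos[r], sk] += 1
        matched += 1
        per_sample_matched[sk] += 1

    idx = pd.MultiIndex.from_product(
        [donor_matcher.ids, recip_matcher.ids],
        names=["donor_barcode", "recipient_barcode"],
    )
    counts = pd.DataFrame(
        grid.reshape(-1, len(sample_pos)),
        index=idx,
        columns=list(sample_pos),
    ).sort_index()
    meta_cols = [c for c in sample_sheet.columns if c != "index_seq"]
    table = FusedCountTable(counts, sample_sheet[meta_cols])

    per_sample = pd.DataFrame(
        {
            "sample_id": list(sample_pos),
            "reads": per_sample_total,
            "matched": per_sample_matched,
        }
    )
    report = MappingReport(
        total_reads=total,
        matched=matched,
        per_sample=per_sample,
        **tallies,
    )
    return table, report
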