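"""Read-level quality control for paired-end FASTQ.

Implements the five-step filter used upstream of droplet scRNA-seq
quantification:

(a) sliding-window quality trim: scan 5'->3' with a 4-base window and cut
    at the start of the first window whose mean Phred quality drops below 10;
(b) trim trailing bases that are low quality (Phred < 3) or ``N``;
(c) remove adapter sequence (leftmost exact match, or an adapter prefix of at
    least ``min_overlap`` bases flush with the 3' end);
(d) drop any mate whose retained length falls below 26 bases;
(e) discard pairs in which either mate was dropped, so the output always
    forms proper pairs.

Steps are applied per mate, in this order.  Qualities are Phred+33 on disk.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

__all__ = [
    "Read",
    "ReadPair",
    "QcParams",
    "QcReport",
    "sliding_window_trim",
    "trim_trailing",
    "remove_adapter",
    "qc_single_read",
    "run_read_qc",
    "read_fastq_pairs",
    "write_fastq",
]


@dataclass
class Read:
    """A single sequencing read with per-base Phred qualities."""

    identifier: str
    bases: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.identifier!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality values"
            )

    def truncated(self, keep: int) -> "Read":
        return Read(self.identifier, self.bases[:keep], self.qualities[:keep])


@dataclass
class ReadPair:
    read1: Read
    read2: Read


@dataclass
class QcParams:
    window: int = 4
    window_q: float = 10.0
    trail_q: int = 3
    adapter: str | None = None
    min_overlap: int = 3
    min_length: int = 26


@dataclass
class QcReport:
    """Per-step bookkeeping of reads/pairs entering and surviving QC."""

    pairs_in: int = 0
    pairs_out: int = 0
    reads_window_trimmed: int = 0
    reads_trail_trimmed: int = 0
    reads_adapter_trimmed: int = 0
    reads_dropped_short: int = 0
    pairs_dropped: int = 0
    extra: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        rows = [
            ("pairs_in", self.pairs_in),
            ("pairs_out", self.pairs_out),
            ("pairs_dropped", self.pairs_dropped),
            ("reads_window_trimmed", self.reads_window_trimmed),
            ("reads_trail_trimmed", self.reads_trail_trimmed),
            ("reads_adapter_trimmed", self.reads_adapter_trimmed),
            ("reads_dropped_short", self.reads_dropped_short),
        ]
        return "metric\tvalue\n" + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def sliding_window_trim(
    qualities: Iterable[int], window: int = 4, threshold: float = 10.0
) -> int:
    """Keep-length after the 5'->3' sliding-window scan.

    Returns the start index of the first length-``window`` window (step 1)
    whose mean quality is below ``threshold``; the full length if none fails.
    Windows shorter than ``window`` at the 3' end are not evaluated.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    quals = list(qualities)
    n = len(quals)
    if n == 0:
        return 0
    if n < window:
        return n
    running = sum(quals[:window])
    cut = window * threshold
    if running < cut:
        return 0
    for start in range(1, n - window + 1):
        running += quals[start + window - 1] - quals[start - 1]
        if running < cut:
            return start
    return n


def trim_trailing(bases: str, qualities: Iterable[int], min_q: int = 3) -> int:
    """Keep-length after removing the maximal 3' run of quality < ``min_q`` or N."""
    quals = list(qualities)
    keep = len(quals)
    while keep > 0 and (quals[keep - 1] < min_q or bases[keep - 1] in "Nn"):
        keep -= 1
    return keep


def remove_adapter(bases: str, adapter: str, min_overlap: int = 3) -> int:
    """Keep-length after exact adapter removal.

    The leftmost exact occurrence of the full adapter wins; failing that, the
    longest adapter *prefix* of at least ``min_overlap`` bases that is flush
    with the read's 3' end.  No match -> full length.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    hit = bases.find(adapter)
    if hit != -1:
        return hit
    n = len(bases)
    max_ov = min(len(adapter) - 1, n)
    for ov in range(max_ov, min_overlap - 1, -1):
        if bases[n - ov :] == adapter[:ov]:
            return n - ov
    return n


def qc_single_read(read: Read, params: QcParams, report: QcReport | None = None) -> Read:
    """Apply trimming steps (a)-(c) to one mate; length filtering is the caller's.

    The three steps run in their stated order; because a truncation can
    expose a new 3' end that an earlier rule would act on (e.g. a low-quality
    base uncovered by adapter removal), the cycle repeats until the read is
    stable, which makes the whole filter idempotent.
    """
    while True:
        before = len(read.bases)

        keep = sliding_window_trim(read.qualities, params.window, params.window_q)
        if report is not None and keep < len(read.bases):
            report.reads_window_trimmed += 1
        read = read.truncated(keep)

        keep = trim_trailing(read.bases, read.qualities, params.trail_q)
        if report is not None and keep < len(read.bases):
            report.reads_trail_trimmed += 1
        read = read.truncated(keep)

        if params.adapter:
            keep = remove_adapter(read.bases, params.adapter, params.min_overlap)
            if report is not None and keep < len(read.bases):
                report.reads_adapter_trimmed += 1
            read = read.truncated(keep)

        if len(read.bases) == before:
            return read


def run_read_qc(
    pairs: Iterable[ReadPair], params: QcParams | None = None
) -> tuple[list[ReadPair], QcReport]:
    """Run the full five-step pipeline over a stream of read pairs."""
    params = params or QcParams()
    report = QcReport()
    surviving: list[ReadPair] = []
    for pair in pairs:
        report.pairs_in += 1
        r1 = qc_single_read(pair.read1, params, report)
        r2 = qc_single_read(pair.read2, params, report)
        ok1 = len(r1.bases) >= params.min_length
        ok2 = len(r2.bases) >= params.min_length
        if not ok1:
            report.reads_dropped_short += 1
        if not ok2:
            report.reads_dropped_short += 1
        if ok1 and ok2:
            surviving.append(ReadPair(r1, r2))
            report.pairs_out += 1
        else:
            report.pairs_dropped += 1
    return surviving, report


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33, plain or gzip)

def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_fastq(handle: IO[str]) -> Iterator[Read]:
    from Bio import SeqIO

    for rec in SeqIO.parse(handle, "fastq"):
        yield Read(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream mate-aligned pairs from two FASTQ files.

    Raises on unequal record counts, naming the first offset at which the
    files go out of step.
    """
    with _open_text(path1) as h1, _open_text(path2) as h2:
        it1, it2 = _iter_fastq(h1), _iter_fastq(h2)
        idx = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                short = path1 if r1 is None else path2
                raise ValueError(
                    f"mismatched pair files: {short} ends at record {idx}"
                )
            yield ReadPair(r1, r2)
            idx += 1


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            out.write(f"@{r.identifier}\n{r.bases}\n+\n{qual}\n")
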