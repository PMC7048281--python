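"""Raw-read preprocessing: 3' adapter trimming, length filter, contaminant removal.

Small RNA libraries sequence a short insert followed by the 3' ligation
adapter, so on a 50-cycle run almost every miRNA-derived read runs into the
adapter. A read is reduced to its insert by locating the adapter; reads where
no adapter is detectable, inserts shorter than 16 nt, and inserts matching
rRNA/tRNA/snRNA/snoRNA references are excluded before miRNA mapping, and every
raw read receives exactly one class label feeding the per-library RNA-species
distribution table.

Adapter location is a two-stage rule: an exact match of the adapter's first
10 nt anywhere in the read, else a 3'-terminal overlap of at least
``min_overlap`` bases with at most ``max_adapter_mismatch`` mismatches. The
leftmost qualifying position wins, so trimming is deterministic. Base
qualities are carried through but never interpreted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


class ReadClass(str, Enum):
    NO_ADAPTOR = "No Adaptor"
    SHORT = "Short"
    RRNA = "rRNA"
    TRNA = "tRNA"
    SNRNA = "snRNA"
    SNORNA = "snoRNA"
    MAPPED = "isomiR/miRNA"
    UNMAPPED = "Unmapped"
    # transient label for inserts that passed all filters and await mapping
    RETAINED = "Retained"


#: fixed priority order for contaminant classes (affects only the breakdown,
#: not which reads are excluded)
CONTAMINANT_ORDER: tuple[ReadClass, ...] = (
    ReadClass.RRNA,
    ReadClass.TRNA,
    ReadClass.SNRNA,
    ReadClass.SNORNA,
)

TERMINAL_CLASSES: tuple[ReadClass, ...] = (
    ReadClass.NO_ADAPTOR,
    ReadClass.SHORT,
    ReadClass.RRNA,
    ReadClass.TRNA,
    ReadClass.SNRNA,
    ReadClass.SNORNA,
    ReadClass.MAPPED,
    ReadClass.UNMAPPED,
)


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality/sequence length mismatch"
            )


@dataclass(frozen=True)
class PreprocessParams:
    adapter: str
    min_overlap: int = 6
    max_adapter_mismatch: int = 1
    min_len: int = 16
    contaminant_max_mismatch: int = 1
    seed_len: int = 10

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.min_overlap < 1 or self.min_len < 1:
            raise ValueError("min_overlap and min_len must be >= 1")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a (optionally gzipped) FASTQ file as ReadRecords."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            yield ReadRecord(header[1:].split()[0], seq.upper().replace("U", "T"), qual)
            idx += 1


def trim_adapter(sequence: str, params: PreprocessParams) -> str | None:
    """Return the insert 5' of the adapter, or None when no adapter is found.

    Stage 1 scans for the adapter's first ``seed_len`` nt anywhere in the read,
    tolerating up to ``max_adapter_mismatch`` substitutions (adapter bases are
    sequenced like any others and carry errors). Stage 2 looks for a
    3'-terminal overlap of at least ``min_overlap`` bases. Leftmost hit wins.
    """
    adapter = params.adapter
    seed = adapter[: params.seed_len]
    k = len(seed)
    for pos in range(len(sequence) - k + 1):
        mm = 0
        for a, b in zip(sequence[pos : pos + k], seed):
            if a != b:
                mm += 1
                if mm > params.max_adapter_mismatch:
                    break
        else:
            return sequence[:pos]
    # 3'-terminal overlap: suffix of the read against a prefix of the adapter
    n = len(sequence)
    for i in range(max(0, n - len(adapter)), n - params.min_overlap + 1):
        k = n - i
        mismatches = 0
        ok = True
        for a, b in zip(sequence[i:], adapter[:k]):
            if a != b:
                mismatches += 1
                if mismatches > params.max_adapter_mismatch:
                    ok = False
                    break
        if ok:
            return sequence[:i]
    return None


def _contains_with_mismatches(needle: str, haystack: str, max_mm: int) -> bool:
    """True if needle occurs in haystack as an ungapped window with <= max_mm mismatches."""
    n, h = len(needle), len(haystack)
    if n > h:
        return False
    for start in range(h - n + 1):
        mm = 0
        for a, b in zip(needle, haystack[start : start + n]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return True
    return False


@dataclass
class ContaminantReference:
    """Per-class contaminant sequence sets (rRNA, tRNA, snRNA, snoRNA)."""

    sequences: dict[ReadClass, list[str]] = field(default_factory=dict)

    @classmethod
    def from_fastas(cls, per_class: Mapping[str, str | Path]) -> "ContaminantReference":
        """Load one FASTA per class; keys are 'rRNA', 'tRNA', 'snRNA', 'snoRNA'."""
        from Bio import SeqIO

        lookup = {c.value: c for c in CONTAMINANT_ORDER}
        ref = cls()
        for name, path in per_class.items():
            if name not in lookup:
                raise ValueError(f"unknown contaminant class {name!r}")
            seqs = [
                str(rec.seq).upper().replace("U", "T")
                for rec in SeqIO.parse(str(path), "fasta")
            ]
            ref.sequences[lookup[name]] = seqs
        return ref

    @classmethod
    def from_single_fasta(cls, path: str | Path) -> "ContaminantReference":
        """One FASTA whose headers start with the class name, e.g. '>rRNA_..'."""
        from Bio import SeqIO

        ref = cls()
        lookup = {c.value.lower(): c for c in CONTAMINANT_ORDER}
        for rec in SeqIO.parse(str(path), "fasta"):
            prefix = rec.id.split("_")[0].lower()
            if prefix not in lookup:
                raise ValueError(f"contaminant record {rec.id!r}: unknown class prefix")
            ref.sequences.setdefault(lookup[prefix], []).append(
                str(rec.seq).upper().replace("U", "T")
            )
        return ref

    def classify(self, insert: str, max_mm: int) -> ReadClass | None:
        for cls_ in CONTAMINANT_ORDER:
            for target in self.sequences.get(cls_, ()):
                if _contains_with_mismatches(insert, target, max_mm):
                    return cls_
        return None


@dataclass
class PreprocessResult:
    retained: list[tuple[str, str]]  # (read_id, insert), input order preserved
    labels: dict[str, ReadClass]
    class_counts: dict[ReadClass, int]


def classify_and_filter(
    reads: Iterable[ReadRecord],
    contaminants: ContaminantReference | None,
    params: PreprocessParams,
) -> PreprocessResult:
    """Trim, length-filter and contaminant-screen a stream of reads.

    Classification order per read: NO_ADAPTOR, then SHORT (insert < min_len),
    then the contaminant classes in fixed priority order, else RETAINED for
    mapping. Identical read sequences always receive identical labels, so
    results are cached per unique sequence.
    """
    cache: dict[str, tuple[ReadClass, str | None]] = {}
    retained: list[tuple[str, str]] = []
    labels: dict[str, ReadClass] = {}
    counts: dict[ReadClass, int] = {c: 0 for c in TERMINAL_CLASSES}
    counts[ReadClass.RETAINED] = 0

    for read in reads:
        hit = cache.get(read.sequence)
        if hit is None:
            insert = trim_adapter(read.sequence, params)
            if insert is None:
                hit = (ReadClass.NO_ADAPTOR, None)
            elif len(insert) < params.min_len:
                hit = (ReadClass.SHORT, None)
            else:
                cls_ = (
                    contaminants.classify(insert, params.contaminant_max_mismatch)
                    if contaminants is not None
                    else None
                )
                hit = (cls_, insert) if cls_ is not None else (ReadClass.RETAINED, insert)
            cache[read.sequence] = hit
        label, insert = hit
        labels[read.read_id] = label
        counts[label] += 1
        if label is ReadClass.RETAINED:
            retained.append((read.read_id, insert))

    return PreprocessResult(retained=retained, labels=labels, class_counts=counts)


def write_class_counts(
    per_sample_counts: Mapping[str, Mapping[ReadClass, int]], path: str | Path
) -> None:
    classes = list(TERMINAL_CLASSES)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(c.value for c in classes) + "\ttotal\n")
        for sample, counts in per_sample_counts.items():
            row = [counts.get(c, 0) for c in classes]
            fh.write(f"{sample}\t" + "\t".join(map(str, row)) + f"\t{sum(row)}\n")
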