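"""Exact/1-mismatch assignment of inserts to isomiR variants and counting.

Reads are assigned to the enumerated isomiR reference ungapped and
length-preserving: a read can match a variant only at Hamming distance 0
(exact) or 1 (one substitution anywhere in the sequence — a "polymorphic"
isomiR). Exact hits always beat 1-mismatch hits (best-stratum rule); within
the 1-mismatch stratum ties are broken deterministically by the smallest
end-offset magnitude ``|e5| + |e3|`` over the candidate's parent annotations,
then by variant id.

Counting keys carry the mismatch descriptor, so an exact read of a variant and
a substituted read of the same variant accumulate under two distinct keys —
every unique read sequence gets its own key.

The 1-mismatch index stores, for every variant sequence, each of its
"deletion-at-position" keys ``(pos, seq[:pos] + seq[pos+1:])``; two
equal-length sequences at Hamming distance 1 share exactly one such key, which
makes the distance-1 lookup exhaustive without a full reference scan.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference import IsomirVariant


@dataclass(frozen=True)
class Mismatch:
    position: int  # 0-based in the read
    ref_base: str
    read_base: str

    def __str__(self) -> str:
        return f"{self.position}{self.ref_base}>{self.read_base}"


@dataclass(frozen=True)
class AlignmentCall:
    read_id: str | None
    variant_id: str
    stratum: int  # 0 = exact, 1 = one mismatch
    mismatch: Mismatch | None = None

    def __post_init__(self) -> None:
        if self.stratum == 0 and self.mismatch is not None:
            raise ValueError("stratum-0 call cannot carry a mismatch")
        if self.stratum == 1 and self.mismatch is None:
            raise ValueError("stratum-1 call requires a mismatch descriptor")

    @property
    def key(self) -> str:
        """Serialized isomiR counting key (variant id + mismatch descriptor)."""
        if self.mismatch is None:
            return self.variant_id
        return f"{self.variant_id}|m{self.mismatch}"


def split_key(key: str) -> tuple[str, str]:
    """Split a serialized key into (variant_id, mismatch descriptor or '')."""
    head, sep, tail = key.rpartition("|m")
    if sep and tail and tail[0].isdigit():
        return head, tail
    return key, ""


class MatchIndex:
    """Exact + Hamming-distance-1 lookup over deduplicated variant sequences."""

    def __init__(self, variants: Sequence[IsomirVariant]):
        self.exact: dict[str, IsomirVariant] = {}
        for v in variants:
            if v.sequence in self.exact:
                raise ValueError(
                    f"duplicate variant sequence for {v.variant_id!r} and "
                    f"{self.exact[v.sequence].variant_id!r}"
                )
            self.exact[v.sequence] = v
        self._neighbors: dict[tuple[int, str], list[IsomirVariant]] = {}
        for v in variants:
            s = v.sequence
            for pos in range(len(s)):
                self._neighbors.setdefault((pos, s[:pos] + s[pos + 1 :]), []).append(v)
        self.lengths = sorted({len(s) for s in self.exact})

    def lookup_exact(self, seq: str) -> IsomirVariant | None:
        return self.exact.get(seq)

    def lookup_distance1(self, seq: str) -> list[IsomirVariant]:
        """All variants of equal length at Hamming distance exactly 1."""
        hits: dict[str, IsomirVariant] = {}
        for pos in range(len(seq)):
            for v in self._neighbors.get((pos, seq[:pos] + seq[pos + 1 :]), ()):
                if v.sequence[pos] != seq[pos]:
                    hits[v.variant_id] = v
        return list(hits.values())


def build_index(variants: Sequence[IsomirVariant]) -> MatchIndex:
    return MatchIndex(variants)


def _tie_break(candidates: list[IsomirVariant]) -> IsomirVariant:
    return min(candidates, key=lambda v: (v.min_offset_magnitude(), v.variant_id))


def assign_read(
    insert: str, index: MatchIndex, read_id: str | None = None
) -> AlignmentCall | None:
    """Assign one insert to a variant, or None when unmapped."""
    v = index.lookup_exact(insert)
    if v is not None:
        return AlignmentCall(read_id, v.variant_id, stratum=0)
    candidates = index.lookup_distance1(insert)
    if not candidates:
        return None
    v = _tie_break(candidates)
    pos = next(i for i, (a, b) in enumerate(zip(v.sequence, insert)) if a != b)
    return AlignmentCall(
        read_id, v.variant_id, stratum=1,
        mismatch=Mismatch(pos, v.sequence[pos], insert[pos]),
    )


@dataclass
class LibraryQuantification:
    key_counts: Counter  # serialized IsomirKey -> count
    unmapped: int
    mapped_read_ids: set[str] | None = None


def quantify_library(
    inserts: Iterable[tuple[str, str]],
    index: MatchIndex,
    keep_read_ids: bool = False,
) -> LibraryQuantification:
    """Count (read_id, insert) pairs per isomiR key.

    Identical insert sequences always produce identical calls, so assignment
    is cached per unique sequence; permuting the input order cannot change
    the resulting counts.
    """
    cache: dict[str, str | None] = {}
    counts: Counter = Counter()
    unmapped = 0
    mapped_ids: set[str] | None = set() if keep_read_ids else None
    for read_id, seq in inserts:
        if seq in cache:
            key = cache[seq]
        else:
            call = assign_read(seq, index)
            key = call.key if call is not None else None
            cache[seq] = key
        if key is None:
            unmapped += 1
        else:
            counts[key] += 1
            if mapped_ids is not None:
                mapped_ids.add(read_id)
    return LibraryQuantification(counts, unmapped, mapped_ids)


def build_count_matrix(per_sample: Mapping[str, Counter]) -> pd.DataFrame:
    """Assemble per-sample key counts into a features x samples integer matrix."""
    df = pd.DataFrame(per_sample).fillna(0).astype(int)
    df = df.sort_index()
    df.index.name = "feature_id"
    return df[list(per_sample)]


def rollup_canonical(
    isomir_counts: pd.DataFrame, variants: Mapping[str, IsomirVariant]
) -> pd.DataFrame:
    """Sum isomiR-key counts to canonical-miRNA level via each variant's
    canonical parent. Total counts are conserved."""
    parents = []
    for key in isomir_counts.index:
        variant_id, _ = split_key(key)
        if variant_id not in variants:
            raise KeyError(f"unknown variant id {variant_id!r} in count matrix")
        parents.append(variants[variant_id].canonical_parent)
    rolled = isomir_counts.groupby(pd.Index(parents, name="feature_id")).sum()
    return rolled.sort_index()


def key_annotation_table(
    keys: Iterable[str], variants: Mapping[str, IsomirVariant]
) -> pd.DataFrame:
    """Annotation for serialized keys: offsets, mismatch, parent ambiguity."""
    rows = []
    for key in keys:
        variant_id, mm = split_key(key)
        v = variants[variant_id]
        own = [(e5, e3) for mid, e5, e3 in v.parents if mid == v.canonical_parent]
        e5, e3 = min(own, key=lambda p: (abs(p[0]) + abs(p[1]), p))
        rows.append(
            {
                "key": key,
                "variant_id": variant_id,
                "canonical_parent": v.canonical_parent,
                "e5": e5,
                "e3": e3,
                "mismatch": mm,
                "all_parents": ";".join(f"{m}({a:+d},{b:+d})" for m, a, b in v.parents),
                "ambiguous": v.is_ambiguous,
            }
        )
    return pd.DataFrame(rows).set_index("key")


def write_sam(
    calls: Iterable[AlignmentCall],
    variants: Mapping[str, IsomirVariant],
    path: str | Path,
) -> None:
    """Optional SAM export of alignment calls (ungapped, forward strand)."""
    variants = dict(variants)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for vid, v in sorted(variants.items()):
            fh.write(f"@SQ\tSN:{vid}\tLN:{len(v.sequence)}\n")
        for call in calls:
            v = variants[call.variant_id]
            seq = v.sequence
            if call.mismatch is not None:
                m = call.mismatch
                seq = seq[: m.position] + m.read_base + seq[m.position + 1 :]
            fh.write(
                f"{call.read_id or '*'}\t0\t{call.variant_id}\t1\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{call.stratum}\n"
            )
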