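"""Mature/hairpin miRNA reference loading and isomiR sequence-space enumeration.

A mature miRNA is excised from a hairpin precursor; imprecise or alternative
DROSHA/DICER cleavage produces *isomiRs* — sequence variants whose 5' and/or 3'
ends are shifted relative to the canonical (miRBase-annotated) mature sequence.
This module enumerates that variant space explicitly so short reads can be
assigned to isomiRs by exact/near-exact lookup instead of genome alignment:
every combination of end trims (up to ``max_trim`` nt) and end additions (up to
``max_add`` nt, templated from the flanking hairpin sequence) is realised as a
concrete sequence.

Internally all sequences live in the DNA alphabet (``U`` is normalised to
``T``) so that FASTQ reads and FASTA references compare directly; coordinates
are 0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGT")


class ReferenceError(ValueError):
    """Raised when a mature/hairpin reference violates its contract."""


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, convert RNA to DNA alphabet, and validate characters."""
    s = str(seq).strip().upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise ReferenceError(
            f"{context}: invalid characters {sorted(bad)} (alphabet is A/C/G/T/U)"
        )
    return s


@dataclass(frozen=True)
class MatureRecord:
    """A canonical mature miRNA located within its hairpin precursor."""

    mirna_id: str
    name: str
    sequence: str
    hairpin_id: str
    start: int  # 0-based start within hairpin
    end: int  # half-open end within hairpin

    def __post_init__(self) -> None:
        if not (16 <= len(self.sequence) <= 30):
            raise ReferenceError(
                f"mature {self.mirna_id!r}: length {len(self.sequence)} outside [16, 30]"
            )


@dataclass(frozen=True)
class HairpinRecord:
    hairpin_id: str
    sequence: str


@dataclass(frozen=True)
class IsomirVariant:
    """One enumerated isomiR sequence.

    ``parents`` lists every ``(mirna_id, e5, e3)`` origin that produces this
    exact sequence. End offsets are signed: negative = nucleotides trimmed from
    that end, positive = templated nucleotides added from the hairpin flank.
    ``(0, 0)`` is the canonical mature sequence itself.
    """

    variant_id: str
    sequence: str
    parents: tuple[tuple[str, int, int], ...]
    canonical_parent: str

    @property
    def is_ambiguous(self) -> bool:
        """True when the sequence arises from more than one distinct miRNA."""
        return len({p[0] for p in self.parents}) > 1

    def min_offset_magnitude(self) -> int:
        return min(abs(e5) + abs(e3) for _, e5, e3 in self.parents)


@dataclass(frozen=True)
class EnumerationParams:
    max_trim: int = 6
    max_add: int = 3
    min_len: int = 16
    addition_mode: str = "templated"  # or "nontemplated_AU"

    def __post_init__(self) -> None:
        if self.max_trim < 0 or self.max_add < 0 or self.min_len < 1:
            raise ValueError("max_trim/max_add must be >= 0 and min_len >= 1")
        if self.addition_mode not in ("templated", "nontemplated_AU"):
            raise ValueError(f"unknown addition_mode {self.addition_mode!r}")


@dataclass
class MirnaReference:
    matures: list[MatureRecord] = field(default_factory=list)
    hairpins: dict[str, HairpinRecord] = field(default_factory=dict)

    def hairpin_of(self, mature: MatureRecord) -> HairpinRecord:
        return self.hairpins[mature.hairpin_id]


def _read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Return (id, description, raw sequence) triples in file order."""
    return [(rec.id, rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _implied_hairpin_id(mirna_id: str) -> str:
    # miRBase convention: mature "xxx-miR-nnn" derives from hairpin "xxx-mir-nnn";
    # strip a trailing -5p/-3p arm suffix first.
    base = mirna_id
    for suffix in ("-5p", "-3p"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return base.replace("miR", "mir")


def load_mirna_reference(
    mature_fasta: str | Path,
    hairpin_fasta: str | Path,
    link_table: str | Path | None = None,
) -> MirnaReference:
    """Load mature and hairpin FASTA files and resolve mature→hairpin linkage.

    Linkage resolution, in order of precedence:

    1. an explicit two-column TSV ``link_table`` (mature_id <tab> hairpin_id);
    2. the miRBase id convention (``-miR-`` matures to the ``-mir-`` hairpin,
       ignoring a -5p/-3p arm suffix), when that hairpin exists and contains
       the mature sequence;
    3. unique substring containment: the mature occurs in exactly one hairpin.

    A mature found in no hairpin, or in several without a declared link, is a
    hard error naming the record.
    """
    links: dict[str, str] = {}
    if link_table is not None:
        for line in Path(link_table).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            mat_id, hp_id = line.split("\t")[:2]
            links[mat_id] = hp_id

    hairpins: dict[str, HairpinRecord] = {}
    for hp_id, _desc, raw in _read_fasta(hairpin_fasta):
        seq = normalize_sequence(raw, context=f"hairpin {hp_id!r}")
        if hp_id in hairpins:
            raise ReferenceError(f"duplicate hairpin id {hp_id!r}")
        hairpins[hp_id] = HairpinRecord(hp_id, seq)

    matures: list[MatureRecord] = []
    seen_ids: set[str] = set()
    for mat_id, desc, raw in _read_fasta(mature_fasta):
        seq = normalize_sequence(raw, context=f"mature {mat_id!r}")
        if mat_id in seen_ids:
            raise ReferenceError(f"duplicate mature id {mat_id!r}")
        seen_ids.add(mat_id)

        hp_id: str | None = None
        if mat_id in links:
            hp_id = links[mat_id]
            if hp_id not in hairpins:
                raise ReferenceError(
                    f"mature {mat_id!r}: declared hairpin {hp_id!r} not present"
                )
            if seq not in hairpins[hp_id].sequence:
                raise ReferenceError(
                    f"mature {mat_id!r} not found within declared hairpin {hp_id!r}"
                )
        else:
            implied = _implied_hairpin_id(mat_id)
            if implied in hairpins and seq in hairpins[implied].sequence:
                hp_id = implied
            else:
                hits = [h for h in hairpins.values() if seq in h.sequence]
                if not hits:
                    raise ReferenceError(
                        f"mature {mat_id!r}: sequence not found in any hairpin"
                    )
                if len(hits) > 1:
                    raise ReferenceError(
                        f"mature {mat_id!r}: found in multiple hairpins "
                        f"({', '.join(sorted(h.hairpin_id for h in hits))}) with no declared link"
                    )
                hp_id = hits[0].hairpin_id

        start = hairpins[hp_id].sequence.index(seq)
        matures.append(
            MatureRecord(
                mirna_id=mat_id,
                name=desc.split(maxsplit=1)[1] if " " in desc else mat_id,
                sequence=seq,
                hairpin_id=hp_id,
                start=start,
                end=start + len(seq),
            )
        )

    matures.sort(key=lambda m: m.mirna_id)
    return MirnaReference(matures=matures, hairpins=hairpins)


def _variant_sequences_for_mature(
    mature: MatureRecord, hairpin: HairpinRecord, params: EnumerationParams
) -> Iterable[tuple[str, int, int]]:
    """Yield (sequence, e5, e3) for one mature under the enumeration grid."""
    hp = hairpin.sequence
    offsets = range(-params.max_trim, params.max_add + 1)
    if params.addition_mode == "templated":
        for e5, e3 in itertools.product(offsets, offsets):
            if len(mature.sequence) + e5 + e3 < params.min_len:
                continue
            new_start = mature.start - e5
            new_end = mature.end + e3
            if new_start < 0 or new_end > len(hp):
                continue  # not enough hairpin flank to template the addition
            yield hp[new_start:new_end], e5, e3
    else:  # nontemplated_AU: 3' A/U tails only; 5' additions are not generated
        for e5 in range(-params.max_trim, 1):
            for e3 in offsets:
                if len(mature.sequence) + e5 + e3 < params.min_len:
                    continue
                core = mature.sequence[-e5 if e5 < 0 else 0 :]
                if e3 < 0:
                    yield core[:e3], e5, e3
                elif e3 == 0:
                    yield core, e5, e3
                else:
                    for tail in itertools.product("AT", repeat=e3):
                        yield core + "".join(tail), e5, e3


def enumerate_isomir_space(
    reference: MirnaReference, params: EnumerationParams | None = None
) -> list[IsomirVariant]:
    """Enumerate all isomiR variant sequences over the (e5, e3) offset grid.

    Identical sequences arising from different origins are collapsed into one
    variant carrying all parent annotations; output is ordered by sequence.
    """
    params = params or EnumerationParams()
    by_seq: dict[str, list[tuple[str, int, int]]] = {}
    for mature in reference.matures:
        hairpin = reference.hairpin_of(mature)
        for seq, e5, e3 in _variant_sequences_for_mature(mature, hairpin, params):
            by_seq.setdefault(seq, []).append((mature.mirna_id, e5, e3))

    variants: list[IsomirVariant] = []
    for seq in sorted(by_seq):
        parents = tuple(sorted(set(by_seq[seq])))
        canonical = parents[0][0]
        # name the variant after the canonical parent's most central origin
        own = [(e5, e3) for mid, e5, e3 in parents if mid == canonical]
        e5, e3 = min(own, key=lambda p: (abs(p[0]) + abs(p[1]), p))
        variants.append(
            IsomirVariant(
                variant_id=f"{canonical}|{e5:+d}|{e3:+d}",
                sequence=seq,
                parents=parents,
                canonical_parent=canonical,
            )
        )
    return variants


def write_variant_fasta(variants: Sequence[IsomirVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f">{v.variant_id}\n{v.sequence}\n")


def write_variant_table(variants: Sequence[IsomirVariant], path: str | Path) -> None:
    """TSV annotation: one row per (variant, parent) pair."""
    with open(path, "w") as fh:
        fh.write("variant_id\tsequence\tmirna_id\te5\te3\tcanonical_parent\tambiguous\n")
        for v in variants:
            for mid, e5, e3 in v.parents:
                fh.write(
                    f"{v.variant_id}\t{v.sequence}\t{mid}\t{e5}\t{e3}\t"
                    f"{v.canonical_parent}\t{int(v.is_ambiguous)}\n"
                )


def read_variant_table(path: str | Path) -> list[IsomirVariant]:
    """Inverse of :func:`write_variant_table`; output ordered by sequence."""
    rows: dict[str, dict] = {}
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        vid = parts[idx["variant_id"]]
        entry = rows.setdefault(
            vid,
            {
                "sequence": parts[idx["sequence"]],
                "canonical_parent": parts[idx["canonical_parent"]],
                "parents": set(),
            },
        )
        entry["parents"].add(
            (parts[idx["mirna_id"]], int(parts[idx["e5"]]), int(parts[idx["e3"]]))
        )
    variants = [
        IsomirVariant(
            variant_id=vid,
            sequence=e["sequence"],
            parents=tuple(sorted(e["parents"])),
            canonical_parent=e["canonical_parent"],
        )
        for vid, e in rows.items()
    ]
    return sorted(variants, key=lambda v: v.sequence)


def variants_by_id(variants: Iterable[IsomirVariant]) -> Mapping[str, IsomirVariant]:
    return {v.variant_id: v for v in variants}
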