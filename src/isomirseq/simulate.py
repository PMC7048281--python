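"""Fully synthetic small RNA-seq study generator with per-read ground truth.

Emulates the structure of a colostrum-feeding transfer experiment: two sample
compartments (colostrum EVs and calf blood EVs) sampled at a pre-feeding time
point and several postprandial time points with a few replicates each. Every
sample is a 50-cycle single-end library whose reads are isomiR inserts
followed by the 3' ligation adapter, mixed with contaminant (rRNA/tRNA/
snRNA/snoRNA-like) reads, too-short inserts and adapterless reads.

Feature abundances are a fixed simplex over the enumerated isomiR space
(log-normal abundance per miRNA; within each miRNA most of the mass sits on
the canonical variant), per-sample counts are negative-binomial around
``depth * proportion`` (gamma-Poisson, shared dispersion), and planted
log2 fold changes act multiplicatively on the proportions of selected
group/time-point combinations before renormalization. Substitution errors are
applied base-wise over the full read at a uniform rate.

Every read carries a ground-truth provenance label (source variant id or
special class), which downstream stages are tested against.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ContaminantReference, PreprocessParams, ReadClass, trim_adapter
from .quantify import MatchIndex, build_index
from .reference import (
    EnumerationParams,
    HairpinRecord,
    IsomirVariant,
    MatureRecord,
    MirnaReference,
    enumerate_isomir_space,
)

BASES = np.array(list("ACGT"))

#: NEBNext small RNA 3' ligation adapter
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"


@dataclass(frozen=True)
class PlantedEffect:
    """A true log2 fold change for one feature in one group/time-point cell,
    relative to that group's pre-feeding baseline."""

    variant_id: str
    group: str
    time_point: str
    log2fc: float


@dataclass(frozen=True)
class SimulationDesign:
    groups: tuple[str, ...] = ("colostrum_EV", "calf_EV")
    time_points: tuple[str, ...] = ("0h", "1h", "3h", "6h", "9-12h")
    replicates: int = 3
    depth: int = 100_000
    dispersion: float = 0.1
    error_rate: float = 0.001
    contaminant_fraction: float = 0.10
    short_fraction: float = 0.02
    no_adapter_fraction: float = 0.02
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    canonical_fraction: float = 0.70
    mirna_abundance_sigma: float = 1.5
    noncanonical_concentration: float = 0.05
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.contaminant_fraction,
            self.short_fraction,
            self.no_adapter_fraction,
        )
        if any(not (0 <= f <= 1) for f in fracs) or sum(fracs) > 1:
            raise ValueError("special-read fractions must lie in [0,1] and sum <= 1")
        if self.depth < 1 or self.replicates < 1:
            raise ValueError("depth and replicates must be >= 1")
        if not (0 < self.canonical_fraction <= 1):
            raise ValueError("canonical_fraction must be in (0, 1]")

    def sample_ids(self) -> list[tuple[str, str, str]]:
        """(sample_id, group, time_point) in deterministic order."""
        out = []
        for g in self.groups:
            for t in self.time_points:
                for r in range(1, self.replicates + 1):
                    out.append((f"{g}_{t}_r{r}", g, t))
        return out


@dataclass
class ReferenceBundle:
    reference: MirnaReference
    variants: list[IsomirVariant]
    contaminants: ContaminantReference
    enumeration_params: EnumerationParams
    index: MatchIndex = field(init=False)

    def __post_init__(self) -> None:
        self.index = build_index(self.variants)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def simulate_reference(
    n_mirnas: int,
    seed: int = 0,
    params: EnumerationParams | None = None,
    n_contaminants_per_class: int = 3,
    contaminant_length: tuple[int, int] = (60, 120),
    hairpin_length: tuple[int, int] = (70, 90),
    mature_length: tuple[int, int] = (20, 23),
    max_attempts: int = 200,
) -> ReferenceBundle:
    """Generate a random mature+hairpin reference and contaminant sequences.

    Each hairpin embeds exactly one mature with at least ``max_add`` nt of
    flank on both sides (so all templated additions are realizable).
    Contaminants are rejection-sampled so that none of their windows lies
    within Hamming distance 1 of any enumerated isomiR variant; this makes
    miRNA-derived and contaminant-derived reads unambiguous by construction.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    params = params or EnumerationParams()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0x5EF)))

    matures: list[MatureRecord] = []
    hairpins: dict[str, HairpinRecord] = {}
    seen_matures: set[str] = set()
    for i in range(1, n_mirnas + 1):
        for _ in range(max_attempts):
            hlen = int(rng.integers(hairpin_length[0], hairpin_length[1] + 1))
            mlen = int(rng.integers(mature_length[0], mature_length[1] + 1))
            start = int(rng.integers(params.max_add, hlen - mlen - params.max_add + 1))
            hp_seq = _random_seq(rng, hlen)
            mat_seq = hp_seq[start : start + mlen]
            # the mature must locate uniquely inside its hairpin and be new
            if hp_seq.count(mat_seq) == 1 and mat_seq not in seen_matures:
                break
        else:
            raise RuntimeError("failed to draw a unique mature/hairpin pair")
        seen_matures.add(mat_seq)
        hp_id = f"syn-mir-{i:03d}"
        hairpins[hp_id] = HairpinRecord(hp_id, hp_seq)
        matures.append(
            MatureRecord(
                mirna_id=f"syn-miR-{i:03d}",
                name=f"syn-miR-{i:03d}",
                sequence=mat_seq,
                hairpin_id=hp_id,
                start=start,
                end=start + mlen,
            )
        )

    reference = MirnaReference(matures=matures, hairpins=hairpins)
    variants = enumerate_isomir_space(reference, params)
    index = build_index(variants)
    lengths = index.lengths

    def clashes(seq: str) -> bool:
        for L in lengths:
            for s in range(len(seq) - L + 1):
                window = seq[s : s + L]
                if index.lookup_exact(window) or index.lookup_distance1(window):
                    return True
        return False

    contaminants = ContaminantReference()
    class_order = [ReadClass.RRNA, ReadClass.TRNA, ReadClass.SNRNA, ReadClass.SNORNA]
    for cls_ in class_order:
        seqs = []
        for _ in range(n_contaminants_per_class):
            for _ in range(max_attempts):
                cand = _random_seq(
                    rng, int(rng.integers(contaminant_length[0], contaminant_length[1] + 1))
                )
                if not clashes(cand):
                    seqs.append(cand)
                    break
            else:
                raise RuntimeError(
                    "contaminant rejection sampling failed; variant space too dense "
                    "for the requested contaminant length"
                )
        contaminants.sequences[cls_] = seqs

    return ReferenceBundle(reference, variants, contaminants, params)


def write_reference_fastas(bundle: ReferenceBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mature": outdir / "mature.fa",
        "hairpin": outdir / "hairpin.fa",
        "contaminants": outdir / "contaminants.fa",
    }
    with open(paths["mature"], "w") as fh:
        for m in bundle.reference.matures:
            fh.write(f">{m.mirna_id}\n{m.sequence}\n")
    with open(paths["hairpin"], "w") as fh:
        for hp_id in sorted(bundle.reference.hairpins):
            fh.write(f">{hp_id}\n{bundle.reference.hairpins[hp_id].sequence}\n")
    with open(paths["contaminants"], "w") as fh:
        for cls_, seqs in bundle.contaminants.sequences.items():
            for i, seq in enumerate(seqs, 1):
                fh.write(f">{cls_.value}_{i:03d}\n{seq}\n")
    return paths


def baseline_proportions(
    bundle: ReferenceBundle, design: SimulationDesign, rng: np.random.Generator
) -> pd.Series:
    """One fixed simplex over the variant space shared by all samples.

    Per-miRNA abundances are log-normal; within a miRNA the canonical (0,0)
    variant receives ``canonical_fraction`` of the mass and the remainder is
    split over the other variants by a sparse symmetric Dirichlet.
    """
    by_parent: dict[str, list[IsomirVariant]] = {}
    for v in bundle.variants:
        by_parent.setdefault(v.canonical_parent, []).append(v)

    props: dict[str, float] = {}
    for mirna in sorted(by_parent):
        variants = sorted(by_parent[mirna], key=lambda v: v.variant_id)
        abundance = float(rng.lognormal(0.0, design.mirna_abundance_sigma))
        canonical = [
            v for v in variants if any(m == mirna and e5 == 0 and e3 == 0 for m, e5, e3 in v.parents)
        ]
        others = [v for v in variants if v not in canonical]
        if canonical:
            props[canonical[0].variant_id] = abundance * design.canonical_fraction
            rest = abundance * (1.0 - design.canonical_fraction)
        else:  # canonical sequence collapsed into another miRNA's variant
            rest = abundance
        if others and rest > 0:
            weights = rng.dirichlet(
                np.full(len(others), design.noncanonical_concentration)
            )
            for v, w in zip(others, weights):
                props[v.variant_id] = props.get(v.variant_id, 0.0) + rest * float(w)
    s = pd.Series(props, dtype=float)
    return s / s.sum()


def draw_base_proportions(bundle: ReferenceBundle, design: SimulationDesign) -> pd.Series:
    """The design's baseline simplex; a pure function of the design seed, shared
    by the read-level and count-level simulators."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(design.seed, 0xBA5E)))
    return baseline_proportions(bundle, design, rng)


def expected_proportions(bundle: ReferenceBundle, design: SimulationDesign) -> pd.DataFrame:
    """True per-sample feature proportions (variants x samples)."""
    base = draw_base_proportions(bundle, design)
    cols = {
        sid: sample_proportions(base, design, group, t)
        for sid, group, t in design.sample_ids()
    }
    df = pd.DataFrame(cols)
    df.index.name = "variant_id"
    return df


def sample_proportions(
    base: pd.Series, design: SimulationDesign, group: str, time_point: str
) -> pd.Series:
    """Apply the planted multiplicative effects for one group/time cell."""
    p = base.copy()
    for eff in design.planted_effects:
        if eff.group == group and eff.time_point == time_point:
            if eff.variant_id not in p.index:
                raise KeyError(
                    f"planted feature {eff.variant_id!r} absent from the variant space"
                )
            p[eff.variant_id] *= 2.0**eff.log2fc
    return p / p.sum()


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def _apply_errors(
    rng: np.random.Generator, read: str, n_copies: int, error_rate: float
) -> list[str]:
    """n_copies of `read` with independent per-base substitution errors."""
    if error_rate <= 0 or n_copies == 0:
        return [read] * n_copies
    L = len(read)
    n_err = rng.binomial(L, error_rate, size=n_copies)
    out = [read] * n_copies
    for i in np.flatnonzero(n_err):
        arr = list(read)
        for pos in rng.choice(L, size=n_err[i], replace=False):
            current = arr[pos]
            choices = [b for b in "ACGT" if b != current]
            arr[pos] = choices[int(rng.integers(3))]
        out[i] = "".join(arr)
    return out


def _assemble_read(insert: str, adapter: str, read_length: int) -> str:
    full = insert + adapter
    while len(full) < read_length:
        full += adapter
    return full[:read_length]


@dataclass
class SimulatedSample:
    sample_id: str
    group: str
    time_point: str
    reads: list[tuple[str, str]]  # (read_id, sequence), shuffled
    provenance: dict[str, str]  # read_id -> variant_id or class label
    true_counts: pd.Series  # realized miRNA-read counts per variant


@dataclass
class SimulatedExperiment:
    design: SimulationDesign
    sample_sheet: pd.DataFrame
    base_proportions: pd.Series
    true_counts: pd.DataFrame  # variants x samples, realized
    true_proportions: pd.DataFrame
    samples: list[SimulatedSample] | None  # None when streamed to disk
    paths: dict[str, Path] = field(default_factory=dict)


def _simulate_sample(
    sample_id: str,
    group: str,
    time_point: str,
    bundle: ReferenceBundle,
    design: SimulationDesign,
    base: pd.Series,
    rng: np.random.Generator,
) -> SimulatedSample:
    props = sample_proportions(base, design, group, time_point)
    mirna_depth = design.depth * (
        1.0
        - design.contaminant_fraction
        - design.short_fraction
        - design.no_adapter_fraction
    )
    mu = (props * mirna_depth).to_numpy()
    counts = _nb_counts(rng, mu, design.dispersion)
    true_counts = pd.Series(counts, index=props.index, dtype=int)

    variants = {v.variant_id: v for v in bundle.variants}
    reads: list[tuple[str, str]] = []
    provenance: dict[str, str] = {}
    serial = 0

    def add_read(seq: str, label: str) -> None:
        nonlocal serial
        rid = f"{sample_id}:{serial:07d}"
        serial += 1
        reads.append((rid, seq))
        provenance[rid] = label

    for vid in props.index:
        c = int(true_counts[vid])
        if c == 0:
            continue
        base_read = _assemble_read(
            variants[vid].sequence, design.adapter, design.read_length
        )
        for seq in _apply_errors(rng, base_read, c, design.error_rate):
            add_read(seq, vid)

    # contaminant reads
    n_cont = int(rng.poisson(design.contaminant_fraction * design.depth))
    cont_pool = [
        (cls_.value, seq)
        for cls_ in (ReadClass.RRNA, ReadClass.TRNA, ReadClass.SNRNA, ReadClass.SNORNA)
        for seq in bundle.contaminants.sequences.get(cls_, ())
    ]
    for _ in range(n_cont):
        label, src = cont_pool[int(rng.integers(len(cont_pool)))]
        ilen = int(rng.integers(16, min(40, len(src)) + 1))
        start = int(rng.integers(0, len(src) - ilen + 1))
        read = _assemble_read(src[start : start + ilen], design.adapter, design.read_length)
        read = _apply_errors(rng, read, 1, design.error_rate)[0]
        add_read(read, label)

    # short-insert reads
    n_short = int(rng.poisson(design.short_fraction * design.depth))
    for _ in range(n_short):
        ilen = int(rng.integers(5, 16))
        read = _assemble_read(_random_seq(rng, ilen), design.adapter, design.read_length)
        add_read(read, ReadClass.SHORT.value)

    # adapterless reads (rejection-sampled so the trimmer finds no adapter)
    trim_params = PreprocessParams(adapter=design.adapter)
    n_noad = int(rng.poisson(design.no_adapter_fraction * design.depth))
    for _ in range(n_noad):
        for _ in range(200):
            read = _random_seq(rng, design.read_length)
            if trim_adapter(read, trim_params) is None:
                break
        else:
            raise RuntimeError("failed to draw an adapterless read")
        add_read(read, ReadClass.NO_ADAPTOR.value)

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return SimulatedSample(sample_id, group, time_point, reads, provenance, true_counts)


def write_fastq(
    reads: Sequence[tuple[str, str]], path: str | Path, quality_char: str = "I"
) -> None:
    path = Path(path)
    text = "".join(
        f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n" for rid, seq in reads
    )
    if path.suffix == ".gz":
        # mtime=0 keeps output byte-identical across runs
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(text.encode())
    else:
        path.write_text(text)


def simulate_experiment(
    bundle: ReferenceBundle,
    design: SimulationDesign,
    outdir: str | Path | None = None,
) -> SimulatedExperiment:
    """Simulate all samples of the design.

    With ``outdir`` given, per-sample gzipped FASTQ files, the sample sheet
    and ground-truth tables are written there and reads are not retained in
    memory; with ``outdir=None`` everything is returned in memory.
    """
    for eff in design.planted_effects:
        if eff.group not in design.groups or eff.time_point not in design.time_points:
            raise ValueError(f"planted effect targets unknown cell: {eff}")

    root = np.random.SeedSequence(entropy=design.seed)
    sample_ss = root.spawn(len(design.sample_ids()))
    base = draw_base_proportions(bundle, design)
    for eff in design.planted_effects:
        if eff.variant_id not in base.index:
            raise KeyError(
                f"planted feature {eff.variant_id!r} absent from the variant space"
            )

    sheet_rows = []
    true_counts: dict[str, pd.Series] = {}
    true_props: dict[str, pd.Series] = {}
    samples: list[SimulatedSample] = []
    paths: dict[str, Path] = {}

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "fastq").mkdir(parents=True, exist_ok=True)
        (outdir / "ground_truth").mkdir(parents=True, exist_ok=True)

    for (sample_id, group, time_point), ss in zip(design.sample_ids(), sample_ss):
        sample = _simulate_sample(
            sample_id, group, time_point, bundle, design, base,
            np.random.default_rng(ss),
        )
        sheet_rows.append(
            {"sample_id": sample_id, "group": group, "time_point": time_point}
        )
        true_counts[sample_id] = sample.true_counts
        true_props[sample_id] = sample_proportions(base, design, group, time_point)
        if outdir is None:
            samples.append(sample)
        else:
            fq = outdir / "fastq" / f"{sample_id}.fastq.gz"
            write_fastq(sample.reads, fq)
            paths[sample_id] = fq
            prov = pd.Series(sample.provenance, name="label")
            prov.index.name = "read_id"
            prov.to_csv(
                outdir / "ground_truth" / f"{sample_id}.provenance.tsv", sep="\t"
            )

    sample_sheet = pd.DataFrame(sheet_rows)
    counts_df = pd.DataFrame(true_counts).fillna(0).astype(int)
    counts_df.index.name = "variant_id"
    props_df = pd.DataFrame(true_props)
    props_df.index.name = "variant_id"

    if outdir is not None:
        sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
        counts_df.to_csv(outdir / "ground_truth" / "true_counts.tsv", sep="\t")
        props_df.to_csv(outdir / "ground_truth" / "true_proportions.tsv", sep="\t")

    return SimulatedExperiment(
        design=design,
        sample_sheet=sample_sheet,
        base_proportions=base,
        true_counts=counts_df,
        true_proportions=props_df,
        samples=samples if outdir is None else None,
        paths=paths,
    )


def simulate_counts(
    bundle: ReferenceBundle, design: SimulationDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw only the per-sample NB count matrix (no reads).

    Returns (variants x samples counts, sample sheet). Useful for count-level
    studies (differential expression, overlap analyses) where read synthesis
    adds nothing.
    """
    root = np.random.SeedSequence(entropy=(design.seed, 0xC0))
    sample_ss = root.spawn(len(design.sample_ids()))
    base = draw_base_proportions(bundle, design)
    counts = {}
    rows = []
    for (sample_id, group, time_point), ss in zip(design.sample_ids(), sample_ss):
        rng = np.random.default_rng(ss)
        props = sample_proportions(base, design, group, time_point)
        counts[sample_id] = pd.Series(
            _nb_counts(rng, (props * design.depth).to_numpy(), design.dispersion),
            index=props.index,
        )
        rows.append({"sample_id": sample_id, "group": group, "time_point": time_point})
    df = pd.DataFrame(counts)
    df.index.name = "variant_id"
    return df, pd.DataFrame(rows)


def simulate_target_sets(
    mirna_ids: Sequence[str],
    seed: int = 0,
    n_genes: int = 300,
    targets_per_mirna: tuple[int, int] = (10, 30),
    n_pathways: int = 12,
    pathway_size: tuple[int, int] = (15, 40),
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """A synthetic miRNA->target map and GMT-style pathway gene sets."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0x7A6)))
    genes = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    target_map = {
        m: set(
            rng.choice(
                genes,
                size=int(rng.integers(targets_per_mirna[0], targets_per_mirna[1] + 1)),
                replace=False,
            )
        )
        for m in sorted(mirna_ids)
    }
    pathways = {
        f"PATHWAY_{i:02d}": set(
            rng.choice(
                genes,
                size=int(rng.integers(pathway_size[0], pathway_size[1] + 1)),
                replace=False,
            )
        )
        for i in range(1, n_pathways + 1)
    }
    return target_map, pathways


def write_target_sets(
    target_map: Mapping[str, set[str]],
    pathways: Mapping[str, set[str]],
    outdir: str | Path,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tm_path = outdir / "target_map.tsv"
    gmt_path = outdir / "pathways.gmt"
    with open(tm_path, "w") as fh:
        for m in sorted(target_map):
            for g in sorted(target_map[m]):
                fh.write(f"{m}\t{g}\tstrong\n")
    with open(gmt_path, "w") as fh:
        for pid in sorted(pathways):
            fh.write(pid + "\tsynthetic\t" + "\t".join(sorted(pathways[pid])) + "\n")
    return {"target_map": tm_path, "pathways": gmt_path}
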