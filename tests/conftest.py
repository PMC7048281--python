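import numpy as np
import pytest

from isomirseq.reference import (
    EnumerationParams,
    HairpinRecord,
    MatureRecord,
    MirnaReference,
    enumerate_isomir_space,
)
from isomirseq.simulate import simulate_reference


def make_reference(matures_and_flanks):
    """Build a MirnaReference from (mirna_id, mature_seq, flank5, flank3) tuples."""
    matures, hairpins = [], {}
    for i, (mid, mat, f5, f3) in enumerate(matures_and_flanks, 1):
        hp_id = f"hp-{i:02d}"
        hp_seq = f5 + mat + f3
        hairpins[hp_id] = HairpinRecord(hp_id, hp_seq)
        matures.append(
            MatureRecord(mid, mid, mat, hp_id, len(f5), len(f5) + len(mat))
        )
    return MirnaReference(matures=sorted(matures, key=lambda m: m.mirna_id), hairpins=hairpins)


def brute_force_isomir_space(reference, params: EnumerationParams):
    """Independent enumeration oracle: realize every (e5, e3) cell by direct
    slicing of the hairpin and collect the surviving sequences with origins."""
    result = {}
    for m in reference.matures:
        hp = reference.hairpins[m.hairpin_id].sequence
        for e5 in range(-params.max_trim, params.max_add + 1):
            for e3 in range(-params.max_trim, params.max_add + 1):
                start, end = m.start - e5, m.end + e3
                if start < 0 or end > len(hp) or end - start < params.min_len:
                    continue
                result.setdefault(hp[start:end], set()).add((m.mirna_id, e5, e3))
    return result


def random_reference(rng: np.random.Generator, n_mirnas: int):
    """Random matures embedded in random hairpins with random (>= 3 nt) flanks."""
    entries = []
    for i in range(1, n_mirnas + 1):
        mat = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 24))))
        f5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 30))))
        f3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 30))))
        entries.append((f"rnd-miR-{i:03d}", mat, f5, f3))
    return make_reference(entries)


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic reference (miRNAs, variants, contaminants)."""
    return simulate_reference(8, seed=11)


@pytest.fixture(scope="session")
def single_mirna_variants():
    """The 79-variant space of one 22-nt mature with full hairpin flanks."""
    ref = make_reference([("one-miR-1", "TGAGGTAGTAGGTTGTATAGTT", "AAGGC", "TCCGA")])
    return enumerate_isomir_space(ref, EnumerationParams())
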