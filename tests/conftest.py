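"""Shared fixtures: tiny constructed libraries with known distance structure."""

import numpy as np
import pytest

from barcode_eval import BarcodeDataset, SpecimenRecord
from barcode_eval.synthetic_data import SimulationConfig, simulate_library

BASE = ("ACGT" * 250)  # 1000 bp scaffold


def mutate(seq: str, positions, new_base) -> str:
    s = list(seq)
    for p in positions:
        s[p] = new_base
    return "".join(s)


def make_dataset(entries, label="fixture") -> BarcodeDataset:
    """entries: (specimen_id, sequence, species[, subfamily])."""
    recs = []
    for e in entries:
        sid, seq, sp = e[:3]
        subfam = e[3] if len(e) > 3 else "SubfamA"
        recs.append(SpecimenRecord(specimen_id=sid, sequence=seq, species=sp,
                                   genus=sp.split("_")[0], subfamily=subfam,
                                   family="FamX"))
    return BarcodeDataset(recs, label=label)


@pytest.fixture
def two_species_dataset() -> BarcodeDataset:
    """2 species x 2 sequences; intraspecific ~1%, interspecific ~10%.

    BASE cycles ACGT so site i holds base 'ACGT'[i % 4]. Substitutions are
    placed at A-sites (i % 4 == 0) and changed to G (transitions).
    """
    a1 = BASE
    a2 = mutate(BASE, range(0, 40, 4), "G")            # 10 transitions
    b1 = mutate(BASE, range(400, 800, 4), "G")         # 100 transitions
    b2 = mutate(b1, range(40, 80, 4), "G")             # 10 more
    return make_dataset([("a1", a1, "sp_a"), ("a2", a2, "sp_a"),
                         ("b1", b1, "sp_b"), ("b2", b2, "sp_b")])


@pytest.fixture
def sim30() -> tuple:
    """~30-sequence simulated library for oracle-equivalence tests."""
    cfg = SimulationConfig(seed=7, n_subfamilies=2, species_per_subfamily=5,
                           seqs_per_species=3, alignment_length=400,
                           target_intra=0.02, target_inter=0.2)
    return simulate_library(cfg)


@pytest.fixture
def gapped_sim() -> tuple:
    """Strict-barcode-gap library: deterministic branch lengths."""
    cfg = SimulationConfig(seed=11, n_subfamilies=2, species_per_subfamily=6,
                           seqs_per_species=3, alignment_length=2000,
                           target_intra=0.02, target_inter=0.24,
                           branch_length_shape=None)
    return simulate_library(cfg)


def rng_seeds(master: int, n: int) -> list[int]:
    return list(np.random.default_rng(master).integers(0, 2**31 - 1, size=n))
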