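"""Synthetic barcode reference libraries with controlled divergence.

The generator emulates the statistical structure of a curated COI library:
subfamily partitions, hundreds of species with variable sampling depth and
frequent singletons, intraspecific divergences around 2% against
interspecific divergences around 25%, a transition bias, and injectable
"problem" cases (shared haplotypes between species, near-zero
interspecific distances, deep intraspecific splits).

Sequences evolve on star phylogenies under the Kimura two-parameter model:
one random family root, an ancestral sequence per subfamily at branch
length ``subfamily_branch`` from the root, a consensus per species at
branch length (target_inter - target_intra)/2 from its subfamily
ancestor, and each specimen at branch length target_intra/2 from its
consensus. K2P branch lengths are additive, so the expected pairwise K2P
estimate is target_intra between conspecifics, target_inter between
heterospecifics of the same subfamily, and target_inter +
2*subfamily_branch across subfamilies; the defaults put the family-wide
interspecific mean near 25%. Branch lengths are
gamma-dispersed by default (shape ``branch_length_shape``), reproducing
the broad, overlapping distance distributions of real libraries; set the
shape to None for deterministic branch lengths (strict-gap scenarios).

All randomness flows from one ``numpy.random.default_rng(seed)`` consumed
in a fixed documented order, so equal seeds give byte-identical libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_metadata import BarcodeDataset, SpecimenRecord

# transition partner of base b is b ^ 2; transversion partners:
_TV1 = np.array([1, 0, 1, 0])
_TV2 = np.array([3, 2, 3, 2])
_BASES = np.array(list("ACGT"))


def k2p_event_probabilities(d: float, kappa: float) -> tuple[float, float]:
    """Per-site transition (P) and transversion (Q) difference
    probabilities after evolving a K2P branch of length d.

    With alpha the transition and beta the per-type transversion rate,
    kappa = alpha/beta and d = (alpha + 2 beta) t:

        Q = 1/2 (1 - e^{-4 beta t})
        P = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2 (alpha + beta) t}
    """
    if d < 0:
        raise ValueError("negative branch length")
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e4b = math.exp(-4.0 * bt)
    q = 0.5 * (1.0 - e4b)
    p = 0.25 + 0.25 * e4b - 0.5 * math.exp(-2.0 * (at + bt))
    return p, q


def check_reachable(d: float, kappa: float, margin: float = 0.05) -> None:
    """Refuse targets so deep that the K2P estimator sits at saturation."""
    p, q = k2p_event_probabilities(d, kappa)
    if 1.0 - 2.0 * p - q <= margin or 1.0 - 2.0 * q <= margin:
        raise ValueError(
            f"target distance {d} with kappa={kappa} is too close to "
            "saturation for reliable K2P estimation")


def evolve(enc: np.ndarray, d: float, kappa: float,
           rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence along a K2P branch of length d (exact
    per-site sampling from the finite-time substitution probabilities)."""
    p, q = k2p_event_probabilities(d, kappa)
    u = rng.random(enc.size)
    out = enc.copy()
    ts = u < p
    tv1 = (u >= p) & (u < p + 0.5 * q)
    tv2 = (u >= p + 0.5 * q) & (u < p + q)
    out[ts] = enc[ts] ^ 2
    out[tv1] = _TV1[enc[tv1]]
    out[tv2] = _TV2[enc[tv2]]
    return out


@dataclass
class SimulationConfig:
    """Generation parameters; defaults emulate a curated family-level
    library of the scale analysed here (~880 sequences, ~260 species in
    10 subfamilies, ~28% singletons, mean ~3.4 sequences/species, 658 bp,
    2% intraspecific vs 25% interspecific K2P divergence, kappa = 2)."""

    seed: int = 0
    alignment_length: int = 658
    n_subfamilies: int = 10
    species_per_subfamily: int = 26
    seqs_per_species: int | None = None   # fixed count; None = mixture below
    singleton_prob: float = 0.28
    seqs_poisson_lambda: float = 2.33     # non-singletons: 2 + Poisson(lam)
    kappa: float = 2.0
    target_intra: float = 0.02
    # expected interspecific distance within a subfamily; one value, or one
    # per subfamily:
    target_inter: float | list[float] = 0.20
    # root -> subfamily-ancestor branch; cross-subfamily interspecific
    # distances are target_inter + 2 * subfamily_branch:
    subfamily_branch: float = 0.028
    branch_length_shape: float | None = 2.0   # gamma shape; None = fixed
    shared_haplotype_pairs: list[tuple[str, str]] = field(default_factory=list)
    near_zero_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    label: str = "simulated"

    def inter_for(self, subfamily_index: int) -> float:
        if isinstance(self.target_inter, (list, tuple)):
            return self.target_inter[subfamily_index]
        return self.target_inter


@dataclass
class SimulatedTruth:
    """Ground truth for closed-loop tests."""

    species_consensus: dict[str, np.ndarray]
    species_subfamily: dict[str, str]
    specimen_branch: dict[str, float]       # K2P distance specimen->consensus
    species_branch: dict[str, float]        # K2P distance consensus->ancestor
    # per subfamily: (max intra model distance, min inter model distance)
    gap_bounds: dict[str, tuple[float, float]]
    injected_shared: list[tuple[str, str]] = field(default_factory=list)
    injected_near_zero: list[tuple[str, str, float]] = field(default_factory=list)
    injected_deep_split: list[tuple[str, float]] = field(default_factory=list)


def _decode(enc: np.ndarray) -> str:
    return "".join(_BASES[enc])


def _branch(mean: float, shape: float | None,
            rng: np.random.Generator) -> float:
    if mean <= 0:
        return 0.0
    if shape is None:
        return mean
    return float(rng.gamma(shape, mean / shape))


def simulate_library(config: SimulationConfig
                     ) -> tuple[BarcodeDataset, SimulatedTruth]:
    """Generate a library plus its ground truth.

    RNG consumption order: the family root first, then per subfamily its
    ancestor branch and sequence, then per species (in order) the species
    branch length, the consensus, the number of specimens, and per
    specimen its branch length and sequence; injected scenarios consume
    randomness last.
    """
    for k in range(config.n_subfamilies):
        inter = config.inter_for(k)
        if not config.target_intra < inter:
            raise ValueError("target_intra must be < target_inter")
        check_reachable(inter + config.target_intra
                        + 2.0 * config.subfamily_branch, config.kappa)
    rng = np.random.default_rng(config.seed)
    L = config.alignment_length
    root = rng.integers(0, 4, size=L).astype(np.int64)

    records: list[SpecimenRecord] = []
    truth = SimulatedTruth({}, {}, {}, {}, {})
    sp_counter = 0
    for k in range(config.n_subfamilies):
        subfam = f"Subfamily{k + 1:02d}"
        b_sub = _branch(config.subfamily_branch, config.branch_length_shape,
                        rng)
        ancestor = evolve(root, b_sub, config.kappa, rng)
        inter = config.inter_for(k)
        sp_branch_mean = (inter - config.target_intra) / 2.0
        intra_branch_mean = config.target_intra / 2.0
        sub_max_intra, sub_min_inter = 0.0, math.inf
        branches = []
        for s in range(config.species_per_subfamily):
            sp_counter += 1
            species = f"Species{sp_counter:04d}"
            genus = f"Genus{(sp_counter - 1) // 4 + 1:03d}"
            b_sp = _branch(sp_branch_mean, config.branch_length_shape, rng)
            consensus = evolve(ancestor, b_sp, config.kappa, rng)
            if config.seqs_per_species is not None:
                n_seq = config.seqs_per_species
            elif rng.random() < config.singleton_prob:
                n_seq = 1
            else:
                n_seq = 2 + int(rng.poisson(config.seqs_poisson_lambda))
            truth.species_consensus[species] = consensus
            truth.species_subfamily[species] = subfam
            truth.species_branch[species] = b_sp
            specimen_branches = []
            for j in range(n_seq):
                b = _branch(intra_branch_mean, config.branch_length_shape,
                            rng)
                seq = evolve(consensus, b, config.kappa, rng)
                sid = f"{species}_{j + 1:02d}"
                records.append(SpecimenRecord(
                    specimen_id=sid, sequence=_decode(seq), species=species,
                    genus=genus, subfamily=subfam, family="SimFamily",
                    source="new"))
                truth.specimen_branch[sid] = b
                specimen_branches.append(b)
            if n_seq >= 2:
                top2 = sorted(specimen_branches)[-2:]
                sub_max_intra = max(sub_max_intra, sum(top2))
            branches.append((b_sp, min(specimen_branches)))
        for a in range(len(branches)):
            for b in range(a + 1, len(branches)):
                sub_min_inter = min(
                    sub_min_inter,
                    branches[a][0] + branches[a][1]
                    + branches[b][0] + branches[b][1])
        truth.gap_bounds[subfam] = (sub_max_intra, sub_min_inter)

    dataset = BarcodeDataset(records, label=config.label,
                             alignment_length=L)
    for pair in config.shared_haplotype_pairs:
        dataset, truth = inject_problem_cases(
            dataset, truth, "shared_haplotype", species=pair, rng=rng)
    for sp_a, sp_b, dist in config.near_zero_pairs:
        dataset, truth = inject_problem_cases(
            dataset, truth, "near_zero_inter", species=(sp_a, sp_b),
            value=dist, rng=rng, kappa=config.kappa)
    return dataset, truth


def inject_problem_cases(dataset: BarcodeDataset, truth: SimulatedTruth,
                         scenario: str,
                         species: tuple[str, str] | str | None = None,
                         value: float = 0.006,
                         rng: np.random.Generator | None = None,
                         kappa: float = 2.0
                         ) -> tuple[BarcodeDataset, SimulatedTruth]:
    """Overwrite part of a simulated library with a known failure mode.

    * ``shared_haplotype`` — copy the first specimen sequence of species A
      verbatim onto the first specimen of species B (introgression-like);
      the affected sequences are heterospecifics at distance 0, hence
      false negatives at every threshold and ambiguous/incorrect under BCM.
    * ``near_zero_inter`` — rebuild species B's specimens from A's
      consensus evolved by ``value`` (default 0.006, a ~0.6% sister-pair).
    * ``deep_intra_split`` — re-generate the last specimen of the species
      at K2P distance ``value`` (use e.g. 0.20) from its consensus,
      making a deep conspecific split.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    records = list(dataset.records)
    index = {r.specimen_id: i for i, r in enumerate(records)}
    by_species: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_species.setdefault(r.species, []).append(i)

    if scenario == "shared_haplotype":
        sp_a, sp_b = species
        src = records[by_species[sp_a][0]]
        dst_i = by_species[sp_b][0]
        records[dst_i] = replace(records[dst_i], sequence=src.sequence)
        truth.specimen_branch[records[dst_i].specimen_id] = math.nan
        truth.injected_shared.append((sp_a, sp_b))
    elif scenario == "near_zero_inter":
        sp_a, sp_b = species
        base = truth.species_consensus[sp_a]
        new_consensus = evolve(base, value, kappa, rng)
        truth.species_consensus[sp_b] = new_consensus
        truth.species_branch[sp_b] = math.nan
        for i in by_species[sp_b]:
            b = truth.specimen_branch[records[i].specimen_id]
            seq = evolve(new_consensus, b, kappa, rng)
            records[i] = replace(records[i], sequence=_decode(seq))
        truth.injected_near_zero.append((sp_a, sp_b, value))
    elif scenario == "deep_intra_split":
        sp = species if isinstance(species, str) else species[0]
        i = by_species[sp][-1]
        seq = evolve(truth.species_consensus[sp], value, kappa, rng)
        records[i] = replace(records[i], sequence=_decode(seq))
        truth.specimen_branch[records[i].specimen_id] = value
        truth.injected_deep_split.append((sp, value))
    else:
        raise ValueError(f"unknown scenario '{scenario}'")
    return (BarcodeDataset(records, label=dataset.label,
                           alignment_length=dataset.alignment_length),
            truth)
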