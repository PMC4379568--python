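"""Synthetic provirus families with known ground truth.

The generator inverts the molecular-clock model: a provirus inserts
with two identical LTR copies of its subgroup ancestor, and each LTR
then accrues substitutions independently at half the inter-LTR rate
(0.15%/My per copy for the default 0.3%/My), so the expected inter-LTR
divergence of an element of age ``a`` is ``rate x a``.  Substitutions
follow a Jukes-Cantor scheme (uniform choice among the three other
bases).  Internal gag/pol/env segments are copied from a synthetic
reference provirus and optionally carry contiguous deletions; with a
configurable probability the element collapses to a solo LTR formed by
recombination between the two LTRs (a single hybrid LTR, internals
lost).  Random host flanks are added on both sides.

Three synthetic subgroup consensi (463/483/501 bp, mirroring the
published LTR2/LTR2B/LTR2C consensus lengths) are derived from one
random ancestor with region-graded divergence — U3 most diverged, U5
most conserved, as in the real subgroups — tuned so pairwise identities
fall in the published 75-85% band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sequence_io import LtrSequence, ReferenceAnnotation, write_fasta, \
    write_reference_annotation
from .subgroup import (
    DEFAULT_R_U5_BOUNDARY,
    DEFAULT_U3_R_BOUNDARY,
    SUBGROUP_LABELS,
    SubgroupConsensus,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: consensus lengths per subgroup (published LTR2/LTR2B/LTR2C lengths)
CONSENSUS_LENGTHS = {"LTR2": 463, "LTR2B": 483, "LTR2C": 501}

#: per-branch substitution proportions per region (U3 > R > U5), chosen so
#: pairwise consensus identities land in the 75-85% band with the real
#: U3 < R < U5 conservation gradient
_REGION_RATES = ((DEFAULT_U3_R_BOUNDARY - 1, 0.12),
                 (DEFAULT_R_U5_BOUNDARY - DEFAULT_U3_R_BOUNDARY, 0.08),
                 (None, 0.025))

#: reference provirus layout: 8,806 bp full-length prototype
REFERENCE_LENGTH = 8806


@dataclass
class DeletionSpec:
    """Per-gene deletion model: each gene independently deleted with
    ``prob``; the deleted fraction is uniform in [min_fraction, max_fraction]
    (the default band maps cleanly onto the structure-caller's
    truncated range)."""

    prob: float = 0.5
    min_fraction: float = 0.35
    max_fraction: float = 0.85

    def __post_init__(self):
        if not (0 <= self.prob <= 1):
            raise ValueError("deletion probability must be in [0, 1]")
        if not (0 <= self.min_fraction <= self.max_fraction <= 1):
            raise ValueError("deletion fractions must satisfy 0 <= min <= max <= 1")


@dataclass
class SimulationConfig:
    n_elements: int = 46
    ages_my: Sequence[float] = (10, 15, 20, 25, 30, 40)
    rate_pct_per_my: float = 0.3  # inter-LTR divergence rate
    subgroup_mix: Dict[str, float] = field(
        default_factory=lambda: {"LTR2": 16 / 46, "LTR2B": 21 / 46, "LTR2C": 9 / 46}
    )
    deletion_spec: DeletionSpec = field(default_factory=DeletionSpec)
    solo_ltr_prob: float = 29 / 46
    indel_rate: float = 0.0  # expected indels per LTR copy
    flank_bp: int = 500
    seed: int = 0

    def __post_init__(self):
        total = sum(self.subgroup_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("subgroup proportions must sum to 1")
        if not (0 <= self.solo_ltr_prob <= 1):
            raise ValueError("solo_ltr_prob must be in [0, 1]")
        if any(a < 0 for a in self.ages_my):
            raise ValueError("ages must be non-negative")


@dataclass
class SimulationTruth:
    element_id: str
    subgroup: str
    age_my: float
    structure: str  # solo_ltr | truncated | full_length
    n_substitutions_ltr5: int
    n_substitutions_ltr3: int
    n_diff_sites: Optional[int]  # realized differing inter-LTR sites
    ltr_length: int
    ltr5_seq: str
    ltr3_seq: Optional[str]
    deletions: List[Tuple[str, float]] = field(default_factory=list)
    sub_positions_ltr5: List[int] = field(default_factory=list)
    sub_positions_ltr3: List[int] = field(default_factory=list)

    @property
    def divergence_pct(self) -> Optional[float]:
        if self.n_diff_sites is None:
            return None
        return 100.0 * self.n_diff_sites / self.ltr_length


def _random_seq(rng, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng, seq: str, positions: np.ndarray) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def make_synthetic_consensi(seed: int = 0) -> List[SubgroupConsensus]:
    """Three subgroup consensi from one random ancestor.

    Deterministic per seed; lengths 463/483/501; each branch mutates at
    region-graded rates and is truncated at its subgroup length.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ancestor = _random_seq(rng, max(CONSENSUS_LENGTHS.values()))
    out = []
    for label in SUBGROUP_LABELS:
        length = CONSENSUS_LENGTHS[label]
        seq = ancestor
        offset = 0
        mutated = []
        for span, rate in _REGION_RATES:
            hi = len(seq) if span is None else offset + span
            block = np.arange(offset, hi)
            n = rng.binomial(len(block), rate)
            mutated.extend(rng.choice(block, size=n, replace=False))
            offset = hi
        seq = _mutate(rng, seq, np.array(sorted(mutated), dtype=int))
        out.append(SubgroupConsensus(label, seq[:length]))
    return out


def make_synthetic_reference(
    consensi: Sequence[SubgroupConsensus], seed: int = 0
) -> Tuple[LtrSequence, ReferenceAnnotation]:
    """A synthetic full-length reference provirus (8,806 bp).

    LTRs are the LTR2C consensus (the full-length prototype is an LTR2C
    element); gag/pol/env are random internal sequence with lengths
    proportioned like the prototype.  Labelled synthetic: it stands in
    for the real reference provirus in download-free runs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    ltr = next(c for c in consensi if c.label == "LTR2C").seq
    L = len(ltr)
    internal_len = REFERENCE_LENGTH - 2 * L
    gag_len = int(round(internal_len * 0.305))
    pol_len = int(round(internal_len * 0.445))
    env_len = internal_len - gag_len - pol_len
    internal = _random_seq(rng, internal_len)
    seq = ltr + internal + ltr
    features = [
        ("ltr5", 1, L),
        ("gag", L + 1, L + gag_len),
        ("pol", L + gag_len + 1, L + gag_len + pol_len),
        ("env", L + gag_len + pol_len + 1, L + internal_len),
        ("ltr3", L + internal_len + 1, REFERENCE_LENGTH),
    ]
    ann = ReferenceAnnotation("synthetic_reference", REFERENCE_LENGTH, features)
    return LtrSequence("synthetic_reference", seq, role="element"), ann


def _apply_indels(rng, seq: str, expected: float) -> str:
    n = rng.poisson(expected)
    arr = list(seq)
    for _ in range(n):
        pos = int(rng.integers(0, max(len(arr) - 6, 1)))
        size = int(rng.integers(1, 6))
        if rng.random() < 0.5:
            del arr[pos : pos + size]
        else:
            arr[pos:pos] = list(_random_seq(rng, size))
    return "".join(arr)


def simulate_provirus(
    ancestor: SubgroupConsensus,
    age_my: float,
    config: SimulationConfig,
    reference: Optional[Tuple[LtrSequence, ReferenceAnnotation]] = None,
    rng: Optional[np.random.Generator] = None,
    element_id: str = "sim",
) -> Tuple[LtrSequence, SimulationTruth]:
    """Simulate one provirus of known age from a subgroup ancestor."""
    if age_my < 0:
        raise ValueError("age must be non-negative")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if reference is None:
        reference = make_synthetic_reference(
            make_synthetic_consensi(config.seed), config.seed
        )
    ref_seq, ann = reference
    L = ancestor.length_bp
    p = (config.rate_pct_per_my / 100.0) / 2.0 * age_my
    if p > 1.0:
        raise ValueError("age x rate implies substitution probability > 1")

    def mutate_copy(seq):
        n = rng.binomial(L, p)
        pos = rng.choice(L, size=n, replace=False)
        return _mutate(rng, seq, pos), sorted(int(x) + 1 for x in pos)

    ltr5, pos5 = mutate_copy(ancestor.seq)
    ltr3, pos3 = mutate_copy(ancestor.seq)
    if config.indel_rate > 0:
        ltr5 = _apply_indels(rng, ltr5, config.indel_rate)
        ltr3 = _apply_indels(rng, ltr3, config.indel_rate)
        n_diff = None
    else:
        n_diff = sum(1 for a, b in zip(ltr5, ltr3) if a != b)

    flank5 = _random_seq(rng, config.flank_bp)
    flank3 = _random_seq(rng, config.flank_bp)

    solo = rng.random() < config.solo_ltr_prob
    if solo:
        crossover = int(rng.integers(1, L))
        hybrid = ltr5[:crossover] + ltr3[crossover:]
        element = LtrSequence(element_id, flank5 + hybrid + flank3, role="element")
        truth = SimulationTruth(
            element_id, ancestor.label, age_my, "solo_ltr",
            len(pos5), len(pos3), None, L, hybrid, None,
            sub_positions_ltr5=pos5, sub_positions_ltr3=pos3,
        )
        return element, truth

    deletions: List[Tuple[str, float]] = []
    internal_parts = []
    for gene in ("gag", "pol", "env"):
        lo, hi = ann.interval(gene)
        gene_seq = ref_seq.seq[lo - 1 : hi]
        if rng.random() < config.deletion_spec.prob:
            frac = float(rng.uniform(config.deletion_spec.min_fraction,
                                     config.deletion_spec.max_fraction))
            del_len = int(round(frac * len(gene_seq)))
            if del_len > len(gene_seq):
                raise ValueError(f"deletion exceeds {gene} length")
            start = int(rng.integers(0, len(gene_seq) - del_len + 1))
            gene_seq = gene_seq[:start] + gene_seq[start + del_len:]
            deletions.append((gene, frac))
        internal_parts.append(gene_seq)

    structure = "truncated" if deletions else "full_length"
    element_seq = flank5 + ltr5 + "".join(internal_parts) + ltr3 + flank3
    element = LtrSequence(element_id, element_seq, role="element")
    truth = SimulationTruth(
        element_id, ancestor.label, age_my, structure,
        len(pos5), len(pos3), n_diff, L, ltr5, ltr3,
        deletions=deletions,
        sub_positions_ltr5=pos5, sub_positions_ltr3=pos3,
    )
    return element, truth


def _allocate_counts(mix: Dict[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder allocation so a 16/21/9-style mix is hit exactly."""
    raw = {k: v * n for k, v in mix.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: (counts[k] - raw[k], k))[:short]:
        counts[k] += 1
    return counts


def generate_cohort(
    config: SimulationConfig,
    consensi: Optional[Sequence[SubgroupConsensus]] = None,
) -> Tuple[List[LtrSequence], List[SimulationTruth], List[SubgroupConsensus]]:
    """Simulate a full cohort; deterministic per config seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if consensi is None:
        consensi = make_synthetic_consensi(config.seed)
    reference = make_synthetic_reference(consensi, config.seed)
    by_label = {c.label: c for c in consensi}
    counts = _allocate_counts(config.subgroup_mix, config.n_elements)
    assignment = [lab for lab in SUBGROUP_LABELS for _ in range(counts.get(lab, 0))]
    assignment = [assignment[i] for i in rng.permutation(len(assignment))]
    if len(config.ages_my) == config.n_elements:
        ages = list(config.ages_my)
    else:
        ages = [float(rng.choice(config.ages_my)) for _ in range(config.n_elements)]
    elements, truths = [], []
    width = max(2, len(str(config.n_elements)))
    for k, (label, age) in enumerate(zip(assignment, ages), start=1):
        eid = f"sim{k:0{width}d}"
        elem, truth = simulate_provirus(
            by_label[label], age, config, reference, rng, element_id=eid
        )
        elements.append(elem)
        truths.append(truth)
    return elements, truths, list(consensi)


TRUTH_COLUMNS = (
    "element_id", "subgroup", "age_my", "structure",
    "n_substitutions_ltr5", "n_substitutions_ltr3", "n_diff_sites",
    "ltr_length", "deletions",
)


def generate_fixture_set(config: SimulationConfig, out_dir) -> Dict[str, Path]:
    """Write a cohort to disk: elements FASTA, LTR FASTAs, truth TSV and
    consensus/reference files.  Byte-identical for identical config+seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    elements, truths, consensi = generate_cohort(config)
    reference, ann = make_synthetic_reference(consensi, config.seed)

    paths = {
        "elements": out / "elements.fasta",
        "ltr_pairs": out / "ltr_pairs.fasta",
        "truth": out / "truth.tsv",
        "consensi": out / "consensi.fasta",
        "boundaries": out / "consensi_boundaries.tsv",
        "reference": out / "reference.fasta",
        "reference_features": out / "reference_features.tsv",
    }
    if elements:
        write_fasta(elements, paths["elements"])
    else:
        paths["elements"].write_text("")
    ltrs = []
    for t in truths:
        ltrs.append(LtrSequence(f"{t.element_id}_5LTR", t.ltr5_seq, role="ltr5"))
        if t.ltr3_seq is not None:
            ltrs.append(LtrSequence(f"{t.element_id}_3LTR", t.ltr3_seq, role="ltr3"))
    if ltrs:
        write_fasta(ltrs, paths["ltr_pairs"])
    else:
        paths["ltr_pairs"].write_text("")
    with open(paths["truth"], "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            dels = ";".join(f"{g}:{f:.3f}" for g, f in t.deletions) or "-"
            nd = "-" if t.n_diff_sites is None else str(t.n_diff_sites)
            fh.write(
                f"{t.element_id}\t{t.subgroup}\t{t.age_my:g}\t{t.structure}\t"
                f"{t.n_substitutions_ltr5}\t{t.n_substitutions_ltr3}\t{nd}\t"
                f"{t.ltr_length}\t{dels}\n"
            )
    write_fasta(
        [LtrSequence(c.label, c.seq, role="consensus") for c in consensi],
        paths["consensi"],
    )
    with open(paths["boundaries"], "w") as fh:
        fh.write("label\tu3_r_boundary\tr_u5_boundary\n")
        for c in consensi:
            fh.write(f"{c.label}\t{c.u3_r_boundary}\t{c.r_u5_boundary}\n")
    write_fasta([reference], paths["reference"])
    write_reference_annotation(ann, paths["reference_features"])
    return paths
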