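"""Subgroup classification and U3/R/U5 segmentation of HERV-E LTRs.

HERV-E LTRs fall into three phylogenetic subgroups — LTR2, LTR2B and
LTR2C — whose consensus sequences are 463, 483 and 501 bp long and share
75-83% pairwise identity.  A query LTR is assigned to the subgroup whose
consensus it is most similar to under global alignment (nearest
consensus), with an explicit ambiguity margin.

An LTR is tripartite: the transcriptional-control U3 region, the repeat
R region (starting at the transcription initiation site) and the unique
U5 region (starting after the polyadenylation signal).  The consensus
boundary positions are projected onto a query through the alignment to
segment it; published boundary positions fall in 298-337 (U3/R) and
399-435 (R/U5), and the range midpoints 317/417 are used as defaults
when per-consensus values are not supplied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import pairwise_align
from .pairwise_align import ScoringScheme, global_align, percent_identity
from .sequence_io import LtrSequence, ParseError, read_fasta

SUBGROUP_LABELS = ("LTR2", "LTR2B", "LTR2C")

#: default tripartition boundaries (midpoints of the published ranges)
DEFAULT_U3_R_BOUNDARY = 317
DEFAULT_R_U5_BOUNDARY = 417

#: classification margin (percentage points) below which a call is ambiguous
DEFAULT_AMBIGUITY_MARGIN = 1.0

#: queries shorter than this are refused (too little signal to classify)
DEFAULT_MIN_QUERY_LENGTH = 100


@dataclass
class SubgroupConsensus:
    label: str
    seq: str
    u3_r_boundary: int = DEFAULT_U3_R_BOUNDARY
    r_u5_boundary: int = DEFAULT_R_U5_BOUNDARY

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not (1 < self.u3_r_boundary < self.r_u5_boundary < len(self.seq)):
            raise ValueError(
                f"boundaries must satisfy 1 < u3r < ru5 < length for {self.label}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.seq)


@dataclass
class SubgroupCall:
    best: str
    identities: Dict[str, float]
    margin: float
    ambiguous: bool


@dataclass
class LtrSegmentation:
    """1-based inclusive intervals of U3, R and U5 on the query LTR."""

    u3: Optional[Tuple[int, int]]
    r: Optional[Tuple[int, int]]
    u5: Optional[Tuple[int, int]]
    missing: List[str] = field(default_factory=list)
    partial: List[str] = field(default_factory=list)

    def interval(self, region: str) -> Tuple[int, int]:
        iv = getattr(self, region)
        if iv is None:
            raise ValueError(f"region {region!r} missing from segmentation")
        return iv


def classify_subgroup(
    query,
    consensi,
    scoring: Optional[ScoringScheme] = None,
    ambiguity_margin: float = DEFAULT_AMBIGUITY_MARGIN,
    min_query_length: int = DEFAULT_MIN_QUERY_LENGTH,
) -> SubgroupCall:
    """Nearest-consensus subgroup call with an ambiguity margin.

    ``consensi`` supplies one consensus per subgroup label.  Ties are
    broken deterministically in label order (LTR2 < LTR2B < LTR2C) and
    marked ambiguous.
    """
    cons = {c.label: c for c in consensi}
    if set(cons) != set(SUBGROUP_LABELS):
        raise ValueError(
            f"need exactly the consensi {SUBGROUP_LABELS}, got {sorted(cons)}"
        )
    qseq = getattr(query, "seq", query)
    if len(qseq) < min_query_length:
        raise ValueError(
            f"query shorter than {min_query_length} bp; too short to classify"
        )
    identities = {
        label: percent_identity(global_align(qseq, cons[label].seq, scoring))
        for label in SUBGROUP_LABELS
    }
    ranked = sorted(identities.items(), key=lambda kv: (-kv[1], kv[0]))
    best = ranked[0][0]
    margin = ranked[0][1] - ranked[1][1]
    return SubgroupCall(
        best=best,
        identities=identities,
        margin=margin,
        ambiguous=margin < ambiguity_margin,
    )


def segment_ltr(
    query,
    consensus: SubgroupConsensus,
    scoring: Optional[ScoringScheme] = None,
) -> LtrSegmentation:
    """Project the consensus U3/R and R/U5 boundaries onto a query LTR.

    A boundary falling in a query gap maps to the next aligned query
    base, keeping the three regions a contiguous partition of the query
    span aligned to the consensus.  Regions truncated away in the query
    are flagged missing; regions whose consensus extent is not fully
    covered are flagged partial.
    """
    qseq = getattr(query, "seq", query)
    aln = global_align(qseq, consensus.seq, scoring)
    b1, b2 = consensus.u3_r_boundary, consensus.r_u5_boundary
    L = consensus.length_bp

    # for every consensus position: the aligned (or next-rightward) query pos
    qpos = cpos = 0
    q_at: Dict[int, int] = {}
    direct = set()  # consensus columns aligned to an actual query residue
    q_first = q_last = None
    for qc, cc in zip(aln.aligned_a, aln.aligned_b):
        if qc != "-":
            qpos += 1
        if cc != "-":
            cpos += 1
            q_at[cpos] = qpos + 1 if qc == "-" else qpos
            if qc != "-":
                direct.add(cpos)
                if q_first is None:
                    q_first = qpos
                q_last = qpos
    if q_first is None:
        return LtrSegmentation(None, None, None, missing=["u3", "r", "u5"])

    def clamp(p: Optional[int]) -> int:
        return min(max(p, q_first), q_last + 1)

    qb1, qb2 = clamp(q_at[b1]), clamp(q_at[b2])
    regions = {
        "u3": (q_first, qb1 - 1),
        "r": (qb1, qb2 - 1),
        "u5": (qb2, q_last),
    }
    spans = {"u3": (1, b1 - 1), "r": (b1, b2 - 1), "u5": (b2, L)}
    c_lo, c_hi = (min(direct), max(direct)) if direct else (0, -1)

    missing, partial = [], []
    out = {}
    for name, (lo, hi) in regions.items():
        if hi < lo:
            out[name] = None
            missing.append(name)
            continue
        out[name] = (lo, hi)
        s_lo, s_hi = spans[name]
        if c_lo > s_lo or c_hi < s_hi:
            partial.append(name)
    return LtrSegmentation(out["u3"], out["r"], out["u5"], missing, partial)


def region_similarity(
    a,
    b,
    segmentation_a: LtrSegmentation,
    segmentation_b: LtrSegmentation,
    region: str,
    scoring: Optional[ScoringScheme] = None,
) -> float:
    """Percent identity of one U3/R/U5 region between two LTRs."""
    if region not in ("u3", "r", "u5"):
        raise ValueError(f"unknown region {region!r}")
    sa = getattr(a, "seq", a)
    sb = getattr(b, "seq", b)
    lo_a, hi_a = segmentation_a.interval(region)
    lo_b, hi_b = segmentation_b.interval(region)
    return percent_identity(
        global_align(sa[lo_a - 1 : hi_a], sb[lo_b - 1 : hi_b], scoring)
    )


# ---------------------------------------------------------------------------
# consensus configuration IO and cohort summaries
# ---------------------------------------------------------------------------


def load_consensi(fasta_path, boundaries_path) -> List[SubgroupConsensus]:
    """Load consensi from FASTA plus a boundary TSV (label, u3_r, r_u5)."""
    seqs = {s.id: s.seq for s in read_fasta(fasta_path)}
    out = []
    with open(boundaries_path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "label":
                continue
            label, b1, b2 = row[0], int(row[1]), int(row[2])
            if label not in seqs:
                raise ParseError(f"boundary row {label!r} has no FASTA record")
            out.append(SubgroupConsensus(label, seqs[label], b1, b2))
    if not out:
        raise ParseError(f"no consensus boundaries in {boundaries_path}")
    return out


def write_classification_report(calls: Dict[str, SubgroupCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tbest\t" + "\t".join(SUBGROUP_LABELS) + "\tmargin\tambiguous\n")
        for qid, call in calls.items():
            idents = "\t".join(f"{call.identities[l]:.2f}" for l in SUBGROUP_LABELS)
            fh.write(
                f"{qid}\t{call.best}\t{idents}\t{call.margin:.2f}\t{call.ambiguous}\n"
            )


def summarize_subgroups(labels) -> List[Tuple[str, int, float]]:
    """(subgroup, n, percentage-to-1-dp) rows over a cohort."""
    labels = [l for l in labels if l is not None]
    total = len(labels)
    out = []
    for sub in SUBGROUP_LABELS:
        n = sum(1 for l in labels if l == sub)
        out.append((sub, n, round(100.0 * n / total, 1) if total else 0.0))
    return out
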