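"""Proviral structure calling by dot-plot homology to a reference provirus.

An intact provirus is 5'LTR - gag - pol - env - 3'LTR.  Most genomic
copies are degraded: recombination between the two LTRs leaves a
solitary LTR, and internal deletions truncate or remove gag/pol/env.
Each element is compared against an annotated reference provirus
(modeled on the 8,806 bp full-length HERV-E prototype) with exact-word
dot plots:

* per-gene coverage = fraction of the gene's reference word positions
  matched anywhere in the element; thresholds classify the gene as
  present (>= 0.80), truncated (0.05-0.80) or absent (< 0.05);
* LTR detection clusters element positions hitting an LTR reference
  into segments; a segment covering enough of the reference LTR counts
  as one LTR, and two segments at least 1 kb apart count as 5' + 3'.

The element is then called ``solo_ltr`` (one LTR, no internal genes),
``full_length`` (both LTRs, all genes present) or ``truncated``.
Elements with no reference homology on either strand are returned as
``unclassified`` rather than silently called solo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .pairwise_align import DotPlot, coverage_fraction, dotplot
from .sequence_io import LtrSequence, ReferenceAnnotation

GENES = ("gag", "pol", "env")

#: gene coverage >= this -> present
DEFAULT_PRESENT_THRESHOLD = 0.80
#: gene coverage < this -> absent
DEFAULT_ABSENT_THRESHOLD = 0.05

DEFAULT_GENE_WORD_SIZE = 11
#: LTR detection uses a shorter word so post-insertion LTR divergence
#: (up to ~8% for the oldest elements) still leaves a dense diagonal
DEFAULT_LTR_WORD_SIZE = 8
#: minimum fraction of reference-LTR words a segment must cover
DEFAULT_LTR_MIN_COVERAGE = 0.35
#: element positions closer than this are clustered into one LTR segment
DEFAULT_CLUSTER_GAP = 200
#: two LTR segments at least this far apart count as a 5'/3' pair
DEFAULT_PAIR_SEPARATION = 1000


@dataclass
class GeneStatus:
    gene: str
    status: str  # present | truncated | absent
    coverage: float

    def __post_init__(self):
        self.coverage = round(self.coverage, 3)


@dataclass
class LtrSegment:
    start: int  # 1-based on the element
    end: int
    coverage: float  # of the best-matching reference LTR


@dataclass
class StructureCall:
    element_id: str
    clazz: str  # solo_ltr | truncated | full_length | unclassified
    gene_statuses: List[GeneStatus] = field(default_factory=list)
    has_ltr5: bool = False
    has_ltr3: bool = False
    ltr_segments: List[LtrSegment] = field(default_factory=list)
    strand: str = "plus"
    note: Optional[str] = None


def call_genes(
    element,
    reference,
    annotation: ReferenceAnnotation,
    word_size: int = DEFAULT_GENE_WORD_SIZE,
    step: int = 1,
    present_threshold: float = DEFAULT_PRESENT_THRESHOLD,
    absent_threshold: float = DEFAULT_ABSENT_THRESHOLD,
    plot: Optional[DotPlot] = None,
) -> List[GeneStatus]:
    """Per-gene presence/truncation from element-vs-reference dot-plot
    coverage of each gene's reference interval."""
    for gene in GENES:
        if not annotation.has(gene):
            raise ValueError(f"reference annotation lacks feature {gene!r}")
    if plot is None:
        plot = dotplot(element, reference, word_size, step)
    statuses = []
    for gene in GENES:
        cov = coverage_fraction(plot, annotation.interval(gene), axis="b")
        if cov >= present_threshold:
            status = "present"
        elif cov >= absent_threshold:
            status = "truncated"
        else:
            status = "absent"
        statuses.append(GeneStatus(gene, status, cov))
    return statuses


def detect_ltrs(
    element,
    ltr_refs: Sequence,
    word_size: int = DEFAULT_LTR_WORD_SIZE,
    step: int = 1,
    min_coverage: float = DEFAULT_LTR_MIN_COVERAGE,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
) -> List[LtrSegment]:
    """LTR-homologous segments of an element.

    Element word positions hitting any reference LTR are clustered by
    proximity; a cluster qualifies as an LTR segment when it covers at
    least ``min_coverage`` of the word positions of its best-matching
    reference LTR.
    """
    segments: List[LtrSegment] = []
    for ref in ltr_refs:
        plot = dotplot(element, ref, word_size, step)
        if not plot.hits:
            continue
        n_ref_words = len(getattr(ref, "seq", ref)) - word_size + 1
        by_qpos = {}
        for i, j in plot.hits:
            by_qpos.setdefault(i, set()).add(j)
        qpos = sorted(by_qpos)
        cluster = [qpos[0]]
        clusters = []
        for p in qpos[1:]:
            if p - cluster[-1] > cluster_gap:
                clusters.append(cluster)
                cluster = [p]
            else:
                cluster.append(p)
        clusters.append(cluster)
        for cl in clusters:
            ref_cov = set().union(*(by_qpos[p] for p in cl))
            cov = len(ref_cov) / n_ref_words
            if cov >= min_coverage:
                segments.append(
                    LtrSegment(cl[0], cl[-1] + word_size - 1, round(cov, 3))
                )
    # merge overlapping segments found against different references
    segments.sort(key=lambda s: s.start)
    merged: List[LtrSegment] = []
    for seg in segments:
        if merged and seg.start <= merged[-1].end:
            last = merged[-1]
            last.end = max(last.end, seg.end)
            last.coverage = max(last.coverage, seg.coverage)
        else:
            merged.append(seg)
    return merged


def classify_structure(
    element,
    reference,
    annotation: ReferenceAnnotation,
    ltr_refs: Optional[Sequence] = None,
    gene_word_size: int = DEFAULT_GENE_WORD_SIZE,
    ltr_word_size: int = DEFAULT_LTR_WORD_SIZE,
    step: int = 1,
    present_threshold: float = DEFAULT_PRESENT_THRESHOLD,
    absent_threshold: float = DEFAULT_ABSENT_THRESHOLD,
    ltr_min_coverage: float = DEFAULT_LTR_MIN_COVERAGE,
    pair_separation: int = DEFAULT_PAIR_SEPARATION,
) -> StructureCall:
    """Classify an element as solo LTR, truncated or full-length provirus.

    ``ltr_refs`` are the sequences used for LTR detection (for instance
    the element's subgroup consensus); by default the reference
    provirus's own LTRs are used.  Both strands are tried: if the
    forward orientation shows no homology at all, the reverse
    complement is scanned before giving up.
    """
    if ltr_refs is None:
        ref_seq = getattr(reference, "seq", reference)
        lo5, hi5 = annotation.interval("ltr5")
        lo3, hi3 = annotation.interval("ltr3")
        ltr_refs = [ref_seq[lo5 - 1 : hi5], ref_seq[lo3 - 1 : hi3]]
    elem_id = getattr(element, "id", "element")

    def scan(elem):
        genes = call_genes(
            elem, reference, annotation, gene_word_size, step,
            present_threshold, absent_threshold,
        )
        segs = detect_ltrs(
            elem, ltr_refs, ltr_word_size, step, ltr_min_coverage
        )
        return genes, segs

    genes, segs = scan(element)
    strand = "plus"
    if not segs and all(g.status == "absent" for g in genes):
        rc = _revcomp(element)
        genes_rc, segs_rc = scan(rc)
        if segs_rc or any(g.status != "absent" for g in genes_rc):
            genes, segs, strand = genes_rc, segs_rc, "minus"
        else:
            return StructureCall(
                elem_id, "unclassified", genes, strand="plus",
                note="no homology to reference on either strand",
            )

    has5 = len(segs) >= 1
    has3 = len(segs) >= 2 and (segs[-1].start - segs[0].start) >= pair_separation
    if len(segs) == 1 and all(g.status == "absent" for g in genes):
        clazz = "solo_ltr"
    elif has5 and has3 and all(g.status == "present" for g in genes):
        clazz = "full_length"
    else:
        clazz = "truncated"
    return StructureCall(elem_id, clazz, genes, has5, has3, segs, strand)


def _revcomp(element):
    if hasattr(element, "reverse_complement"):
        return element.reverse_complement()
    comp = str.maketrans("ACGTN", "TGCAN")
    return element.upper().translate(comp)[::-1]


def render_structure(call: StructureCall) -> str:
    """Human-readable structure in the annotation-table vocabulary."""
    if call.clazz == "solo_ltr":
        return "solo LTR"
    if call.clazz == "full_length":
        return "full length"
    if call.clazz == "unclassified":
        return "unclassified"
    parts = [g.gene for g in call.gene_statuses if g.status != "present"]
    if not call.has_ltr3:
        parts.append("3'LTR")
    return ", ".join(parts) + " truncated" if parts else "truncated"


def summarize_structures(calls) -> List[Tuple[str, int, float]]:
    """(class, n, percentage-to-1-dp) rows over a cohort of calls."""
    labels = [getattr(c, "clazz", c) for c in calls]
    labels = [l for l in labels if l is not None]
    total = len(labels)
    out = []
    for clazz in ("solo_ltr", "truncated", "full_length", "unclassified"):
        n = sum(1 for l in labels if l == clazz)
        if clazz == "unclassified" and n == 0:
            continue
        out.append((clazz, n, round(100.0 * n / total, 1) if total else 0.0))
    return out
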