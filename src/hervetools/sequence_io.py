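"""Readers and writers for the formats the pipeline touches.

FASTA (via Biopython), the tab-separated element annotation table of the
46-locus HERV-E cohort, Newick trees (via dendropy) and genome-browser
style interval strings (``chr:start-end``, 1-based inclusive; a start
greater than its end encodes minus-strand orientation and is normalized
on parsing).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clock_dating import AgeEstimate

_ALPHABET = set("ACGTN")

#: path of the bundled 46-element HERV-E annotation table
ELEMENT_TABLE = Path(__file__).parent / "data" / "herve_elements.tsv"

SUBGROUPS = ("LTR2", "LTR2B", "LTR2C")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genomic intervals
# ---------------------------------------------------------------------------

_INTERVAL_RE = re.compile(r"^([A-Za-z0-9_.]+):(\d+)-(\d+)$")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "plus"

    def __post_init__(self):
        if self.start > self.end or self.start < 1:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def render(self) -> str:
        if self.strand == "minus":
            return f"{self.chrom}:{self.end}-{self.start}"
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_interval(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end``; reversed coordinates mean minus strand."""
    m = _INTERVAL_RE.match(text.strip())
    if not m:
        raise ParseError(f"malformed genomic interval: {text!r}")
    chrom, a, b = m.group(1), int(m.group(2)), int(m.group(3))
    if a < 1 or b < 1:
        raise ParseError(f"non-positive coordinate in interval: {text!r}")
    if a > b:
        return GenomicInterval(chrom, b, a, "minus")
    return GenomicInterval(chrom, a, b, "plus")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


@dataclass
class LtrSequence:
    """A nucleotide sequence with an identifier and optional role/location.

    Roles: ``ltr5``, ``ltr3``, ``internal``, ``element``, ``consensus``.
    """

    id: str
    seq: str
    role: Optional[str] = None
    interval: Optional[GenomicInterval] = None

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - _ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq, 1) if c in bad)
            raise ParseError(
                f"illegal character {sorted(bad)[0]!r} at position {pos} "
                f"in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "LtrSequence":
        comp = str.maketrans("ACGTN", "TGCAN")
        return LtrSequence(self.id, self.seq.translate(comp)[::-1], self.role)


def read_fasta(path) -> List[LtrSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(LtrSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs, path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# element annotation table
# ---------------------------------------------------------------------------

_AGE_CENSORED_RE = re.compile(r"^>\s*(\d+)\s*My$")
_AGE_POINT_RE = re.compile(r"^(\d+)\s*My$")


@dataclass
class ProvirusElement:
    locus: str
    name: Optional[str] = None
    subgroup: Optional[str] = None
    ltr5_interval: Optional[GenomicInterval] = None
    ltr3_interval: Optional[GenomicInterval] = None
    size_bp: int = 0
    structure: Optional[str] = None  # solo_ltr | truncated | full_length
    structure_text: Optional[str] = None
    divergence_pct: Optional[float] = None
    clock_age: Optional[AgeEstimate] = None
    epo_age: Optional[AgeEstimate] = None
    amplification: Optional[str] = None


def _norm(cell: Optional[str]) -> Optional[str]:
    if cell is None:
        return None
    cell = cell.replace("’", "'").strip()
    return cell if cell not in ("", "-") else None


def _parse_age(cell: str, method: str) -> AgeEstimate:
    m = _AGE_CENSORED_RE.match(cell)
    if m:
        v = int(m.group(1))
        return AgeEstimate(value_my=float(v), rounded_my=v, censored=True, method=method)
    m = _AGE_POINT_RE.match(cell)
    if m:
        v = int(m.group(1))
        return AgeEstimate(value_my=float(v), rounded_my=v, censored=False, method=method)
    raise ParseError(f"unparsable age cell {cell!r}")


def _parse_structure(cell: str) -> str:
    low = cell.lower()
    if "solo" in low:
        return "solo_ltr"
    if "full length" in low:
        return "full_length"
    if "truncated" in low:
        return "truncated"
    raise ParseError(f"unknown structure description {cell!r}")


def read_element_table(path=None) -> List[ProvirusElement]:
    """Read the element annotation TSV (defaults to the bundled 46-locus table).

    "-" and empty cells are absent values; ">50 My"-style cells parse to
    censored age estimates; the literature "Genomic Amplification" column
    is kept as opaque annotation.
    """
    path = ELEMENT_TABLE if path is None else path
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = [
            _norm_header(h) for h in next(reader)
        ]
        rows = [r for r in reader if any(c.strip() for c in r)]
    col = {name: idx for idx, name in enumerate(header)}
    required = ["locus", "subgroup", "5'ltr genomic location", "size (bp)", "structure"]
    for name in required:
        if name not in col:
            raise ParseError(f"missing column {name!r} in {path}")

    def get(row, name):
        idx = col.get(name)
        if idx is None or idx >= len(row):
            return None
        return _norm(row[idx])

    elements = []
    for row in rows:
        locus = get(row, "locus")
        if locus is None:
            raise ParseError("row with empty locus")
        try:
            subgroup = get(row, "subgroup")
            if subgroup is not None and subgroup not in SUBGROUPS:
                raise ParseError(f"unknown subgroup label {subgroup!r}")
            ltr5 = get(row, "5'ltr genomic location")
            ltr3 = get(row, "3'ltr genomic location")
            struct_text = get(row, "structure")
            clock = get(row, "molecular clock dating")
            epo = get(row, "epo alignment dating")
            div = get(row, "5' and 3'ltr divergences")
            size = get(row, "size (bp)")
            elem = ProvirusElement(
                locus=locus,
                name=get(row, "herv name"),
                subgroup=subgroup,
                ltr5_interval=parse_interval(ltr5) if ltr5 else None,
                ltr3_interval=parse_interval(ltr3) if ltr3 else None,
                size_bp=int(size.replace(",", "")) if size else 0,
                structure=_parse_structure(struct_text) if struct_text else None,
                structure_text=struct_text,
                divergence_pct=float(div.rstrip("%")) if div else None,
                clock_age=_parse_age(clock, "molecular_clock") if clock else None,
                epo_age=_parse_age(epo, "epo_bound") if epo else None,
                amplification=get(row, "genomic amplification"),
            )
        except ParseError as exc:
            raise ParseError(f"row {locus!r}: {exc}") from exc
        if elem.size_bp <= 0:
            raise ParseError(f"row {locus!r}: non-positive size")
        if elem.structure == "solo_ltr" and elem.ltr3_interval is not None:
            raise ParseError(f"row {locus!r}: solo LTR with a 3'LTR interval")
        elements.append(elem)
    return elements


def _norm_header(h: str) -> str:
    return h.replace("’", "'").strip().lower()


# ---------------------------------------------------------------------------
# reference provirus annotation
# ---------------------------------------------------------------------------

_REF_FEATURES = ("ltr5", "gag", "pol", "env", "ltr3")


@dataclass
class ReferenceAnnotation:
    """Feature map of a reference provirus (LTRs and internal genes)."""

    name: str
    total_length: int
    features: List[Tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        feats = sorted(self.features, key=lambda f: f[1])
        prev_end = 0
        for feat, start, end in feats:
            if feat not in _REF_FEATURES:
                raise ValueError(f"unknown feature {feat!r}")
            if start <= prev_end:
                raise ValueError(f"overlapping/unsorted feature {feat!r}")
            if not (1 <= start <= end <= self.total_length):
                raise ValueError(f"feature {feat!r} outside [1, {self.total_length}]")
            prev_end = end
        names = [f[0] for f in feats]
        if names.count("ltr5") != 1 or names.count("ltr3") != 1:
            raise ValueError("annotation must contain exactly one ltr5 and one ltr3")
        if names.index("ltr5") > names.index("ltr3"):
            raise ValueError("ltr5 must precede ltr3")
        self.features = feats

    def interval(self, feature: str) -> Tuple[int, int]:
        for feat, start, end in self.features:
            if feat == feature:
                return (start, end)
        raise KeyError(f"feature {feature!r} not annotated")

    def has(self, feature: str) -> bool:
        return any(f[0] == feature for f in self.features)


def read_reference_annotation(path, name: str = "reference") -> ReferenceAnnotation:
    """Read a 4-column TSV (feature, start, end, name); length = max end."""
    feats = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "feature":
                continue
            feats.append((row[0], int(row[1]), int(row[2])))
    if not feats:
        raise ParseError(f"empty reference annotation {path}")
    return ReferenceAnnotation(name, max(e for _, _, e in feats), feats)


def write_reference_annotation(ann: ReferenceAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tstart\tend\tname\n")
        for feat, start, end in ann.features:
            fh.write(f"{feat}\t{start}\t{end}\t{ann.name}\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def write_newick(tree, path) -> None:
    """Serialize a :class:`~hervetools.phylogeny.PhyloTree` as Newick.

    Integer clade supports are written as internal node labels.
    """
    from . import phylogeny

    if not isinstance(tree, phylogeny.PhyloTree):
        raise TypeError("write_newick expects a PhyloTree")
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


def read_newick(path):
    from . import phylogeny

    with open(path) as fh:
        text = fh.read()
    return phylogeny.PhyloTree.from_newick(text)
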