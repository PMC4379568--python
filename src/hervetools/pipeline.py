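"""End-to-end orchestration: from sequences (or a printed annotation
table) to a cohort report and a bootstrap consensus tree.

Two entry modes:

* **sequence mode** — elements plus LTR pairs plus consensi plus
  reference provirus: classify subgroups, call structures, clock-date
  LTR pairs and reconstruct the 5'LTR phylogeny;
* **table mode** (``from_table``) — recompute the derivable columns
  (clock ages, cohort summaries) directly from the divergences printed
  in an annotation table, with no sequence data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import clock_dating, phylogeny, sequence_io, structure_call, subgroup
from .pairwise_align import ScoringScheme, DEFAULT_SCORING, divergence_pct
from .sequence_io import LtrSequence

log = logging.getLogger("hervetools")


@dataclass
class PipelineConfig:
    out_dir: Path
    # sequence mode inputs
    elements_fasta: Optional[Path] = None
    ltr_pairs_fasta: Optional[Path] = None
    consensi_fasta: Optional[Path] = None
    consensi_boundaries: Optional[Path] = None
    reference_fasta: Optional[Path] = None
    reference_features: Optional[Path] = None
    # table mode input
    element_table: Optional[Path] = None
    from_table: bool = False
    # parameters
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    rate_pct_per_my: float = clock_dating.DEFAULT_RATE_PCT_PER_MY
    cap_my: int = clock_dating.DEFAULT_CAP_MY
    bootstrap_reps: int = 200
    bootstrap_starts: int = 1
    seed: int = 0

    def validate(self):
        if self.from_table:
            needed = [self.element_table]
        else:
            needed = [
                self.elements_fasta, self.ltr_pairs_fasta,
                self.consensi_fasta, self.consensi_boundaries,
                self.reference_fasta, self.reference_features,
            ]
        missing = [p for p in needed if p is None or not Path(p).exists()]
        if missing:
            raise FileNotFoundError(
                f"missing pipeline inputs: {[str(m) for m in missing]}"
            )


@dataclass
class PipelineResults:
    rows: List[Dict]
    subgroup_summary: List
    structure_summary: List
    tree: Optional[phylogeny.PhyloTree] = None


class StageError(RuntimeError):
    def __init__(self, stage: str, element: Optional[str], exc: Exception):
        super().__init__(f"stage {stage!r}"
                         + (f", element {element!r}" if element else "")
                         + f": {exc}")
        self.stage = stage
        self.element = element


def _setup_logging(out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    config.validate()
    out = Path(config.out_dir)
    _setup_logging(out)
    log.info("pipeline start seed=%d mode=%s", config.seed,
             "table" if config.from_table else "sequence")
    if config.from_table:
        results = _run_table_mode(config)
    else:
        results = _run_sequence_mode(config)
    df, text = render_report(results)
    df.to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "summary.txt").write_text(text)
    if results.tree is not None:
        sequence_io.write_newick(results.tree, out / "tree.nwk")
    manifest = {
        "seed": config.seed,
        "mode": "table" if config.from_table else "sequence",
        "n_elements": len(results.rows),
        "outputs": ["report.tsv", "summary.txt"]
        + (["tree.nwk"] if results.tree is not None else []),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("pipeline done: %d elements", len(results.rows))
    return results


def _run_table_mode(config: PipelineConfig) -> PipelineResults:
    try:
        elements = sequence_io.read_element_table(config.element_table)
    except Exception as exc:
        raise StageError("read_table", None, exc) from exc
    rows = []
    for el in elements:
        clock = None
        if el.divergence_pct is not None:
            clock = clock_dating.estimate_age(
                el.divergence_pct, config.rate_pct_per_my, config.cap_my
            )
        rows.append({
            "element_id": el.locus,
            "name": el.name,
            "subgroup": el.subgroup,
            "size_bp": el.size_bp,
            "structure": el.structure,
            "structure_text": el.structure_text,
            "divergence_pct": el.divergence_pct,
            "clock_age": clock,
            "epo_age": el.epo_age,
        })
    return PipelineResults(
        rows,
        subgroup.summarize_subgroups([r["subgroup"] for r in rows]),
        structure_call.summarize_structures([r["structure"] for r in rows]),
    )


def _run_sequence_mode(config: PipelineConfig) -> PipelineResults:
    try:
        elements = sequence_io.read_fasta(config.elements_fasta)
        ltrs = {s.id: s for s in sequence_io.read_fasta(config.ltr_pairs_fasta)}
        consensi = subgroup.load_consensi(
            config.consensi_fasta, config.consensi_boundaries
        )
        reference = sequence_io.read_fasta(config.reference_fasta)[0]
        annotation = sequence_io.read_reference_annotation(config.reference_features)
    except Exception as exc:
        raise StageError("load_inputs", None, exc) from exc
    cons_by_label = {c.label: c for c in consensi}

    rows = []
    ltr5_seqs = []
    for elem in elements:
        ltr5 = ltrs.get(f"{elem.id}_5LTR")
        ltr3 = ltrs.get(f"{elem.id}_3LTR")
        if ltr5 is None:
            raise StageError("pair_ltrs", elem.id,
                             ValueError("no 5'LTR sequence provided"))
        try:
            call = subgroup.classify_subgroup(ltr5, consensi, config.scoring)
        except Exception as exc:
            raise StageError("classify", elem.id, exc) from exc
        log.info("classify element=%s best=%s margin=%.2f",
                 elem.id, call.best, call.margin)
        try:
            struct = structure_call.classify_structure(
                elem, reference, annotation,
                ltr_refs=[cons_by_label[call.best].seq],
            )
        except Exception as exc:
            raise StageError("structure", elem.id, exc) from exc
        div = age = None
        if ltr3 is not None:
            try:
                div = divergence_pct(ltr5, ltr3, config.scoring)
                age = clock_dating.estimate_age(
                    div, config.rate_pct_per_my, config.cap_my
                )
            except Exception as exc:
                raise StageError("date", elem.id, exc) from exc
        rows.append({
            "element_id": elem.id,
            "name": None,
            "subgroup": call.best,
            "subgroup_margin": round(call.margin, 2),
            "size_bp": len(elem),
            "structure": struct.clazz,
            "structure_text": structure_call.render_structure(struct),
            "divergence_pct": None if div is None else round(div, 1),
            "clock_age": age,
            "epo_age": None,
        })
        ltr5_seqs.append(LtrSequence(elem.id, ltr5.seq, role="ltr5"))

    tree = None
    if len(ltr5_seqs) >= 4:
        try:
            log.info("tree: aligning %d 5'LTRs", len(ltr5_seqs))
            msa = phylogeny.build_msa(ltr5_seqs, config.scoring)
            log.info("tree: bootstrap n_reps=%d seed=%d",
                     config.bootstrap_reps, config.seed)
            tree = phylogeny.bootstrap_support(
                msa, n_reps=config.bootstrap_reps, seed=config.seed,
                n_random_addition_starts=config.bootstrap_starts,
            )
        except Exception as exc:
            raise StageError("tree", None, exc) from exc
    return PipelineResults(
        rows,
        subgroup.summarize_subgroups([r["subgroup"] for r in rows]),
        structure_call.summarize_structures([r["structure"] for r in rows]),
        tree,
    )


_CLASS_DISPLAY = {"solo_ltr": "solo LTR", "truncated": "truncated",
                  "full_length": "full length", "unclassified": "unclassified"}


def render_report(results: PipelineResults):
    """Cohort report as a DataFrame (annotation-table column order) plus
    a human-readable summary text."""
    records = []
    for r in results.rows:
        clock = r.get("clock_age")
        epo = r.get("epo_age")
        records.append({
            "Locus": r["element_id"],
            "HERV Name": r.get("name") or "-",
            "Subgroup": r.get("subgroup") or "-",
            "Size (bp)": r.get("size_bp") or "-",
            "Structure": r.get("structure_text") or "-",
            "5' and 3'LTR Divergences":
                "-" if r.get("divergence_pct") is None
                else f"{r['divergence_pct']:.1f}%",
            "Molecular Clock Dating": "-" if clock is None else clock.render(),
            "EPO Alignment Dating": "-" if epo is None else epo.render(),
        })
    df = pd.DataFrame.from_records(records)
    lines = [f"Cohort of {len(results.rows)} elements", "", "Subgroups:"]
    for label, n, pct in results.subgroup_summary:
        lines.append(f"  {label}: {n} ({pct:.1f}%)")
    lines.append("Structures:")
    for clazz, n, pct in results.structure_summary:
        lines.append(f"  {_CLASS_DISPLAY.get(clazz, clazz)}: {n} ({pct:.1f}%)")
    return df, "\n".join(lines) + "\n"
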