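"""End-to-end survey pipeline: pattern search -> hydrogen-bond filter ->
geometric classification -> inventory report.

Stage 1 screens the structure's pseudo-atom graph against every pattern
in the library under the chosen distance tolerance. Stage 2 keeps only
candidate triples in which each base makes at least two base-base
hydrogen bonds. Stage 3 classifies survivors into geometric families and
assigns composition codes. The report carries per-family and per-code
counts and the fraction of triples containing a (cis) Watson-Crick pair.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .classify import TripleCodeRegistry, TripleRecord, classify_triple
from .config import Config
from .matcher import StructureGraph, canonicalize_hits, ullmann_search
from .patterns import PatternMatrix, ToleranceSpec
from .structure_io import Nucleotide, ResId

logger = logging.getLogger(__name__)


@dataclass
class InventoryReport:
    structure_id: str
    triples: list[TripleRecord] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    @property
    def counts_by_family(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.triples:
            out[t.family] = out.get(t.family, 0) + 1
        return dict(sorted(out.items()))

    @property
    def counts_by_code(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.triples:
            out[t.code] = out.get(t.code, 0) + 1
        return dict(sorted(out.items()))

    def counts_by_chain(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.triples:
            chains = sorted({r[0] for r in t.residues})
            key = "+".join(chains)
            out[key] = out.get(key, 0) + 1
        return dict(sorted(out.items()))

    def counts_by_region(self, regions: dict[str, tuple[int, int]]) -> dict[str, int]:
        """Counts per user-defined residue-number region; a triple counts
        toward a region when all three residues fall inside it."""
        out = {name: 0 for name in regions}
        for t in self.triples:
            for name, (lo, hi) in regions.items():
                if all(lo <= r[1] <= hi for r in t.residues):
                    out[name] += 1
        return out


def wc_pair_fraction(report: InventoryReport) -> float:
    """Fraction of admitted triples that contain a cis Watson-Crick /
    Watson-Crick pair."""
    if not report.triples:
        raise ValueError("empty report: Watson-Crick fraction undefined")
    n_wc = sum(1 for t in report.triples if t.contains_wc_pair)
    return n_wc / len(report.triples)


def run_search(nucleotides: list[Nucleotide],
               library: list[PatternMatrix],
               tol: ToleranceSpec,
               config: Config | None = None,
               structure_id: str = "structure",
               chains: list[str] | None = None,
               registry: TripleCodeRegistry | None = None) -> InventoryReport:
    """Run the three-stage survey on one structure's nucleotides."""
    if not library:
        raise ValueError("empty pattern library")
    config = config or Config()
    registry = registry or TripleCodeRegistry()
    if chains:
        nucleotides = [n for n in nucleotides if n.res_id[0] in chains]

    report = InventoryReport(
        structure_id=structure_id,
        parameters={
            "tolerance": str(tol),
            "hbond_mode": config.hbond_mode,
            "allow_protonation": config.allow_protonation,
            "patterns": [p.name for p in library],
            "chains": chains or "all",
        },
    )
    report.stage_counts["nucleotides"] = len(nucleotides)
    if len(nucleotides) < 3:
        report.stage_counts.update(stage1_hits=0, stage2_pass=0)
        return report

    graph = StructureGraph.from_nucleotides(nucleotides)
    by_id: dict[ResId, Nucleotide] = {n.res_id: n for n in nucleotides}

    candidate_sets: dict[tuple[ResId, ...], list[str]] = {}
    for pattern in library:
        hits = canonicalize_hits(ullmann_search(pattern, graph, tol))
        logger.info("stage 1: pattern %s -> %d hits", pattern.name, len(hits))
        for hit in hits:
            candidate_sets.setdefault(hit.residues, []).append(pattern.name)
    report.stage_counts["stage1_hits"] = len(candidate_sets)

    from .hbond import triple_hbond_filter

    n_pass = 0
    for residues in sorted(candidate_sets):
        nucs = [by_id[r] for r in residues]
        ok, counts, bonds = triple_hbond_filter(
            nucs, criteria=config.hbond_criteria, mode=config.hbond_mode,
            protonation_search=config.allow_protonation)
        logger.info("stage 2: %s bonds/base %s -> %s",
                    residues, counts, "pass" if ok else "drop")
        if not ok:
            continue
        n_pass += 1
        record = classify_triple(nucs, bonds, registry)
        record.matched_patterns = sorted(set(candidate_sets[residues]))
        report.triples.append(record)
    report.stage_counts["stage2_pass"] = n_pass
    logger.info("pipeline %s: %d nucleotides, %d stage-1 candidates, %d triples",
                structure_id, len(nucleotides), len(candidate_sets), n_pass)
    return report


def report_to_tsv(report: InventoryReport) -> str:
    """Hit table as TSV text (one admitted triple per row)."""
    header = [
        "structure", "residues", "composition", "code", "family",
        "contains_wc_pair", "n_hbonds", "pair_labels", "patterns",
    ]
    rows = ["\t".join(header)]
    for t in report.triples:
        residues = ";".join(f"{c}:{n}{i}" for c, n, i in t.residues)
        pairs = ";".join(pg.label() for pg in t.pair_geometries)
        patterns = ";".join(getattr(t, "matched_patterns", []))
        rows.append("\t".join([
            report.structure_id, residues, t.composition, t.code, t.family,
            str(t.contains_wc_pair).lower(), str(len(t.hbonds)), pairs,
            patterns,
        ]))
    return "\n".join(rows) + "\n"


def report_to_json(report: InventoryReport) -> str:
    """Full records as JSON (provenance parameters included)."""
    from . import __version__

    payload = {
        "tool_version": __version__,
        "structure": report.structure_id,
        "parameters": report.parameters,
        "stage_counts": report.stage_counts,
        "counts_by_family": report.counts_by_family,
        "counts_by_code": report.counts_by_code,
        "counts_by_chain": report.counts_by_chain(),
        "triples": [
            {
                "residues": [list(r) for r in t.residues],
                "composition": t.composition,
                "code": t.code,
                "family": t.family,
                "contains_wc_pair": t.contains_wc_pair,
                "hbonds": [
                    {
                        "donor": [list(hb.donor[0]), hb.donor[1]],
                        "acceptor": [list(hb.acceptor[0]), hb.acceptor[1]],
                        "d_DA": round(hb.d_da, 3),
                        "protonated": hb.protonated,
                    }
                    for hb in t.hbonds
                ],
                "pairs": [pg.label() for pg in t.pair_geometries],
            }
            for t in report.triples
        ],
    }
    if report.triples:
        payload["wc_pair_fraction"] = wc_pair_fraction(report)
    return json.dumps(payload, indent=2) + "\n"
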