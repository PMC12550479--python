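"""End-to-end annotation: detect -> families -> classify -> scan.

``annotate_genome`` is the single entry point the CLI and the benchmark
use: de novo structural candidates, family construction, superfamily
labels, a genome-wide scan with the family seeds, and the landscape
summary, returned together.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import classify_families
from .detect import DetectionParams, detect_genome
from .families import ClusterParams, build_families
from .model import Contig, MITEFamily, MITEHit
from .scan import (LandscapeSummary, scan, seed_library_from_families,
                   summarize_landscape)


@dataclass
class AnnotationResult:
    candidates: list
    families: list[MITEFamily]
    singletons: list
    hits: list[MITEHit]
    landscape: LandscapeSummary


def annotate_genome(genome: list[Contig],
                    detection: DetectionParams | None = None,
                    clustering: ClusterParams | None = None,
                    rules=None,
                    max_divergence: float = 0.15,
                    min_score: float = 50.0) -> AnnotationResult:
    """Run the full annotation pipeline on one genome.

    Families need at least ``clustering.min_copies`` structural candidates,
    so isolated spurious candidates never reach the scan stage; the scan
    then recovers diverged or truncated copies the structural detector
    missed.
    """
    detection = detection or DetectionParams()
    clustering = clustering or ClusterParams()
    candidates = detect_genome(genome, detection)
    families, singletons = build_families(candidates, genome, clustering)
    classify_families(families, genome, rules)
    if families:
        hits = scan(genome, seed_library_from_families(families),
                    max_divergence=max_divergence, min_score=min_score)
    else:
        hits = []
    landscape = summarize_landscape(hits, genome)
    return AnnotationResult(candidates=candidates, families=families,
                            singletons=singletons, hits=hits,
                            landscape=landscape)
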