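"""Input readers, report writers, and the end-to-end pipeline.

The pipeline chains discovery -> off-target search -> exon annotation ->
scoring/ranking -> oligo design and emits three artifacts: a candidates
FASTA, a full tab-separated report (1-based inclusive coordinates, the
human-facing convention) and a UCSC-style custom-track BED (0-based
half-open) with rank scores rescaled to 0-1000.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from pyfaidx import Fasta

from .annotation import ExonAnnotation, ExonSet, closest_exon
from .config import PatternConfig
from .discovery import CandidateSite, find_candidate_sites
from .offtargets import OffTargetHit, SeedIndex, search_off_targets
from .oligos import design_oligos
from .scoring import RankedSite, off_target_score, rank_sites, site_rank_score

__all__ = [
    "RunReport",
    "load_query",
    "load_genome",
    "run_pipeline",
    "write_candidates_fasta",
    "write_full_tsv",
    "write_track_bed",
]

logger = logging.getLogger("guidefinder")


@dataclass
class RunReport:
    config: PatternConfig
    sites: list[RankedSite]
    stats: dict = field(default_factory=dict)


def load_query(source: str | Path) -> str:
    """Read a query sequence from a FASTA file (first record) or raw text.

    A path to an existing file is parsed as FASTA when it starts with '>',
    otherwise its whole content is treated as a raw sequence; any other
    string is the sequence itself.
    """
    if isinstance(source, Path) or os.path.exists(str(source)):
        text = Path(source).read_text()
        if text.lstrip().startswith(">"):
            lines = text.lstrip().splitlines()
            seq_lines = []
            for line in lines[1:]:
                if line.startswith(">"):
                    break
                seq_lines.append(line.strip())
            return "".join(seq_lines)
        return "".join(text.split())
    return "".join(str(source).split())


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a multi-FASTA genome; names are headers up to the first whitespace."""
    fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def run_pipeline(
    query: str,
    genome: Mapping[str, str],
    exons: ExonSet | None,
    cfg: PatternConfig,
) -> RunReport:
    """Execute the full analysis; deterministic for identical inputs."""
    try:
        candidates = find_candidate_sites(query, cfg)
    except ValueError as exc:
        raise RuntimeError(f"site discovery failed: {exc}") from exc
    logger.info("discovery: %d candidate sites", len(candidates))
    if not candidates:
        return RunReport(cfg, [], {"candidates": 0})

    try:
        index = SeedIndex(genome, cfg)
    except ValueError as exc:
        raise RuntimeError(f"off-target indexing failed: {exc}") from exc

    sites: list[RankedSite] = []
    n_hits = 0
    n_annotated = 0
    for cand in candidates:
        hits = search_off_targets(cand, index, cfg, include_on_target=True)
        on_target = next((h for h in hits if h.is_on_target), None)
        off_hits = [h for h in hits if not h.is_on_target]
        n_hits += len(off_hits)
        pairs: list[tuple[OffTargetHit, ExonAnnotation]] = []
        for hit in off_hits:
            hit.mismatch_score = off_target_score(
                hit.mismatch_positions, cfg.score_base, cfg.protospacer_length
            )
            if exons is not None:
                ann = closest_exon(hit, exons, cfg.exon_assignment_radius)
            else:
                ann = ExonAnnotation(None, None, None, "intergenic")
            if ann.distance is not None:
                n_annotated += 1
            pairs.append((hit, ann))
        site = RankedSite(
            candidate=cand,
            off_targets=pairs,
            rank_score=site_rank_score(pairs),
            oligos=design_oligos(cand.protospacer, cfg.oligo_gg_mode),
            on_target=on_target,
        )
        sites.append(site)
    logger.info("search: %d off-target hits (%d exon-annotated)", n_hits, n_annotated)
    ranked = rank_sites(sites)
    return RunReport(
        cfg,
        ranked,
        {"candidates": len(candidates), "off_targets": n_hits, "annotated": n_annotated},
    )


def write_candidates_fasta(sites: list[RankedSite], path: str | Path) -> None:
    """One record per ranked site: ``T<rank>|<start+1>-<end>|<strand>``."""
    if not sites:
        logger.warning("no candidate sites; writing empty FASTA %s", path)
    with open(path, "w") as fh:
        for site in sites:
            c = site.candidate
            fh.write(f">{c.site_id}|{c.query_start + 1}-{c.query_end}|{c.strand}\n")
            fh.write(c.sequence + "\n")


def _render_mismatched(hit: OffTargetHit) -> str:
    """Protospacer with mismatched bases lowercased, PAM appended uppercase."""
    rendered = [
        b.lower() if (i + 1) in hit.mismatch_positions else b.upper()
        for i, b in enumerate(hit.site_sequence)
    ]
    return "".join(rendered) + hit.pam_observed.upper()


_SITE_COLS = [
    "record", "site_id", "query_start", "query_end", "strand", "protospacer",
    "pam", "rank_score", "total_off_targets", "forward_oligo", "reverse_oligo",
]
_OT_COLS = [
    "record", "chrom", "start", "end", "strand", "sequence", "mismatches",
    "mismatch_score", "exon_distance", "category", "gene_name", "gene_id",
]


def write_full_tsv(report: RunReport, path: str | Path) -> None:
    """Full tab-separated report: a site line then one line per off-target.

    Coordinates are 1-based inclusive; real numbers carry 4 decimals; NA
    marks missing exon assignments.
    """
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        fh.write("# site columns: " + "\t".join(_SITE_COLS) + "\n")
        fh.write("# offtarget columns: " + "\t".join(_OT_COLS) + "\n")
        for site in report.sites:
            c = site.candidate
            oligos = site.oligos
            fh.write(
                "\t".join(
                    [
                        "site", str(c.site_id), str(c.query_start + 1), str(c.query_end),
                        c.strand, c.protospacer, c.pam, f"{site.rank_score:.4f}",
                        str(site.total_off_targets),
                        oligos.forward if oligos else "NA",
                        oligos.reverse if oligos else "NA",
                    ]
                )
                + "\n"
            )
            for hit, ann in site.off_targets:
                dist = "NA" if ann.distance is None else str(ann.distance)
                fh.write(
                    "\t".join(
                        [
                            "offtarget", hit.chrom, str(hit.start + 1), str(hit.end),
                            hit.strand, _render_mismatched(hit),
                            str(hit.total_mismatches),
                            f"{hit.mismatch_score:.4f}" if hit.mismatch_score is not None else "NA",
                            dist, ann.category,
                            ann.gene_name or "NA", ann.gene_id or "NA",
                        ]
                    )
                    + "\n"
                )


def write_track_bed(report: RunReport, path: str | Path) -> None:
    """BED6 custom track; scores min-max rescaled to 0-1000 over the run.

    Sites without a located on-target genomic locus are skipped with a
    warning. With a single site (or all-equal scores) every score maps to
    1000.
    """
    placed = [s for s in report.sites if s.on_target is not None]
    skipped = len(report.sites) - len(placed)
    if skipped:
        logger.warning("%d site(s) lack a genomic locus; skipped in BED track", skipped)
    scores = [s.rank_score for s in placed]
    lo, hi = (min(scores), max(scores)) if scores else (0.0, 0.0)
    with open(path, "w") as fh:
        for site in placed:
            if hi > lo:
                bed_score = round(1000 * (site.rank_score - lo) / (hi - lo))
            else:
                bed_score = 1000
            ot = site.on_target
            fh.write(
                f"{ot.chrom}\t{ot.start}\t{ot.end}\t{site.candidate.site_id}\t"
                f"{bed_score}\t{ot.strand}\n"
            )
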