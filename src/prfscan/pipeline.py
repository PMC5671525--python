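"""End-to-end analysis: annotate -> align -> PRF scan -> conserve -> tree.

Mirrors the order of a comparative genome announcement: genome organization
first, polyprotein relatedness second, frameshift-site discovery last.  All
outputs are plain text (GFF3, FASTA, TSV, newick, JSON manifest) and a
re-run with identical inputs and config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .align import AlignConfig, global_align, p_distance_matrix
from .annotate import GenomeAnnotation, find_longest_orf, write_gff3
from .conserve import ConserveConfig, compare_sites, report_text
from .phylo import midpoint_root, neighbor_joining, write_newick
from .prf import PRFConfig, scan_genome
from .seq_io import GenomeRecord, read_fasta

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    genomes: list  # FASTA paths
    outdir: str
    align: AlignConfig = field(default_factory=AlignConfig)
    prf: PRFConfig = field(default_factory=PRFConfig)
    conserve: ConserveConfig = field(default_factory=ConserveConfig)
    conserve_pair: tuple | None = None  # (id_a, id_b) for the two-genome site report
    tree: bool = False
    pairs: str = "all"  # pairwise alignment policy

    def validate(self) -> None:
        if not self.genomes:
            raise ValueError("at least one genome FASTA is required")
        if self.pairs not in ("all", "none"):
            raise ValueError(f"pairs must be 'all' or 'none', got {self.pairs!r}")
        if not (0 <= self.prf.spacer_min <= self.prf.spacer_max):
            raise ValueError("invalid spacer bounds")


@dataclass
class PipelineResult:
    records: list
    annotations: dict  # id -> GenomeAnnotation
    candidates: dict  # id -> [PRFCandidate]
    pairwise: list  # rows of the identity/similarity table
    outdir: Path


def _candidate_rows(rec_id: str, cands) -> list[str]:
    rows = []
    for c in cands:
        flags = []
        if c.site.via_exception:
            flags.append("xxx-exception")
        if not c.site.in_frame:
            flags.append("off-frame")
        if c.minus1_truncated:
            flags.append("minus1-truncated")
        rows.append(
            "\t".join(
                [
                    rec_id,
                    str(c.site.pos + 1),  # 1-based for reporting
                    c.site.display,
                    str(c.spacer_len),
                    f"bp={c.hairpin.total_bp};wc_base_run={c.hairpin.base_run_wc};"
                    f"gc_in_run={c.hairpin.base_run_gc};loop={c.hairpin.loop_len}",
                    str(c.minus1_orf_codons),
                    ",".join(flags) or ".",
                ]
            )
        )
    return rows


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full analysis over a set of genome FASTAs.

    Writes per-genome GFF3 + polyprotein FASTA, a pairwise
    identity/similarity TSV, a PRF candidate TSV, optionally a two-genome
    conservation report and an NJ tree, plus a manifest recording the
    configuration for provenance.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records: list[GenomeRecord] = []
    for path in cfg.genomes:
        records.extend(read_fasta(path))
    if len({r.id for r in records}) != len(records):
        raise ValueError("duplicate genome ids in input")

    annotations: dict[str, GenomeAnnotation] = {}
    for rec in records:
        ann = find_longest_orf(rec)
        annotations[rec.id] = ann
        write_gff3(ann, outdir / f"{rec.id}.gff3")
        with open(outdir / f"{rec.id}.polyprotein.faa", "w") as fh:
            fh.write(f">{rec.id} polyprotein\n")
            for i in range(0, len(ann.polyprotein), 70):
                fh.write(ann.polyprotein[i : i + 70] + "\n")

    pairwise_rows = []
    if cfg.pairs == "all" and len(records) >= 2:
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                a, b = records[i], records[j]
                aln = global_align(
                    annotations[a.id].polyprotein,
                    annotations[b.id].polyprotein,
                    cfg.align,
                    a_id=a.id,
                    b_id=b.id,
                )
                pairwise_rows.append(
                    [
                        a.id,
                        b.id,
                        aln.columns,
                        round(aln.identity_pct, 2),
                        round(aln.similarity_pct, 2),
                        aln.score,
                    ]
                )
        with open(outdir / "pairwise.tsv", "w") as fh:
            fh.write("a_id\tb_id\tcolumns\tidentity_pct\tsimilarity_pct\tscore\n")
            for row in pairwise_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")

    candidates = {}
    cand_rows = []
    for rec in records:
        cands = scan_genome(rec, annotations[rec.id], cfg.prf)
        candidates[rec.id] = cands
        cand_rows.extend(_candidate_rows(rec.id, cands))
    with open(outdir / "prf_candidates.tsv", "w") as fh:
        fh.write("genome_id\tpos\theptamer\tspacer_len\tstem\tminus1_orf_codons\tflags\n")
        for row in cand_rows:
            fh.write(row + "\n")

    if cfg.conserve_pair is not None:
        ida, idb = cfg.conserve_pair
        rec_by_id = {r.id: r for r in records}
        ca = candidates.get(ida) or []
        cb = candidates.get(idb) or []
        if ca and cb:
            site_aln, classes = compare_sites(
                (rec_by_id[ida], annotations[ida], ca[0]),
                (rec_by_id[idb], annotations[idb], cb[0]),
                cfg.conserve,
            )
            (outdir / f"conserve_{ida}_{idb}.txt").write_text(
                report_text(site_aln, classes, ca[0])
            )

    if cfg.tree and len(records) >= 3:
        dm = p_distance_matrix(
            [annotations[r.id].polyprotein for r in records],
            [r.id for r in records],
            cfg.align,
        )
        tree = midpoint_root(neighbor_joining(dm))
        write_newick(tree, outdir / "tree.nwk")

    manifest = {
        "tool": "prfscan",
        "version": __version__,
        "genomes": [str(p) for p in cfg.genomes],
        "config": {
            "align": asdict(cfg.align),
            "prf": {
                "xxx_exceptions": sorted(cfg.prf.xxx_exceptions),
                "spacer_min": cfg.prf.spacer_min,
                "spacer_max": cfg.prf.spacer_max,
                "frame_filter": cfg.prf.frame_filter,
                "fold": {
                    k: v
                    for k, v in asdict(cfg.prf.fold).items()
                    if k != "pair_scores"
                },
            },
        },
    }
    blob = json.dumps(manifest, sort_keys=True)
    manifest["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        records=records,
        annotations=annotations,
        candidates=candidates,
        pairwise=pairwise_rows,
        outdir=outdir,
    )
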