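"""End-to-end orchestration: preprocess -> identify -> expression ->
degradome, driven by a single run configuration.

Stages communicate through on-disk TSV/FASTA artifacts so each one is
independently inspectable and resumable; :func:`run_all` wires them together
and writes a Markdown run report with the filter cascade, known/novel
counts, the tissue partition, differential-expression calls and the
degradome target table.  In-memory helpers (:func:`identify_stage`,
:func:`expression_stage`, :func:`degradome_stage`) carry the actual logic
and are what the test-suite exercises.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import degradome as deg
from .expression import delta_delta_ct, differential_expression, tissue_partition
from .identify import (
    CriteriaThresholds,
    assign_family,
    evaluate_window,
    extract_flanks,
    format_variant_name,
    map_to_matures,
)
from .preprocess import JunkRules, UniqueTag, run_preprocess

__all__ = [
    "RunConfig",
    "StageError",
    "identify_stage",
    "expression_stage",
    "degradome_stage",
    "run_all",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run.

    Defaults are the screening values used throughout the package: 18-25 nt
    clean tags, end shift <= 4 and one internal mismatch for known-miRNA
    mapping, the 11 hairpin criteria at their standard thresholds, target
    score cutoff 7.0, presence threshold 1 raw count, significance 0.01 and
    Z threshold 1.  The free-energy criterion reads "dG at most -15
    kcal/mol"; the sign convention is explicit in
    :class:`~mirforge.identify.CriteriaThresholds`.
    """

    srna_fastqs: dict[str, str] = field(default_factory=dict)  # tissue -> path
    degradome_fastq: str | None = None
    mature_fa: str | None = None
    hairpin_fa: str | None = None
    other_mature_fa: str | None = None
    other_hairpin_fa: str | None = None
    genome_fa: str | None = None
    transcripts_fa: str | None = None
    contaminants_dir: str | None = None
    qpcr_ct: str | None = None
    qpcr_calibrator: str = "root"
    outdir: str = "forge_out"
    seed: int = 0

    adapter3: str = "TGGAATTCTCGG"
    min_adapter_overlap: int = 6
    min_tag_len: int = 18
    max_tag_len: int = 25
    junk: JunkRules = field(default_factory=JunkRules)
    max_end_shift: int = 4
    max_internal_mismatch: int = 1
    flank: int = 120
    max_loci: int = 20
    criteria: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    degradome_adaptor: str = "CAGCAG"
    degradome_tag_len: int = 20
    score_cutoff: float = 7.0
    presence_threshold: int = 1
    alpha: float = 0.01
    z_threshold: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "junk" in raw:
            raw["junk"] = JunkRules(**raw["junk"])
        if "criteria" in raw:
            raw["criteria"] = CriteriaThresholds(**raw["criteria"])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# identify stage


def identify_stage(
    tags: list[UniqueTag],
    matures: dict[str, str],
    precursors: dict[str, str] | None = None,
    genome: dict[str, str] | None = None,
    config: RunConfig | None = None,
    other_matures: dict[str, str] | None = None,
    other_precursors: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Call known miRNAs from clean tags and screen the rest for novel loci.

    Known-miRNA calling is two-stage: same-species references first, then
    (for tags still unmatched) an other-species reference group whose hits
    additionally require an exact genomic match when a genome is supplied.
    Returns (known table, novel table, novel candidate records).  Known
    rows: variant name, reference, family, tag sequence and per-library
    counts (one row per clean tag with a best mapping).  Novel rows carry
    the accepted precursor locus, structure and criterion metrics; the
    record list additionally keeps the rejected candidates with their
    failing criteria.
    """
    cfg = config or RunConfig()
    libs = sorted({lib for t in tags for lib in t.counts})
    known_rows, unmapped = [], []

    def _map(tag, mat, prec):
        return map_to_matures(
            tag.sequence, mat, prec, cfg.max_end_shift, cfg.max_internal_mismatch
        )

    def _genomic_hit(seq: str) -> bool:
        if genome is None:
            return True
        from .identify import revcomp

        seq = seq.upper()
        rc = revcomp(seq)
        return any(seq in c or rc in c for c in genome.values())

    for tag in tags:
        if tag.annotation != "clean":
            continue
        hits = _map(tag, matures, precursors)
        if not hits and other_matures:
            cand = _map(tag, other_matures, other_precursors)
            if cand and _genomic_hit(tag.sequence):
                hits = cand
        if hits:
            best = hits[0]
            name = format_variant_name(best)
            known_rows.append(
                {
                    "name": name,
                    "reference": best.base,
                    "family": assign_family(name) or "",
                    "sequence": tag.sequence,
                    **{lib: tag.counts.get(lib, 0) for lib in libs},
                }
            )
        else:
            unmapped.append(tag)
    known = pd.DataFrame(known_rows)
    if not known.empty:
        known = known.sort_values(
            ["name", "sequence"], kind="stable"
        ).reset_index(drop=True)

    novel_rows, records = [], []
    idx = 0
    for tag in unmapped:
        if genome is None:
            break
        windows = extract_flanks(genome, tag.sequence, cfg.flank, cfg.max_loci)
        best_pass = None
        for w in windows:
            cand, metrics, ok, verdicts = evaluate_window(w, cfg.criteria)
            records.append(
                {
                    "sequence": tag.sequence,
                    "window": w,
                    "candidate": cand,
                    "metrics": metrics,
                    "passes": ok,
                    "verdicts": verdicts,
                }
            )
            if ok:
                # two passing windows: keep the lower free energy;
                # tie -> the downstream window
                key = (cand.free_energy, 0 if w.side == "downstream" else 1)
                if best_pass is None or key < best_pass[0]:
                    best_pass = (key, w, cand, metrics)
        if best_pass is not None:
            _, w, cand, metrics = best_pass
            idx += 1
            name = f"PC-{metrics.arm}-{idx}_{tag.total}"
            novel_rows.append(
                {
                    "name": name,
                    "sequence": tag.sequence,
                    "contig": cand.contig,
                    "start": cand.start,
                    "end": cand.end,
                    "strand": cand.strand,
                    "arm": metrics.arm,
                    "precursor": cand.sequence,
                    "structure": cand.structure,
                    "free_energy": cand.free_energy,
                    **{lib: tag.counts.get(lib, 0) for lib in libs},
                }
            )
    novel = pd.DataFrame(novel_rows)
    return known, novel, records


# ---------------------------------------------------------------------------
# expression stage


def expression_stage(
    known: pd.DataFrame,
    novel: pd.DataFrame,
    libs: list[str],
    library_totals: pd.Series,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Count matrix, tissue partition and differential-expression table for
    the identified miRNAs."""
    cfg = config or RunConfig()
    frames = []
    for df in (known, novel):
        if df is not None and not df.empty:
            frames.append(df.set_index("name")[libs])
    if not frames:
        raise StageError("expression", "no miRNAs identified")
    counts = pd.concat(frames)
    counts = counts.groupby(level=0).sum()
    partition = tissue_partition(counts, cfg.presence_threshold)
    de = differential_expression(
        counts,
        library_totals=library_totals,
        alpha=cfg.alpha,
        z_threshold=cfg.z_threshold,
    )
    return counts, partition, de


# ---------------------------------------------------------------------------
# degradome stage


def degradome_stage(
    reads: list[str],
    transcripts: dict[str, str],
    mirnas: dict[str, str],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, deg.TPlot]]:
    """Gate/trim degradome reads, build T-plots, and call target sites for
    every supplied miRNA sequence."""
    cfg = config or RunConfig()
    tags = deg.gate_and_trim(
        reads, cfg.degradome_adaptor, cfg.degradome_tag_len
    )
    tplots = deg.build_tplots(tags, transcripts)
    rows = []
    for mname, mseq in mirnas.items():
        for tname, tseq in transcripts.items():
            for site in deg.find_sites(
                mname, mseq, tname, tseq, tplots[tname], cfg.score_cutoff
            ):
                rows.append(
                    {
                        "mirna": site.mirna,
                        "transcript": site.transcript,
                        "cleavage_position": site.cleavage_position,
                        "score": site.score,
                        "category": site.category,
                        "peak_count": site.peak_count,
                        "transcript_max": site.transcript_max,
                        "transcript_median": site.transcript_median,
                        "alignment": site.alignment,
                    }
                )
    sites = pd.DataFrame(rows)
    if not sites.empty:
        sites = sites.sort_values(
            ["mirna", "transcript", "cleavage_position"], kind="stable"
        ).reset_index(drop=True)
    return sites, tplots


# ---------------------------------------------------------------------------
# file-driven run


def _read_fastq(path) -> list[str]:
    from Bio import SeqIO

    return [str(r.seq) for r in SeqIO.parse(str(path), "fastq")]


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def run_all(config: RunConfig) -> dict:
    """Execute every configured stage and write a run report.

    Returns a summary dict (also serialized to ``report.md`` and TSVs under
    ``config.outdir``).  Raises :class:`StageError` naming the failing
    stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    summary: dict = {}

    # --- preprocess
    if not config.srna_fastqs:
        raise StageError("preprocess", "no small-RNA FASTQ inputs configured")
    libraries = {}
    for tissue, path in config.srna_fastqs.items():
        reads = _read_fastq(path)
        if not reads:
            raise StageError("preprocess", f"empty FASTQ for {tissue}: {path}")
        libraries[tissue] = reads
    references = {}
    if config.contaminants_dir:
        for fa in sorted(Path(config.contaminants_dir).glob("*.fa")):
            references[fa.stem] = list(_read_fasta(fa).values())
    tags, report = run_preprocess(
        libraries,
        references,
        adapter3=config.adapter3,
        min_overlap=config.min_adapter_overlap,
        junk_rules=config.junk,
        min_len=config.min_tag_len,
        max_len=config.max_tag_len,
    )
    report.to_csv(out / "filter_report.tsv", sep="\t")
    clean = [t for t in tags if t.annotation == "clean"]
    libs = sorted(libraries)
    tag_df = pd.DataFrame(
        [
            {
                "sequence": t.sequence,
                "annotation": t.annotation,
                **{lib: t.counts.get(lib, 0) for lib in libs},
            }
            for t in tags
        ]
    )
    tag_df.to_csv(out / "unique_tags.tsv", sep="\t", index=False)
    summary["filter_report"] = report
    summary["n_clean_tags"] = len(clean)

    # --- identify
    with open(out / "clean_tags.fa", "w") as fh:
        for i, t in enumerate(clean):
            fh.write(f">tag{i + 1}_{t.total}\n{t.sequence}\n")
    matures = _read_fasta(config.mature_fa) if config.mature_fa else {}
    precursors = _read_fasta(config.hairpin_fa) if config.hairpin_fa else None
    genome = _read_fasta(config.genome_fa) if config.genome_fa else None
    known, novel, _records = identify_stage(
        clean, matures, precursors, genome, config,
        _read_fasta(config.other_mature_fa) if config.other_mature_fa else None,
        _read_fasta(config.other_hairpin_fa) if config.other_hairpin_fa else None,
    )
    known.to_csv(out / "known_mirnas.tsv", sep="\t", index=False)
    novel.to_csv(out / "novel_mirnas.tsv", sep="\t", index=False)
    with open(out / "novel_precursors.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in novel.iterrows():
            fh.write(
                f"{r['contig']}\tmirforge\tpre_miRNA\t{r['start']}\t{r['end']}"
                f"\t.\t{r['strand']}\t.\tID={r['name']}\n"
            )
    summary["n_known"] = len(known)
    summary["n_novel"] = len(novel)

    # --- expression
    library_totals = pd.Series(
        {lib: report.loc["Clean reads", (lib, "total")] for lib in libs},
        dtype=float,
    )
    counts, partition, de = expression_stage(
        known, novel, libs, library_totals, config
    )
    counts.to_csv(out / "counts.tsv", sep="\t")
    partition.rename("tissues").to_csv(out / "tissue_partition.tsv", sep="\t")
    de.to_csv(out / "differential_expression.tsv", sep="\t")
    summary["partition"] = partition.value_counts().to_dict()
    up_down = {
        lib: {
            "up": int((de[f"call_{lib}"] == "up").sum()),
            "down": int((de[f"call_{lib}"] == "down").sum()),
        }
        for lib in libs
    }
    summary["de_calls"] = up_down

    # --- degradome
    sites = pd.DataFrame()
    if config.degradome_fastq and config.transcripts_fa:
        deg_reads = _read_fastq(config.degradome_fastq)
        transcripts = _read_fasta(config.transcripts_fa)
        mirna_seqs = {}
        for _, row in known.iterrows():
            mirna_seqs.setdefault(row["name"], row["sequence"])
        for _, row in novel.iterrows():
            mirna_seqs.setdefault(row["name"], row["sequence"])
        sites, tplots = degradome_stage(deg_reads, transcripts, mirna_seqs, config)
        sites.to_csv(out / "target_sites.tsv", sep="\t", index=False)
        tdir = out / "tplots"
        tdir.mkdir(exist_ok=True)
        if not sites.empty:
            from .degradome import render_tplot

            for tname in sorted(set(sites["transcript"]))[:12]:
                render_tplot(tplots[tname], path=tdir / f"{tname}.svg")
        summary["n_target_sites"] = len(sites)
        summary["category_counts"] = (
            sites["category"].value_counts().sort_index().to_dict()
            if not sites.empty
            else {}
        )

    # --- qPCR
    if config.qpcr_ct:
        ct = pd.read_csv(config.qpcr_ct, sep="\t")
        rel = delta_delta_ct(ct, config.qpcr_calibrator)
        rel.to_csv(out / "qpcr_relative_expression.tsv", sep="\t", index=False)
        summary["n_qpcr_genes"] = rel["gene"].nunique()

    _write_report(out, config, summary, known, novel, partition, de, sites)
    return summary



def _write_report(out, config, summary, known, novel, partition, de, sites):
    lines = ["# forge run report", ""]
    lines.append("## Filter cascade")
    lines.append("")
    lines.append(summary["filter_report"].to_markdown())
    lines.append("")
    lines.append(f"Clean unique tags: {summary['n_clean_tags']}")
    lines.append("")
    lines.append("## miRNA identification")
    lines.append("")
    lines.append(
        f"Known miRNA tags: {summary['n_known']}; novel precursors: "
        f"{summary['n_novel']}"
    )
    lines.append("")
    lines.append("## Tissue partition")
    lines.append("")
    for k, v in sorted(summary["partition"].items()):
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append("## Differential expression (p <= %g, |Z| > %g)" % (
        config.alpha, config.z_threshold))
    lines.append("")
    for lib, d in summary["de_calls"].items():
        lines.append(f"- {lib}: {d['up']} up, {d['down']} down")
    if "n_target_sites" in summary:
        lines.append("")
        lines.append("## Degradome targets")
        lines.append("")
        lines.append(f"Sites: {summary['n_target_sites']}")
        lines.append(f"Category counts: {summary.get('category_counts', {})}")
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    digest = hashlib.sha256(text.encode()).hexdigest()
    (out / "report.md.sha256").write_text(digest + "\n")
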