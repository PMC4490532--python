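"""End-to-end driver: simulate/load -> preprocess -> map -> scan -> call -> report.

One configuration mapping covers every stage parameter; outputs are
plain TSV/JSON files with stable ordering, so a fixed seed yields
byte-identical runs. Any stage failure aborts with the stage name and
cause.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__, align, cleavage, precursor, preprocess, profiles, report
from ._seq import MatureMiRNA, parse_mirna_fasta, read_fasta
from .synthetic import SimConfig, simulate

DEFAULTS: dict[str, Any] = {
    "simulate": False,
    "seed": 0,
    "adapter": None,  # falls back to the simulator default
    "min_len": preprocess.DEFAULT_MIN_LEN,
    "max_len": preprocess.DEFAULT_MAX_LEN,
    "min_overlap": preprocess.DEFAULT_MIN_OVERLAP,
    "max_score": align.DEFAULT_MAX_SCORE,
    "window": cleavage.DEFAULT_WINDOW,
    "fractional": False,
    "plot": False,
    "reads": None,
    "transcripts": None,
    "mirnas": None,
    "hairpins": None,
    "ncrna": None,
    "sim": {},
}


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


def _stage(log: logging.Logger, name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Execute all stages and write the artifact directory; returns its path."""
    cfg = {**DEFAULTS, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("degracall")
    log.setLevel(logging.INFO)
    log.handlers = [logging.FileHandler(outdir / "run.log", mode="w")]
    log.handlers[0].setFormatter(logging.Formatter("%(asctime)s %(message)s"))

    sim_result = None
    with _stage(log, "simulate"):
        if cfg["simulate"]:
            sim_cfg = SimConfig(**{"seed": cfg["seed"], **cfg["sim"]})
            sim_result = simulate(sim_cfg, outdir / "sim")
            cfg["reads"] = str(
                sim_result.outdir / f"reads.{ 'fastq' if sim_cfg.read_format == 'fastq' else 'fasta'}"
            )
            cfg["transcripts"] = str(sim_result.outdir / "transcripts.fasta")
            cfg["mirnas"] = str(sim_result.outdir / "mirnas.fasta")
            cfg["hairpins"] = str(sim_result.outdir / "hairpins.fasta")
            cfg["ncrna"] = str(sim_result.outdir / "ncrna.fasta")
            if cfg["adapter"] is None:
                cfg["adapter"] = sim_cfg.adapter

    with _stage(log, "load-inputs"):
        for key in ("reads", "transcripts", "mirnas"):
            if not cfg[key] or not Path(cfg[key]).exists():
                raise FileNotFoundError(f"required input '{key}' missing: {cfg[key]!r}")
        transcripts = {rid: seq for rid, _, seq in read_fasta(cfg["transcripts"])}
        catalog: list[MatureMiRNA] = parse_mirna_fasta(cfg["mirnas"])
        hairpins = (
            {rid: seq for rid, _, seq in read_fasta(cfg["hairpins"])}
            if cfg["hairpins"] and Path(cfg["hairpins"]).exists()
            else {}
        )
        hairpin_families = {}
        if cfg["hairpins"] and Path(cfg["hairpins"]).exists():
            for rid, desc, _ in read_fasta(cfg["hairpins"]):
                for token in desc.split():
                    if token.startswith("family="):
                        hairpin_families[rid] = token.split("=", 1)[1]
        ncrna = (
            {rid: seq for rid, _, seq in read_fasta(cfg["ncrna"])}
            if cfg["ncrna"] and Path(cfg["ncrna"]).exists()
            else {}
        )
        if cfg["adapter"] is None:
            raise ValueError("adapter sequence not configured")

    with _stage(log, "preprocess"):
        tags, stats = preprocess.preprocess_file(
            cfg["reads"],
            cfg["adapter"],
            ncrna,
            min_len=cfg["min_len"],
            max_len=cfg["max_len"],
            min_overlap=cfg["min_overlap"],
        )
        preprocess.write_tags(tags, outdir / "tags.tsv")
        hist_rows = [
            (k, c, f) for k, (c, f) in sorted(stats.length_histogram.items())
        ]
        pd.DataFrame(hist_rows, columns=["length", "reads", "fraction"]).to_csv(
            outdir / "length_histogram.tsv", sep="\t", index=False
        )

    with _stage(log, "mapping"):
        hits, unannotated = profiles.map_tags(tags, transcripts, fractional=cfg["fractional"])
        stats.unannotated = unannotated
        (outdir / "stats.json").write_text(json.dumps(stats.as_dict(), indent=2) + "\n")
        profs = profiles.build_profiles(hits)
        profiles.hits_frame(hits).to_csv(outdir / "hits.tsv", sep="\t", index=False)
        profiles.profiles_frame(profs).to_csv(outdir / "profiles.tsv", sep="\t", index=False)

    with _stage(log, "scan"):
        alignments = align.scan_catalog(catalog, transcripts, max_score=cfg["max_score"])
        pd.DataFrame(
            [
                (
                    a.mirna_id,
                    a.transcript_id,
                    a.site_start,
                    a.site_end,
                    a.score,
                    a.canonical_cleavage,
                    a.pairing_string,
                )
                for a in alignments
            ],
            columns=[
                "mirna_id",
                "transcript_id",
                "site_start",
                "site_end",
                "score",
                "canonical_cleavage",
                "pairing",
            ],
        ).to_csv(outdir / "alignments.tsv", sep="\t", index=False)

    with _stage(log, "call"):
        calls = cleavage.call_cleavages(alignments, profs, window=cfg["window"])
        cleavage.calls_frame(calls).to_csv(outdir / "calls.tsv", sep="\t", index=False)
        tplot_dir = outdir / "tplots"
        tplot_dir.mkdir(exist_ok=True)
        called_tids = sorted({c.transcript_id for c in calls})
        for tid in called_tids:
            table = cleavage.tplot_table(profs[tid], calls)
            table.to_csv(tplot_dir / f"{tid}.tsv", sep="\t", index=False)
            if cfg["plot"]:
                cleavage.tplot_figure(profs[tid], calls, tplot_dir / f"{tid}.png")

    with _stage(log, "precursor-scan"):
        precursor_calls: list[cleavage.CleavageCall] = []
        if hairpins:
            queries = precursor.product_queries(tags, catalog)
            products = precursor.locate_products(queries, hairpins)
            precursor.products_frame(products).to_csv(
                outdir / "precursor_products.tsv", sep="\t", index=False
            )
            precursor_calls = precursor.precursor_self_targets(
                catalog, hairpins, tags, max_score=cfg["max_score"], window=cfg["window"]
            )
            cleavage.calls_frame(precursor_calls).to_csv(
                outdir / "precursor_calls.tsv", sep="\t", index=False
            )
            loops = precursor.detect_feedback_loops(
                precursor_calls, catalog, precursor_families=hairpin_families
            )
            precursor.loops_frame(loops).to_csv(
                outdir / "feedback_loops.tsv", sep="\t", index=False
            )
            pairs = precursor.functional_star_pairs(calls + precursor_calls, catalog)
            precursor.star_pairs_frame(pairs).to_csv(
                outdir / "star_pairs.tsv", sep="\t", index=False
            )

    with _stage(log, "census"):
        class_of = {m.id: m.mclass for m in catalog}
        censuses = report.category_census(calls + precursor_calls, class_of)
        report.census_frame(censuses).to_csv(outdir / "census.tsv", sep="\t", index=False)
        tallies, summary = report.targets_per_mirna(calls + precursor_calls, class_of)
        report.tallies_frame(tallies).to_csv(outdir / "tallies.tsv", sep="\t", index=False)

    manifest = {
        "degracall_version": __version__,
        "seed": cfg["seed"],
        "config_hash": _config_hash(cfg),
        "config": {k: v for k, v in cfg.items() if k != "sim"} | {"sim": dict(cfg["sim"])},
        "n_tags": len(tags),
        "n_alignments": len(alignments),
        "n_calls": len(calls),
        "n_precursor_calls": len(precursor_calls),
        "targets_summary": summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    logging.shutdown()
    return outdir
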