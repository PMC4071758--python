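"""End-to-end orchestration: classify -> orf -> nmd -> project -> conserve -> losses.

One :class:`RunConfig` drives the whole run.  Outputs are deterministic:
TSVs carry no timestamps, the run log records the package version and a
hash of the configuration, and re-running on identical inputs produces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gene_model_io import (
    ConsistencyError,
    GeneModel,
    SpeciesTree,
    SpliceFateError,
    ValidationError,
    load_gene_model,
    load_transcript_chains,
    write_reports,
)
from .intron_projection import losses_for_matrix, map_to_alignment, project_gene
from .orf_ptc import analyze_orf, annotate_nmd_features
from .splice_classification import (
    TranscriptForm,
    assign_form_names,
    classify_form,
    compare_tissues,
    tally_events,
)

logger = logging.getLogger("splicefate")


class ConfigError(SpliceFateError, ValueError):
    """The run configuration is incomplete or inconsistent."""


class StageError(SpliceFateError, RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, thresholds and seed for one pipeline run."""

    gff3: str
    fasta: str
    gene_id: str
    out_dir: str
    forms: str | None = None
    msa: str | None = None
    tree: str | None = None
    long_3utr: int = 350
    min_intron: int = 20
    k_conserved: int | None = None
    seed: int = 0
    conserve: bool = False
    extra_genes: list[dict] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        missing = [f for f in ("gff3", "fasta", "gene_id", "out_dir") if f not in raw]
        if missing:
            raise ConfigError(f"missing config fields: {missing}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("gff3", "fasta", "forms", "msa", "tree"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise ConfigError(f"config field {name!r}: path {val} does not exist")
        if self.conserve and (self.msa is None or self.tree is None):
            missing = "msa" if self.msa is None else "tree"
            raise ConfigError(f"conserve stage requested but config field {missing!r} is unset")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SpliceFateError as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@dataclass
class RunResult:
    forms: list[TranscriptForm]
    orf_reports: dict
    nmd_reports: dict
    tally: object
    tissue_partition: dict
    matrix: object | None
    losses: dict | None
    out_files: dict[str, Path]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis described by *config*.

    Stages: load the gene model; classify each observed form (the canonical
    chain is always included as the alpha form); translate and flag each
    form; optionally project introns of this and any extra genes through an
    MSA, mark conserved classes and infer Dollo losses; write TSV reports
    and a run log.  Any stage failure aborts with the stage name.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model = _stage("load")(load_gene_model)(
        config.gff3, config.fasta, config.gene_id, min_intron_len=config.min_intron
    )

    @_stage("classify")
    def _classify() -> list[TranscriptForm]:
        forms = [
            TranscriptForm(gene_id=model.gene_id, chain=list(model.exons),
                           tissues=frozenset(), provenance="observed")
        ]
        if config.forms:
            for mrna_id, chain, tissues in load_transcript_chains(config.forms, model):
                events = classify_form(model, chain)
                forms.append(
                    TranscriptForm(
                        gene_id=model.gene_id, chain=chain, events=events, tissues=tissues
                    )
                )
        return assign_form_names(forms)

    named = _classify()
    tally = tally_events(named)
    partition = compare_tissues([f for f in named if f.tissues or f.is_canonical])

    @_stage("orf")
    def _orf():
        orf_reports = {}
        nmd_reports = {}
        for f in named:
            rep = analyze_orf(model, f)
            orf_reports[f.form_name] = rep
            nmd_reports[f.form_name] = annotate_nmd_features(
                model, f, rep, long_3utr_threshold=config.long_3utr
            )
        return orf_reports, nmd_reports

    orf_reports, nmd_reports = _orf()

    matrix = None
    losses = None
    if config.conserve:

        @_stage("conserve")
        def _conserve():
            models: dict[str, GeneModel] = {model.gene_id: model}
            for extra in config.extra_genes:
                m = load_gene_model(
                    extra["gff3"], extra["fasta"], extra["gene_id"],
                    min_intron_len=config.min_intron,
                )
                models[m.gene_id] = m
            msa = _read_aligned_fasta(config.msa)
            projections = {g: project_gene(m) for g, m in models.items()}
            matrix = map_to_alignment(msa, projections, k=config.k_conserved, models=models)
            tree = SpeciesTree.from_file(config.tree)
            return matrix, losses_for_matrix(matrix, tree)

        matrix, losses = _conserve()

    @_stage("report")
    def _report():
        files = write_reports(named, orf_reports, matrix, out_dir)
        nmd_rows = [
            {
                "form": name,
                "uorf_count": r.uorf_count,
                "utr3_len": r.utr3_len,
                "long_3utr": r.long_3utr,
                "intron_in_3utr": r.intron_in_3utr,
            }
            for name, r in sorted(nmd_reports.items())
        ]
        nmd_path = out_dir / "nmd_features.tsv"
        pd.DataFrame(nmd_rows).to_csv(nmd_path, sep="\t", index=False)
        files["nmd"] = nmd_path
        if losses is not None:
            loss_rows = [
                {"class": f"c{col + 1}.{ph}", "branch": ev.branch,
                 "terminal": ev.terminal}
                for (col, ph), evs in sorted(losses.items())
                for ev in evs
            ]
            loss_path = out_dir / "losses.tsv"
            pd.DataFrame(loss_rows, columns=["class", "branch", "terminal"]).to_csv(
                loss_path, sep="\t", index=False
            )
            files["losses"] = loss_path
        return files

    files = _report()

    config_text = yaml.safe_dump(
        {k: getattr(config, k) for k in config.__dataclass_fields__}, sort_keys=True
    )
    (out_dir / "config.yaml").write_text(config_text)
    log_lines = [
        f"splicefate {__version__}",
        f"config_sha256 {hashlib.sha256(config_text.encode()).hexdigest()}",
        f"gene {model.gene_id} exons {len(model.exons)} forms {len(named)}",
        f"noncanonical {tally.total_noncanonical}",
    ]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("run complete: %s", out_dir)

    return RunResult(named, orf_reports, nmd_reports, tally, partition, matrix, losses, files)


def _read_aligned_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    with open(path) as fh:
        msa = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    lengths = {len(s) for s in msa.values()}
    if len(lengths) > 1:
        raise ConsistencyError(f"aligned FASTA {path} rows differ in length")
    if not msa:
        raise ValidationError(f"aligned FASTA {path} is empty")
    return msa


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
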