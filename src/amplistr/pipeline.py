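"""End-to-end pipeline: FASTQ per sample -> genotypes, cohort and linkage reports.

The pipeline is a pure function of (config, inputs, seed): re-running with
the same inputs produces identical tables.  Every output table carries a
comment header naming the parameters that produced it, and a JSON manifest
records versions, parameters and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import (
    CallerParams,
    NoCallError,
    SampleGenotype,
    build_histogram,
    call_modes,
    genotypes_to_frame,
    phase_and_refine,
)
from .counting import CounterParams, observations_to_frame, observe_reads
from .haplotypes import extract_haplotypes, tabulate_linkage
from .locus import RepeatLocus, default_ctg18_locus, load_locus
from .readqc import QcThresholds, filter_reads, read_fastq
from .stats import summarize_cohort

__all__ = ["PipelineConfig", "run_pipeline", "genotype_sample"]


@dataclass(frozen=True)
class PipelineConfig:
    locus_path: str | None = None  # None -> built-in synthetic CTG18.1 locus
    qc: QcThresholds = field(default_factory=QcThresholds)
    counter: CounterParams = field(default_factory=CounterParams)
    caller: CallerParams = field(default_factory=CallerParams)
    population_counts: dict[str, int] | None = None
    seed: int = 0

    def load_locus(self) -> RepeatLocus:
        if self.locus_path is None:
            return default_ctg18_locus()
        return load_locus(self.locus_path)

    def describe(self) -> dict:
        return {
            "locus": self.locus_path or "<built-in CTG18.1 (synthetic flanks)>",
            "qc": dataclasses.asdict(self.qc),
            "counter": dataclasses.asdict(self.counter),
            "caller": dataclasses.asdict(self.caller),
            "seed": self.seed,
        }


def _param_header(config: PipelineConfig) -> str:
    return "# amplistr " + __version__ + " " + json.dumps(config.describe(), sort_keys=True)


def _write_table(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_param_header(config) + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def genotype_sample(
    fastq_path: str | Path,
    locus: RepeatLocus,
    config: PipelineConfig,
    sample_id: str | None = None,
    out_dir: Path | None = None,
) -> SampleGenotype | None:
    """QC, count and call one sample; optionally write its per-sample tables.

    Returns None (after writing whatever is writable) when no allele
    survives the depth gate.
    """
    fastq_path = Path(fastq_path)
    if sample_id is None:
        sample_id = fastq_path.name.split(".")[0]
    reads = read_fastq(fastq_path)
    kept, qc_summary = filter_reads(reads, config.qc)
    observations = observe_reads(kept, locus, config.counter)
    histogram = build_histogram(observations, config.caller.artefact_floor)
    if out_dir is not None:
        _write_table(
            observations_to_frame(observations, locus),
            out_dir / f"{sample_id}.reads.tsv",
            config,
        )
        _write_table(histogram.to_frame(), out_dir / f"{sample_id}.histogram.tsv", config)
        qc_summary.to_json(out_dir / f"{sample_id}.qc.json")
    try:
        modes = call_modes(histogram, config.caller)
        return phase_and_refine(observations, modes, locus, sample_id, config.caller)
    except NoCallError:
        return None


def run_pipeline(
    config: PipelineConfig,
    case_fastqs: dict[str, str | Path],
    control_fastqs: dict[str, str | Path] | None = None,
    out_dir: str | Path = "amplistr_out",
) -> Path:
    """Run QC -> counting -> calling per sample, then cohort/linkage reports.

    ``case_fastqs``/``control_fastqs`` map sample_id -> FASTQ path.  Outputs
    land in ``out_dir``: per-sample reads/histogram tables, a genotype table
    per arm, a cohort report, a linkage table when population counts are
    configured, and a run manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    control_fastqs = control_fastqs or {}
    for sid, path in {**case_fastqs, **control_fastqs}.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"sample {sid!r}: FASTQ not found at {path}")
    locus = config.load_locus()

    arms: dict[str, list[SampleGenotype]] = {"cases": [], "controls": []}
    no_calls: list[str] = []
    for arm, fastqs in (("cases", case_fastqs), ("controls", control_fastqs)):
        for sid, path in fastqs.items():
            genotype = genotype_sample(path, locus, config, sid, out)
            if genotype is None:
                no_calls.append(sid)
            else:
                arms[arm].append(genotype)

    for arm, genotypes in arms.items():
        if genotypes:
            _write_table(genotypes_to_frame(genotypes), out / f"genotypes_{arm}.tsv", config)

    report = summarize_cohort(arms["cases"], arms["controls"])
    with open(out / "cohort_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")

    if config.population_counts:
        haplotypes = extract_haplotypes(arms["cases"])
        linkage = tabulate_linkage(haplotypes, config.population_counts)
        _write_table(linkage.to_frame(), out / "linkage.tsv", config)

    manifest = {
        "amplistr_version": __version__,
        "parameters": config.describe(),
        "inputs": {
            sid: _sha256(Path(path))
            for sid, path in {**case_fastqs, **control_fastqs}.items()
        },
        "no_calls": no_calls,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
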