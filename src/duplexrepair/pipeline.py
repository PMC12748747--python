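"""End-to-end pipeline orchestration and structured run logging."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from . import __version__
from .config import RunConfig
from .duplex import (
    DuplexCall,
    FilterParams,
    preference_ratio,
    reconstruct_molecules,
    summarize,
)
from .io import load_substrate, read_fastq, write_json, write_table
from .quant import (
    DpcrCounts,
    both_joined_fraction,
    fraction_rna,
    load_dpcr_csv,
    load_qpcr_csv,
    relative_abundance,
)
from .readproc import AdapterSpec, AnnotatedRead, annotate_reads
from .simulate import (
    molecule_truth_table,
    simulate_repair,
    synthesize_reads,
)
from .substrate import (
    ExpectedProductSet,
    SubstrateSpec,
    demo_substrate,
    demo_substrate_names,
    enumerate_expected_products,
    substrate_to_mapping,
    validate_substrate,
)


class PipelineError(RuntimeError):
    pass


class RunLog:
    """JSON-lines event log; every threshold and count ends up here."""

    def __init__(self, path: Optional[Path] = None):
        self.path = path
        self.events: List[Dict] = []

    def record(self, stage: str, **payload) -> None:
        event = {"stage": stage, **payload}
        self.events.append(event)
        if self.path is not None:
            with open(self.path, "a") as handle:
                handle.write(json.dumps(event, sort_keys=True) + "\n")


def resolve_substrate(name_or_path: str) -> SubstrateSpec:
    if name_or_path in demo_substrate_names():
        return demo_substrate(name_or_path)
    return load_substrate(name_or_path)


def annotated_to_frame(annotated: Iterable[AnnotatedRead]) -> pd.DataFrame:
    return pd.DataFrame(annotated, columns=AnnotatedRead._fields)


def calls_to_frame(calls: Iterable[DuplexCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "umi": c.umi,
                "top_label": c.top_label,
                "bottom_label": c.bottom_label,
                "molecule_class": c.molecule_class,
                "path": c.path,
            }
            for c in calls
        ]
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Identical config (including seed) reproduces byte-identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.jsonl"
    log_path.unlink(missing_ok=True)
    log = RunLog(log_path)
    write_json(config.as_dict(), outdir / "config.json")
    log.record("start", version=__version__, seed=config.seed, mode=config.mode)

    spec = resolve_substrate(config.substrate)
    report = validate_substrate(spec, require_full_mismatch=False)
    if report:
        raise PipelineError("invalid substrate:\n  " + "\n  ".join(report))
    products = enumerate_expected_products(
        spec, config.insertion_labels, config.window
    )
    write_json(
        {
            "substrate": substrate_to_mapping(spec),
            "windows": products.windows,
            "degenerate_pairs": {
                k: [list(p) for p in v] for k, v in products.degenerate_pairs.items()
            },
        },
        outdir / "products.json",
    )

    records = None
    if config.mode in ("simulate", "all"):
        records = _stage_simulate(config, spec, products, outdir, log)
    if config.mode in ("analyze", "all"):
        if records is None:
            fastq = config.fastq or outdir / "reads.fastq"
            records = list(read_fastq(fastq))
            if not records:
                raise PipelineError(f"no reads in {fastq}")
        _stage_analyze(config, spec, products, records, outdir, log)
    if config.mode in ("quantify", "all") and (config.qpcr_csv or config.dpcr_csv):
        _stage_quantify(config, outdir, log)

    log.record("done")
    return outdir


def _stage_simulate(config, spec, products, outdir: Path, log: RunLog,
                    ) -> List[Tuple[str, str, str]]:
    states = simulate_repair(
        spec, config.kinetics(), config.n_molecules, config.harvest_time,
        config.seed,
    )
    molecule_truth_table(states).to_csv(
        outdir / "molecule_truth.tsv", sep="\t", index=False
    )
    with open(outdir / "reads.fastq", "w") as handle:
        records, truth = synthesize_reads(
            states,
            spec,
            products,
            umi_length=config.umi_length,
            oversampling_mean=config.oversampling_mean,
            error_rate=config.error_rate,
            barcode=config.barcode,
            sample=config.sample,
            max_phasing=config.max_phasing,
            seed=config.seed,
            fastq_out=handle,
            keep_records=True,
        )
    truth.to_tsv(outdir / "read_truth.tsv")
    log.record(
        "simulate",
        n_molecules=config.n_molecules,
        n_reads=len(records),
        harvest_time=config.harvest_time,
    )
    return records


def _stage_analyze(config, spec, products, records, outdir: Path, log: RunLog,
                   ) -> None:
    if not records:
        raise PipelineError("no reads")
    barcode_table = {config.sample: config.barcode}
    adapter = AdapterSpec(umi_length=config.umi_length)
    annotated, stats = annotate_reads(
        records, spec, products, barcode_table,
        adapter=adapter, max_edit=config.max_edit,
        max_phasing=config.max_phasing,
    )
    annotated_to_frame(annotated).to_csv(
        outdir / "annotated_reads.tsv", sep="\t", index=False
    )
    log.record("annotate", **stats.as_dict())

    params = config.filter_params()
    calls, duplex_log = reconstruct_molecules(
        annotated, products, params, total_reads=stats.n_input,
        umi_clustering=config.umi_clustering,
    )
    write_table(calls_to_frame(calls), outdir / "duplex_calls.tsv")
    log.record("reconstruct", **duplex_log)

    if calls:
        summary = summarize(calls, sample=config.sample,
                            timepoint=config.timepoint)
        payload = summary.as_dict()
        if summary.class_counts.get("both_joined", 0):
            ratio = preference_ratio(summary)
            payload["preference_ratio"] = {
                "model1_to_model2": ratio.model1_to_model2,
                "model2_to_model1": ratio.model2_to_model1,
                "n_model1": ratio.n_model1,
                "n_model2": ratio.n_model2,
                "n_indeterminate": ratio.n_indeterminate,
                "zero_denominator": ratio.zero_denominator,
            }
        write_json(payload, outdir / "summary.json")
        class_rows = pd.DataFrame(
            [
                {"molecule_class": k, "count": v,
                 "frequency": summary.class_frequencies[k]}
                for k, v in summary.class_counts.items()
            ]
        )
        write_table(class_rows, outdir / "summary.tsv")
    log.record("analyze_done")


def _stage_quantify(config, outdir: Path, log: RunLog) -> None:
    if config.qpcr_csv:
        frame = load_qpcr_csv(config.qpcr_csv)
        rows = []
        mock = frame[frame.treatment == "mock"]
        alkali = frame[frame.treatment == "alkali"]
        paired = mock.merge(
            alkali, on=["sample", "target", "strand"], suffixes=("_mock", "_alkali")
        )
        for row in paired.itertuples(index=False):
            rows.append({
                "sample": row.sample,
                "target": row.target,
                "strand": row.strand,
                "fraction_rna": fraction_rna(row.ct_mock, row.ct_alkali),
            })
        untreated = frame[frame.treatment == "none"]
        if len(untreated):
            ref = untreated.iloc[0]
            for row in untreated.itertuples(index=False):
                rows.append({
                    "sample": row.sample,
                    "target": row.target,
                    "strand": row.strand,
                    "relative_abundance": relative_abundance(
                        row.ct, row.spike_ct, ref.ct, ref.spike_ct
                    ),
                })
        write_table(pd.DataFrame(rows), outdir / "qpcr_quant.tsv")
        log.record("quantify_qpcr", n_rows=len(rows))
    if config.dpcr_csv:
        frame = load_dpcr_csv(config.dpcr_csv)
        rows = []
        for (sample, target), group in frame.groupby(["sample", "target"]):
            by_strand = {}
            for row in group.itertuples(index=False):
                by_strand[getattr(row, "strand", target)] = DpcrCounts(
                    int(row.positives), int(row.total)
                )
            if {"top", "bottom"} <= set(by_strand):
                ratio = both_joined_fraction(by_strand["bottom"], by_strand["top"])
                rows.append({
                    "sample": sample,
                    "target": target,
                    "bottom_to_top": ratio.ratio,
                    "flagged": ratio.flagged,
                })
        write_table(pd.DataFrame(rows), outdir / "dpcr_ratios.tsv")
        log.record("quantify_dpcr", n_rows=len(rows))
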