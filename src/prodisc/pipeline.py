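"""End-to-end orchestration: batch screen -> classification ->
discriminability -> characteristic proteins -> cross-cancer -> CES.

All tabular outputs are TSVs whose first line is a comment carrying the
run-manifest hash, so every file can be traced to the exact configuration
and seed that produced it.  Re-running with an identical config reproduces
every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import batch as batch_mod
from . import classify as classify_mod
from .core_data import (
    AlignedData,
    align_cases,
    read_annotations,
    read_class_assignment,
    read_cna_table,
    read_mutation_table,
    read_protein_matrix,
)
from .crosscancer import CesReport, ces, cross_cancer_table, find_cross_cancer_effects
from .discriminability import results_table, run_subtests
from .neighbors import neighbor_consistency


@dataclass
class RunConfig:
    matrix_path: str
    annotations_path: str
    mutations_path: str | None = None
    cna_path: str | None = None
    class_table_path: str | None = None
    classification: str = "gcr"  # gcr | nearest-neighbor | table
    screen_batches: bool = False
    dsc_threshold: float = batch_mod.DSC_THRESHOLD
    p_threshold: float = batch_mod.P_THRESHOLD
    min_group: int = 5
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"

    def manifest(self) -> dict:
        return dataclasses.asdict(self)

    def manifest_hash(self) -> str:
        # hash the analytic configuration; where the outputs land is not
        # part of what they contain
        manifest = {k: v for k, v in self.manifest().items() if k != "out_dir"}
        blob = json.dumps(manifest, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    aligned: AlignedData
    batch_report: batch_mod.BatchScreenReport | None
    assignment: classify_mod.ClassAssignment
    subtests: list
    cross_cancer: list
    ces_report: CesReport
    consistency: dict = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest={manifest_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_full_analysis(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mhash = config.manifest_hash()
    with open(out / "manifest.json", "w") as fh:
        json.dump({"hash": mhash, "config": config.manifest()}, fh, indent=2)

    matrix = read_protein_matrix(config.matrix_path)
    annotations = read_annotations(config.annotations_path)
    # A MAF-like table lists mutated cases only; annotated cases without
    # records are wild-type, not missing, so the annotation case list is
    # taken as the mutation-assayed universe.
    mutations = (
        read_mutation_table(config.mutations_path, case_ids=annotations.case_ids)
        if config.mutations_path
        else None
    )
    cna = read_cna_table(config.cna_path) if config.cna_path else None
    aligned = align_cases(matrix, annotations, mutations, cna)

    batch_report = None
    if config.screen_batches:
        batch_report = batch_mod.screen_batches(
            aligned.matrix,
            aligned.annotations,
            dsc_threshold=config.dsc_threshold,
            p_threshold=config.p_threshold,
            seed=config.seed,
        )
        kept = batch_report.kept_cases(aligned.annotations)
        aligned = align_cases(
            aligned.matrix.subset_cases(kept),
            aligned.annotations.subset_cases(kept),
            aligned.mutations,
            aligned.cna,
        )
        _write_tsv(batch_report.trace_table(), out / "batch_trace.tsv", mhash)

    if config.classification == "gcr":
        if aligned.mutations is None:
            raise ValueError("gcr classification requires a mutation table")
        assignment = classify_mod.gcr_classify(aligned.mutations)
    elif config.classification == "nearest-neighbor":
        if aligned.mutations is None:
            raise ValueError("nearest-neighbor classification requires mutations")
        assignment = classify_mod.nearest_neighbor_classify(
            aligned.mutations, aligned.annotations
        )
    elif config.classification == "table":
        if not config.class_table_path:
            raise ValueError("classification 'table' needs class_table_path")
        assignment = read_class_assignment(config.class_table_path)
        assignment = assignment.subset_cases(aligned.case_ids)
    else:
        raise ValueError(f"unknown classification {config.classification!r}")

    from .core_data import write_class_assignment

    write_class_assignment(assignment, out / "class_assignment.tsv")

    subtests = run_subtests(
        aligned.matrix,
        assignment,
        aligned.annotations,
        n_perm=config.n_perm,
        min_group=config.min_group,
        alpha=config.alpha,
        seed=config.seed,
    )
    _write_tsv(results_table(subtests), out / "subtests.tsv", mhash)

    candidates = find_cross_cancer_effects(subtests, alpha=config.alpha)
    _write_tsv(cross_cancer_table(candidates), out / "cross_cancer.tsv", mhash)

    report = ces(subtests, classification_name=assignment.name)
    ces_df = pd.DataFrame([
        {"level": "global", "unit": "", "significant": report.global_counts[0],
         "evaluated": report.global_counts[1], "ces": report.global_ces},
    ])
    if len(report.per_class):
        per_class = report.per_class.rename(columns={"class": "unit"})
        per_class.insert(0, "level", "class")
        ces_df = pd.concat([ces_df, per_class], ignore_index=True)
    if len(report.per_histotype):
        per_hist = report.per_histotype.rename(columns={"histotype": "unit"})
        per_hist.insert(0, "level", "histotype")
        ces_df = pd.concat([ces_df, per_hist], ignore_index=True)
    _write_tsv(ces_df, out / "ces.tsv", mhash)

    consistency = {}
    if aligned.mutations is not None:
        rep = neighbor_consistency(aligned.mutations, aligned.annotations)
        consistency["mutation"] = rep
        rep.chord_matrix.to_csv(out / "chord_mutation.tsv", sep="\t")
    rep = neighbor_consistency(aligned.matrix, aligned.annotations)
    consistency["protein"] = rep
    rep.chord_matrix.to_csv(out / "chord_protein.tsv", sep="\t")

    return RunResult(
        aligned=aligned,
        batch_report=batch_report,
        assignment=assignment,
        subtests=subtests,
        cross_cancer=candidates,
        ces_report=report,
        consistency=consistency,
    )
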