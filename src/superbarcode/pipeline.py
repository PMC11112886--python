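"""Study orchestration: run every evaluation stage over a set of datasets.

A :class:`StudyConfig` lists datasets (each one or more aligned FASTA
files, optionally with a pre-built support tree or ``"njboot"`` to build
one in-repo), the shared sample map, and thresholds. :func:`run_study`
writes four TSV outputs — alignment features, distance reports, tree
reports, and cross-dataset comparisons — plus a JSON run log with seeds
and thresholds, so every printed percentage is auditable.
"""

from __future__ import annotations

import json
import os
import tomllib
import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .distances import evaluate_distance, resolution_vs_zero_k2p
from .errors import SuperbarcodeError
from .io_model import (
    DiscriminationReport,
    LabeledAlignment,
    concatenate,
    read_alignment,
    read_tree,
)
from .njboot import BootstrapConfig, bootstrap_tree
from .seqstats import features_table
from .treedisc import compare_datasets, monophyly_test, resolution, support_summary


@dataclass
class DatasetSpec:
    code: str
    alignments: list[str]  # FASTA paths; >1 = concatenated
    tree: str = "njboot"  # newick path or "njboot"


@dataclass
class StudyConfig:
    datasets: list[DatasetSpec]
    map_path: str
    outgroup: list[str] = field(default_factory=list)
    support_threshold: float = 50.0
    pi_threshold: float = 0.020
    window: int = 600
    step: int = 100
    replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        codes = [d.code for d in self.datasets]
        if len(set(codes)) != len(codes):
            raise SuperbarcodeError("dataset codes must be unique")


def load_study_config(path) -> StudyConfig:
    """Read a study TOML: [[datasets]] tables plus top-level keys."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    datasets = [
        DatasetSpec(
            code=d["code"],
            alignments=list(d["alignments"]),
            tree=d.get("tree", "njboot"),
        )
        for d in raw.get("datasets", [])
    ]
    kwargs = {k: v for k, v in raw.items() if k != "datasets"}
    return StudyConfig(datasets=datasets, **kwargs)


def _load_dataset(spec: DatasetSpec, map_path: str) -> LabeledAlignment:
    parts = [read_alignment(p, map_path) for p in spec.alignments]
    if len(parts) == 1:
        parts[0].name = spec.code
        return parts[0]
    return concatenate(parts, spec.code)


def run_study(cfg: StudyConfig, out_dir: str) -> dict:
    """Run features, distance and tree evaluation for every dataset.

    A dataset that fails is recorded in the log and skipped; the function
    returns a dict with the output tables and the list of failures.
    """
    os.makedirs(out_dir, exist_ok=True)
    alignments: dict[str, LabeledAlignment] = {}
    tree_verdicts: dict[str, list] = {}
    distance_reports: dict[str, DiscriminationReport] = {}
    failures: dict[str, str] = {}
    for spec in cfg.datasets:
        try:
            aln = _load_dataset(spec, cfg.map_path)
            alignments[spec.code] = aln
            distance_reports[spec.code] = evaluate_distance(aln)
            if spec.tree == "njboot":
                tree = bootstrap_tree(
                    aln, BootstrapConfig(replicates=cfg.replicates, seed=cfg.seed)
                )
            else:
                tree = read_tree(spec.tree)
            ingroup = [s for s in aln.samples if s.sample_id not in set(cfg.outgroup)]
            tree_verdicts[spec.code] = monophyly_test(
                tree,
                ingroup,
                outgroup=cfg.outgroup or None,
                support_threshold=cfg.support_threshold,
            )
        except (SuperbarcodeError, OSError) as exc:
            failures[spec.code] = str(exc)
            alignments.pop(spec.code, None)
            distance_reports.pop(spec.code, None)
            warnings.warn(f"dataset {spec.code!r} aborted: {exc}")

    features = features_table(list(alignments.values())) if alignments else pd.DataFrame()

    dist_rows = []
    for code, rep in distance_reports.items():
        row = {"dataset": code, **rep.summary}
        dist_rows.append(row)
    dist_df = pd.DataFrame(dist_rows)

    tree_rows = []
    for code, verdicts in tree_verdicts.items():
        hist, sups = support_summary(verdicts)
        tree_rows.append(
            {
                "dataset": code,
                "n_assessed": len(verdicts),
                "n_success": sum(v.monophyletic for v in verdicts),
                "resolution_pct": resolution(verdicts) if verdicts else float("nan"),
                **{f"support_{k}": v for k, v in hist.items()},
            }
        )
    tree_df = pd.DataFrame(tree_rows)

    comp_rows = []
    codes = sorted(tree_verdicts)
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            try:
                gained, lost, _ = compare_datasets(tree_verdicts[a], tree_verdicts[b])
            except SuperbarcodeError as exc:
                failures[f"{a}~{b}"] = str(exc)
                continue
            comp_rows.append(
                {
                    "dataset_a": a,
                    "dataset_b": b,
                    "gained_by_a": ";".join(gained),
                    "lost_by_a": ";".join(lost),
                }
            )
    comp_df = pd.DataFrame(comp_rows)

    regression = None
    regression_note = None
    if len(dist_df) >= 3:
        try:
            slope, r, p = resolution_vs_zero_k2p(list(distance_reports.values()))
            regression = {"slope": slope, "r": r, "p": p}
        except SuperbarcodeError as exc:
            # degenerate predictor (e.g. all datasets at zero) is expected on
            # well-separated data; record it without failing the study
            regression_note = str(exc)

    features.to_csv(os.path.join(out_dir, "features.tsv"), sep="\t", index=False)
    dist_df.to_csv(os.path.join(out_dir, "distance_reports.tsv"), sep="\t", index=False)
    tree_df.to_csv(os.path.join(out_dir, "tree_reports.tsv"), sep="\t", index=False)
    comp_df.to_csv(os.path.join(out_dir, "comparison.tsv"), sep="\t", index=False)
    log = {
        "version": __version__,
        "seed": cfg.seed,
        "support_threshold": cfg.support_threshold,
        "pi_threshold": cfg.pi_threshold,
        "window": cfg.window,
        "step": cfg.step,
        "replicates": cfg.replicates,
        "datasets": [d.code for d in cfg.datasets],
        "failures": failures,
        "regression": regression,
        "regression_note": regression_note,
    }
    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=1)
    return {
        "features": features,
        "distance": dist_df,
        "tree": tree_df,
        "comparison": comp_df,
        "regression": regression,
        "failures": failures,
    }
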