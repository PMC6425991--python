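"""End-to-end orchestration: CPL screen -> ranking -> assay summaries.

A single declarative YAML config drives the run; every stage is optional and
executes only when its inputs are configured. Each stage writes one TSV
report; a JSON manifest records all inputs, parameters, digests and versions
so the run can be re-executed exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from . import __version__
from .assays import (
    ChromiumInput,
    KillingInput,
    TitrationSeries,
    chromium_specific_lysis,
    fit_dose_response,
    flow_killing_percent,
)
from .clonotypes import overlap, read_repertoire, unique_clonotypes
from .landscape import build_scoring_model, preprocess, read_cpl
from .priming import heat_bar
from .search import hamming_distance, top_k
from .structure import mimicry_report, read_structure

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Declarative description of a full analysis run."""

    out_dir: Path
    seed: int = 0
    # CPL / ranking stage
    cpl_path: Path | None = None
    background: float | None = None
    pseudocount: float | None = None
    k: int = 10
    index_peptide: str | None = None
    # assay stages
    titration_path: Path | None = None
    killing_path: Path | None = None
    chromium_path: Path | None = None
    priming_path: Path | None = None
    repertoire_a_path: Path | None = None
    repertoire_b_path: Path | None = None
    # structure stage
    structure_a_path: Path | None = None
    structure_b_path: Path | None = None
    peptide_chain: str = "C"
    hla_chain: str = "A"
    contact_cutoff: float = 4.0
    groove_range: tuple[int, int] = (1, 180)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name, value in dataclasses.asdict(self).items():
            if name.endswith(("_path", "out_dir")) and value is not None:
                setattr(self, name, Path(value))

    def validate_inputs(self) -> None:
        for f in dataclasses.fields(self):
            if not f.name.endswith("_path"):
                continue
            value = getattr(self, f.name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{f.name}: {value} does not exist")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "groove_range" in raw:
        raw["groove_range"] = tuple(raw["groove_range"])
    return PipelineConfig(**raw)


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_topk(config: PipelineConfig) -> str:
    matrix = read_cpl(config.cpl_path, index_peptide=config.index_peptide)
    matrix = preprocess(matrix, config.background or 0.0)
    model = build_scoring_model(matrix, config.pseudocount)
    ranked = top_k(model, config.k, index_peptide=config.index_peptide)
    rows = []
    for r in ranked:
        mask = "".join("1" if s else "0" for s in r.shared_mask) if r.shared_mask else ""
        ham = (
            hamming_distance(r.sequence, config.index_peptide)
            if config.index_peptide
            else ""
        )
        rows.append(
            {"rank": r.rank, "sequence": r.sequence, "score": r.score,
             "shared_mask": mask, "hamming": ham}
        )
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def _stage_titration(config: PipelineConfig) -> str:
    df = pd.read_csv(config.titration_path, comment="#")
    rows = []
    for peptide, sub in df.groupby("peptide"):
        series = TitrationSeries(
            peptide=str(peptide),
            concentrations=tuple(sub["concentration_molar"]),
            readouts=tuple(sub["readout"]),
            background=float(sub["background"].iloc[0]) if "background" in sub else 0.0,
        )
        fit = fit_dose_response(series)
        rows.append(
            {"peptide": peptide, "bottom": fit.bottom, "top": fit.top,
             "log10_ec50": fit.log10_ec50, "ec50_molar": fit.ec50,
             "hill_slope": fit.hill_slope, "rss": fit.residual_sum_squares,
             "converged": fit.converged}
        )
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def _stage_killing(config: PipelineConfig) -> str:
    df = pd.read_csv(config.killing_path, comment="#")
    group_col = "group" if "group" in df.columns else None
    rows = []
    groups = df.groupby(group_col) if group_col else [("all", df)]
    for name, sub in groups:
        exp = sub[sub["condition"] == "exp"].iloc[0]
        con = sub[sub["condition"] == "con"].iloc[0]
        inp = KillingInput(
            exp_target_events=int(exp["target_events"]),
            exp_ref_events=int(exp["ref_events"]),
            con_target_events=int(con["target_events"]),
            con_ref_events=int(con["ref_events"]),
        )
        pct = flow_killing_percent(inp)
        rows.append({"group": name, "killing_percent": pct, "outgrowth": pct < 0})
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def _stage_chromium(config: PipelineConfig) -> str:
    df = pd.read_csv(config.chromium_path, comment="#")
    rows = []
    for row in df.itertuples():
        inp = ChromiumInput(
            experimental_release=float(row.experimental_release),
            spontaneous_release=float(row.spontaneous_release),
            maximum_release=float(row.maximum_release),
        )
        rows.append(
            {"well": getattr(row, "well", row.Index),
             "specific_lysis_percent": chromium_specific_lysis(inp)}
        )
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def _stage_priming(config: PipelineConfig) -> str:
    df = pd.read_csv(config.priming_path, comment="#")
    pivot = df.pivot_table(
        index="donor", columns="peptide", values="tetramer_pos_percent"
    )
    bars = heat_bar(pivot)
    combined = bars.combined.to_frame().T
    out = pd.concat([bars.matrix, combined])
    return out.to_csv(sep="\t", index_label="donor")


def _stage_clonotypes(config: PipelineConfig) -> str:
    rep_a = read_repertoire(config.repertoire_a_path, line_id="a")
    rep_b = read_repertoire(config.repertoire_b_path, line_id="b")
    summary = overlap(rep_a, rep_b)
    ua, ub = unique_clonotypes(rep_a), unique_clonotypes(rep_b)
    df = pd.DataFrame(
        [
            {"metric": "unique_a_alpha", "value": ua.alpha},
            {"metric": "unique_a_beta", "value": ua.beta},
            {"metric": "unique_b_alpha", "value": ub.alpha},
            {"metric": "unique_b_beta", "value": ub.beta},
            {"metric": "shared_alpha", "value": summary.shared_alpha},
            {"metric": "shared_beta", "value": summary.shared_beta},
            {"metric": "total_unique_union", "value": summary.total_unique_union},
            {"metric": "jaccard_alpha", "value": summary.jaccard_alpha},
            {"metric": "jaccard_beta", "value": summary.jaccard_beta},
        ]
    )
    return df.to_csv(sep="\t", index=False)


def _stage_structure(config: PipelineConfig) -> str:
    model_a = read_structure(config.structure_a_path)
    model_b = read_structure(config.structure_b_path)
    report = mimicry_report(
        model_a,
        model_b,
        peptide_chain=config.peptide_chain,
        hla_chain=config.hla_chain,
        groove_residue_range=config.groove_range,
        cutoff=config.contact_cutoff,
    )
    rows = [
        {"metric": "groove_superposition_rmsd_A", "value": report.groove_superposition_rmsd},
        {"metric": "peptide_backbone_rmsd_A", "value": report.peptide_backbone_rmsd},
        {"metric": "contacts_a", "value": report.contacts_a.contact_count},
        {"metric": "contacts_b", "value": report.contacts_b.contact_count},
    ]
    for label, recs in (("a", report.orientation_a), ("b", report.orientation_b)):
        for rec in recs:
            rows.append(
                {"metric": f"orientation_{label}_res{rec.resnum}",
                 "value": rec.classification}
            )
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


_STAGES: list[tuple[str, Callable[[PipelineConfig], str], Callable[[PipelineConfig], bool]]] = [
    ("topk", _stage_topk, lambda c: c.cpl_path is not None),
    ("titration", _stage_titration, lambda c: c.titration_path is not None),
    ("killing", _stage_killing, lambda c: c.killing_path is not None),
    ("chromium", _stage_chromium, lambda c: c.chromium_path is not None),
    ("priming", _stage_priming, lambda c: c.priming_path is not None),
    (
        "clonotypes",
        _stage_clonotypes,
        lambda c: c.repertoire_a_path is not None and c.repertoire_b_path is not None,
    ),
    (
        "structure",
        _stage_structure,
        lambda c: c.structure_a_path is not None and c.structure_b_path is not None,
    ),
]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every configured stage; returns the manifest dictionary.

    Fails fast, naming the offending stage; per-stage reports are written
    atomically (temp file then rename) so a failed run leaves no partial
    report behind.
    """
    config.validate_inputs()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "aplkit_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {},
        "stages": {},
    }
    for f in dataclasses.fields(config):
        if f.name.endswith("_path"):
            value = getattr(config, f.name)
            if value is not None:
                manifest["inputs"][f.name] = {
                    "path": str(value),
                    "sha256_16": _digest(Path(value)),
                }
    for name, fn, enabled in _STAGES:
        if not enabled(config):
            continue
        started = time.perf_counter()
        try:
            text = fn(config)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        report_path = out_dir / f"{name}.tsv"
        _atomic_write(report_path, text)
        manifest["stages"][name] = {
            "report": str(report_path),
            "wall_time_s": round(time.perf_counter() - started, 4),
        }
    _atomic_write(out_dir / "manifest.json", json.dumps(manifest, indent=2) + "\n")
    return manifest
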