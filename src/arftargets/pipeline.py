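"""End-to-end orchestration: simulate/read -> DE -> classify -> enrich -> QC.

:func:`run_pipeline` executes the whole analysis from a :class:`RunConfig`
and writes contrast tables, classifier outputs, enrichment tables, a QC
summary and a JSON run manifest.  Stage failures abort with a stage-named
:class:`PipelineError`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrich import read_annotation
from .factorial import ALL_CONTRASTS
from .io import read_counts, read_design, read_gene_lengths, write_table
from .model import FactorialTargetModel, FactorialTargetResults
from .simulate import SimulationConfig, write_fixture

log = logging.getLogger("arftargets")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds and flags of one pipeline run."""

    output_dir: str | Path = "arftargets_out"
    counts_path: str | Path | None = None
    design_path: str | Path | None = None
    lengths_path: str | Path | None = None
    annotation_path: str | Path | None = None
    tau_fdr: float = 0.05
    tau_lfc: float = 1.0
    auxin_fold_gate: bool = True
    strict_arf4_prevention: bool = True
    seed: int = 0
    log_level: str = "INFO"
    simulate: bool = False
    sim_config: SimulationConfig | None = None

    def validate(self) -> None:
        if not (0 < self.tau_fdr <= 1):
            raise ValueError("tau_fdr must lie in (0, 1]")
        if self.tau_lfc < 0:
            raise ValueError("tau_lfc must be non-negative")
        if not self.simulate and (self.counts_path is None or self.design_path is None):
            raise ValueError("need counts and design paths unless simulating")

    def header_lines(self) -> list[str]:
        return [
            f"arftargets {__version__}",
            f"seed={self.seed} tau_fdr={self.tau_fdr} tau_lfc={self.tau_lfc}",
        ]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def summarize_venn(results: FactorialTargetResults) -> dict:
    """JSON-ready 7- and 15-segment count tables with up/down and
    conformance tallies."""
    classified = results.classified
    seg3: dict[str, dict[str, int]] = {}
    if len(results.auxin_independent):
        for col in ("segment_mock", "segment_iaa"):
            seg3[col] = (
                results.auxin_independent[col].value_counts().to_dict()
            )
    class_counts = {
        str(label): {
            "n": int(row["n"]),
            "up": int(row["n_up"]),
            "down": int(row["n_down"]),
        }
        for label, row in results.class_counts().iterrows()
    }
    seg4 = results.partition4.segment_counts().to_dict()
    models = {
        str(m): {k: int(v) for k, v in row.items()}
        for m, row in results.antagonism.tallies.iterrows()
    }
    return {
        "three_way_segments": seg3,
        "auxin_independent_classes": class_counts,
        "n_classified": int(len(classified)),
        "n_removed_auxin_sensitive": int(
            results.auxin_independent["removed_auxin_sensitive"].sum()
        ),
        "four_way_segments": {str(k): int(v) for k, v in seg4.items()},
        "antagonism_models": models,
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write all outputs under
    ``config.output_dir``.  Returns the map of written files."""
    config.validate()
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s %(levelname)s %(message)s",
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header_lines()
    written: dict[str, Path] = {}
    inputs: dict[str, str] = {}

    # ---- input stage -------------------------------------------------
    try:
        if config.simulate:
            sim = config.sim_config or SimulationConfig(seed=config.seed)
            log.info("[simulate] generating synthetic experiment")
            model = FactorialTargetModel.simulate(sim)
            fixture = write_fixture(
                model.counts, model.design, model.truth, out / "simulated_input"
            )
            written.update({f"input_{k}": v for k, v in fixture.items()})
        else:
            log.info("[read] loading counts and design")
            model = FactorialTargetModel.from_tsv(
                config.counts_path, config.design_path
            )
            inputs["counts_sha256"] = _checksum(Path(config.counts_path))
            inputs["design_sha256"] = _checksum(Path(config.design_path))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    # ---- DE + classification stage -----------------------------------
    try:
        log.info("[fit] normalization, dispersion, 10 contrasts, classifiers")
        results = model.fit(
            tau_fdr=config.tau_fdr,
            tau_lfc=config.tau_lfc,
            auxin_fold_gate=config.auxin_fold_gate,
            strict_arf4_prevention=config.strict_arf4_prevention,
        )
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    try:
        for cid, ct in results.contrasts.items():
            written[f"contrast_{cid}"] = write_table(
                ct.table, out / f"contrast_{cid}.tsv", header
            )
        excluded = sorted(
            set().union(*(set(ct.excluded) for ct in results.contrasts.values()))
        )
        written["exclusions"] = write_table(
            pd.DataFrame({"gene_id": excluded}),
            out / "excluded_genes.tsv", header, index=False,
        )
        written["auxin_independent"] = write_table(
            results.auxin_independent, out / "auxin_independent_targets.tsv", header
        )
        sens = results.partition4.table.join(
            results.antagonism.assignments[["model_id", "conforming"]]
        )
        written["auxin_sensitive"] = write_table(
            sens, out / "auxin_sensitive_targets.tsv", header
        )
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    # ---- enrichment stage --------------------------------------------
    if config.annotation_path is not None:
        try:
            log.info("[enrich] over-representation per labelled class")
            annotation = read_annotation(config.annotation_path)
            inputs["annotation_sha256"] = _checksum(Path(config.annotation_path))
            for label in results.class_counts().index:
                table = results.enrich(str(label), annotation,
                                       fdr_cutoff=config.tau_fdr)
                written[f"enrichment_{label}"] = write_table(
                    table, out / f"enrichment_{label}.tsv", header, index=False
                )
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc

    # ---- QC stage -----------------------------------------------------
    try:
        log.info("[qc] PCA of log-normalized counts")
        summary = results.qc()
        written["qc_pca"] = write_table(
            summary.coordinates, out / "qc_pca.tsv", header
        )
        qc_stats = {
            "variance_explained": summary.variance_explained.tolist(),
            "genotype_spread": summary.genotype_spread,
            "treatment_spread": summary.treatment_spread,
            "spread_ratio": summary.spread_ratio,
        }
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    # ---- manifest ------------------------------------------------------
    manifest = {
        "tool": "arftargets",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {"tau_fdr": config.tau_fdr, "tau_lfc": config.tau_lfc},
        "flags": {
            "auxin_fold_gate": config.auxin_fold_gate,
            "strict_arf4_prevention": config.strict_arf4_prevention,
        },
        "inputs": inputs,
        "contrasts": list(ALL_CONTRASTS),
        "venn_summary": summarize_venn(results),
        "qc": qc_stats,
    }
    if model.truth is not None:
        manifest["recovery"] = {
            str(m): {"n": int(r["n"]), "fraction": float(r["fraction"])}
            for m, r in results.recovery().iterrows()
        }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = manifest_path
    log.info("[done] %d files written to %s", len(written), out)
    return written
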