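"""End-to-end profiling pipeline: matrix build → assay ranking → compound
scoring, with a provenance manifest.

All stage outputs are TSV with a ``# key: value`` parameter header;
identical inputs and parameters produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, assay_relevance, compound_scoring, io as tio
from .datamodel import drop_marginal, filter_low_info_assays

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameters of a full profiling run.

    Exactly one of ``outcomes`` (long-format records) or ``matrix`` (a
    pre-built wide TSV) must be given.  The parameter defaults are the
    reference settings of the workflow: assay filter of 6 actives, CCR
    cutoff 0.6, top 50% of candidates by L, compound eligibility at 3
    actives or >50% coverage, S classification boundary at 0.
    """

    labels: str | Path
    outcomes: str | Path | None = None
    matrix: str | Path | None = None
    out_dir: str | Path = "toxprofile_out"
    min_actives: int = 6
    ccr_cutoff: float = 0.6
    top_fraction: float = 0.5
    compound_min_actives: int = 3
    coverage_fraction: float = 0.5
    s_threshold: float = 0.0
    drop_marginal_labels: bool = True
    stats_scope: str = "panel"
    min_l: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def parameters(self) -> dict:
        return {
            "min_actives": self.min_actives,
            "ccr_cutoff": self.ccr_cutoff,
            "top_fraction": self.top_fraction,
            "compound_min_actives": self.compound_min_actives,
            "coverage_fraction": self.coverage_fraction,
            "s_threshold": self.s_threshold,
            "seed": self.seed,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Log stage timing and convert failures into PipelineError."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages and write artifacts into ``config.out_dir``.

    Returns a mapping of artifact names to paths: matrix, relevance,
    panel, scores, profiles, manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.parameters()
    artifacts: dict[str, Path] = {}
    inputs: dict[str, str] = {}

    with _stage("load-labels"):
        labels_path = Path(config.labels)
        if not labels_path.exists():
            raise FileNotFoundError(f"labels file not found: {labels_path}")
        inputs["labels"] = _sha256(labels_path)
        labels = tio.read_labels(labels_path)
        if config.drop_marginal_labels:
            n0 = len(labels)
            labels = drop_marginal(labels)
            logger.info("dropped %d marginal compounds, %d retained", n0 - len(labels), len(labels))

    with _stage("build-matrix"):
        if (config.outcomes is None) == (config.matrix is None):
            raise ValueError("exactly one of 'outcomes' or 'matrix' must be set")
        if config.outcomes is not None:
            opath = Path(config.outcomes)
            if not opath.exists():
                raise FileNotFoundError(f"outcomes file not found: {opath}")
            inputs["outcomes"] = _sha256(opath)
            records = tio.read_outcomes(opath)
            from .datamodel import build_matrix
            m = build_matrix(records)
        else:
            mpath = Path(config.matrix)
            if not mpath.exists():
                raise FileNotFoundError(f"matrix file not found: {mpath}")
            inputs["matrix"] = _sha256(mpath)
            m = tio.read_matrix(mpath)
        m, removed = filter_low_info_assays(m, min_actives=config.min_actives)
        logger.info("assay filter: removed %d low-information assays, %d retained",
                    len(removed), len(m.assay_ids))
        artifacts["matrix"] = out / "matrix.tsv"
        tio.write_matrix(m, artifacts["matrix"], comments=params)

    with _stage("rank-assays"):
        relevances = assay_relevance.score_assays(m, labels)
        sel = assay_relevance.rank_and_select(
            relevances,
            ccr_cutoff=config.ccr_cutoff,
            top_fraction=config.top_fraction,
            min_l=config.min_l,
        )
        artifacts["relevance"] = out / "relevance.tsv"
        tio.write_table(assay_relevance.relevance_table(relevances),
                        artifacts["relevance"], comments=params)
        artifacts["panel"] = out / "panel.txt"
        artifacts["panel"].write_text(
            "".join(a + "\n" for a in sel.panel_assays), encoding="utf-8"
        )
        logger.info("selected panel of %d assays from %d candidates",
                    len(sel.panel_assays), len(sel.candidate_assays))

    with _stage("score-compounds"):
        if sel.panel_assays:
            ranking = compound_scoring.prioritize(
                m, sel.panel_assays, labels=labels,
                min_actives=config.compound_min_actives,
                coverage_fraction=config.coverage_fraction,
                s_threshold=config.s_threshold,
                stats_scope=config.stats_scope,
            )
            profiles = compound_scoring.panel_profiles(
                m, sel.panel_assays, compound_order=ranking["compound_id"]
            )
        else:
            import pandas as pd
            ranking = pd.DataFrame(
                columns=["compound_id", "s_score", "n_active", "n_inactive",
                         "n_reported", "eligible", "predicted_toxic", "label"]
            )
            profiles = pd.DataFrame()
        artifacts["scores"] = out / "scores.tsv"
        tio.write_table(ranking, artifacts["scores"], comments=params)
        artifacts["profiles"] = out / "profiles.tsv"
        profiles.index.name = "compound_id"
        tio.write_table(profiles.reset_index(), artifacts["profiles"], comments=params)

    with _stage("manifest"):
        manifest = {
            "toxprofile_version": __version__,
            "parameters": params,
            "inputs_sha256": inputs,
            "n_compounds": len(m.compound_ids),
            "n_assays": len(m.assay_ids),
            "n_candidates": len(sel.candidate_assays),
            "panel_size": len(sel.panel_assays),
            "n_scored_compounds": int(len(ranking)),
        }
        artifacts["manifest"] = out / "manifest.json"
        artifacts["manifest"].write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return artifacts
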