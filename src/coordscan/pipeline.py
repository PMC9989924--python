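"""End-to-end orchestration: scan → gene set → enrichment → motif scan.

A YAML run config is validated up front (all problems reported at once,
unknown keys get a nearest-key suggestion); the pipeline is a pure function
of (inputs, config, seed) and writes byte-stable TSV outputs plus a JSON
report. Any stage failure removes partial outputs and propagates with the
stage name.
"""

from __future__ import annotations

import difflib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

import coordscan
import coordscan.enrichment as enr
import coordscan.expression_io as eio
import coordscan.promoter_motif as pm
from coordscan.coordination import (
    coordination_scan,
    correlated_gene_table,
    permutation_pvalue,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run configuration is invalid; message lists all problems."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class RunConfig:
    expression: str
    panel: list[str]
    sample_sheet: str | None = None
    gmt: str | None = None
    promoters: str | None = None
    query_gene: str | None = None
    alpha: float = 0.05
    direction: str = "positive"
    aggregation: str = "mean"
    n_permutations: int = 0
    seed: int = 0
    motif_consensus: str = "TGATGNAAN"
    max_edit: int = 2
    min_overlap: int = 2
    units: str = "normalized"
    out_dir: str = "coordscan_out"

    _FILE_KEYS = ("expression", "sample_sheet", "gmt", "promoters")


def validate_config(path: str | Path, **overrides) -> RunConfig:
    """Load and validate a YAML run config; keyword overrides win over the file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path.name}: top level must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return _validate_mapping(raw, base_dir=path.parent)


def _validate_mapping(raw: dict, base_dir: Path) -> RunConfig:
    known = [f for f in RunConfig.__dataclass_fields__ if not f.startswith("_")]
    problems: list[str] = []

    for key in raw:
        if key not in known:
            suggestion = difflib.get_close_matches(key, known, n=1)
            hint = f" (did you mean {suggestion[0]!r}?)" if suggestion else ""
            problems.append(f"unknown key {key!r}{hint}")

    if "expression" not in raw:
        problems.append("missing required key 'expression'")
    if "panel" not in raw:
        problems.append("missing required key 'panel'")

    kwargs = {k: v for k, v in raw.items() if k in known}
    if isinstance(kwargs.get("panel"), str):
        kwargs["panel"] = [g.strip() for g in kwargs["panel"].split(",") if g.strip()]

    cfg: RunConfig | None = None
    if "expression" in kwargs and "panel" in kwargs:
        try:
            cfg = RunConfig(**kwargs)
        except TypeError as exc:
            problems.append(str(exc))

    if cfg is not None:
        if not isinstance(cfg.panel, (list, tuple)) or not cfg.panel:
            problems.append("panel must be a non-empty list of gene ids")
        if not isinstance(cfg.alpha, (int, float)) or not 0 < cfg.alpha < 1:
            problems.append(f"alpha must be in (0, 1), got {cfg.alpha!r}")
        if cfg.direction not in ("positive", "both"):
            problems.append(f"direction must be 'positive' or 'both', got {cfg.direction!r}")
        if cfg.aggregation not in ("mean", "min"):
            problems.append(f"aggregation must be 'mean' or 'min', got {cfg.aggregation!r}")
        if cfg.units not in eio.VALID_UNITS:
            problems.append(f"units must be one of {eio.VALID_UNITS}, got {cfg.units!r}")
        if not isinstance(cfg.n_permutations, int) or cfg.n_permutations < 0:
            problems.append("n_permutations must be a non-negative integer")
        if cfg.n_permutations and cfg.n_permutations < 99:
            problems.append("n_permutations must be 0 (disabled) or >= 99")
        if not isinstance(cfg.max_edit, int) or cfg.max_edit < 0:
            problems.append("max_edit must be a non-negative integer")
        for key in RunConfig._FILE_KEYS:
            value = getattr(cfg, key)
            if value is None:
                continue
            resolved = (base_dir / value) if not Path(value).is_absolute() else Path(value)
            if not resolved.exists():
                problems.append(f"{key} file not found: {value}")
            else:
                setattr(cfg, key, str(resolved))
        try:
            pm.MotifPattern(cfg.motif_consensus, cfg.max_edit)
        except pm.PromoterError as exc:
            problems.append(f"motif_consensus: {exc}")

    if problems:
        raise ConfigError("invalid run configuration:\n  - " + "\n  - ".join(problems))
    assert cfg is not None
    cfg.panel = [str(g) for g in cfg.panel]
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write TSV outputs plus a JSON report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {
        "versions": {
            "coordscan": coordscan.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "config": {k: v for k, v in asdict(config).items() if not k.startswith("_")},
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                for p in written:
                    p.unlink(missing_ok=True)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 4)}
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result

        return deco

    @stage("load")
    def matrix():
        m = eio.load_expression(
            config.expression, sample_sheet=config.sample_sheet, units=config.units
        )
        if m.units == "counts":
            m = eio.normalize_log(m)
        m, removed = eio.filter_invariant_genes(m)
        report["stages"].setdefault("load", {})
        report["n_genes"] = m.n_genes
        report["n_samples"] = m.n_samples
        report["removed_invariant_genes"] = removed
        return m

    @stage("scan")
    def scan():
        res = coordination_scan(matrix, config.panel)
        p = out_dir / "scan.tsv"
        _write_tsv(res.table, p)
        written.append(p)
        return res

    query = config.query_gene or scan.top_candidate()
    report["query_gene"] = query
    report["top_candidate"] = scan.top_candidate()

    @stage("geneset")
    def gene_table():
        t = correlated_gene_table(matrix, query, config.alpha, config.direction)
        p = out_dir / "gene_set.tsv"
        _write_tsv(t, p)
        written.append(p)
        return t

    report["gene_set_size"] = int(len(gene_table))

    if config.n_permutations:
        @stage("permutation")
        def perm_results():
            rows = []
            for i, pg in enumerate(config.panel):
                res = permutation_pvalue(
                    matrix, query, pg, config.n_permutations, seed=config.seed + i
                )
                rows.append(
                    {
                        "gene_a": query,
                        "gene_b": pg,
                        "coordination_r": res.coordination_r,
                        "p_analytic": res.p_analytic,
                        "p_permutation": res.p_permutation,
                        "n_permutations": res.n_permutations,
                    }
                )
            df = pd.DataFrame(rows)
            p = out_dir / "permutation.tsv"
            _write_tsv(df, p)
            written.append(p)
            return df

    if config.gmt:
        @stage("enrich")
        def enrichment_results():
            collection = enr.read_gmt(config.gmt)
            results = enr.enrich(
                list(gene_table["gene"]),
                list(matrix.gene_ids),
                collection,
                min_overlap=config.min_overlap,
            )
            df = pd.DataFrame(
                [
                    {
                        "term": r.term,
                        "description": r.description,
                        "k": r.k,
                        "K": r.K,
                        "n": r.n,
                        "N": r.N,
                        "p": r.p_value,
                        "q": r.q_value,
                    }
                    for r in results
                ]
            )
            p = out_dir / "enrichment.tsv"
            _write_tsv(df, p)
            written.append(p)
            return results

        report["n_enriched_terms"] = len(enrichment_results)
        if enrichment_results:
            report["top_term"] = enrichment_results[0].term

    if config.promoters:
        @stage("motif")
        def motif_hits():
            pattern = pm.MotifPattern(config.motif_consensus, config.max_edit)
            promoters = pm.read_promoters(config.promoters)
            rows = []
            for prom in promoters:
                for hit in pm.scan_consensus(prom, pattern):
                    rows.append(
                        {
                            "promoter": hit.promoter_id,
                            "start": hit.start,
                            "end": hit.end,
                            "matched": hit.matched,
                            "edit_distance": hit.edit_distance,
                            "strand": hit.strand,
                        }
                    )
            df = pd.DataFrame(
                rows,
                columns=["promoter", "start", "end", "matched", "edit_distance", "strand"],
            )
            p = out_dir / "motif_hits.tsv"
            _write_tsv(df, p)
            written.append(p)
            return df

        report["n_motif_hits"] = int(len(motif_hits))

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
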