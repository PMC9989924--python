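"""Seeded latent-factor simulator for coordination-analysis benchmarks.

Each individual (sample) i carries a latent pathway activity
``u_i ~ N(0, sigma_u^2)`` shifted by ``delta`` for treated samples, and an
independent second factor ``v_i ~ N(0, sigma_u^2)``. Gene expression is

* module / planted-target genes:  x_gi = mu_g + lam * u_i + eps_gi
* dual-loading genes:             x_gi = mu_g + (lam/2) * u_i + rho_secondary * v_i + eps_gi
* background genes:               x_gi = mu_g + eps_gi

with per-gene baselines ``mu_g ~ N(baseline_mean, baseline_sd^2)`` and noise
``eps ~ N(0, sigma_e^2)``. The module emulates a tightly coordinated
stress-response pathway, the planted target a hidden gene co-regulated with
it, and the dual-loading gene a partially coordinated gene also driven by an
unrelated pathway. All randomness flows from a single mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from coordscan.expression_io import ExpressionMatrix, write_expression

#: Canonical stress-pathway panel ids used by the F1 fixture.
F1_MODULE_IDS = ("HSPA5", "DNAJB9", "HSP90B1", "ATF4", "DNAJC3", "DDIT3")
F1_TARGET_IDS = ("RASSF1",)
F1_DUAL_IDS = ("DDIT3-alt",)
F1_SEED = 20230214


class SyntheticError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the latent-factor generative model."""

    seed: int
    n_samples: int = 12
    n_background: int = 2000
    module_genes: int = 6
    planted_targets: int = 1
    dual_loading_genes: int = 1
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    lam: float = 1.0
    sigma_u: float = 1.0
    sigma_e: float = 0.5
    delta: float = 1.0
    treated_fraction: float = 0.5
    rho_secondary: float = 1.0
    module_ids: tuple[str, ...] | None = None
    target_ids: tuple[str, ...] | None = None
    dual_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SyntheticError("seed is mandatory")
        if self.n_samples < 3:
            raise SyntheticError("need at least 3 samples")
        for name in ("baseline_sd", "sigma_u", "sigma_e"):
            if getattr(self, name) <= 0:
                raise SyntheticError(f"{name} must be > 0")
        for name in ("n_background", "module_genes", "planted_targets", "dual_loading_genes"):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be >= 0")
        if not 0 <= self.treated_fraction <= 1:
            raise SyntheticError("treated_fraction must be in [0, 1]")
        if self.n_genes == 0:
            raise SyntheticError("configuration yields zero genes")
        for attr, count in (
            ("module_ids", self.module_genes),
            ("target_ids", self.planted_targets),
            ("dual_ids", self.dual_loading_genes),
        ):
            ids = getattr(self, attr)
            if ids is not None and len(ids) != count:
                raise SyntheticError(f"{attr} has {len(ids)} ids but {count} genes configured")

    @property
    def n_genes(self) -> int:
        return (
            self.n_background
            + self.module_genes
            + self.planted_targets
            + self.dual_loading_genes
        )


@dataclass(frozen=True)
class GroundTruth:
    """Per-gene roles, per-sample latent activities and the config that made them."""

    roles: dict[str, str]  # gene id -> background | module | planted_target | dual
    u: np.ndarray  # latent pathway activity per sample (treatment shift included)
    v: np.ndarray  # independent secondary factor per sample
    config: SyntheticConfig = field(repr=False, default=None)

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]


def _default_ids(prefix: str, count: int) -> tuple[str, ...]:
    width = max(4, len(str(count)))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(1, count + 1))


def generate(config: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one expression matrix plus its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    n_treated = int(round(config.treated_fraction * n))
    condition = ("control",) * (n - n_treated) + ("treated",) * n_treated
    treated_mask = np.array([c == "treated" for c in condition], dtype=float)

    u = rng.normal(0.0, config.sigma_u, n) + config.delta * treated_mask
    v = rng.normal(0.0, config.sigma_u, n)

    module_ids = config.module_ids or _default_ids("MOD", config.module_genes)
    target_ids = config.target_ids or _default_ids("TARGET", config.planted_targets)
    dual_ids = config.dual_ids or _default_ids("DUAL", config.dual_loading_genes)
    background_ids = _default_ids("BG", config.n_background)
    gene_ids = tuple(module_ids) + tuple(target_ids) + tuple(dual_ids) + background_ids

    mu = rng.normal(config.baseline_mean, config.baseline_sd, len(gene_ids))
    eps = rng.normal(0.0, config.sigma_e, (len(gene_ids), n))

    values = mu[:, None] + eps
    n_mod = config.module_genes
    n_tar = config.planted_targets
    n_dual = config.dual_loading_genes
    values[: n_mod + n_tar] += config.lam * u
    dual_slice = slice(n_mod + n_tar, n_mod + n_tar + n_dual)
    values[dual_slice] += (config.lam / 2.0) * u + config.rho_secondary * v

    roles: dict[str, str] = {}
    for g in module_ids:
        roles[g] = "module"
    for g in target_ids:
        roles[g] = "planted_target"
    for g in dual_ids:
        roles[g] = "dual"
    for g in background_ids:
        roles[g] = "background"

    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=tuple(f"S{i:02d}" for i in range(1, n + 1)),
        values=values,
        condition=condition,
        units="normalized",
    )
    return matrix, GroundTruth(roles=roles, u=u, v=v, config=config)


def f1_config(seed: int = F1_SEED, **overrides) -> SyntheticConfig:
    """The canonical F1 fixture configuration (2008 genes × 12 samples)."""
    params = dict(
        seed=seed,
        n_samples=12,
        n_background=2000,
        module_genes=6,
        planted_targets=1,
        dual_loading_genes=1,
        lam=1.0,
        sigma_u=1.0,
        sigma_e=0.5,
        delta=1.0,
        treated_fraction=0.5,
        rho_secondary=1.0,
        module_ids=F1_MODULE_IDS,
        target_ids=F1_TARGET_IDS,
        dual_ids=F1_DUAL_IDS,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def fixture_F1() -> tuple[ExpressionMatrix, GroundTruth]:
    """The canonical deterministic test fixture (seed 20230214)."""
    return generate(f1_config())


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "roles": truth.roles,
        "u": list(truth.u),
        "v": list(truth.v),
        "config": {
            k: (list(val) if isinstance(val, tuple) else val)
            for k, val in asdict(truth.config).items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_dataset(
    matrix: ExpressionMatrix,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write expression TSV, sample sheet and ground-truth JSON into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_expression(matrix, paths["expression"], sample_sheet=paths["samples"])
    write_ground_truth(truth, paths["ground_truth"])
    return paths
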