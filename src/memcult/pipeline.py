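"""End-to-end orchestration: simulate -> score -> compare -> transfer -> rfe -> model.

A YAML-configurable, seeded run writing every inter-stage artifact in the
package's plain-text dialects plus a machine-readable manifest (stage,
output digests, seed, timestamps) for reproducibility audits.  Rerunning
with the same config and seed reproduces every output byte-for-byte; only
the manifest timestamps differ.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import _rng, io, models, synthetic
from .cross_culture import assign_quadrants, compare_dimensions, cross_group_correlation
from .errors import MemcultError
from .rfe import LabeledFeatureSet, run_rfe
from .scoring import memorability_table
from .transfer import evaluate_transfer, fit_dimension_models, models_to_json

log = logging.getLogger("memcult")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults reproduce the study design."""

    out_dir: str = "memcult_run"
    seed: int = 0
    # design
    n_participants_per_group: int = 120
    n_stimuli: int = 600
    n_subsets: int = 4
    n_dims: int = 49
    sparsity: float = 0.7
    groups: tuple[str, str] = ("CN", "US")
    # planted effects (see synthetic.plant_cultural_effects)
    effects: dict = field(default_factory=dict)
    # trials (optional user data; skips the simulate stage)
    trials_csv: str | None = None
    dimensions_tsv: str | None = None
    categories_tsv: str | None = None
    # transfer
    with_embeddings: bool = True
    embed_dim: int = 128
    embedding_noise_sd: float = 0.25
    transfer_holdout_fraction: float = 0.2
    # cross-culture
    tie_policy: str = "strict_gt"
    # rfe
    rfe_repeats: int = 6
    rfe_folds: int = 10
    rfe_window: int = 7
    rfe_C: float = 1.0
    # models
    k: int = 6
    selection_target: str = "residual"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise MemcultError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.groups = tuple(cfg.groups)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["groups"] = list(self.groups)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def validate_config(config: RunConfig) -> list[str]:
    """Content validation; returns a list of error strings (empty = ok)."""
    errors = []
    if config.n_stimuli % config.n_subsets != 0:
        errors.append(
            f"n_stimuli={config.n_stimuli} not divisible by n_subsets={config.n_subsets}"
        )
    n_pairs = config.n_subsets * (config.n_subsets - 1)
    if config.n_participants_per_group % n_pairs != 0:
        errors.append(
            f"n_participants_per_group={config.n_participants_per_group} not divisible "
            f"by number of (old,new) subset pairs ({n_pairs})"
        )
    if config.rfe_window % 2 == 0:
        errors.append(f"window must be odd, got {config.rfe_window}")
    if not 0 <= config.sparsity < 1:
        errors.append(f"sparsity must be in [0, 1), got {config.sparsity}")
    if len(config.groups) != 2:
        errors.append(f"exactly two groups required, got {list(config.groups)}")
    if config.with_embeddings and config.embed_dim < config.n_dims:
        errors.append(f"embed_dim={config.embed_dim} must be >= n_dims={config.n_dims}")
    if config.tie_policy not in ("strict_gt", "ge"):
        errors.append(f"tie_policy must be strict_gt or ge, got {config.tie_policy!r}")
    for name in ("trials_csv", "dimensions_tsv", "categories_tsv"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            errors.append(f"{name} path does not exist: {p}")
    # category sizes only checkable against the bundled map when simulating
    if config.categories_tsv is None and config.dimensions_tsv is None:
        _, cats = synthetic.load_default_dimension_metadata()
        for cat in ("life", "nonlife"):
            size = sum(1 for c in cats.values() if c == cat)
            if config.k > size:
                errors.append(f"k={config.k} exceeds {cat} category size ({size})")
    return errors


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    errors = validate_config(config)
    if errors:
        raise MemcultError("invalid config: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config), "stages": []}
    manifest["config"]["groups"] = list(config.groups)

    state: dict = {}

    def _simulate():
        if config.trials_csv is not None:
            trials = io.read_trials_csv(config.trials_csv)
            dims_df = io.read_dimensions_tsv(config.dimensions_tsv)
            cats = (
                io.read_categories_tsv(config.categories_tsv)
                if config.categories_tsv
                else synthetic.load_default_dimension_metadata()[1]
            )
            state["trials"] = trials
            state["dimensions"] = synthetic.StimulusDimensionTable(scores=dims_df, categories=cats)
            state["embeddings"] = None
            return []
        names, cats = synthetic.load_default_dimension_metadata()
        names, cats_list = names[: config.n_dims], [cats[n] for n in names[: config.n_dims]]
        design = synthetic.generate_design(
            config.n_participants_per_group, config.n_stimuli, config.n_subsets, seed=config.seed
        )
        dims = synthetic.generate_dimension_space(
            config.n_stimuli, config.n_dims, names, dict(zip(names, cats_list)),
            sparsity=config.sparsity, seed=config.seed,
        )
        effect = synthetic.plant_cultural_effects(
            dims, group_ids=config.groups, seed=config.seed, **config.effects
        )
        ds = synthetic.simulate_trials(design, dims, effect, group_ids=config.groups, seed=config.seed)
        if config.with_embeddings:
            ds.embeddings, _ = synthetic.generate_embeddings(
                dims, config.embed_dim, noise_sd=config.embedding_noise_sd, seed=config.seed
            )
        state["trials"] = ds.trials
        state["dimensions"] = ds.dimensions
        state["embeddings"] = ds.embeddings
        state["true_memorability"] = ds.true_memorability
        written = [out / "trials.csv", out / "dimensions.tsv", out / "categories.tsv", out / "truth.json"]
        io.write_trials_csv(ds.trials, written[0])
        io.write_dimensions_tsv(ds.dimensions, written[1])
        io.write_categories_tsv(ds.dimensions.categories, written[2])
        io.write_truth_json(ds, written[3])
        if ds.embeddings is not None:
            p = out / "embeddings.tsv"
            io.write_embeddings_tsv(ds.embeddings, p)
            written.append(p)
        return written

    def _score():
        table = memorability_table(state["trials"], groups=list(config.groups))
        state["memorability"] = table
        p = out / "memorability.tsv"
        io.write_memorability_tsv(table, p)
        return [p]

    def _compare():
        wide = io.memorability_wide(state["memorability"])
        g_a, g_b = config.groups
        mem_a, mem_b = wide[g_a], wide[g_b]
        r, pval, n = cross_group_correlation(mem_a, mem_b)
        quad = assign_quadrants(mem_a, mem_b, tie_policy=config.tie_policy)
        dims_df = state["dimensions"].scores
        comp = compare_dimensions(dims_df, quad.stimuli_in(2), quad.stimuli_in(4))
        state["quadrants"] = quad
        state["cross_r"] = r
        written = [out / "quadrants.tsv", out / "dimension_comparisons.tsv", out / "compare.json"]
        quad.quadrants.rename_axis("stimulus").to_frame().to_csv(written[0], sep="\t")
        comp.round(10).to_csv(written[1], sep="\t")
        written[2].write_text(
            json.dumps(
                {
                    "pearson_r": r, "p": pval, "n": n,
                    "median_" + g_a: quad.median_a, "median_" + g_b: quad.median_b,
                    "tie_policy": quad.tie_policy, "quadrant_counts": quad.counts,
                }
            )
        )
        return written

    def _transfer():
        if state.get("embeddings") is None:
            log.info("transfer: no embeddings configured; skipped")
            state["transfer_report"] = None
            return []
        emb, dims_df = state["embeddings"], state["dimensions"].scores
        rng = _rng.substream(config.seed, _rng.KEY_CV_FOLDS + 1)
        n = len(emb)
        n_hold = max(3, int(round(config.transfer_holdout_fraction * n)))
        holdout = np.sort(rng.choice(n, size=n_hold, replace=False))
        train = np.setdiff1d(np.arange(n), holdout)
        fitted = fit_dimension_models(
            emb.iloc[train], dims_df.iloc[train], n_folds=10, seed=config.seed
        )
        report = evaluate_transfer(fitted, emb.iloc[holdout], dims_df.iloc[holdout])
        state["transfer_report"] = report
        written = [out / "transfer_models.json", out / "transfer_report.json"]
        models_to_json(fitted, written[0])
        written[1].write_text(
            json.dumps(
                {
                    "per_dimension_r": report.per_dimension_r.round(10).to_dict(),
                    "counts": {str(t): c for t, c in report.counts.items()},
                    "n_heldout": int(n_hold),
                }
            )
        )
        return written

    def _rfe_stage():
        quad = state["quadrants"]
        s2, s4 = quad.stimuli_in(2), quad.stimuli_in(4)
        dims_df = state["dimensions"].scores
        feats = dims_df.loc[s2 + s4]
        labels = np.concatenate([np.ones(len(s2), dtype=int), -np.ones(len(s4), dtype=int)])
        result = run_rfe(
            LabeledFeatureSet(features=feats, labels=labels),
            n_repeats=config.rfe_repeats, n_folds=config.rfe_folds,
            C=config.rfe_C, window=config.rfe_window, seed=config.seed,
        )
        state["rfe"] = result
        written = [out / "rfe_result.json", out / "rfe_trace.tsv"]
        written[0].write_text(json.dumps(result.to_dict()))
        result.trace_frame().round(10).to_csv(written[1], sep="\t", index=False)
        return written

    def _model():
        wide = io.memorability_wide(state["memorability"])
        g_a, g_b = config.groups
        table = models.run_culture_models(
            wide[g_a], wide[g_b], state["dimensions"].scores,
            state["dimensions"].categories, k=config.k,
            group_names=(g_a, g_b), selection_target=config.selection_target,
        )
        state["culture_models"] = table
        p = out / "culture_models.tsv"
        table.round(10).to_csv(p, sep="\t", index=False)
        return [p]

    stages = [
        ("simulate", _simulate),
        ("score", _score),
        ("compare", _compare),
        ("transfer", _transfer),
        ("rfe", _rfe_stage),
        ("model", _model),
    ]
    for name, fn in stages:
        rec = {"stage": name, "seed": config.seed, "started": time.time()}
        log.info("[%s] starting", name)
        try:
            written = fn()
        except Exception as exc:  # noqa: BLE001 - failure point recorded in manifest
            rec.update(status="failed", error=f"{type(exc).__name__}: {exc}", finished=time.time())
            manifest["stages"].append(rec)
            log.error("[%s] failed: %s", name, exc)
            break
        rec.update(
            status="ok",
            outputs={p.name: _digest(p) for p in written},
            finished=time.time(),
        )
        manifest["stages"].append(rec)
        log.info("[%s] done (%d outputs)", name, len(written))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    manifest["state"] = state
    return manifest
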