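"""Run configuration and the end-to-end pipeline.

A run is described by a flat ``key = value`` text file (or a RunConfig
built in code). The pipeline is: load or synthesize labeled sequences ->
embed -> optional grid search -> repeated stratified CV (10 fold models) ->
soft-voting ensemble -> threshold (fixed or FPR-calibrated) -> optional
screening and eSHAP scans. Every artifact is stamped with the seed and a
hash of the configuration; rerunning an identical config reproduces the
artifacts byte for byte (wall-clock timestamps go to the log, never into
artifacts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import embedding, eshap, modeling, screening, sequence_io, synthetic
from .descriptors import featurize_records

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    # inputs: either a FASTA + label table, or the synthetic benchmark preset
    fasta: str = ""
    labels: str = ""
    preset: str = ""  # "benchmark" generates the synthetic cohort
    residue_policy: str = "drop"

    # features
    featurizer: str = "fixture_embedder"  # fixture_embedder | precomputed:<path> | descriptor name
    embed_dim: int = 256
    embed_k: int = 3

    # modeling
    algorithm: str = "rf"
    grid: dict[str, list] = field(default_factory=dict)  # empty -> skip grid search
    hyperparameters: dict = field(default_factory=lambda: {"n_estimators": 100})
    n_splits: int = 5
    n_repeats: int = 2
    seed: int = 0

    # operating point
    ensemble_mode: str = "soft"
    threshold: float = 0.90
    target_fpr: float | None = None  # when set, calibrate instead of fixed threshold

    # optional stages
    screen_fasta: str = ""  # screen these proteins (empty -> skip)
    explain_ids: list[str] = field(default_factory=list)  # eSHAP scan these training ids
    eshap_k: int = 20

    outdir: str = "preprotac_run"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_LIST_KEYS = {"explain_ids"}
_INT_KEYS = {"embed_dim", "embed_k", "n_splits", "n_repeats", "seed", "eshap_k"}
_FLOAT_KEYS = {"threshold", "target_fpr"}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file (# comments allowed).

    ``grid.<param>`` and ``hp.<param>`` keys hold comma-separated candidate
    values / single values for the four tuned hyperparameters, e.g.
    ``grid.n_estimators = 100, 200`` or ``hp.max_depth = 10``.
    """
    cfg = RunConfig()
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key.startswith("grid."):
            cfg.grid[key[5:]] = [_hp_value(v) for v in val.split(",")]
        elif key.startswith("hp."):
            cfg.hyperparameters[key[3:]] = _hp_value(val)
        elif key in _LIST_KEYS:
            setattr(cfg, key, [v.strip() for v in val.split(",") if v.strip()])
        elif key in _INT_KEYS:
            setattr(cfg, key, int(val))
        elif key in _FLOAT_KEYS:
            setattr(cfg, key, float(val))
        elif key in valid:
            setattr(cfg, key, val)
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    return cfg


def _hp_value(s: str):
    s = s.strip()
    if s.lower() in ("none", "null"):
        return None
    try:
        return int(s)
    except ValueError:
        return float(s)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    lines = [f"# config hash: {cfg.config_hash()}"]
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if f.name == "grid":
            lines += [f"grid.{k} = {', '.join(str(x) for x in vs)}" for k, vs in v.items()]
        elif f.name == "hyperparameters":
            lines += [f"hp.{k} = {x}" for k, x in v.items()]
        elif f.name in _LIST_KEYS:
            if v:
                lines.append(f"{f.name} = {', '.join(v)}")
        elif f.name == "outdir":
            continue  # output location, not configuration (excluded from the hash too)
        elif v is not None:
            lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def _load_inputs(cfg: RunConfig):
    if cfg.preset == "benchmark":
        return synthetic.default_benchmark(seed=cfg.seed)
    if cfg.preset:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    if not cfg.fasta or not cfg.labels:
        raise ValueError("config needs either preset=benchmark or fasta= and labels= paths")
    for p in (cfg.fasta, cfg.labels):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    records = sequence_io.read_fasta(cfg.fasta, residue_policy=cfg.residue_policy)
    return sequence_io.read_labels(cfg.labels, records), {}


def _make_embedder(cfg: RunConfig) -> embedding.Embedder:
    return embedding.FixtureEmbedder(dim=cfg.embed_dim, k=cfg.embed_k, seed=cfg.seed)


def _featurize(cfg: RunConfig, records):
    if cfg.featurizer == "fixture_embedder":
        return embedding.embed_records(records, _make_embedder(cfg))
    if cfg.featurizer.startswith("precomputed:"):
        fm = embedding.load_precomputed(cfg.featurizer.split(":", 1)[1])
        order = {sid: i for i, sid in enumerate(fm.sample_ids)}
        missing = [r.id for r in records if r.id not in order]
        if missing:
            raise ValueError(f"precomputed embeddings missing ids: {missing[:5]}")
        rows = [order[r.id] for r in records]
        return dataclasses.replace(
            fm, sample_ids=[r.id for r in records], values=fm.values[rows]
        )
    return featurize_records(records, cfg.featurizer)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured pipeline; returns a dict of in-memory artifacts.

    Writes to ``cfg.outdir``: the resolved config (with hash), the CV report
    JSON, the persisted ensemble, and any screening/eSHAP outputs. Aborts
    with the failing stage named in the exception.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    artifacts: dict = {"config_hash": chash}
    save_config(cfg, outdir / "config.txt")

    def stage(name, fn, *args, **kw):
        logger.info("stage %s [config %s]", name, chash)
        try:
            return fn(*args, **kw)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    dataset, truth = stage("load_inputs", _load_inputs, cfg)
    features = stage("featurize", _featurize, cfg, dataset.records)
    labels = [dataset.labels[sid] for sid in features.sample_ids]

    hp = dict(cfg.hyperparameters)
    if cfg.grid:
        best, grid_results = stage(
            "grid_search", modeling.grid_search, features, labels, cfg.algorithm, cfg.grid, cfg.seed
        )
        hp.update(best)
        artifacts["grid_results"] = grid_results
        (outdir / "grid_search.json").write_text(
            json.dumps({"best": best, "results": grid_results}, indent=1, sort_keys=True)
        )

    report, fold_models = stage(
        "cv",
        modeling.repeated_stratified_cv,
        features, labels, cfg.algorithm, hp,
        n_splits=cfg.n_splits, n_repeats=cfg.n_repeats, seed=cfg.seed,
    )
    cvj = report.to_jsonable()
    cvj["config_hash"] = chash
    (outdir / "cv_report.json").write_text(json.dumps(cvj, indent=1, sort_keys=True))

    threshold = cfg.threshold
    if cfg.target_fpr is not None:
        threshold = stage("calibrate", modeling.calibrate_threshold, report, cfg.target_fpr)
    ensemble = modeling.EnsembleModel(members=fold_models, mode=cfg.ensemble_mode, threshold=threshold)
    modeling.save_model(ensemble, outdir / "ensemble.joblib")
    artifacts.update(cv_report=report, ensemble=ensemble, threshold=threshold, truth=truth,
                     features=features, dataset=dataset)

    if cfg.screen_fasta:
        screen_records = stage(
            "read_screen_fasta", sequence_io.read_fasta, cfg.screen_fasta, "replace"
        )
        rep = stage(
            "screen", screening.screen, screen_records, _make_embedder(cfg), ensemble,
            threshold, {"config_hash": chash, "seed": cfg.seed},
        )
        rep.to_tsv(outdir / "screening.tsv")
        rep.to_json(outdir / "screening.json")
        artifacts["screening"] = rep

    if cfg.explain_ids:
        emb = _make_embedder(cfg)
        selection = stage("shap_selection", eshap.select_top_features, ensemble, features, cfg.eshap_k)
        by_id = {r.id: r for r in dataset.records}
        scans = []
        for rid in cfg.explain_ids:
            if rid not in by_id:
                raise RuntimeError(f"pipeline stage 'eshap' failed: unknown id {rid!r}")
            res = stage("eshap", eshap.eshap_scan, by_id[rid], emb, ensemble, selection=selection)
            res.to_tsv(outdir / f"eshap_{rid}.tsv")
            scans.append(res)
        artifacts["eshap"] = scans

    return artifacts
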