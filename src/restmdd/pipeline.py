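"""End-to-end experiment orchestration.

``run_all`` ties the four stages together — simulate a cohort, preprocess
each recording, extract the 570 features, train and evaluate the six model
families — under a single master seed. Stage seeds are derived by stable
hashing of (master seed, stage name), so each stage is independently
reproducible, and a run manifest records the config hash and checksums of
every artifact written.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .cohort import (ArtifactSpec, SpectralProfile, draw_subject_profiles,
                     make_default_protocol, synth_recording)
from .features import (build_feature_table, default_band_set,
                       features_for_subject, write_feature_table)
from .modeling import run_experiment
from .preprocess import extract_resting_periods, preprocess_recording


class ConfigError(ValueError):
    """A configuration document failed validation; message names the field."""


@dataclass
class ExperimentConfig:
    n_mdd: int = 70
    n_healthy: int = 70
    fs: float = 200.0
    total_resting_seconds: float = 100.0
    photic_seconds: float = 10.0
    hyperventilation_seconds: float = 30.0
    spectral: SpectralProfile = field(default_factory=SpectralProfile)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec.none)
    filter_low: float = 0.1
    filter_high: float = 40.0
    drop_policy: str = "auto"
    wavelet: str = "db4"
    dwt_levels: int = 6
    entropy_blocks: int = 8
    test_size: int = 40
    top_k: int = 100
    cv_folds: int = 10
    grid_preset: str = "default"  # "default" or "compact"
    seed: int = 0
    write_edf: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


_SECTIONS = {
    "cohort": {"n_mdd", "n_healthy", "fs", "total_resting_seconds",
               "photic_seconds", "hyperventilation_seconds"},
    "spectral": {"band_weights", "one_over_f_exponent", "background_weight",
                 "ec_alpha_gain", "group_effect", "subject_sigma",
                 "channel_sigma"},
    "artifacts": {"blink_rate", "blink_amplitude", "line_noise_amplitude",
                  "drift_amplitude"},
    "preprocess": {"filter_low", "filter_high", "drop_policy"},
    "features": {"wavelet", "dwt_levels", "entropy_blocks"},
    "modeling": {"test_size", "top_k", "cv_folds", "grid_preset"},
    "run": {"seed", "write_edf"},
}


def validate_config(raw: dict | None) -> ExperimentConfig:
    """Build a validated config from a (possibly empty) nested document.

    The document has sections ``cohort``, ``spectral``, ``artifacts``,
    ``preprocess``, ``features``, ``modeling`` and ``run``; every field is
    optional and defaults are filled in. Unknown sections or fields and
    cross-field violations (e.g. a filter cutoff at or above the Nyquist
    frequency, or ``top_k`` exceeding the feature count) are rejected with
    the offending field path.
    """
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("config document must be a mapping")
    for section, content in raw.items():
        if section not in _SECTIONS:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(content, dict):
            raise ConfigError(f"{section}: must be a mapping")
        for key in content:
            if key not in _SECTIONS[section]:
                raise ConfigError(f"{section}.{key}: unknown field")

    cfg = ExperimentConfig()
    flat_targets = {**{k: ("cohort", k) for k in _SECTIONS["cohort"]},
                    **{k: ("preprocess", k) for k in _SECTIONS["preprocess"]},
                    **{k: ("features", k) for k in _SECTIONS["features"]},
                    **{k: ("modeling", k) for k in _SECTIONS["modeling"]},
                    **{k: ("run", k) for k in _SECTIONS["run"]}}
    for attr, (section, key) in flat_targets.items():
        if section in raw and key in raw[section]:
            setattr(cfg, attr, raw[section][key])
    try:
        if "spectral" in raw:
            cfg.spectral = SpectralProfile(**{**asdict(SpectralProfile()),
                                              **raw["spectral"]})
        if "artifacts" in raw:
            cfg.artifacts = ArtifactSpec(**{**asdict(ArtifactSpec.none()),
                                            **raw["artifacts"]})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    if cfg.n_mdd < 1 or cfg.n_healthy < 1:
        raise ConfigError("cohort.n_mdd / cohort.n_healthy: must be >= 1")
    if cfg.fs <= 0:
        raise ConfigError("cohort.fs: must be positive")
    if not (0 < cfg.filter_low < cfg.filter_high):
        raise ConfigError("preprocess.filter_low/filter_high: need 0 < low < high")
    if cfg.filter_high >= cfg.fs / 2:
        raise ConfigError(
            f"preprocess.filter_high: {cfg.filter_high} Hz violates the "
            f"Nyquist constraint (must be < fs/2 = {cfg.fs / 2} Hz)")
    if cfg.drop_policy not in ("auto", "none"):
        raise ConfigError("preprocess.drop_policy: must be 'auto' or 'none'")
    if cfg.total_resting_seconds < 50:
        raise ConfigError(
            "cohort.total_resting_seconds: must be >= 50 (five periods of "
            "at least 10 s)")
    n_features = 19 * 5 * 6
    if not (0 < cfg.top_k <= n_features):
        raise ConfigError(f"modeling.top_k: must be in (0, {n_features}]")
    if cfg.test_size <= 0 or cfg.test_size >= cfg.n_mdd + cfg.n_healthy:
        raise ConfigError("modeling.test_size: must be in (0, n_subjects)")
    if cfg.cv_folds < 2:
        raise ConfigError("modeling.cv_folds: must be >= 2")
    if cfg.grid_preset not in ("default", "compact"):
        raise ConfigError("modeling.grid_preset: must be 'default' or 'compact'")
    if cfg.dwt_levels < 2:
        raise ConfigError("features.dwt_levels: must be >= 2")
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_seconds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)  # path -> sha256

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_all(config: ExperimentConfig, out_dir) -> tuple[RunManifest, "EvaluationReport"]:
    """Execute simulate -> preprocess -> features -> train/evaluate.

    Writes the archived config, the feature table CSV, the evaluation report
    (JSON + summary CSV + confusion-matrix figure) and a manifest with
    checksums. Re-running with the same config reproduces the report
    bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        version=__version__,
    )
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))

    protocol = make_default_protocol(config.total_resting_seconds,
                                     config.photic_seconds,
                                     config.hyperventilation_seconds)
    bands = default_band_set(config.fs, wavelet=config.wavelet,
                             levels=config.dwt_levels)

    t0 = time.perf_counter()
    profiles = draw_subject_profiles(config.n_mdd, config.n_healthy,
                                     stage_seed(config.seed, "simulate"))
    recordings = []
    for prof in profiles:
        rec = synth_recording(prof, spectral=config.spectral,
                              protocol=protocol, artifacts=config.artifacts,
                              fs=config.fs)
        recordings.append(rec)
    if config.write_edf:
        from .edf import write_edf
        edf_dir = out / "edf"
        edf_dir.mkdir(exist_ok=True)
        rows = ["subject_id,group,age,sex,path"]
        for rec in recordings:
            p = edf_dir / f"{rec.subject_id}.edf"
            write_edf(rec, p)
            rows.append(f"{rec.subject_id},{rec.group},{rec.age},{rec.sex},"
                        f"{p.relative_to(out)}")
        (out / "cohort_manifest.csv").write_text("\n".join(rows) + "\n")
    manifest.stage_seconds["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pp_seed = stage_seed(config.seed, "preprocess")
    logs = []
    vectors = []
    for i, rec in enumerate(recordings):
        clean, log = preprocess_recording(
            rec, low=config.filter_low, high=config.filter_high,
            drop_policy=config.drop_policy, seed=(pp_seed + i) % (2**31))
        logs.append(log)
        segments = extract_resting_periods(clean)
        vectors.append(features_for_subject(
            segments, bands=bands, entropy_blocks=config.entropy_blocks,
            group=rec.group))
    with open(out / "preprocess_log.jsonl", "w") as fh:
        for log in logs:
            fh.write(json.dumps(log) + "\n")
    manifest.stage_seconds["preprocess+features"] = time.perf_counter() - t0

    table = build_feature_table(vectors)
    write_feature_table(table, out / "features.csv")

    t0 = time.perf_counter()
    from .modeling import compact_model_grids, default_model_grids
    grids = (compact_model_grids() if config.grid_preset == "compact"
             else default_model_grids())
    report = run_experiment(table, seed=stage_seed(config.seed, "model"),
                            k=config.top_k, test_size=config.test_size,
                            folds=config.cv_folds, grids=grids)
    manifest.stage_seconds["model"] = time.perf_counter() - t0

    report.to_json(out / "report.json")
    report.summary_table().to_csv(out / "results_table.csv")
    report.plot_confusions(out / "confusion_matrices.png")

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.files[str(p.relative_to(out))] = _sha256(p)
    manifest.to_json(out / "manifest.json")
    return manifest, report
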